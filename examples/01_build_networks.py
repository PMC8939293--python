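"""Build species, female, and male interaction networks from specimen records.

Generates a small synthetic museum collection, filters it the way the real
records are filtered (unsexed or incompletely labelled specimens dropped),
and tabulates one origin into plant x visitor count matrices.
"""

from sexnest import (
    SyntheticConfig,
    build_matrix,
    filter_records,
    generate_study,
    partition_by_origin,
    sex_composition,
)

config = SyntheticConfig(
    n_origins=2, n_specimens_per_origin=300, n_visitor_species=80,
    n_plants=20, master_seed=42,
)
study = generate_study(config)
records = [r for recs in study.values() for r in recs]
kept, report = filter_records(records)
print(f"{report.kept} of {report.total} records kept after filtering")

for origin, recs in partition_by_origin(kept).items():
    comp = sex_composition(recs)
    print(f"\norigin {origin}: {len(recs)} specimens")
    for ntype in ("species", "female", "male"):
        m = build_matrix(recs, ntype, origin=origin)
        print(f"  {ntype:8s} network: {m.shape[0]} plants x {m.shape[1]} visitors, "
              f"{m.total} interactions")
    pf, pm, pb = comp.proportions
    print(f"  visitor species all-female {pf:.0%}, all-male {pm:.0%}, both {pb:.0%}")

# The female and male matrices cell-wise sum to the species matrix; species
# collected as a single specimen are necessarily single-sex, so rare species
# inflate the single-sex fractions.
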