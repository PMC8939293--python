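"""Synthetic specimen-record generator: mechanism encoding and sampling."""

import numpy as np
import pytest
from scipy import stats as sps

from sexnest.records import build_matrix, sex_composition
from sexnest.simulate import (
    SyntheticConfig,
    generate_community,
    generate_study,
    simulate_specimens,
)


def small_config(**kw):
    defaults = dict(
        n_plants=10, n_visitor_species=20, n_specimens_per_origin=100,
        n_origins=3, master_seed=1,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestGenerateCommunity:
    def test_fully_neutral_male_tracks_plant_abundance(self):
        cfg = small_config(neutrality_male=1.0)
        com = generate_community(cfg, origin_seed=42)
        assert np.allclose(com.choice_male, com.plant_abundance[None, :])

    def test_zero_neutrality_female_equals_preference(self):
        cfg = small_config(neutrality_female=0.0)
        com = generate_community(cfg, origin_seed=42)
        assert np.allclose(com.choice_female, com.preferences)

    def test_large_concentration_approaches_uniform_preferences(self):
        cfg = small_config(preference_concentration=1e6)
        com = generate_community(cfg, origin_seed=0)
        assert np.allclose(com.preferences, 1.0 / cfg.n_plants, atol=1e-2)

    def test_distributions_normalized(self):
        com = generate_community(small_config(), origin_seed=5)
        assert com.plant_abundance.sum() == pytest.approx(1.0)
        assert np.allclose(com.choice_female.sum(axis=1), 1.0)
        assert np.allclose(com.choice_male.sum(axis=1), 1.0)


class TestSimulateSpecimens:
    def test_zero_specimens(self):
        cfg = small_config(n_specimens_per_origin=0)
        com = generate_community(cfg, 1)
        assert simulate_specimens(com, cfg, 1) == []

    def test_single_plant_forces_all_records(self):
        cfg = small_config(n_plants=1)
        com = generate_community(cfg, 2)
        records = simulate_specimens(com, cfg, 2)
        assert {r.plant_taxon for r in records} == {"Plant_000"}

    def test_deterministic_given_seed(self):
        cfg = small_config()
        com = generate_community(cfg, 3)
        assert simulate_specimens(com, cfg, 3) == simulate_specimens(com, cfg, 3)

    def test_plant_frequencies_converge_to_choice_distribution(self):
        """LLN check: one abundant species' empirical plant visits match its
        choice distribution (chi-squared goodness of fit not rejected)."""
        cfg = SyntheticConfig(
            n_plants=6, n_visitor_species=1, n_specimens_per_origin=50_000,
            n_origins=1, female_fraction=1.0, neutrality_female=0.3,
            master_seed=9,
        )
        com = generate_community(cfg, 11)
        records = simulate_specimens(com, cfg, 11)
        counts = np.zeros(cfg.n_plants)
        for r in records:
            counts[int(r.plant_taxon.split("_")[1])] += 1
        expected = com.choice_female[0] * len(records)
        _, p = sps.chisquare(counts, expected)
        assert p > 0.01


class TestGenerateStudy:
    def test_origin_count_and_conservation(self):
        cfg = small_config(n_origins=11)
        study = generate_study(cfg)
        assert len(study) == 11
        assert sum(len(v) for v in study.values()) == 11 * cfg.n_specimens_per_origin

    def test_bit_identical_on_rerun(self):
        cfg = small_config()
        assert generate_study(cfg) == generate_study(cfg)

    def test_records_flow_through_network_builder(self):
        cfg = small_config()
        study = generate_study(cfg)
        origin, records = next(iter(study.items()))
        m = build_matrix(records, "species", origin=origin)
        assert m.total == len(records)

    def test_sex_ratio_near_configured_fraction(self):
        cfg = small_config(n_specimens_per_origin=2000, female_fraction=0.625)
        study = generate_study(cfg)
        records = [r for v in study.values() for r in v]
        frac = sum(r.sex == "female" for r in records) / len(records)
        assert frac == pytest.approx(0.625, abs=0.03)


class TestSexPolarization:
    def test_both_sex_fraction_increases_with_sampling_effort(self):
        """More specimens per species -> more species observed in both sexes."""
        fractions = []
        for n_spec in (100, 2000):
            cfg = SyntheticConfig(
                n_plants=10, n_visitor_species=30, n_specimens_per_origin=n_spec,
                n_origins=1, female_fraction=0.5, master_seed=31,
            )
            records = next(iter(generate_study(cfg).values()))
            comp = sex_composition(records)
            fractions.append(comp.both / comp.total_species)
        assert fractions[0] < fractions[1]

    def test_high_richness_low_effort_gives_mostly_single_sex_species(self):
        """With many rare species, most visitor species are sex-polarized."""
        study = generate_study(SyntheticConfig(master_seed=17))
        both_fracs = []
        for records in study.values():
            comp = sex_composition(records)
            both_fracs.append(comp.both / comp.total_species)
        assert np.mean(both_fracs) < 0.5


def test_matched_neutrality_gives_no_artifactual_sex_effect():
    """With equal neutrality, shared preferences and a 1:1 sex ratio, the
    female-male z difference is sampling noise only (paired t-test)."""
    from sexnest.nulls import derive_seed, standardize
    from scipy import stats as scstats

    cfg = SyntheticConfig(
        neutrality_female=0.5, neutrality_male=0.5, female_fraction=0.5,
        n_plants=15, n_visitor_species=60, n_specimens_per_origin=300,
        n_origins=8, master_seed=29,
    )
    diffs = []
    for origin, records in generate_study(cfg).items():
        z = {}
        for sex in ("female", "male"):
            m = build_matrix(records, sex, origin=origin)
            seed = derive_seed(cfg.master_seed, *origin, sex)
            z[sex] = standardize(m, "wnodf", n_nulls=100, seed=seed)["wnodf"].z
        diffs.append(z["male"] - z["female"])
    _, p = scstats.ttest_1samp(diffs, 0.0)
    assert p > 0.01


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(female_fraction=1.5)
    with pytest.raises(ValueError):
        SyntheticConfig(n_plants=0)
    with pytest.raises(ValueError):
        SyntheticConfig(preference_concentration=0.0)
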