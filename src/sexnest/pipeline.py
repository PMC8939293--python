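"""End-to-end orchestration: records -> networks -> indices -> comparisons.

A run is configured by :class:`RunConfig` (YAML-serializable), executes
deterministically under a master seed, and writes every output file into an
inventory manifest together with the seed that produced it. Per-network
null seeds are derived from the master seed and the (site, year, type) key,
so any single standardization is reproducible in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metrics import connectance, network_size
from .nulls import derive_seed, standardize
from .records import (
    EmptyNetworkError,
    NETWORK_TYPES,
    build_matrix,
    filter_records,
    partition_by_origin,
    read_records,
    sex_composition,
)
from .simulate import DEFAULT_COLUMN_MAP, SyntheticConfig, generate_study
from .stats import compare_index, compare_sex_composition, covariate_model

logger = logging.getLogger(__name__)

#: Metrics standardized against nulls in a default run.
DEFAULT_Z_METRICS = [
    "wnodf",
    "niche_overlap_visitor",
    "niche_overlap_plant",
    "partner_diversity_visitor",
    "partner_diversity_plant",
]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``records_path`` (a specimen CSV/TSV) or ``synthetic``
    (a generator configuration) supplies the input. Defaults reproduce the
    reference analysis settings: 1000 fixed-margin nulls per network and a
    Bonferroni-corrected pairwise threshold of 0.05/3.
    """

    outdir: str | Path = "sexnest_run"
    records_path: str | Path | None = None
    column_map: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))
    synthetic: SyntheticConfig | None = None
    n_nulls: int = 1000
    master_seed: int = 0
    z_metrics: list[str] = field(default_factory=lambda: list(DEFAULT_Z_METRICS))
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if (self.records_path is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of records_path or synthetic")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        syn = raw.pop("synthetic", None)
        if syn is not None:
            syn = SyntheticConfig.from_dict(syn)
        return cls(synthetic=syn, **raw)

    def to_dict(self) -> dict:
        d = {
            "outdir": str(self.outdir),
            "records_path": str(self.records_path) if self.records_path else None,
            "column_map": dict(self.column_map),
            "n_nulls": self.n_nulls,
            "master_seed": self.master_seed,
            "z_metrics": list(self.z_metrics),
            "alpha": self.alpha,
        }
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d


def _origin_key(origin: tuple[str, int]) -> str:
    return f"{origin[0]}_{origin[1]}"


def build_index_table(
    origins: dict,
    n_nulls: int,
    master_seed: int,
    z_metrics: list[str],
) -> pd.DataFrame:
    """Standardize every network of every origin; tidy long-format result.

    Returns one row per (origin, network_type, metric) with observed value,
    null mean/sd, z, and the seed used. Raw connectance and network size
    (not standardized) are included with empty null columns.
    """
    rows = []
    for origin, records in origins.items():
        for ntype in NETWORK_TYPES:
            try:
                matrix = build_matrix(records, ntype, origin=origin)
            except EmptyNetworkError:
                logger.warning("origin %s has no %s network; skipped", origin, ntype)
                continue
            seed = derive_seed(master_seed, origin[0], origin[1], ntype)
            t0 = time.time()
            std = standardize(matrix, z_metrics, n_nulls=n_nulls, seed=seed)
            logger.info(
                "standardized origin=%s type=%s (%.1fs, seed=%d)",
                origin, ntype, time.time() - t0, seed,
            )
            base = {
                "site": origin[0],
                "year": origin[1],
                "origin": _origin_key(origin),
                "network_type": ntype,
            }
            for name, si in std.items():
                rows.append({
                    **base, "metric": name, "observed": si.observed,
                    "null_mean": si.null_mean, "null_sd": si.null_sd, "z": si.z,
                    "n_nulls": si.n_nulls, "n_undefined": si.n_undefined,
                    "seed": si.seed,
                })
            for name, value in [
                ("connectance", connectance(matrix)),
                ("network_size", float(network_size(matrix))),
            ]:
                rows.append({
                    **base, "metric": name, "observed": value,
                    "null_mean": np.nan, "null_sd": np.nan, "z": np.nan,
                    "n_nulls": 0, "n_undefined": 0, "seed": seed,
                })
    return pd.DataFrame(rows)


def unify_partner_diversity(indices: pd.DataFrame) -> pd.DataFrame:
    """Collapse visitor- and plant-level partner-diversity z into one metric.

    Under shared fixed-margin nulls the two z-scores coincide (the raw
    values differ by a margins-only constant), so they are reported as the
    single metric ``partner_diversity`` carrying the visitor-level rows.
    """
    vis = indices[indices["metric"] == "partner_diversity_visitor"].copy()
    vis["metric"] = "partner_diversity"
    return pd.concat([indices, vis], ignore_index=True)


def run_comparisons(indices: pd.DataFrame, compositions: pd.DataFrame,
                    alpha: float = 0.05) -> dict:
    """All cross-network-type comparisons on a tidy index table."""
    out: dict = {}
    for metric in ["wnodf", "niche_overlap_visitor", "niche_overlap_plant",
                   "partner_diversity"]:
        sub = indices[indices["metric"] == metric]
        if sub["z"].notna().sum() < 6:
            continue
        res = compare_index(sub, value_col="z", response_name=f"z_{metric}",
                            alpha=alpha)
        out[f"z_{metric}"] = res.to_dict()
    if compositions is not None and len(compositions):
        out["sex_composition"] = compare_sex_composition(
            compositions, alpha=alpha
        ).to_dict()
    # covariate models: does size/connectance explain the swNODF differences?
    wn = indices[indices["metric"] == "wnodf"][
        ["origin", "network_type", "z"]
    ]
    for cov in ["network_size", "connectance"]:
        cv = indices[indices["metric"] == cov][
            ["origin", "network_type", "observed"]
        ].rename(columns={"observed": cov})
        merged = wn.merge(cv, on=["origin", "network_type"])
        if len(merged) >= 9:
            out[f"swnodf_vs_{cov}"] = covariate_model(
                merged, covariate_col=cov, value_col="z"
            ).to_dict()
    return out


def composition_table(origins: dict) -> pd.DataFrame:
    """Long-format sex-composition counts, one row per origin and category."""
    rows = []
    for origin, records in origins.items():
        comp = sex_composition(records)
        for category, count in [("all_female", comp.all_female),
                                ("all_male", comp.all_male),
                                ("both", comp.both)]:
            rows.append({
                "site": origin[0], "year": origin[1],
                "origin": _origin_key(origin), "category": category,
                "count": count, "total": comp.total_species,
            })
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run manifest.

    Stages: load or simulate specimen records, filter, partition by origin,
    build species/female/male matrices (written as TSV), standardize the
    configured metrics against shared fixed-margin nulls, compare network
    types, and write a manifest listing every output with its seed.
    """
    outdir = Path(config.outdir)
    if config.records_path is not None and not Path(config.records_path).exists():
        raise FileNotFoundError(config.records_path)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": [],
        "files": [],
    }

    def _record(stage: str, path: Path | None = None) -> None:
        manifest["stages"].append(stage)
        if path is not None:
            manifest["files"].append(str(path.relative_to(outdir)))

    try:
        if config.records_path is not None:
            records = read_records(config.records_path, config.column_map)
        else:
            study = generate_study(config.synthetic)
            records = [r for recs in study.values() for r in recs]
        _record("load")

        kept, report = filter_records(records)
        report_path = outdir / "filter_report.json"
        report.to_json(report_path)
        _record("filter", report_path)

        origins = partition_by_origin(kept)
        matdir = outdir / "matrices"
        matdir.mkdir(exist_ok=True)
        for origin, recs in origins.items():
            for ntype in NETWORK_TYPES:
                try:
                    m = build_matrix(recs, ntype, origin=origin)
                except EmptyNetworkError:
                    continue
                p = matdir / f"{_origin_key(origin)}_{ntype}.tsv"
                m.to_tsv(p)
                _record(f"matrix:{_origin_key(origin)}:{ntype}", p)

        indices = build_index_table(
            origins, config.n_nulls, config.master_seed, config.z_metrics
        )
        indices = unify_partner_diversity(indices)
        idx_path = outdir / "indices.csv"
        indices.to_csv(idx_path, index=False)
        _record("standardize", idx_path)

        comps = composition_table(origins)
        comp_path = outdir / "sex_composition.csv"
        comps.to_csv(comp_path, index=False)
        _record("sex_composition", comp_path)

        comparisons = run_comparisons(indices, comps, alpha=config.alpha)
        cmp_path = outdir / "comparisons.json"
        cmp_path.write_text(json.dumps(comparisons, indent=2))
        _record("compare", cmp_path)
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2))
    return manifest
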