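"""Specimen records and interaction matrices.

A specimen record is one collected insect: the visitor taxon, its sex, the
plant it was netted on, and the collection site and year. Records are
filtered (incomplete labels and unsexed specimens discarded), partitioned by
network origin (site, year), and tabulated into plant x visitor count
matrices — one species network per origin plus its female and male
subnetworks.
"""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEMALE = "female"
MALE = "male"
UNKNOWN = "unknown"

#: Default case-insensitive synonym table for sex labels.
DEFAULT_SEX_SYNONYMS: dict[str, str] = {
    "f": FEMALE,
    "female": FEMALE,
    "m": MALE,
    "male": MALE,
    "u": UNKNOWN,
    "unknown": UNKNOWN,
    "": UNKNOWN,
    "?": UNKNOWN,
}

NETWORK_TYPES = ("species", "female", "male")


class ConfigurationError(ValueError):
    """A column mapping or config file does not match the input."""


class EmptyNetworkError(ValueError):
    """No records survive the requested sex filter for an origin."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One collected flower-visiting insect."""

    visitor_taxon: str
    sex: str  # "female" | "male" | "unknown"
    plant_taxon: str
    site: str
    year: int | None
    date: str | None = None


@dataclass
class FilterReport:
    """Counts of records discarded per reason during filtering."""

    kept: int = 0
    discarded: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return self.kept + sum(self.discarded.values())

    def to_json(self, path: str | Path) -> None:
        payload = {"kept": self.kept, "discarded": dict(self.discarded)}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


@dataclass
class InteractionMatrix:
    """Plant x visitor count matrix for one (site, year) and network type.

    Rows are plant taxa, columns visitor taxa, cells the number of individual
    visitors of that taxon collected on that plant. Species with no
    interactions under the sex filter are excluded, so every row and column
    sum is at least 1.
    """

    plants: list[str]
    visitors: list[str]
    counts: np.ndarray  # (len(plants), len(visitors)) non-negative ints
    origin: tuple[str, int] | None = None
    network_type: str = "species"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.plants), len(self.visitors)):
            raise ValueError("counts shape does not match taxon lists")
        if (self.counts < 0).any():
            raise ValueError("negative interaction count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.plants, columns=self.visitors)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "plant"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        origin: tuple[str, int] | None = None,
        network_type: str = "species",
    ) -> "InteractionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            plants=[str(p) for p in df.index],
            visitors=[str(v) for v in df.columns],
            counts=df.to_numpy(dtype=np.int64),
            origin=origin,
            network_type=network_type,
        )


@dataclass(frozen=True)
class SexComposition:
    """Per-network counts of single-sex and both-sex visitor species."""

    all_female: int
    all_male: int
    both: int

    @property
    def total_species(self) -> int:
        return self.all_female + self.all_male + self.both

    @property
    def proportions(self) -> tuple[float, float, float]:
        n = self.total_species
        return (self.all_female / n, self.all_male / n, self.both / n)


def _normalize_sex(raw: object, synonyms: Mapping[str, str]) -> str | None:
    """Map a raw sex label to female/male/unknown; None if unrecognized."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return UNKNOWN
    return synonyms.get(str(raw).strip().lower())


def read_records(
    path: str | Path,
    column_map: Mapping[str, str],
    sex_synonyms: Mapping[str, str] | None = None,
) -> list[SpecimenRecord]:
    """Read specimen records from a delimited table.

    Parameters
    ----------
    path
        CSV or TSV file with a header row. The delimiter is taken from the
        extension (``.tsv``/``.txt`` → tab, otherwise comma).
    column_map
        Mapping of logical field name (``visitor``, ``sex``, ``plant``,
        ``site``, ``year``; optionally ``date``) to the column name in the
        file. Extra file columns are ignored.
    sex_synonyms
        Case-insensitive raw-label → {female, male, unknown} table;
        defaults to :data:`DEFAULT_SEX_SYNONYMS`.

    Raises
    ------
    ConfigurationError
        If a mapped column is absent from the header.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    required = ["visitor", "sex", "plant", "site", "year"]
    for logical in required:
        if logical not in column_map:
            raise ConfigurationError(f"column_map missing logical field {logical!r}")
        if column_map[logical] not in df.columns:
            raise ConfigurationError(
                f"mapped column {column_map[logical]!r} (for {logical!r}) "
                f"not found in {path.name}; header has {list(df.columns)}"
            )
    date_col = column_map.get("date")
    synonyms = {k.lower(): v for k, v in (sex_synonyms or DEFAULT_SEX_SYNONYMS).items()}

    records: list[SpecimenRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        sex = _normalize_sex(row[column_map["sex"]], synonyms)
        if sex is None:
            skipped += 1
            continue
        year_raw = str(row[column_map["year"]]).strip()
        year: int | None
        if year_raw == "":
            year = None
        else:
            try:
                year = int(float(year_raw))
            except ValueError:
                skipped += 1
                continue
        records.append(
            SpecimenRecord(
                visitor_taxon=str(row[column_map["visitor"]]).strip(),
                sex=sex,
                plant_taxon=str(row[column_map["plant"]]).strip(),
                site=str(row[column_map["site"]]).strip(),
                year=year,
                date=str(row[date_col]).strip() if date_col else None,
            )
        )
    if skipped:
        logger.warning("read_records: skipped %d unparseable rows in %s", skipped, path)
    return records


def filter_records(
    records: Iterable[SpecimenRecord],
) -> tuple[list[SpecimenRecord], FilterReport]:
    """Apply the dataset-assembly filters.

    Discards records lacking a visitor taxon, plant taxon, site or year
    (incomplete labels) and records whose sex is not female or male.
    Genus-level labels (e.g. ``"Lasioglossum sp."``) are retained as
    distinct taxa. Returns the kept records and a per-reason report.
    """
    kept: list[SpecimenRecord] = []
    report = FilterReport()
    for rec in records:
        if not rec.visitor_taxon:
            report.discarded["no_visitor"] += 1
        elif not rec.plant_taxon:
            report.discarded["no_plant"] += 1
        elif not rec.site:
            report.discarded["no_site"] += 1
        elif rec.year is None:
            report.discarded["no_year"] += 1
        elif rec.sex not in (FEMALE, MALE):
            report.discarded["sex_unidentified"] += 1
        else:
            kept.append(rec)
    report.kept = len(kept)
    return kept, report


def partition_by_origin(
    records: Iterable[SpecimenRecord],
) -> dict[tuple[str, int], list[SpecimenRecord]]:
    """Group filtered records by network origin (site, year).

    Origins are returned in sorted order; empty origins never appear.
    """
    groups: dict[tuple[str, int], list[SpecimenRecord]] = defaultdict(list)
    for rec in records:
        groups[(rec.site, rec.year)].append(rec)
    return dict(sorted(groups.items()))


def build_matrix(
    records: Sequence[SpecimenRecord],
    sex_filter: str = "species",
    origin: tuple[str, int] | None = None,
) -> InteractionMatrix:
    """Tabulate one origin's records into a count matrix.

    ``sex_filter="species"`` pools both sexes; ``"female"``/``"male"``
    restrict to one sex (the subnetworks). Taxa are ordered
    lexicographically; metric values must not depend on this ordering.

    Raises :class:`EmptyNetworkError` if no record passes the sex filter.
    """
    if sex_filter not in NETWORK_TYPES:
        raise ValueError(f"sex_filter must be one of {NETWORK_TYPES}")
    if sex_filter == "species":
        selected = list(records)
    else:
        selected = [r for r in records if r.sex == sex_filter]
    if not selected:
        raise EmptyNetworkError(
            f"no records for origin={origin!r} sex_filter={sex_filter!r}"
        )
    if origin is None:
        origins = {(r.site, r.year) for r in selected}
        if len(origins) == 1:
            origin = next(iter(origins))

    plants = sorted({r.plant_taxon for r in selected})
    visitors = sorted({r.visitor_taxon for r in selected})
    p_idx = {p: i for i, p in enumerate(plants)}
    v_idx = {v: j for j, v in enumerate(visitors)}
    counts = np.zeros((len(plants), len(visitors)), dtype=np.int64)
    for rec in selected:
        counts[p_idx[rec.plant_taxon], v_idx[rec.visitor_taxon]] += 1
    return InteractionMatrix(
        plants=plants,
        visitors=visitors,
        counts=counts,
        origin=origin,
        network_type=sex_filter,
    )


def sex_composition(records: Sequence[SpecimenRecord]) -> SexComposition:
    """Classify each visitor species as all-female, all-male, or both-sex."""
    sexes: dict[str, set[str]] = defaultdict(set)
    for rec in records:
        sexes[rec.visitor_taxon].add(rec.sex)
    all_female = sum(1 for s in sexes.values() if s == {FEMALE})
    all_male = sum(1 for s in sexes.values() if s == {MALE})
    both = sum(1 for s in sexes.values() if FEMALE in s and MALE in s)
    return SexComposition(all_female=all_female, all_male=all_male, both=both)
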