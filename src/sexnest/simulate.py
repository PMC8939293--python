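"""Synthetic specimen-record generator.

Emulates a museum collection of flower-visiting insects with the
statistical structure the analysis assumes: heavy-tailed (log-normal)
abundance distributions for plants and visitor species (hence many
singleton visitors), a visitor sex ratio, and sex-specific visitation
rules. Each visitor species carries a Dirichlet preference vector over
plants; the realized flower-choice distribution of each sex is the convex
mixture

    choice = lambda * (plant relative abundance) + (1 - lambda) * preference

where ``lambda`` is the sex's *neutrality*: 1 means visits track encounter
probability alone (the null-model expectation), 0 means pure preference.
The headline mechanism scenario sets male neutrality to 1 and female
neutrality to 0 with concentrated preferences — males behave like the
fixed-margin null, females build specialized, less nested structure.

Sampling into specimen records mirrors netting along a census route: each
captured individual is one record naming the plant it was taken on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .records import FEMALE, MALE, SpecimenRecord


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-level parameters of the generator.

    Defaults mirror the empirical study's conditions: 11 origins of roughly
    474 specimens each (5212 total over 11 site-year datasets), a 3256:1956
    female:male specimen split (female fraction ~0.625), a heavy-tailed
    visitor abundance distribution with many singleton species and a
    majority of species observed in a single sex, fully neutral males and
    preference-driven females. Richness is kept moderate relative to
    specimen count: because per-species preferences are drawn independently,
    the female under-nestedness mechanism requires enough multi-specimen
    species to express diet concentration (see the methods note).
    """

    n_plants: int = 40
    n_visitor_species: int = 250
    plant_abundance_shape: float = 1.5  # log-normal sigma
    visitor_abundance_shape: float = 2.0
    female_fraction: float = 0.625
    neutrality_female: float = 0.0  # lambda_F
    neutrality_male: float = 1.0  # lambda_M
    preference_concentration: float = 0.1  # Dirichlet alpha per plant
    n_specimens_per_origin: int = 474
    n_origins: int = 11
    master_seed: int = 20220322

    def __post_init__(self) -> None:
        for name in ("n_plants", "n_visitor_species", "n_origins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_specimens_per_origin < 0:
            raise ValueError("n_specimens_per_origin must be >= 0")
        for name in ("female_fraction", "neutrality_female", "neutrality_male"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.preference_concentration <= 0:
            raise ValueError("preference_concentration must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        return cls(**dict(d))


@dataclass
class Community:
    """One origin's latent community."""

    plant_names: list[str]
    plant_abundance: np.ndarray  # relative, sums to 1
    visitor_names: list[str]
    visitor_abundance: np.ndarray  # relative, sums to 1
    choice_female: np.ndarray  # (n_visitors, n_plants), rows sum to 1
    choice_male: np.ndarray
    preferences: np.ndarray = field(repr=False, default=None)


def _lognormal_relative(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    a = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return a / a.sum()


def generate_community(config: SyntheticConfig, origin_seed: int) -> Community:
    """Draw one origin's plants, visitor species, and choice distributions."""
    rng = np.random.default_rng(origin_seed)
    plant_ab = _lognormal_relative(config.n_plants, config.plant_abundance_shape, rng)
    visitor_ab = _lognormal_relative(
        config.n_visitor_species, config.visitor_abundance_shape, rng
    )
    prefs = rng.dirichlet(
        np.full(config.n_plants, config.preference_concentration),
        size=config.n_visitor_species,
    )
    lam_f = config.neutrality_female
    lam_m = config.neutrality_male
    choice_f = lam_f * plant_ab[None, :] + (1.0 - lam_f) * prefs
    choice_m = lam_m * plant_ab[None, :] + (1.0 - lam_m) * prefs
    return Community(
        plant_names=[f"Plant_{i:03d}" for i in range(config.n_plants)],
        plant_abundance=plant_ab,
        visitor_names=[f"Visitor_{j:04d}" for j in range(config.n_visitor_species)],
        visitor_abundance=visitor_ab,
        choice_female=choice_f,
        choice_male=choice_m,
        preferences=prefs,
    )


def simulate_specimens(
    community: Community,
    config: SyntheticConfig,
    origin_seed: int,
    site: str = "SiteA",
    year: int = 2000,
) -> list[SpecimenRecord]:
    """Sample one origin's specimen records from its community.

    Each record: visitor species drawn proportional to species abundance,
    sex Bernoulli(female_fraction), plant drawn from that species-sex
    choice distribution. Deterministic given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([origin_seed, 1]))
    n = config.n_specimens_per_origin
    if n == 0:
        return []
    species = rng.choice(
        config.n_visitor_species, size=n, p=community.visitor_abundance
    )
    is_female = rng.random(n) < config.female_fraction
    records: list[SpecimenRecord] = []
    for j, fem in zip(species, is_female):
        choice = community.choice_female[j] if fem else community.choice_male[j]
        plant = rng.choice(config.n_plants, p=choice)
        records.append(
            SpecimenRecord(
                visitor_taxon=community.visitor_names[j],
                sex=FEMALE if fem else MALE,
                plant_taxon=community.plant_names[plant],
                site=site,
                year=year,
            )
        )
    return records


def generate_study(
    config: SyntheticConfig,
) -> dict[tuple[str, int], list[SpecimenRecord]]:
    """Generate a full multi-origin study of specimen records.

    Each origin gets an independent community and sample, with child seeds
    derived from the master seed; the output schema matches the record
    reader's, so the full pipeline runs end-to-end on the result.
    """
    ss = np.random.SeedSequence(config.master_seed)
    origin_seeds = [int(s & 0x7FFFFFFF) for s in ss.generate_state(config.n_origins)]
    study: dict[tuple[str, int], list[SpecimenRecord]] = {}
    for k, seed in enumerate(origin_seeds):
        site = f"Site{k % 3 + 1}"
        year = 2000 + k // 3
        community = generate_community(config, seed)
        study[(site, year)] = simulate_specimens(
            community, config, seed, site=site, year=year
        )
    return study


def records_to_csv(study, path) -> None:
    """Write a study to a specimen CSV with the standard column schema."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["visitor_taxon", "sex", "plant_taxon", "site", "year"])
        for (_, _), records in sorted(study.items()):
            for r in records:
                writer.writerow([r.visitor_taxon, r.sex, r.plant_taxon, r.site, r.year])


#: Column map matching :func:`records_to_csv` output.
DEFAULT_COLUMN_MAP = {
    "visitor": "visitor_taxon",
    "sex": "sex",
    "plant": "plant_taxon",
    "site": "site",
    "year": "year",
}
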