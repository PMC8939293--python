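"""Fixed-marginal null models and z-score standardization.

The null universe for a count network is the set of integer tables with the
observed row and column sums, weighted by the multiple hypergeometric
distribution — the expectation under purely encounter-probability-driven
interactions. Tables are drawn with the Patefield (r2d) algorithm; an
independent multiset pairing shuffle is provided as a distributional oracle.

An observed index is standardized as z = (obs - mean(nulls)) / sd(nulls)
over a set of null networks (1000 by default). Within one network a single
null set (one seed) serves all metrics, so that indices differing only by a
margins-determined constant (visitor- and plant-level partner diversity)
receive identical z-scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .metrics import METRIC_FUNCTIONS, UndefinedMetricError
from .records import InteractionMatrix


@dataclass(frozen=True)
class StandardizedIndex:
    """A raw metric value with its null distribution and z-score."""

    metric: str
    observed: float
    null_mean: float
    null_sd: float
    z: float  # NaN when the null sd is zero (degenerate margins)
    n_nulls: int
    n_undefined: int  # null draws on which the metric was undefined
    seed: int

    @property
    def z_defined(self) -> bool:
        return not math.isnan(self.z)


def _check_margins(row_margins, col_margins) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(row_margins, dtype=np.int64)
    c = np.asarray(col_margins, dtype=np.int64)
    if (r <= 0).any() or (c <= 0).any():
        raise ValueError("margins must be positive")
    if r.sum() != c.sum():
        raise ValueError(f"margin sums differ: {r.sum()} != {c.sum()}")
    return r, c


def patefield_sample(
    row_margins, col_margins, rng: np.random.Generator
) -> np.ndarray:
    """Draw one random count table with exactly the given margins (r2d).

    Samples from the multiple hypergeometric distribution on tables with
    the given row and column sums, via the Patefield algorithm.
    """
    r, c = _check_margins(row_margins, col_margins)
    if len(r) == 1 or len(c) == 1:  # forced table; scipy's patefield degenerates
        return np.outer(r, c) // r.sum()
    return sps.random_table(r, c).rvs(method="patefield", random_state=rng).astype(
        np.int64
    )


def shuffle_pairing_sample(
    row_margins, col_margins, rng: np.random.Generator
) -> np.ndarray:
    """Independent oracle for :func:`patefield_sample`.

    Builds the table by writing S row labels (each row i repeated r_i times)
    against a random permutation of S column labels, then tabulating the
    pairs. This is distributionally identical to Patefield sampling.
    """
    r, c = _check_margins(row_margins, col_margins)
    row_labels = np.repeat(np.arange(len(r)), r)
    col_labels = np.repeat(np.arange(len(c)), c)
    rng.shuffle(col_labels)
    table = np.zeros((len(r), len(c)), dtype=np.int64)
    np.add.at(table, (row_labels, col_labels), 1)
    return table


def derive_seed(master_seed: int, *keys) -> int:
    """Deterministic child seed (< 2**31) from a master seed and hashable keys.

    Uses numpy's SeedSequence spawn-key mechanism on a stable string digest
    of the keys, so any single network's standardization is reproducible in
    isolation.
    """
    digest = [ord(ch) for ch in "|".join(str(k) for k in keys)]
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF] + digest)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def standardize(
    matrix,
    metrics: str | list[str] = "wnodf",
    n_nulls: int = 1000,
    seed: int = 0,
) -> dict[str, StandardizedIndex]:
    """z-standardize one or more indices against shared fixed-margin nulls.

    Parameters
    ----------
    matrix
        Observed count matrix (``InteractionMatrix`` or array).
    metrics
        A metric name or list of names from
        :data:`sexnest.metrics.METRIC_FUNCTIONS`.
    n_nulls
        Number of Patefield null networks (>= 2). All requested metrics are
        evaluated on the *same* null set.
    seed
        Seed for the null generator; recorded in every result.

    Null draws on which a metric is undefined are excluded from its null
    mean/sd and counted in ``n_undefined``. When the null sd is zero the
    z-score is reported as NaN rather than +/-infinity.
    """
    if isinstance(metrics, str):
        metrics = [metrics]
    unknown = set(metrics) - set(METRIC_FUNCTIONS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    if n_nulls < 2:
        raise ValueError("n_nulls must be >= 2")

    X = matrix.counts if isinstance(matrix, InteractionMatrix) else np.asarray(matrix)
    r = X.sum(axis=1).astype(np.int64)
    c = X.sum(axis=0).astype(np.int64)
    observed = {name: float(METRIC_FUNCTIONS[name](X)) for name in metrics}

    rng = np.random.default_rng(seed)
    null_values: dict[str, list[float]] = {name: [] for name in metrics}
    n_undef = {name: 0 for name in metrics}
    degenerate = X.shape[0] == 1 or X.shape[1] == 1
    dist = None if degenerate else sps.random_table(r, c)
    for _ in range(n_nulls):
        if degenerate:  # single row or column: the table is forced
            null = np.outer(r, c) // r.sum()
        else:
            null = dist.rvs(method="patefield", random_state=rng).astype(np.int64)
        for name in metrics:
            try:
                null_values[name].append(float(METRIC_FUNCTIONS[name](null)))
            except (UndefinedMetricError, ValueError):
                n_undef[name] += 1

    out: dict[str, StandardizedIndex] = {}
    for name in metrics:
        vals = np.asarray(null_values[name])
        if vals.size >= 2:
            mu = float(vals.mean())
            sd = float(vals.std(ddof=1))
        else:
            mu, sd = float("nan"), 0.0
        z = (observed[name] - mu) / sd if sd > 0 else float("nan")
        out[name] = StandardizedIndex(
            metric=name,
            observed=observed[name],
            null_mean=mu,
            null_sd=sd,
            z=z,
            n_nulls=n_nulls,
            n_undefined=n_undef[name],
            seed=seed,
        )
    return out
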