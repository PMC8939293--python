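"""Raw bipartite network indices on count matrices.

All metrics accept either an :class:`~sexnest.records.InteractionMatrix` or a
plain 2-D array of non-negative counts with plants on rows and visitors on
columns, and are invariant to row/column permutations of the input.

Weighted NODF follows the overlap-and-decreasing-fill definition for
quantitative matrices: rows and columns are ranked by decreasing marginal
totals, and an ordered pair contributes the percentage of the smaller
member's non-empty cells holding strictly lower values than the larger
member's, provided the smaller member's marginal total is strictly smaller
(ties contribute zero).

Niche overlap is the mean, over all unordered species pairs within one
guild, of the abundance-based Jaccard similarity of Chao and colleagues,
which corrects for unseen shared species through shared singletons and
doubletons. Partner diversity is the abundance-weighted mean Shannon
entropy of per-species interaction distributions.
"""

from __future__ import annotations

import numpy as np

from .records import InteractionMatrix

VALID_LEVELS = ("visitor", "plant")


class UndefinedMetricError(ValueError):
    """The metric is not defined on this input (e.g. too few species)."""


def _as_counts(matrix) -> np.ndarray:
    if isinstance(matrix, InteractionMatrix):
        arr = matrix.counts
    else:
        arr = np.asarray(matrix)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D count matrix")
    if (arr < 0).any():
        raise ValueError("negative counts")
    return np.asarray(arr, dtype=float)


def _wnodf_half(X: np.ndarray, totals: np.ndarray) -> float:
    """Sum of 100*k_ij/N_j over ordered column pairs of X (entities on axis 1).

    Columns must already be sorted by decreasing ``totals``. A pair (i<j)
    contributes only when totals[j] < totals[i] strictly; k_ij counts the
    non-empty cells of column j whose value is strictly below column i's.
    """
    nz = X > 0
    N = nz.sum(axis=0).astype(float)  # non-empty cells per column
    # lower[r, i, j] = column j's cell r is non-empty and below column i's
    lower = (X[:, None, :] < X[:, :, None]) & nz[:, None, :]
    k = lower.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(N[None, :] > 0, 100.0 * k / N[None, :], 0.0)
    i, j = np.triu_indices(X.shape[1], k=1)
    decreasing = totals[j] < totals[i]
    return float(contrib[i[decreasing], j[decreasing]].sum())


def weighted_nodf(matrix) -> float:
    """Weighted NODF of a count matrix, in [0, 100].

    Requires at least two rows and two columns. The value is invariant to
    permutations of the input rows and columns (ranking is internal).
    """
    X = _as_counts(matrix)
    m, n = X.shape
    if m < 2 or n < 2:
        raise UndefinedMetricError(
            f"weighted NODF undefined for a {m}x{n} matrix (need >=2x2)"
        )
    row_tot = X.sum(axis=1)
    col_tot = X.sum(axis=0)
    # stable sort by decreasing marginal totals
    ro = np.argsort(-row_tot, kind="stable")
    co = np.argsort(-col_tot, kind="stable")
    Xs = X[np.ix_(ro, co)]
    wnodf_c = _wnodf_half(Xs, col_tot[co])
    wnodf_r = _wnodf_half(Xs.T, row_tot[ro])
    return 2.0 * (wnodf_c + wnodf_r) / (m * (m - 1) + n * (n - 1))


def connectance(matrix) -> float:
    """Fraction of possible plant-visitor links observed: nonzero cells / (m*n)."""
    X = _as_counts(matrix)
    if X.size == 0:
        raise ValueError("empty matrix")
    return float((X > 0).sum() / X.size)


def network_size(matrix) -> int:
    """Total species count: number of plants plus number of visitors."""
    X = _as_counts(matrix)
    return int(X.shape[0] + X.shape[1])


def chao_jaccard_similarity(x_a: np.ndarray, x_b: np.ndarray) -> float:
    """Abundance-based Jaccard similarity between two count communities.

    ``x_a`` and ``x_b`` are aligned per-species counts (same species order).
    Estimates U, the total relative abundance in A of the species shared
    with B, with the unseen-shared-species correction driven by the shared
    species that are singletons (f+1) or doubletons (f+2) in the other
    community; when f+2 = 0 the denominator uses 1 in its place. Each U is
    truncated at 1. Returns U_A*U_B / (U_A + U_B - U_A*U_B), which is 0
    when no species is shared and 1 for identical communities.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.shape != x_b.shape:
        raise ValueError("count vectors must be aligned to the same species")
    n_a = x_a.sum()
    n_b = x_b.sum()
    if n_a < 1 or n_b < 1:
        raise ValueError("each community needs at least one individual")
    shared = (x_a > 0) & (x_b > 0)
    if not shared.any():
        return 0.0

    def _u(x_self, n_self, x_other, n_other):
        f1 = int(np.sum(shared & (x_other == 1)))
        f2 = int(np.sum(shared & (x_other == 2)))
        p_shared = x_self[shared].sum() / n_self
        p_single = x_self[shared & (x_other == 1)].sum() / n_self
        u = p_shared + ((n_other - 1) / n_other) * (f1 / (2 * max(f2, 1))) * p_single
        return min(u, 1.0)

    u_a = _u(x_a, n_a, x_b, n_b)
    u_b = _u(x_b, n_b, x_a, n_a)
    if u_a == 0.0 or u_b == 0.0:
        return 0.0
    return float(u_a * u_b / (u_a + u_b - u_a * u_b))


def pairwise_chao_similarity(profiles: np.ndarray) -> np.ndarray:
    """Chao Jaccard similarity for every pair of rows of a count matrix.

    Vectorized equivalent of calling :func:`chao_jaccard_similarity` on each
    unordered row pair; returns a symmetric (k, k) matrix with ones on the
    diagonal positions left unused (only off-diagonal entries are meaningful).
    """
    X = np.asarray(profiles, dtype=float)
    k = X.shape[0]
    n = X.sum(axis=1)  # community totals
    nz = X > 0
    one = X == 1
    two = X == 2
    rel = X / n[:, None]
    # shared[a, b, d]: species d present in both communities a and b
    shared = nz[:, None, :] & nz[None, :, :]
    p_shared = (rel[:, None, :] * shared).sum(axis=2)  # U_a main term
    single_other = shared & one[None, :, :]  # shared, singleton in b
    f1 = single_other.sum(axis=2).astype(float)
    f2 = (shared & two[None, :, :]).sum(axis=2).astype(float)
    p_single = (rel[:, None, :] * single_other).sum(axis=2)
    corr = ((n[None, :] - 1) / n[None, :]) * (f1 / (2 * np.maximum(f2, 1.0)))
    u = np.minimum(p_shared + corr * p_single, 1.0)  # u[a, b] = U_a vs b
    ub = u.T  # U_b for the same pair, by role symmetry
    denom = u + ub - u * ub
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where((u > 0) & (ub > 0), u * ub / denom, 0.0)
    sim[np.arange(k), np.arange(k)] = 1.0
    return sim


def niche_overlap(matrix, level: str = "visitor") -> float:
    """Mean pairwise Chao similarity of partner-use profiles within one guild.

    For ``level="visitor"`` each visitor's community is its column of plant
    counts; for ``level="plant"`` each plant's community is its row of
    visitor counts. High values mean species in the guild use similar
    partner sets with similar frequencies.
    """
    if level not in VALID_LEVELS:
        raise ValueError(f"level must be one of {VALID_LEVELS}")
    X = _as_counts(matrix)
    profiles = X.T if level == "visitor" else X
    k = profiles.shape[0]
    if k < 2:
        raise UndefinedMetricError(
            f"niche overlap undefined with {k} species at level {level!r}"
        )
    sim = pairwise_chao_similarity(profiles)
    iu, ju = np.triu_indices(k, k=1)
    return float(sim[iu, ju].mean())


def shannon_entropy(counts) -> float:
    """Natural-log Shannon entropy of a count vector; zero counts are ignored."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("shannon_entropy needs at least one positive count")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def partner_diversity(matrix, level: str = "visitor") -> float:
    """Abundance-weighted mean Shannon entropy of partner use at one guild level.

    Each species j contributes its interaction-distribution entropy H'_j
    weighted by its interaction total n_j; the normalizer is the grand total
    S = sum_j n_j, so the result is a weighted mean. Species with a single
    partner (including singletons) contribute zero entropy with their
    weight.
    """
    if level not in VALID_LEVELS:
        raise ValueError(f"level must be one of {VALID_LEVELS}")
    X = _as_counts(matrix)
    if X.sum() <= 0:
        raise ValueError("empty matrix")
    profiles = X.T if level == "visitor" else X
    totals = profiles.sum(axis=1)
    # n_j * H'_j = n_j ln n_j - sum_i x_ij ln x_ij
    xlogx = np.where(profiles > 0, profiles * np.log(np.where(profiles > 0, profiles, 1.0)), 0.0)
    weighted = totals * np.log(np.maximum(totals, 1.0)) - xlogx.sum(axis=1)
    return float(weighted.sum() / totals.sum())


#: Named metric functions usable with null-model standardization.
METRIC_FUNCTIONS = {
    "wnodf": weighted_nodf,
    "connectance": connectance,
    "network_size": network_size,
    "niche_overlap_visitor": lambda m: niche_overlap(m, "visitor"),
    "niche_overlap_plant": lambda m: niche_overlap(m, "plant"),
    "partner_diversity_visitor": lambda m: partner_diversity(m, "visitor"),
    "partner_diversity_plant": lambda m: partner_diversity(m, "plant"),
}
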