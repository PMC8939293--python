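"""Network indices: weighted NODF, connectance, Chao overlap, diversity.

The weighted-NODF implementation is checked against a naive pair-enumeration
oracle written directly from the formula; the vectorized pairwise Chao
similarity is checked against the scalar per-pair function.
"""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sexnest.metrics import (
    UndefinedMetricError,
    chao_jaccard_similarity,
    connectance,
    network_size,
    niche_overlap,
    pairwise_chao_similarity,
    partner_diversity,
    shannon_entropy,
    weighted_nodf,
)
from .conftest import random_count_matrix


def wnodf_oracle(X):
    """Naive weighted NODF: explicit loops straight from the definition."""
    X = np.asarray(X, dtype=float)
    m, n = X.shape

    def half(vectors, totals):
        total = 0.0
        for i, j in combinations(range(len(vectors)), 2):
            if totals[j] >= totals[i]:  # decreasing-totals condition, ties -> 0
                continue
            nj = sum(1 for v in vectors[j] if v > 0)
            if nj == 0:
                continue
            k = sum(1 for a, b in zip(vectors[i], vectors[j]) if b > 0 and b < a)
            total += 100.0 * k / nj
        return total

    ro = np.argsort(-X.sum(axis=1), kind="stable")
    co = np.argsort(-X.sum(axis=0), kind="stable")
    Xs = X[np.ix_(ro, co)]
    cols = [Xs[:, j] for j in range(n)]
    rows = [Xs[i, :] for i in range(m)]
    return 2.0 * (
        half(cols, Xs.sum(axis=0)) + half(rows, Xs.sum(axis=1))
    ) / (m * (m - 1) + n * (n - 1))


class TestWeightedNodf:
    def test_strictly_nested_is_100(self, nested_matrix):
        assert weighted_nodf(nested_matrix) == pytest.approx(100.0)

    def test_tied_margins_give_zero(self):
        # equal row totals and equal column totals: no pair qualifies
        assert weighted_nodf([[1, 2], [2, 1]]) == 0.0
        assert weighted_nodf(np.ones((3, 4))) == 0.0

    def test_too_small_matrix_rejected(self):
        with pytest.raises(UndefinedMetricError):
            weighted_nodf([[5]])
        with pytest.raises(UndefinedMetricError):
            weighted_nodf([[1], [2]])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = random_count_matrix(rng)
        assert weighted_nodf(X) == pytest.approx(wnodf_oracle(X))

    def test_oracle_equivalence_small_matrices_exhaustive_sample(self):
        """Shapes up to 4x4, cells in {0,1,2}: optimized == naive oracle."""
        rng = np.random.default_rng(2024)
        for m in range(2, 5):
            for n in range(2, 5):
                for _ in range(40):
                    X = rng.integers(0, 3, size=(m, n))
                    assert weighted_nodf(X) == pytest.approx(wnodf_oracle(X))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(99)
        X = random_count_matrix(rng, m=5, n=6)
        ref = weighted_nodf(X)
        for _ in range(5):
            P = X[rng.permutation(5)][:, rng.permutation(6)]
            assert weighted_nodf(P) == pytest.approx(ref)

    def test_range(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            v = weighted_nodf(random_count_matrix(rng))
            assert 0.0 <= v <= 100.0


class TestConnectance:
    @pytest.mark.parametrize(
        "matrix,expected",
        [
            ([[1, 2], [3, 4]], 1.0),
            ([[1, 0], [0, 0]], 0.25),
            (np.eye(3), 3 / 9),
        ],
    )
    def test_examples(self, matrix, expected):
        assert connectance(matrix) == pytest.approx(expected)


def test_network_size_is_species_total():
    assert network_size(np.ones((3, 5))) == 8
    assert network_size([[1]]) == 2


class TestChaoJaccard:
    def test_identical_communities_no_rare_shared(self):
        x = np.array([5, 3, 4])  # all counts >= 3: no singleton correction
        assert chao_jaccard_similarity(x, x) == pytest.approx(1.0)

    def test_disjoint_communities(self):
        assert chao_jaccard_similarity([2, 0, 1], [0, 3, 0]) == 0.0

    def test_hand_computed_example(self):
        # A = {s1:3, s2:1}, B = {s1:2, s3:2}; only s1 shared.
        # U_A: f+1(B)=0, f+2(B)=1 -> U_A = 3/4. U_B: f+1(A)=0, f+2(A)=0 -> 1
        # substituted in denominator -> U_B = 2/4. J = .375/.875 = 3/7.
        got = chao_jaccard_similarity([3, 1, 0], [2, 0, 2])
        assert got == pytest.approx(3 / 7)

    @given(
        st.lists(st.integers(0, 6), min_size=2, max_size=8),
        st.data(),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_symmetric_and_bounded(self, xa, data):
        xb = data.draw(
            st.lists(st.integers(0, 6), min_size=len(xa), max_size=len(xa))
        )
        xa, xb = np.array(xa), np.array(xb)
        if xa.sum() == 0 or xb.sum() == 0:
            return
        s1 = chao_jaccard_similarity(xa, xb)
        s2 = chao_jaccard_similarity(xb, xa)
        assert s1 == pytest.approx(s2)
        assert 0.0 <= s1 <= 1.0


class TestNicheOverlap:
    def test_identical_columns(self):
        X = np.array([[3, 3], [4, 4], [5, 5]])
        assert niche_overlap(X, "visitor") == pytest.approx(1.0)

    def test_disjoint_plant_sets(self):
        X = np.array([[2, 0], [0, 3]])
        assert niche_overlap(X, "visitor") == 0.0

    def test_single_species_undefined(self):
        with pytest.raises(UndefinedMetricError):
            niche_overlap(np.array([[1], [2]]), "visitor")

    @pytest.mark.parametrize("level", ["visitor", "plant"])
    @pytest.mark.parametrize("seed", range(5))
    def test_mean_over_pairs_matches_scalar_enumeration(self, level, seed):
        rng = np.random.default_rng(seed)
        X = random_count_matrix(rng, m=4, n=5)
        profiles = X.T if level == "visitor" else X
        expected = np.mean([
            chao_jaccard_similarity(profiles[i], profiles[j])
            for i, j in combinations(range(profiles.shape[0]), 2)
        ])
        assert niche_overlap(X, level) == pytest.approx(expected)

    def test_vectorized_pairwise_matches_scalar(self):
        rng = np.random.default_rng(7)
        P = rng.integers(0, 4, size=(6, 5))
        P[P.sum(1) == 0, 0] = 1
        sim = pairwise_chao_similarity(P)
        for i, j in combinations(range(6), 2):
            assert sim[i, j] == pytest.approx(chao_jaccard_similarity(P[i], P[j]))


class TestDiversity:
    def test_single_partner_zero(self):
        assert shannon_entropy([7]) == 0.0

    def test_uniform_is_log_k(self):
        assert shannon_entropy([4, 4, 4, 4, 4]) == pytest.approx(math.log(5))

    def test_hand_arithmetic(self):
        assert shannon_entropy([2, 1, 1]) == pytest.approx(1.0397207, abs=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([0, 0])

    def test_partner_diversity_every_species_one_partner(self):
        X = np.diag([2, 3, 4])
        assert partner_diversity(X, "visitor") == 0.0
        assert partner_diversity(X, "plant") == 0.0

    def test_partner_diversity_uniform_single_plant(self):
        X = np.full((1, 6), 3)
        assert partner_diversity(X, "plant") == pytest.approx(math.log(6))

    def test_partner_diversity_hand_example(self):
        X = np.array([[2, 1], [0, 3]])
        # visitor level: col (2,0) H=0 w=2; col (1,3) H=0.562335 w=4; S=6
        assert partner_diversity(X, "visitor") == pytest.approx(0.3748900, abs=1e-6)
        # plant level: row (2,1) H=0.6365142 w=3; row (0,3) H=0 w=3
        assert partner_diversity(X, "plant") == pytest.approx(0.3182571, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_level_difference_is_margins_only(self, seed):
        """S*(H'0_visitor - H'0_plant) = sum c_j ln c_j - sum r_i ln r_i.

        This margins-only identity is why visitor- and plant-level partner
        diversity receive identical z-scores under fixed-margin nulls.
        """
        rng = np.random.default_rng(seed)
        X = random_count_matrix(rng).astype(float)
        S = X.sum()
        lhs = S * (partner_diversity(X, "visitor") - partner_diversity(X, "plant"))
        c = X.sum(axis=0)
        r = X.sum(axis=1)
        rhs = (c * np.log(c)).sum() - (r * np.log(r)).sum()
        assert lhs == pytest.approx(rhs)

    def test_permutation_invariance_all_metrics(self):
        rng = np.random.default_rng(13)
        X = random_count_matrix(rng, m=4, n=5)
        P = X[rng.permutation(4)][:, rng.permutation(5)]
        for fn in (connectance,
                   lambda A: niche_overlap(A, "visitor"),
                   lambda A: niche_overlap(A, "plant"),
                   lambda A: partner_diversity(A, "visitor"),
                   lambda A: partner_diversity(A, "plant")):
            assert fn(P) == pytest.approx(fn(X))
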