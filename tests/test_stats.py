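"""Exact tail tests and multiple-testing adjustment against independent oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import enrichkit as ek
from enrichkit.errors import ValidationError
from enrichkit.stats import ContingencyCounts, fisher_tail_all_k, hypergeom_sf_all_k

from .helpers import stepup_bh, stepup_by


def exact_tail(k, n, K, N) -> Fraction:
    """Integer-arithmetic enumeration of P(X >= k) for Hypergeom(N, K, n)."""
    total = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
    )
    return Fraction(total, math.comb(N, n))


def random_counts(rng) -> ContingencyCounts:
    N = int(rng.integers(1, 26))
    K = int(rng.integers(0, N + 1))
    n = int(rng.integers(0, N + 1))
    lo, hi = max(0, n + K - N), min(n, K)
    k = int(rng.integers(lo, hi + 1))
    return ContingencyCounts(k=k, n=n, K=K, N=N)


class TestHypergeomUpperTail:
    def test_k_zero_is_exactly_one(self):
        assert ek.hypergeom_upper_tail(ContingencyCounts(k=0, n=3, K=4, N=10)) == 1.0

    def test_worked_example_5_over_210(self):
        p = ek.hypergeom_upper_tail(ContingencyCounts(k=4, n=4, K=5, N=10))
        assert p == pytest.approx(5 / 210, rel=1e-12)

    def test_small_table_one_sixth(self):
        p = ek.hypergeom_upper_tail(ContingencyCounts(k=2, n=2, K=2, N=4))
        assert p == pytest.approx(1 / 6, rel=1e-12)

    def test_invariant_violations_name_the_bound(self):
        with pytest.raises(ValidationError, match="N"):
            ContingencyCounts(k=0, n=0, K=0, N=0)
        with pytest.raises(ValidationError, match="k"):
            ContingencyCounts(k=5, n=4, K=5, N=10)
        with pytest.raises(ValidationError, match="K"):
            ContingencyCounts(k=0, n=2, K=11, N=10)

    def test_matches_integer_enumeration_on_random_counts(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            c = random_counts(rng)
            expected = float(exact_tail(c.k, c.n, c.K, c.N))
            assert ek.hypergeom_upper_tail(c) == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_sf(self):
        from scipy.stats import hypergeom

        rng = np.random.default_rng(2)
        for _ in range(100):
            c = random_counts(rng)
            expected = hypergeom.sf(c.k - 1, c.N, c.K, c.n)
            assert ek.hypergeom_upper_tail(c) == pytest.approx(expected, rel=1e-9)


class TestFisherExactGreater:
    def test_identity_with_hypergeometric_tail(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            c = random_counts(rng)
            assert ek.fisher_exact_greater(c) == pytest.approx(
                ek.hypergeom_upper_tail(c), rel=1e-12
            )

    def test_worked_example(self):
        assert ek.fisher_exact_greater(
            ContingencyCounts(k=4, n=4, K=5, N=10)
        ) == pytest.approx(5 / 210, rel=1e-12)

    def test_k_zero_is_one(self):
        assert ek.fisher_exact_greater(ContingencyCounts(k=0, n=3, K=4, N=10)) == 1.0

    def test_matches_scipy_fisher_exact(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(4)
        for _ in range(50):
            c = random_counts(rng)
            table = [[c.k, c.n - c.k], [c.K - c.k, c.N - c.K - c.n + c.k]]
            expected = fisher_exact(table, alternative="greater")[1]
            assert ek.fisher_exact_greater(c) == pytest.approx(expected, rel=1e-9)

    def test_vectorized_tails_agree_groupwise(self):
        for N in range(1, 20):
            for K in range(N + 1):
                for n in range(N + 1):
                    np.testing.assert_allclose(
                        fisher_tail_all_k(N, K, n),
                        hypergeom_sf_all_k(N, K, n),
                        rtol=1e-12,
                    )


class TestFoldEnrichment:
    def test_worked_example(self):
        assert ek.fold_enrichment(ContingencyCounts(k=4, n=4, K=5, N=10)) == 2.0

    def test_zero_overlap_gives_zero(self):
        assert ek.fold_enrichment(ContingencyCounts(k=0, n=4, K=5, N=10)) == 0.0

    def test_proportional_overlap_gives_one(self):
        assert ek.fold_enrichment(ContingencyCounts(k=2, n=4, K=5, N=10)) == 1.0

    def test_requires_positive_n_and_K(self):
        with pytest.raises(ValidationError):
            ek.fold_enrichment(ContingencyCounts(k=0, n=0, K=5, N=10))


class TestAdjustPvalues:
    def test_bh_worked_example(self):
        np.testing.assert_allclose(
            ek.adjust_pvalues([0.005, 0.011, 0.02, 0.04], "BH"),
            [0.02, 0.022, 0.0266667, 0.04],
            rtol=1e-5,
        )

    def test_bonferroni_worked_example(self):
        np.testing.assert_allclose(
            ek.adjust_pvalues([0.01, 0.2], "bonferroni"), [0.02, 0.4]
        )

    @pytest.mark.parametrize("method", ["BH", "BY", "bonferroni", "fdr", "FDR"])
    def test_single_hypothesis_is_identity(self, method):
        np.testing.assert_allclose(ek.adjust_pvalues([0.037], method), [0.037])

    def test_fdr_aliases_bh(self):
        rng = np.random.default_rng(5)
        p = rng.random(30)
        np.testing.assert_array_equal(
            ek.adjust_pvalues(p, "FDR"), ek.adjust_pvalues(p, "BH")
        )

    def test_matches_longhand_stepup_and_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 60)))
            bh = ek.adjust_pvalues(p, "BH")
            np.testing.assert_allclose(bh, stepup_bh(list(p)), rtol=1e-12)
            np.testing.assert_allclose(
                bh, statsmodels.multipletests(p, method="fdr_bh")[1], rtol=1e-10
            )
            by = ek.adjust_pvalues(p, "BY")
            np.testing.assert_allclose(by, stepup_by(list(p)), rtol=1e-12)
            np.testing.assert_allclose(
                by, statsmodels.multipletests(p, method="fdr_by")[1], rtol=1e-10
            )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    def test_dominance_bonferroni_ge_bh_ge_raw(self, p):
        p = np.array(p)
        bh = ek.adjust_pvalues(p, "BH")
        bonf = ek.adjust_pvalues(p, "bonferroni")
        by = ek.adjust_pvalues(p, "BY")
        assert np.all(bonf >= bh - 1e-15)
        assert np.all(by >= bh - 1e-15)
        assert np.all(bh >= p - 1e-15)
        assert np.all(bh <= 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_permutation_equivariance(self, p, rand):
        order = list(range(len(p)))
        rand.shuffle(order)
        p = np.array(p)
        direct = ek.adjust_pvalues(p, "BH")[order]
        permuted = ek.adjust_pvalues(p[order], "BH")
        np.testing.assert_allclose(direct, permuted, rtol=1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            ek.adjust_pvalues([0.1, 1.5], "BH")
        with pytest.raises(ValidationError):
            ek.adjust_pvalues([-0.1], "BH")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValidationError, match="holm"):
            ek.adjust_pvalues([0.1], "holm")
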