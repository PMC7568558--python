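"""Statistics: lysis fraction, exact Wilcoxon, Spearman-t, power-law fits."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from nk3d.errors import InvalidAssayError, UndefinedStatisticError
from nk3d.stats import (lysis_fraction, powerlaw_fit, spearman_t,
                        wilcoxon_signed_rank_exact)


class TestLysisFraction:
    def test_limits(self):
        assert lysis_fraction(100, 100, 1100) == 0.0
        assert lysis_fraction(1100, 100, 1100) == 1.0

    def test_midpoint(self):
        assert lysis_fraction(600, 100, 1100) == pytest.approx(0.5)

    def test_noisy_input_unclamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert lysis_fraction(1200, 100, 1100) > 1.0

    def test_invalid_assay(self):
        with pytest.raises(InvalidAssayError):
            lysis_fraction(500, 1100, 1100)


def _naive_exact_wilcoxon(diffs):
    """Brute-force oracle: enumerate sign assignments with itertools."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [np.dot(signs, ranks)
          for signs in itertools.product([0, 1], repeat=len(d))]
    ws = np.array(ws)
    p_low = np.mean(ws <= w_obs + 1e-9)
    p_high = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxonExact:
    def test_all_same_sign_n10(self):
        pairs = [(i + 1.0, 0.0) for i in range(10)]
        res = wilcoxon_signed_rank_exact(pairs)
        assert res.p == pytest.approx(2.0 / 1024.0)
        assert res.p == pytest.approx(0.001953125)
        assert round(res.p, 3) == 0.002

    def test_n1(self):
        assert wilcoxon_signed_rank_exact([(1.0, 0.0)]).p == 1.0

    def test_antisymmetric_pair(self):
        res = wilcoxon_signed_rank_exact([(1.0, 0.0), (0.0, 1.0)])
        assert res.p == 1.0

    def test_all_zero_differences(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank_exact([(1.0, 1.0), (2.0, 2.0)])
        assert res.p == 1.0 and res.n == 0

    def test_matches_scipy_exact_on_random_data(self):
        """Property sweep: tie-free datasets vs scipy's exact method."""
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(3, 11))
            a = rng.normal(0, 1, n)
            b = a - rng.normal(0.3, 1, n)
            ours = wilcoxon_signed_rank_exact(list(zip(a, b)))
            ref = sps.wilcoxon(a, b, method="exact")
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_matches_naive_enumeration_with_ties(self):
        tied_sets = [
            [1.0, 1.0, -1.0, 2.0, 3.0],
            [2.0, 2.0, 2.0, -2.0],
            [0.5, -0.5, 0.5, 1.5, -1.5, 2.5],
            [1.0, 2.0, 2.0, 3.0, 3.0, 3.0, -1.0],
        ]
        for diffs in tied_sets:
            pairs = [(d, 0.0) for d in diffs]
            ours = wilcoxon_signed_rank_exact(pairs)
            assert ours.p == pytest.approx(_naive_exact_wilcoxon(diffs), rel=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10).filter(lambda x: abs(x) > 1e-6),
                    min_size=2, max_size=10))
    def test_invariances(self, diffs):
        pairs = [(d, 0.0) for d in diffs]
        p0 = wilcoxon_signed_rank_exact(pairs).p
        # pair order is irrelevant
        assert wilcoxon_signed_rank_exact(pairs[::-1]).p == p0
        # flipping every sign leaves the two-sided p unchanged
        flipped = [(0.0, d) for d in diffs]
        assert wilcoxon_signed_rank_exact(flipped).p == pytest.approx(p0, rel=1e-12)

    def test_large_n_normal_approximation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.5, 1, 30)
        b = np.zeros(30)
        ours = wilcoxon_signed_rank_exact(list(zip(a, b)))
        ref = sps.wilcoxon(a, b, method="approx", correction=False)
        assert "normal approximation" in ours.notes
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestSpearmanT:
    def test_perfect_monotone(self):
        res = spearman_t([1, 2, 3, 4, 5], [2, 4, 9, 16, 25])
        assert res.statistic == 1.0
        assert res.p == pytest.approx(2.0 / math.factorial(5))
        res = spearman_t([1, 2, 3, 4], [5, 4, 3, 2])
        assert res.statistic == -1.0

    def test_matches_scipy_with_ties(self):
        x = [1.0, 2.0, 2.0, 4.0, 5.0]
        y = [3.0, 1.0, 4.0, 4.0, 6.0]
        res = spearman_t(x, y)
        ref = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(1, 10, 8)
        y = rng.uniform(1, 10, 8)
        r0 = spearman_t(x, y)
        r1 = spearman_t(np.exp(x), y ** 3)
        assert r1.statistic == pytest.approx(r0.statistic, rel=1e-12)
        assert r1.p == pytest.approx(r0.p, rel=1e-9)

    def test_t_based_p_near_permutation_p_small_n(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        res = spearman_t(x, y)
        rho_obs = abs(res.statistic)
        perm = [abs(sps.spearmanr(x, np.asarray(y)[list(p)]).statistic)
                for p in itertools.permutations(range(5))]
        p_perm = np.mean(np.array(perm) >= rho_obs - 1e-12)
        assert res.p == pytest.approx(p_perm, abs=0.1)

    def test_errors(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_t([1, 2], [1, 2])
        with pytest.raises(UndefinedStatisticError):
            spearman_t([1, 1, 1], [1, 2, 3])


def _ols_loglog_oracle(x, y):
    lx, ly = np.log(x), np.log(y)
    b = np.cov(lx, ly, bias=True)[0, 1] / np.var(lx)
    a = math.exp(ly.mean() - b * lx.mean())
    return a, b


class TestPowerLaw:
    def test_noiseless_recovery(self):
        x = np.linspace(0.5, 9.0, 12)
        fit = powerlaw_fit(x, 2.0 * x ** 0.3)
        assert fit.a == pytest.approx(2.0, rel=1e-12)
        assert fit.b == pytest.approx(0.3, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y(self):
        fit = powerlaw_fit([1.0, 2.0, 4.0], [5.0, 5.0, 5.0])
        assert fit.b == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 0.0

    def test_noisy_fit_matches_closed_form_oracle(self):
        rng = np.random.default_rng(3)
        x = np.linspace(1.0, 20.0, 10)
        y = 1.7 * x ** 0.35 * np.exp(rng.normal(0, 0.1, 10))
        fit = powerlaw_fit(x, y)
        a, b = _ols_loglog_oracle(x, y)
        assert fit.a == pytest.approx(a, rel=1e-10)
        assert fit.b == pytest.approx(b, rel=1e-10)
        assert abs(fit.b - 0.35) < 0.1

    def test_x_scaling_covariance(self):
        """Scaling x by c multiplies a by c^-b and leaves b unchanged."""
        rng = np.random.default_rng(4)
        x = np.linspace(1.0, 5.0, 8)
        y = 3.0 * x ** 0.4 * np.exp(rng.normal(0, 0.05, 8))
        c = 2.5
        f0 = powerlaw_fit(x, y)
        f1 = powerlaw_fit(c * x, y)
        assert f1.b == pytest.approx(f0.b, rel=1e-9)
        assert f1.a == pytest.approx(f0.a * c ** (-f0.b), rel=1e-9)
        assert f1.r_squared == pytest.approx(f0.r_squared, rel=1e-9)

    def test_slope_test_significant_for_clear_trend(self):
        x = np.linspace(1.0, 30.0, 10)
        rng = np.random.default_rng(5)
        y = 2.0 * x ** 0.5 * np.exp(rng.normal(0, 0.05, 10))
        fit = powerlaw_fit(x, y)
        assert fit.b_p < 0.001

    def test_nonpositive_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            powerlaw_fit([1.0, -2.0], [1.0, 2.0])
        with pytest.raises(UndefinedStatisticError):
            powerlaw_fit([1.0, 2.0], [0.0, 2.0])
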