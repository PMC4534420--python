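"""Cumulative paired t-test engine: toys, brute-force oracles, thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from aslpower import (find_nonresponders, paired_t, significant_fraction,
                      t_curves, time_to_significance)
from aslpower.exceptions import (EmptyMaskError, InsufficientDataError,
                                 InvalidParameterError)
from aslpower.significance import NEVER, adjusted_alpha, one_sided_p


def naive_prefix_t(diffs, grid):
    """Independent per-prefix recomputation via scipy's one-sample t-test."""
    out = np.empty(len(grid))
    for i, n in enumerate(grid):
        d = diffs[:n]
        out[i] = stats.ttest_1samp(d, 0.0).statistic
    return out


class TestPairedT:
    def test_symmetric_pair(self):
        ts = paired_t([1.0, -1.0])
        assert ts.u == 0 and ts.t == 0
        assert ts.p == pytest.approx(0.5)

    def test_toy_hand_formula(self):
        # u = 2.5, sd = sqrt(0.5), t = 2.5 * sqrt(2) / sqrt(0.5) = 5
        ts = paired_t([2.0, 3.0])
        assert ts.u == pytest.approx(2.5)
        assert ts.sd == pytest.approx(np.sqrt(0.5))
        assert ts.t == pytest.approx(5.0)

    @given(st.lists(st.floats(-100, 100), min_size=5, max_size=5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_formula_oracle_length_5(self, diffs):
        d = np.asarray(diffs)
        ts = paired_t(d)
        u, sd = d.mean(), d.std(ddof=1)
        if sd > 0:
            assert ts.t == pytest.approx(u * np.sqrt(5) / sd, abs=1e-12)
            # defining identity t = u sqrt(n) / sd
            assert abs(ts.t - ts.u * np.sqrt(ts.n) / ts.sd) < 1e-10

    def test_sd_zero_sentinels(self):
        assert paired_t([2.0, 2.0]).t == np.inf
        assert paired_t([2.0, 2.0]).p == 0.0
        assert paired_t([0.0, 0.0]).t == 0.0
        assert paired_t([0.0, 0.0]).p == pytest.approx(0.5)
        assert paired_t([-1.0, -1.0]).t == -np.inf
        assert paired_t([-1.0, -1.0]).p == 1.0

    def test_single_pair_rejected(self):
        with pytest.raises(InsufficientDataError):
            paired_t([1.0])

    def test_matches_scipy_on_stack(self, rng):
        d = rng.normal(0.2, 1.0, size=(50, 30))
        ts = paired_t(d)
        ref = stats.ttest_1samp(d, 0.0, axis=-1, alternative="greater")
        assert np.allclose(ts.t, ref.statistic, atol=1e-12)
        assert np.allclose(ts.p, ref.pvalue, atol=1e-12)


class TestTCurves:
    def test_prefix_engine_equals_naive_recomputation(self, rng):
        """Running-sums engine vs per-prefix recomputation on 400-pair voxels."""
        d = rng.normal(0.1, 1.0, size=(20, 400))
        grid = np.arange(2, 401)
        curves = t_curves(d, grid)
        for v in range(20):
            ref = naive_prefix_t(d[v], grid)
            assert np.allclose(curves.t[v], ref, atol=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_prefix_engine_property(self, seed):
        r = np.random.default_rng(seed)
        d = r.normal(r.uniform(-1, 1), r.uniform(0.5, 2.0), size=60)
        grid = np.array([2, 3, 7, 30, 60])
        curves = t_curves(d[None, :], grid)
        assert np.allclose(curves.t[0], naive_prefix_t(d, grid), atol=1e-9)

    def test_constant_positive_gives_inf_everywhere(self):
        d = np.full((1, 50), 3.0)
        curves = t_curves(d, np.array([2, 10, 50]))
        assert np.all(np.isinf(curves.t) & (curves.t > 0))

    def test_sqrt_n_law_full_population_moments(self):
        """t at 4N is exactly twice t at N when u and sd are population values."""
        u, sd = 0.3, 1.7
        for n in (10, 25, 100):
            t_n = u * np.sqrt(n) / sd
            t_4n = u * np.sqrt(4 * n) / sd
            assert t_4n == pytest.approx(2 * t_n, abs=1e-12)

    def test_grid_validation(self, rng):
        d = rng.normal(size=(4, 20))
        with pytest.raises(InvalidParameterError):
            t_curves(d, np.array([1, 5]))      # below 2
        with pytest.raises(InvalidParameterError):
            t_curves(d, np.array([5, 25]))     # beyond data
        with pytest.raises(InvalidParameterError):
            t_curves(d, np.array([5, 5, 10]))  # not strictly increasing


class TestThresholding:
    def test_bonferroni_threshold_arithmetic(self):
        assert adjusted_alpha(0.05, "bonferroni", 100) == pytest.approx(5e-4)
        assert adjusted_alpha(0.05, "none", 100) == 0.05

    def test_noiseless_responders_fraction_one(self):
        d = np.full((30, 40), 2.0)  # constant positive effect, sd = 0
        curves = t_curves(d, np.array([2, 10, 40]))
        sc = significant_fraction(curves, alpha=0.05)
        assert np.all(sc.fraction == 1.0)

    def test_threshold_ordering(self, rng):
        """Bonferroni <= uncorrected 0.01 <= uncorrected 0.05 at every NSA."""
        d = rng.normal(0.15, 1.0, size=(500, 200))
        curves = t_curves(d, np.arange(10, 201, 10))
        f05 = significant_fraction(curves, alpha=0.05).fraction
        f01 = significant_fraction(curves, alpha=0.01).fraction
        fb = significant_fraction(curves, alpha=0.05,
                                  correction="bonferroni").fraction
        assert np.all(fb <= f01 + 1e-15)
        assert np.all(f01 <= f05 + 1e-15)

    def test_empty_mask_rejected(self, rng):
        d = rng.normal(size=(5, 20))
        curves = t_curves(d, np.array([2, 20]))
        with pytest.raises(EmptyMaskError):
            significant_fraction(curves, np.zeros(5, dtype=bool))

    def test_null_calibration_at_alpha(self, rng):
        """Zero-effect voxels reject at rate alpha (one-tailed)."""
        d = rng.normal(0.0, 1.0, size=(20000, 50))
        curves = t_curves(d, np.array([50]))
        for alpha in (0.05, 0.01):
            frac = significant_fraction(curves, alpha=alpha).fraction[0]
            se = np.sqrt(alpha * (1 - alpha) / 20000)
            assert abs(frac - alpha) < 3 * se


class TestTimeToSignificance:
    def test_noiseless_responder_first_grid_value(self):
        d = np.full((3, 40), 1.0)
        curves = t_curves(d, np.array([2, 10, 40]))
        tts = time_to_significance(curves)
        assert np.all(tts == 2)

    def test_nonresponder_never(self):
        d = np.full((2, 40), -1.0)
        curves = t_curves(d, np.array([2, 10, 40]))
        assert np.all(time_to_significance(curves) == NEVER)

    def test_brute_force_crossing(self, rng):
        """First-crossing NSA equals a per-prefix scan of p-values."""
        d = rng.normal(0.2, 1.0, size=(40, 400))
        grid = np.arange(2, 401)
        curves = t_curves(d, grid)
        tts = time_to_significance(curves, alpha=0.05)
        for v in range(40):
            expect = NEVER
            for n in grid:
                p = stats.ttest_1samp(d[v, :n], 0.0,
                                      alternative="greater").pvalue
                if p < 0.05:
                    expect = n
                    break
            assert tts[v] == expect

    def test_masked_voxels_are_never(self, rng):
        d = rng.normal(1.0, 0.1, size=(6, 50))
        curves = t_curves(d, np.array([2, 50]))
        mask = np.array([True, True, False, True, False, True])
        tts = time_to_significance(curves, mask=mask)
        assert np.all(tts[~mask] == NEVER)
        assert np.all(tts[mask] >= 2)


class TestFindNonresponders:
    def test_all_positive_mean_noiseless_empty(self):
        d = np.full((4, 30), 0.5)
        curves = t_curves(d, np.array([2, 15, 30]))
        assert not find_nonresponders(curves).any()

    def test_strictly_negative_mean_included(self, rng):
        d = -1.0 + 0.01 * rng.normal(size=(5, 30))
        curves = t_curves(d, np.array([2, 15, 30]))
        assert find_nonresponders(curves).all()

    def test_brute_force_scan_on_mixed_phantom(self, rng):
        d = rng.normal(0.05, 1.0, size=(1000, 100))
        grid = np.arange(2, 101, 7)
        curves = t_curves(d, grid)
        got = find_nonresponders(curves)
        expect = np.array([all(naive_prefix_t(d[v], grid) < 0)
                           for v in range(1000)])
        assert np.array_equal(got, expect)


class TestOneSidedP:
    def test_matches_scipy_survival(self):
        for t, n in [(0.0, 10), (2.0, 5), (-3.0, 30), (5.0, 400)]:
            assert one_sided_p(t, n) == pytest.approx(
                stats.t.sf(t, n - 1), abs=1e-15)
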