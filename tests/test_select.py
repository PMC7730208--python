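import numpy as np
import pytest
from scipy import stats

from nirsbci import (
    Recording,
    apply_selection,
    baseline_select,
    cross_correlate_max,
    irls_fit,
    trial_template,
    tvalue_select,
    zscore_select,
)
from nirsbci.preprocess import EpochSet
from nirsbci.select import DegenerateInputError, EmptySelectionError

FS = 12.5


def brute_force_xcorr(x, y):
    """All-lag raw cross-correlation r(tau) = sum_t x(t) y(t - tau)."""
    best = -np.inf
    best_lag = None
    for lag in range(-(len(y) - 1), len(x)):
        r = 0.0
        for t in range(len(x)):
            n = t - lag
            if 0 <= n < len(y):
                r += x[t] * y[n]
        if r > best or (r == best and (abs(lag), lag) < (abs(best_lag), best_lag)):
            best, best_lag = r, lag
    return best, best_lag


class TestCrossCorrelateMax:
    def test_hand_case(self):
        r, lag = cross_correlate_max(np.array([1.0, 2, 3]), np.array([0.0, 0, 1]))
        assert r == 3.0

    def test_zero_template(self):
        r, lag = cross_correlate_max(np.array([1.0, 2, 3]), np.zeros(3))
        assert r == 0.0 and lag == 0  # tie rule: smallest |tau|

    def test_constructed_shift_recovers_lag(self):
        tmpl = trial_template(FS, (0.0, 24.0), 10.0)
        x = np.zeros_like(tmpl)
        x[10:] = tmpl[:-10]
        r, lag = cross_correlate_max(x, tmpl)
        assert lag == 10

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(25):
            x = rng.normal(size=rng.integers(2, 40))
            y = rng.normal(size=rng.integers(2, 40))
            r, lag = cross_correlate_max(x, y)
            rb, lagb = brute_force_xcorr(x, y)
            assert r == pytest.approx(rb, rel=1e-12)
            assert lag == lagb

    def test_tie_breaks_toward_negative_lag(self):
        # symmetric vectors: r(tau) = r(-tau) exactly for integer data
        r, lag = cross_correlate_max(np.array([1.0, 0, 1]), np.array([1.0, 0, 1]))
        rb, lagb = brute_force_xcorr(np.array([1.0, 0, 1]), np.array([1.0, 0, 1]))
        assert (r, lag) == (rb, lagb)

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError):
            cross_correlate_max(np.array([1.0]), np.array([1.0, 2.0]))


class TestZScoreSelect:
    def test_closed_form_z_scores(self):
        template = np.array([0.0, 1.0, 0.0])
        avg = np.column_stack([i * template for i in (1.0, 2.0, 3.0)])
        res = zscore_select(avg, template)
        np.testing.assert_allclose(
            res.scores, [-np.sqrt(1.5), 0.0, np.sqrt(1.5)], atol=1e-12
        )
        # z = 0 fails the strict rule: only the top channel selected
        assert list(res.selected) == [False, False, True]
        np.testing.assert_allclose(res.aux["r_max"], [1.0, 2.0, 3.0])

    def test_identical_channels_degenerate(self):
        template = np.array([0.0, 1.0, 0.0])
        avg = np.column_stack([template, template, template])
        with pytest.raises(DegenerateInputError):
            zscore_select(avg, template)

    def test_z_sums_to_zero_and_sigma_invariance(self, rng):
        tmpl = rng.normal(size=64)
        for _ in range(20):
            avg = rng.normal(size=(64, 8))
            r0 = zscore_select(avg, tmpl, ddof=0)
            r1 = zscore_select(avg, tmpl, ddof=1)
            assert abs(r0.scores.sum()) <= 1e-9
            np.testing.assert_array_equal(r0.selected, r1.selected)
            # z > 0 is exactly r > mean(r)
            np.testing.assert_array_equal(
                r0.selected, r0.aux["r_max"].to_numpy() > r0.aux["r_max"].mean()
            )

    def test_selects_some_but_not_all(self, rng):
        tmpl = rng.normal(size=32)
        for _ in range(20):
            avg = rng.normal(size=(32, 6))
            res = zscore_select(avg, tmpl)
            assert 1 <= res.n_selected <= 5

    def test_anticorrelated_channel_not_selected(self):
        tmpl = trial_template(FS, (0.0, 24.0), 10.0)
        avg = np.column_stack([tmpl, -tmpl, 0.5 * tmpl])
        res = zscore_select(avg, tmpl)
        assert not res.selected[1]


class TestIRLSFit:
    def test_exact_fit_limit_convention(self):
        x = np.linspace(0, 10, 300)
        f = irls_fit(2 * x + 1, x)
        assert f.phi == pytest.approx(2.0, abs=1e-9)
        assert f.psi == pytest.approx(1.0, abs=1e-9)
        assert f.t == np.inf and f.p == 0.0

    def test_negative_exact_fit_sign(self):
        x = np.linspace(0, 10, 50)
        f = irls_fit(-x, x)
        assert f.phi == pytest.approx(-1.0, abs=1e-9)
        assert f.t == -np.inf and f.p == 1.0

    def test_equal_magnitude_residuals_match_ols_exactly(self):
        # residuals orthogonal to the design and of equal magnitude:
        # every bisquare weight is identical, so IRLS == OLS
        n = 100
        x = np.arange(n, dtype=float)
        e = 0.3 * np.tile([1.0, -1.0, -1.0, 1.0], n // 4)
        f = irls_fit(2 * x + 1 + e, x)
        assert f.phi == pytest.approx(2.0, rel=1e-9)
        assert f.psi == pytest.approx(1.0, abs=1e-9)

    def test_close_to_ols_on_clean_gaussian_noise(self, rng):
        x = rng.normal(size=300)
        y = 2 * x + 1 + rng.normal(0, 0.3, 300)
        f = irls_fit(y, x)
        slope_ols = np.polyfit(x, y, 1)[0]
        assert f.phi == pytest.approx(slope_ols, rel=5e-3)

    def test_robust_to_leverage_outliers(self, rng):
        x = rng.normal(size=100)
        y = 2 * x + 1 + rng.normal(0, 0.2, 100)
        y[np.argsort(x)[-5:]] += 8.0  # 5% gross outliers at high leverage
        f = irls_fit(y, x)
        slope_ols = np.polyfit(x, y, 1)[0]
        assert abs(f.phi - 2.0) < abs(slope_ols - 2.0)

    def test_one_tailed_p_against_t_distribution(self, rng):
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(0, 1.0, 200)
        f = irls_fit(y, x)
        assert f.p == pytest.approx(stats.t.sf(f.t, 199), rel=1e-12)

    def test_constant_design_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            irls_fit(np.arange(10.0), np.ones(10))


class TestTValueSelect:
    def test_template_plus_noise_selected(self, rng):
        tmpl = trial_template(FS, (0.0, 24.0), 10.0)
        noisy = tmpl + rng.normal(0, 0.01 * np.abs(tmpl).max(), tmpl.size)
        avg = np.column_stack([noisy, rng.normal(size=tmpl.size)])
        res = tvalue_select(avg, tmpl)
        assert res.selected[0]
        assert res.scores[0] > res.params["t_crt"]

    def test_negative_template_not_selected(self, rng):
        tmpl = trial_template(FS, (0.0, 24.0), 10.0)
        avg = np.column_stack([-tmpl, rng.normal(size=tmpl.size)])
        res = tvalue_select(avg, tmpl)
        assert not res.selected[0]
        assert res.scores[0] < 0

    def test_default_critical_value_from_df(self):
        tmpl = trial_template(FS, (0.0, 24.0), 10.0)  # 300 samples
        avg = np.column_stack([tmpl, 2 * tmpl])
        res = tvalue_select(avg, tmpl)
        assert res.params["t_crt"] == pytest.approx(stats.t.ppf(0.95, 299))

    def test_template_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            tvalue_select(np.zeros((10, 2)), np.zeros(5))


def _epochset(arr, window=(0.0, 1.0)):
    arr = np.asarray(arr, dtype=float)
    return EpochSet(arr, window, 10.0, ("t",) * arr.shape[0], tuple(f"c{i}" for i in range(arr.shape[2])))


class TestBaselineSelect:
    def test_peak_comparison_rules(self):
        task = _epochset(np.array([[[2.0, 1.0, 0.5], [0.0, 1.0, 0.2]]]).transpose(0, 2, 1))
        rest = _epochset(np.array([[[1.0, 1.0, 0.9], [0.0, 1.0, 0.1]]]).transpose(0, 2, 1))
        res = baseline_select(task, rest)
        # ch0: 2 > 1 selected; ch1: tie 1 == 1 not selected (strict)
        assert list(res.selected) == [True, False]

    def test_rest_dominant_not_selected(self):
        task = _epochset(np.ones((3, 10, 2)))
        rest = _epochset(2 * np.ones((3, 10, 2)))
        assert baseline_select(task, rest).n_selected == 0

    def test_channel_mismatch_rejected(self):
        task = _epochset(np.ones((2, 10, 2)))
        rest = EpochSet(np.ones((2, 10, 2)), (0, 1), 10.0, ("t", "t"), ("x", "y"))
        with pytest.raises(ValueError, match="different channels"):
            baseline_select(task, rest)


class TestApplySelection:
    def _rec(self, c=3):
        return Recording(np.arange(20.0 * c).reshape(20, c), 10.0, "HbO",
                         tuple(f"ch{i}" for i in range(c)))

    def _result(self, mask):
        from nirsbci.select import SelectionResult
        import pandas as pd

        n = len(mask)
        return SelectionResult("zscore", np.zeros(n), np.asarray(mask),
                               tuple(f"ch{i}" for i in range(n)), pd.DataFrame(index=range(n)))

    def test_all_true_identity(self):
        rec = self._rec()
        out = apply_selection(rec, self._result([True] * 3))
        np.testing.assert_array_equal(out.data, rec.data)

    def test_partial_mask_preserves_order(self):
        out = apply_selection(self._rec(), self._result([True, False, True]))
        assert out.channel_ids == ("ch0", "ch2")

    def test_empty_selection_rejected(self):
        with pytest.raises(EmptySelectionError):
            apply_selection(self._rec(), self._result([False] * 3))

    def test_none_bypasses(self):
        rec = self._rec()
        assert apply_selection(rec, None) is rec
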