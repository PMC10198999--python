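import numpy as np
import pytest

from photophen import GppSeries, InsufficientDataError
from photophen.series_prep import (grubbs_flags_outlier, interpolate_to_daily,
                                   iterative_smooth, read_series_csv)
from photophen.synthetic import COMPOSITE_DOYS
from photophen.types import DailySeries

from _oracles import notaknot_spline_eval


class TestInterpolation:
    def test_constant_series_reproduced_everywhere(self):
        s = GppSeries(2001, COMPOSITE_DOYS, np.full(46, 5.0), cadence=8)
        daily = interpolate_to_daily(s)
        assert daily.doy[0] == 1 and daily.doy[-1] == 365
        np.testing.assert_allclose(daily.values, 5.0)

    def test_collinear_inputs_give_exact_line(self):
        s = GppSeries(2001, COMPOSITE_DOYS, 0.1 * COMPOSITE_DOYS, cadence=8)
        daily = interpolate_to_daily(s)
        inside = (daily.doy >= 1) & (daily.doy <= 361)
        np.testing.assert_allclose(daily.values[inside],
                                   0.1 * daily.doy[inside], atol=1e-10)

    def test_exact_at_knots(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0, 10, 46)
        daily = interpolate_to_daily(GppSeries(2001, COMPOSITE_DOYS, vals, 8))
        np.testing.assert_allclose(daily.values[COMPOSITE_DOYS - 1], vals,
                                   rtol=0, atol=1e-12)

    def test_sine_cycle_matches_independent_spline(self):
        # oracle: from-scratch not-a-knot spline; the daily curve must
        # agree with it and stay within the oracle's own truth error
        t = COMPOSITE_DOYS.astype(float)
        vals = 4.0 + 3.0 * np.sin(2 * np.pi * (t - 80) / 365.0)
        daily = interpolate_to_daily(GppSeries(2001, COMPOSITE_DOYS, vals, 8))
        days = np.arange(1, 366, dtype=float)
        oracle = notaknot_spline_eval(t, vals, days)
        inside = (days >= t[0]) & (days <= t[-1])
        np.testing.assert_allclose(daily.values[inside], oracle[inside],
                                   atol=1e-8)
        true = 4.0 + 3.0 * np.sin(2 * np.pi * (days - 80) / 365.0)
        oracle_err = np.abs(oracle[inside] - true[inside]).max()
        assert np.abs(daily.values[inside] - true[inside]).max() \
            <= oracle_err + 1e-8

    def test_edges_clamped_not_extrapolated(self):
        doy = np.arange(41, 322, 8)
        vals = np.linspace(1, 10, doy.size)
        daily = interpolate_to_daily(GppSeries(2001, doy, vals, 8))
        np.testing.assert_allclose(daily.values[:40], vals[0])
        np.testing.assert_allclose(daily.values[doy[-1]:], vals[-1])

    def test_too_few_points_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            interpolate_to_daily(GppSeries(2001, np.array([1, 9, 17]),
                                           np.array([1.0, 2.0, 3.0]), 8))

    def test_long_gap_is_insufficient(self):
        vals = np.full(46, 5.0)
        vals[10:14] = np.nan  # 4 consecutive missing composites
        with pytest.raises(InsufficientDataError):
            interpolate_to_daily(GppSeries(2001, COMPOSITE_DOYS, vals, 8))
        vals = np.full(46, 5.0)
        vals[10:13] = np.nan  # 3 missing is still tolerated
        interpolate_to_daily(GppSeries(2001, COMPOSITE_DOYS, vals, 8))

    def test_leap_year_runs_to_day_366(self):
        daily = interpolate_to_daily(
            GppSeries(2004, COMPOSITE_DOYS, np.full(46, 3.0), 8))
        assert daily.doy[-1] == 366


class TestGrubbs:
    def test_critical_value_matches_published_table(self):
        # two-sided Grubbs critical value for n=8, alpha=0.05 is 2.1266
        from photophen.series_prep import _grubbs_critical
        assert _grubbs_critical(8, 0.05) == pytest.approx(2.1266, abs=2e-3)

    def test_flags_gross_outlier_not_noise(self):
        rng = np.random.default_rng(3)
        x = rng.normal(1.0, 0.01, 200)
        assert not grubbs_flags_outlier(x.copy())
        x[50] = 2.0
        assert grubbs_flags_outlier(x)

    def test_degenerate_vectors_are_not_flagged(self):
        assert not grubbs_flags_outlier(np.full(50, 1.0))
        assert not grubbs_flags_outlier(np.array([1.0, 2.0]))


class TestIterativeSmooth:
    def test_clean_curve_terminates_first_iteration(self, clean_daily_logistic):
        sm = iterative_smooth(clean_daily_logistic)
        assert sm.n_iterations == 1
        assert sm.replaced.sum() == 0
        # output agrees with input within the filter's own error
        assert np.abs(sm.values - clean_daily_logistic.values).max() < 0.1

    def test_single_spike_flagged_and_replaced(self, clean_daily_logistic):
        from scipy.signal import savgol_filter

        y = clean_daily_logistic.values.copy()
        y[200] += 10.0
        spiked = DailySeries(2001, clean_daily_logistic.doy, y)
        sm = iterative_smooth(spiked)
        assert sm.replaced[200]
        ref = iterative_smooth(clean_daily_logistic)
        # replacement must reduce the spike's imprint on the smooth below
        # what the filter alone would leave (the ratio-based rule is
        # relative, so an in-season spike is damped, not erased)
        no_replacement = savgol_filter(y, 31, 3, mode="interp")
        d_plain = np.abs(no_replacement - ref.values).max()
        d_despiked = np.abs(sm.values - ref.values).max()
        assert d_despiked < d_plain

    def test_masking_cascade_halts_at_cap(self):
        # geometric spike tiers: each iteration unmasks the next tier, so
        # the Grubbs gate keeps firing and the loop must stop at max_iter
        t = np.arange(1, 366)
        y = np.full(365, 5.0)
        for k, d in enumerate(np.arange(10, 226, 18)):
            y[d] += 1e13 / 30.0**k
        sm = iterative_smooth(DailySeries(2001, t, y))
        assert sm.n_iterations == 20

    def test_idempotent_on_smooth_input(self, clean_daily_logistic):
        first = iterative_smooth(clean_daily_logistic)
        again = iterative_smooth(DailySeries(2001, first.doy,
                                             first.values.copy()))
        assert again.n_iterations == 1
        assert np.abs(again.values - first.values).max() < 0.1

    def test_window_longer_than_series_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            iterative_smooth(DailySeries(2001, np.arange(1, 11),
                                         np.ones(10)), window_days=31)


class TestCsvReader:
    def test_year_doy_and_date_layouts_agree(self, tmp_path):
        import pandas as pd
        doy = COMPOSITE_DOYS[:10]
        vals = np.linspace(1, 5, 10)
        p1 = tmp_path / "a.csv"
        pd.DataFrame({"year": 2001, "doy": doy, "gpp": vals}).to_csv(
            p1, index=False)
        dates = pd.to_datetime("2001-01-01") + pd.to_timedelta(doy - 1, "D")
        p2 = tmp_path / "b.csv"
        pd.DataFrame({"date": dates, "gpp": vals}).to_csv(p2, index=False)
        a = read_series_csv(p1)[0]
        b = read_series_csv(p2)[0]
        assert a.year == b.year == 2001
        np.testing.assert_array_equal(a.doy, b.doy)
        np.testing.assert_allclose(a.values, b.values)

    def test_missing_cells_become_nan(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("year,doy,gpp\n2001,1,1.0\n2001,9,\n2001,17,3.0\n")
        s = read_series_csv(p)[0]
        assert np.isnan(s.values[1])

    def test_rejects_unknown_layout(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError):
            read_series_csv(p)
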