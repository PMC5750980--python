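"""Heat-wave detection and excess-heat index checks against naive oracles."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatexcess import heatmetrics as hm
from conftest import make_temp
from oracles import loop_ehf, loop_ehi_accl, loop_ehi_sig, quantile_sorted, scan_heat_waves


class TestThresholds:
    def test_constant_series_collapses_both_percentiles(self):
        thr = hm.compute_thresholds(make_temp([20.0] * 365))
        assert thr.t95 == thr.t98 == 20.0

    def test_matches_sort_and_interpolate_oracle(self, rng):
        values = np.array(list(range(1, 101)) * 4, dtype=float)  # >= 1 year
        rng.shuffle(values)
        temp = make_temp(values)
        thr = hm.compute_thresholds(temp)
        assert thr.t95 == pytest.approx(quantile_sorted(values, 0.95), abs=1e-12)
        assert thr.t98 == pytest.approx(quantile_sorted(values, 0.98), abs=1e-12)

    def test_invalid_percentile_order_rejected(self):
        temp = make_temp(np.linspace(0, 30, 400))
        with pytest.raises(ValueError):
            hm.compute_thresholds(temp, p_low=0.98, p_high=0.95)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            hm.compute_thresholds(make_temp([20.0] * 100))

    def test_shift_equivariance(self, rng):
        values = rng.normal(10, 8, size=730)
        t0 = hm.compute_thresholds(make_temp(values))
        t1 = hm.compute_thresholds(make_temp(values + 3.5))
        assert t1.t95 == pytest.approx(t0.t95 + 3.5)
        assert t1.t98 == pytest.approx(t0.t98 + 3.5)


class TestDetector:
    def test_toy_runs_only_qualifying_one_kept(self):
        # runs above t95=21.2: len 2 / len 3 with a >t98 peak / len 5 capped at t98
        base = [15.0] * 5
        series = (
            base + [22, 22] +           # too short
            base + [22, 24, 22] +       # qualifies
            base + [23.2, 23.2, 23.2, 23.2, 23.2] +  # never exceeds t98
            base
        )
        thr = hm.Thresholds(21.2, 23.2, (dt.date(2000, 1, 1), dt.date(2000, 12, 31)))
        temp = make_temp(series)
        events = hm.detect_heat_waves(temp, thr)
        assert len(events) == 1
        assert events[0].duration_days == 3
        oracle = scan_heat_waves(series, 21.2, 23.2)
        assert [(e.start, e.end) for e in events] == [
            (temp.index[i].date(), temp.index[j - 1].date()) for i, j in oracle
        ]

    def test_cool_series_yields_no_events(self):
        thr = hm.Thresholds(21.2, 23.2, (dt.date(2000, 1, 1), dt.date(2000, 12, 31)))
        assert hm.detect_heat_waves(make_temp([10.0] * 100), thr) == []

    def test_august_window_duration_thirteen_days(self):
        # a qualifying 3-15 August period spans 13 days
        idx = pd.date_range("2015-06-01", "2015-09-30", freq="D")
        temp = pd.Series(15.0, index=idx)
        temp.loc["2015-08-03":"2015-08-15"] = 24.0
        thr = hm.Thresholds(21.2, 23.2, (dt.date(2015, 1, 1), dt.date(2015, 12, 31)))
        (event,) = hm.detect_heat_waves(temp, thr)
        assert event.duration_days == 13
        assert event.start == dt.date(2015, 8, 3)
        assert event.end == dt.date(2015, 8, 15)
        assert event.id == "2015_1"

    def test_matches_run_scan_oracle_on_random_series(self, rng):
        thr = hm.Thresholds(21.2, 23.2, (dt.date(2000, 1, 1), dt.date(2000, 12, 31)))
        for _ in range(200):
            values = rng.normal(20, 3, size=120)
            temp = make_temp(values)
            got = [
                (temp.index.get_loc(pd.Timestamp(e.start)),
                 temp.index.get_loc(pd.Timestamp(e.end)) + 1)
                for e in hm.detect_heat_waves(temp, thr)
            ]
            assert got == scan_heat_waves(values, 21.2, 23.2)

    def test_ids_ordinal_per_calendar_year(self, rng):
        idx = pd.date_range("2001-06-01", periods=500, freq="D")
        values = rng.normal(20, 3, size=500)
        temp = pd.Series(values, index=idx)
        thr = hm.Thresholds(21.2, 23.2, (dt.date(2001, 1, 1), dt.date(2002, 12, 31)))
        events = hm.detect_heat_waves(temp, thr)
        for year in {e.start.year for e in events}:
            ids = [e.id for e in events if e.start.year == year]
            assert ids == [f"{year}_{k}" for k in range(1, len(ids) + 1)]


class TestIndices:
    def test_ehi_sig_constant_series(self):
        temp = make_temp([25.0] * 40)
        sig = hm.ehi_sig(temp, 21.2)
        assert sig.iloc[:2].isna().all()
        assert np.allclose(sig.iloc[2:], 25.0 - 21.2)

    def test_ehi_sig_three_day_arithmetic(self):
        sig = hm.ehi_sig(make_temp([20.0, 22.0, 24.0]), 21.2)
        assert sig.iloc[2] == pytest.approx(22.0 - 21.2)

    def test_ehi_accl_constant_series_is_zero(self):
        accl = hm.ehi_accl(make_temp([17.0] * 60))
        assert accl.iloc[:32].isna().all()
        assert np.allclose(accl.iloc[32:], 0.0)

    def test_ehi_accl_step_series(self):
        accl = hm.ehi_accl(make_temp([10.0] * 30 + [16.0] * 3))
        assert accl.iloc[-1] == pytest.approx(6.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_indices_match_loop_oracles(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(18, 6, size=60)
        temp = make_temp(values)
        sig = hm.ehi_sig(temp, 21.2)
        accl = hm.ehi_accl(temp)
        f = hm.ehf(sig, accl)
        np.testing.assert_allclose(
            sig.to_numpy(), loop_ehi_sig(values, 21.2), atol=1e-12
        )
        np.testing.assert_allclose(accl.to_numpy(), loop_ehi_accl(values), atol=1e-12)
        np.testing.assert_allclose(
            f.to_numpy(), loop_ehf(loop_ehi_sig(values, 21.2), loop_ehi_accl(values)),
            atol=1e-12,
        )

    @pytest.mark.parametrize(
        "sig,accl,expected", [(-0.5, 5.0, 0.0), (2.0, 0.5, 2.0), (3.0, 2.0, 6.0)]
    )
    def test_ehf_floors(self, sig, accl, expected):
        idx = pd.date_range("2000-01-01", periods=1, freq="D")
        out = hm.ehf(pd.Series([sig], index=idx), pd.Series([accl], index=idx))
        assert out.iloc[0] == pytest.approx(expected)

    def test_ehf_misaligned_dates_rejected(self):
        a = pd.Series([1.0], index=pd.date_range("2000-01-01", periods=1))
        b = pd.Series([1.0], index=pd.date_range("2000-01-02", periods=1))
        with pytest.raises(ValueError):
            hm.ehf(a, b)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(shift=st.floats(-10, 10), seed=st.integers(0, 100))
    def test_shift_leaves_ehi_accl_unchanged(self, shift, seed):
        values = np.random.default_rng(seed).normal(15, 5, size=50)
        a0 = hm.ehi_accl(make_temp(values))
        a1 = hm.ehi_accl(make_temp(values + shift))
        np.testing.assert_allclose(a0.dropna(), a1.dropna(), atol=1e-9)


class TestSummaries:
    def _summer_event(self, bump=3.0):
        idx = pd.date_range("1994-05-01", "1994-09-30", freq="D")
        temp = pd.Series(18.0, index=idx)
        temp.loc["1994-07-22":"1994-08-08"] += bump + 4.0
        thr = hm.Thresholds(21.2, 23.2, (dt.date(1994, 1, 1), dt.date(1994, 12, 31)))
        (event,) = hm.detect_heat_waves(temp, thr)
        return event, temp, thr

    def test_late_july_window_spans_eighteen_days(self):
        event, temp, thr = self._summer_event()
        metrics = hm.compute_daily_metrics(temp, thr)
        hw = hm.summarize_heat_wave(event, temp, metrics)
        assert hw.duration_days == 18
        assert hw.start == dt.date(1994, 7, 22)
        assert hw.end == dt.date(1994, 8, 8)

    def test_three_day_constant_event_sums(self):
        idx = pd.date_range("2000-05-01", periods=120, freq="D")
        temp = pd.Series(21.2 + 1.0, index=idx)  # constant at t95 + 1
        thr = hm.Thresholds(21.2, 21.2, (dt.date(2000, 1, 1), dt.date(2000, 12, 31)))
        hw = hm.HeatWave("2000_1", dt.date(2000, 8, 1), dt.date(2000, 8, 3), 3, 22.2, 22.2)
        metrics = hm.compute_daily_metrics(temp, thr)
        out = hm.summarize_heat_wave(hw, temp, metrics)
        assert out.sum_ehi_sig == pytest.approx(3.0)
        assert out.sum_ehi_accl == pytest.approx(0.0)
        assert out.sum_ehf == pytest.approx(3.0)  # accl floored at 1

    def test_random_event_sums_match_loop_oracle(self, rng):
        values = rng.normal(22, 2, size=80)
        temp = make_temp(values)
        thr = hm.Thresholds(21.0, 23.0, (dt.date(2000, 1, 1), dt.date(2000, 12, 31)))
        metrics = hm.compute_daily_metrics(temp, thr)
        hw = hm.HeatWave(
            "2000_1", temp.index[40].date(), temp.index[44].date(), 5,
            float(values[40:45].mean()), float(values[40:45].max()),
        )
        out = hm.summarize_heat_wave(hw, temp, metrics)
        sig = loop_ehi_sig(values, 21.0)
        accl = loop_ehi_accl(values)
        f = loop_ehf(sig, accl)
        assert out.sum_ehi_sig == pytest.approx(sum(sig[40:45]), abs=1e-10)
        assert out.sum_ehi_accl == pytest.approx(sum(accl[40:45]), abs=1e-10)
        assert out.sum_ehf == pytest.approx(sum(f[40:45]), abs=1e-10)

    def test_warm_up_overlap_rejected(self):
        temp = make_temp([25.0] * 60)
        thr = hm.Thresholds(21.2, 23.2, (dt.date(2000, 1, 1), dt.date(2000, 12, 31)))
        metrics = hm.compute_daily_metrics(temp, thr)
        hw = hm.HeatWave("2000_1", dt.date(2000, 1, 5), dt.date(2000, 1, 9), 5, 25.0, 25.0)
        with pytest.raises(ValueError, match="warm-up"):
            hm.summarize_heat_wave(hw, temp, metrics)

    def test_warming_an_event_increases_its_heat_load(self):
        event, temp, thr = self._summer_event()
        metrics = hm.compute_daily_metrics(temp, thr)
        base = hm.summarize_heat_wave(event, temp, metrics)
        hotter = temp.copy()
        hotter.loc[event.dates] += 1.0
        metrics2 = hm.compute_daily_metrics(hotter, thr)
        warmer = hm.summarize_heat_wave(event, hotter, metrics2)
        assert warmer.sum_ehf > base.sum_ehf

    def test_ehf_nonnegative_and_zero_below_threshold(self, rng):
        values = rng.normal(18, 5, size=200)
        temp = make_temp(values)
        thr = hm.compute_thresholds(make_temp(rng.normal(18, 5, size=400)))
        metrics = hm.compute_daily_metrics(temp, thr)
        defined = metrics.dropna()
        assert (defined["ehf"] >= 0).all()
        below = defined[defined["ehi_sig"] <= 0]
        assert np.allclose(below["ehf"], 0.0)
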