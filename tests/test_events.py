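"""Event detection: threshold calibration, run detection, HWMId, droughts,
GEV floods, dryness masking and percentile sensitivity."""

import numpy as np
import pytest
from scipy import stats

from hazex import Grid
from hazex import events as ev
from hazex import synthetic as syn
from hazex.events import CalibrationError, DegenerateReferenceError


def brute_force_runs(mask):
    """Independent maximal-run scanner: plain python loop."""
    runs, start = [], None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(mask) - start))
    return runs


class TestDoyPercentile:
    def test_constant_series(self):
        x = np.full((35, 365), 20.0)
        np.testing.assert_allclose(ev.calibrate_doy_percentile(x), 20.0)

    def test_window_one_is_per_day_percentile(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 365, 2, 2))
        got = ev.calibrate_doy_percentile(x, q=90, window=1)
        np.testing.assert_allclose(got, np.percentile(x, 90, axis=0))

    def test_matches_pooled_window_oracle(self):
        # seasonal sine + noise, 200 years, one cell; oracle pools windows
        # by explicit looping with wraparound
        rng = np.random.default_rng(2)
        doy = np.arange(365)
        x = 10 * np.sin(2 * np.pi * doy / 365) + rng.normal(0, 3, size=(200, 365))
        got = ev.calibrate_doy_percentile(x, q=90, window=31)
        for d in (0, 17, 180, 364):
            pool = [x[:, (d + off) % 365] for off in range(-15, 16)]
            expect = np.percentile(np.concatenate(pool), 90)
            assert got[d] == pytest.approx(expect)

    def test_even_window_rejected(self):
        with pytest.raises(CalibrationError):
            ev.calibrate_doy_percentile(np.zeros((30, 365)), window=30)

    def test_bad_percentile_rejected(self):
        with pytest.raises(CalibrationError):
            ev.calibrate_doy_percentile(np.zeros((30, 365)), q=0)


class TestHeatwavePeriods:
    def setup_method(self):
        self.thr = np.zeros(365)

    def _series(self, hot_days):
        t = np.full(365, -1.0)
        t[list(hot_days)] = 1.0
        return t

    def test_three_day_run_detected(self):
        periods = ev.detect_heatwave_periods(self._series(range(100, 103)), self.thr)
        assert periods == [(100, 3)]

    def test_two_day_run_ignored(self):
        assert ev.detect_heatwave_periods(self._series([100, 101]), self.thr) == []

    def test_tttftt_pattern(self):
        hot = list(range(10, 13)) + list(range(14, 17))
        periods = ev.detect_heatwave_periods(self._series(hot), self.thr)
        assert periods == [(10, 3), (14, 3)]

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            t = rng.normal(size=365)
            thr = rng.normal(scale=0.5, size=365)
            expected = [r for r in brute_force_runs(t > thr) if r[1] >= 3]
            assert ev.detect_heatwave_periods(t, thr) == expected

    def test_exceedance_must_be_strict(self):
        t = np.zeros(365)
        assert ev.detect_heatwave_periods(t, np.zeros(365)) == []


class TestHwmid:
    def test_year_without_period_is_zero(self):
        t = np.full(365, -5.0)
        assert ev.hwmid_annual(t, np.zeros(365), q25=0.0, q75=2.0) == 0.0

    def test_hand_built_five_day_heatwave(self):
        # quartiles Q25=30, Q75=34 -> IQR 4; 5 hot days above threshold 28
        t = np.full(365, 20.0)
        temps = [31.0, 33.0, 29.5, 36.0, 32.0]
        t[50:55] = temps
        thr = np.full(365, 28.0)
        # manual daily magnitudes: (T-30)/4 if T>30 else 0
        expected = (1.0 + 3.0 + 0.0 + 6.0 + 2.0) / 4.0
        assert ev.hwmid_annual(t, thr, q25=30.0, q75=34.0) == pytest.approx(expected)

    def test_annual_value_is_max_over_periods(self):
        t = np.full(365, 20.0)
        t[10:13] = 35.0   # magnitude 3 * 5/4
        t[100:106] = 33.0  # magnitude 6 * 3/4
        thr = np.full(365, 28.0)
        v = ev.hwmid_annual(t, thr, q25=30.0, q75=34.0)
        assert v == pytest.approx(6 * 3 / 4)

    def test_extending_period_never_decreases(self):
        thr = np.full(365, 28.0)
        t = np.full(365, 20.0)
        t[50:54] = 32.0
        v1 = ev.hwmid_annual(t, thr, q25=30.0, q75=34.0)
        t[54] = 31.0
        v2 = ev.hwmid_annual(t, thr, q25=30.0, q75=34.0)
        assert v2 >= v1

    def test_degenerate_quartiles_flagged(self):
        with pytest.raises(DegenerateReferenceError):
            ev.hwmid_annual(np.zeros(365), np.zeros(365), q25=1.0, q75=1.0)

    def test_batch_matches_scalar(self):
        g = Grid.regular(3, 3, 0.5)
        run = syn.generate_control(g, 35, seed=41, variables=("tasmax",))
        s = ev.summarize_control(run)
        tas = run.fields["tasmax"]
        batch = ev.hwmid_annual_batch(tas, s.hw_doy_p90, s.hw_q25, s.hw_q75)
        for y in (0, 17, 34):
            for i in range(3):
                for j in range(3):
                    scalar = ev.hwmid_annual(
                        tas[y, :, i, j], s.hw_doy_p90[:, i, j], s.hw_q25[i, j], s.hw_q75[i, j]
                    )
                    assert batch[y, i, j] == pytest.approx(scalar)


class TestClassifyExtremeYears:
    def test_self_classification_rate_near_default_tail(self):
        rng = np.random.default_rng(5)
        ctrl = rng.normal(size=2000)
        flags = ev.classify_extreme_years(ctrl, ctrl, q=97.5, tail="upper")
        assert flags.mean() == pytest.approx(0.025, abs=0.009)

    def test_tie_does_not_flag(self):
        ctrl = np.zeros(100)
        flags = ev.classify_extreme_years(np.array([0.0]), ctrl, q=97.5)
        assert not flags[0]

    def test_above_control_maximum_flags(self):
        ctrl = np.linspace(0, 1, 100)
        assert ev.classify_extreme_years(np.array([2.0]), ctrl, q=97.5)[0]

    def test_lower_tail(self):
        ctrl = np.linspace(0, 1, 1000)
        flags = ev.classify_extreme_years(np.array([0.001, 0.5]), ctrl, q=2.5, tail="lower")
        assert flags.tolist() == [True, False]

    def test_empty_control_rejected(self):
        with pytest.raises(CalibrationError):
            ev.classify_extreme_years(np.array([1.0]), np.array([]))


class TestDrought:
    def test_three_consecutive_months_flags_year(self):
        sm = np.ones((1, 12))
        sm[0, 3:6] = 0.0
        assert ev.detect_drought_years(sm, 0.5)[0]

    def test_split_runs_do_not_flag(self):
        sm = np.ones((1, 12))
        sm[0, [2, 3, 5, 6]] = 0.0  # two 2-month runs with a wet month between
        assert not ev.detect_drought_years(sm, 0.5)[0]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(6)
        sm = rng.uniform(size=(50, 12))
        level = 0.3
        got = ev.detect_drought_years(sm, level)
        for y in range(50):
            expect = any(ln >= 3 for _, ln in brute_force_runs(sm[y] < level))
            assert got[y] == expect

    def test_below_must_be_strict(self):
        sm = np.full((1, 12), 0.5)
        assert not ev.detect_drought_years(sm, 0.5)[0]


class TestDrynessMask:
    def test_cutoff_semantics(self):
        d = np.array([0.05, 0.1, 1.0])
        np.testing.assert_array_equal(
            ev.compute_dryness_mask(d), [False, True, True]
        )

    def test_negative_discharge_rejected(self):
        with pytest.raises(ValueError):
            ev.compute_dryness_mask(np.array([-0.1]))


class TestGev:
    def test_return_period_percentile_identity(self):
        assert 1 - 1 / 40 == 0.975
        assert ev.return_period_for_percentile(97.5) == pytest.approx(40.0)
        assert ev.return_period_for_percentile(95.0) == pytest.approx(20.0)
        assert ev.return_period_for_percentile(99.0) == pytest.approx(100.0)

    def test_gumbel_40yr_level(self):
        rng = np.random.default_rng(7)
        x = rng.gumbel(0.0, 1.0, size=10000)
        _, level = ev.fit_gev_annual_maxima(x, return_period=40)
        target = -np.log(-np.log(0.975))
        assert level == pytest.approx(target, rel=0.05)

    def test_parameter_recovery(self):
        x = stats.genextreme.rvs(c=-0.2, loc=10, scale=2, size=5000, random_state=8)
        params, _ = ev.fit_gev_annual_maxima(x)
        assert params.loc == pytest.approx(10, abs=0.15)
        assert params.scale == pytest.approx(2, rel=0.08)
        assert params.shape == pytest.approx(0.2, abs=0.08)

    def test_constant_series_flagged_unusable(self):
        with pytest.raises(DegenerateReferenceError):
            ev.fit_gev_annual_maxima(np.full(100, 3.0))

    def test_lmoment_fallback_close_to_mle_on_gumbel(self):
        rng = np.random.default_rng(9)
        x = rng.gumbel(5.0, 2.0, size=5000)
        lm = ev._lmoment_gev(x)
        assert lm.loc == pytest.approx(5.0, abs=0.15)
        assert lm.scale == pytest.approx(2.0, rel=0.05)
        assert abs(lm.shape) < 0.05

    def test_gev_level_equivalent_to_empirical_percentile(self):
        # large-sample agreement between return-level and empirical-percentile
        # classification of annual maxima
        rng = np.random.default_rng(10)
        x = rng.gumbel(0.0, 1.0, size=5000)
        _, level = ev.fit_gev_annual_maxima(x, return_period=40)
        emp = np.percentile(x, 97.5)
        agree = ((x > level) == (x > emp)).mean()
        assert agree >= 0.99


class TestFloodClassification:
    def test_flood_year(self):
        assert ev.classify_flood_years(
            np.array([10.0]), 5.0, np.array([0.05]), True
        )[0]

    def test_low_flooded_fraction_excluded(self):
        assert not ev.classify_flood_years(
            np.array([10.0]), 5.0, np.array([0.005]), True
        )[0]

    def test_outflow_below_level_not_flood(self):
        assert not ev.classify_flood_years(
            np.array([4.0]), 5.0, np.array([0.5]), True
        )[0]

    def test_dryness_mask_vetoes(self):
        assert not ev.classify_flood_years(
            np.array([10.0]), 5.0, np.array([0.5]), False
        )[0]


class TestSensitivity:
    def test_event_counts_nested_in_percentile(self, small_grid, small_control, small_summaries):
        matrices = ev.run_sensitivity(small_summaries, small_control, small_grid)
        for e in ev.EVENT_TYPES:
            c95 = matrices[95.0].flags[e].sum(axis=0)
            c975 = matrices[97.5].flags[e].sum(axis=0)
            c99 = matrices[99.0].flags[e].sum(axis=0)
            assert np.all(c95 >= c975)
            assert np.all(c975 >= c99)

    def test_drought_flags_superset_at_looser_percentile(self, small_grid, small_control, small_summaries):
        matrices = ev.run_sensitivity(small_summaries, small_control, small_grid)
        loose = matrices[95.0].flags["drought"]
        tight = matrices[97.5].flags["drought"]
        assert np.all(loose | ~tight)  # tight implies loose

    def test_flood_return_period_tracks_percentile(self, small_summaries):
        thr95 = ev.thresholds_for_percentile(small_summaries, 95.0)
        thr99 = ev.thresholds_for_percentile(small_summaries, 99.0)
        assert thr95.flood_return_period == pytest.approx(20.0)
        assert thr99.flood_return_period == pytest.approx(100.0)
        ok = small_summaries.gev_usable
        assert np.all(thr95.flood_return_level[ok] < thr99.flood_return_level[ok])


class TestDetectEvents:
    def test_year_axis_relabelling_invariance(self, small_grid, small_control, small_summaries):
        thr = ev.thresholds_for_percentile(small_summaries, 97.5)
        m1 = ev.detect_events(small_control, thr, small_grid)
        shifted = syn.SimulationRun(
            small_control.run_kind, small_control.scenario_tag,
            small_control.climate_model_id, small_control.impact_model_id,
            small_control.years + 57, small_control.fields,
        )
        m2 = ev.detect_events(shifted, thr, small_grid)
        for e in m1.flags:
            np.testing.assert_array_equal(m1.flags[e], m2.flags[e])

    def test_flags_false_outside_valid_cells(self, small_grid, small_control, small_summaries):
        thr = ev.thresholds_for_percentile(small_summaries, 97.5)
        m = ev.detect_events(small_control, thr, small_grid)
        for e in m.flags:
            assert not m.flags[e][:, ~m.valid[e]].any()
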