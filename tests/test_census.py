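import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import small_config
from surgecast import SarimaxSpec, SplitSpec
from surgecast.calendars import generate_calendar
from surgecast.census import (
    CensusFeedForward,
    CutoffAudit,
    ExogFeature,
    LeakageError,
    VolumeForecaster,
    build_census,
    census_variants,
    observed_census_canary,
    relative_error_report,
    run_model,
    run_model_grid,
)
from surgecast.los import compute_historic_mean_los
from surgecast.series import DailySeries
from surgecast.synthetic import generate_encounters
from surgecast.volume import build_daily_counts


def cases(days, los):
    return pd.DataFrame(
        {
            "case_id": [f"E{i}" for i in range(len(days))],
            "day_index": days,
            "los_days": np.asarray(los, dtype=float),
            "surgery_type": ["A"] * len(days),
            "planned_same_day_discharge": [l == 0 for l in los],
        }
    )


def census_oracle(days, nights, n_days):
    """Per-case-per-night double loop."""
    out = np.zeros(n_days)
    for d, l in zip(days, nights):
        for night in range(d, min(d + int(l), n_days)):
            out[night] += 1
    return out


class TestBuildCensus:
    def test_hand_example(self):
        cal = generate_calendar(10, 0, frozenset())
        c = build_census(cases([3], [2]), cal)
        assert c.values.tolist() == [0, 0, 0, 1, 1, 0, 0, 0, 0, 0]

    def test_all_same_day_gives_zero_census(self):
        cal = generate_calendar(10, 0, frozenset())
        c = build_census(cases([1, 2, 3], [0, 0, 0]), cal)
        assert np.all(c.values == 0)

    def test_matches_double_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        cal = generate_calendar(60, 0, frozenset())
        for _ in range(20):
            n = rng.integers(1, 500)
            days = rng.integers(0, 60, size=n)
            los = rng.integers(0, 12, size=n)
            c = build_census(cases(days, los), cal)
            assert np.array_equal(c.values, census_oracle(days, los, 60))

    def test_fractional_los_rounds_half_up(self):
        cal = generate_calendar(10, 0, frozenset())
        c = build_census(cases([0, 0], [0.5, 0.49]), cal)
        assert c.values[0] == 1  # 0.5 -> 1 night, 0.49 -> 0

    def test_expected_aggregation_is_fractional_and_conservative(self):
        cal = generate_calendar(10, 0, frozenset())
        c = build_census(cases([2], [1.3]), cal, aggregation="expected")
        assert c.values.tolist() == pytest.approx([0, 0, 1.0, 0.3, 0, 0, 0, 0, 0, 0])
        assert c.values.sum() == pytest.approx(1.3)

    def test_negative_and_missing_los_rejected(self):
        cal = generate_calendar(10, 0, frozenset())
        with pytest.raises(ValueError):
            build_census(cases([0], [-1]), cal)
        with pytest.raises(ValueError, match="missing"):
            build_census(cases([0], [np.nan]), cal)

    @given(
        st.lists(
            st.tuples(st.integers(0, 29), st.integers(0, 40)), min_size=0, max_size=60
        )
    )
    def test_conservation_identity(self, case_list):
        cal = generate_calendar(30, 0, frozenset())
        days = [d for d, _ in case_list]
        los = [l for _, l in case_list]
        t = cases(days, los) if case_list else cases([0], [0])
        c = build_census(t, cal)
        truncated = sum(min(l, 30 - d) for d, l in zip(t["day_index"], t["los_days"]))
        assert c.values.sum() == truncated


class TestVariants:
    def test_perfect_equals_observed(self):
        enc, cal, _ = generate_encounters(small_config(seed=2))
        historic = compute_historic_mean_los(enc)
        v = census_variants(enc, cal, enc["los_days"].to_numpy(float), historic)
        assert np.array_equal(v["perfect"].values, v["observed"].values)

    def test_adjusted_zeroes_flagged_cases(self):
        cal = generate_calendar(10, 0, frozenset())
        t = cases([2, 4], [3, 3])
        t["planned_same_day_discharge"] = [True, False]
        historic = compute_historic_mean_los(t.assign(los_days=[3.0, 3.0]))
        v = census_variants(t, cal, np.array([3.0, 3.0]), historic)
        # the flagged case contributes no nights in the adjusted variant
        assert v["adjusted"].values.tolist() == pytest.approx([0, 0, 0, 0, 1, 1, 1, 0, 0, 0])
        assert v["predicted"].values.sum() == pytest.approx(6.0)

    def test_every_variant_conserves_bed_nights(self):
        enc, cal, _ = generate_encounters(small_config(seed=6))
        historic = compute_historic_mean_los(enc)
        pred = np.clip(enc["los_days"].to_numpy(float) + 0.4, 0, None)
        v = census_variants(enc, cal, pred, historic)
        n = cal.n_days
        day = enc["day_index"].to_numpy()
        sources = {
            "observed": np.floor(enc["los_days"].to_numpy(float) + 0.5),
            "perfect": np.floor(enc["los_days"].to_numpy(float) + 0.5),
            "predicted": pred,
            "adjusted": np.where(enc["planned_same_day_discharge"], 0.0, pred),
            "surgery_mean": historic.lookup(enc["surgery_type"]),
        }
        for name, los in sources.items():
            if name in ("observed", "perfect"):
                truncated = np.minimum(los, n - day).sum()
            else:  # expected aggregation: full nights truncated, fraction kept if inside
                full = np.floor(los)
                frac = los - full
                truncated = (np.minimum(full, n - day) + np.where(day + full < n, frac, 0.0)).sum()
            assert v[name].values.sum() == pytest.approx(truncated, rel=1e-12)


class TestAuditAndLeakage:
    def split(self):
        return SplitSpec(train_end_day=90, val_end_day=115, n_days=140)

    def test_ols_leak_canary_triggers(self):
        enc, cal, _ = generate_encounters(small_config(seed=3))
        obs = build_census(enc, cal)
        canary = observed_census_canary(obs)
        with pytest.raises(LeakageError):
            run_model(obs, "ols", [canary], "two_week", self.split())

    def test_same_day_schedule_feature_is_legal_but_two_week_needs_forecaster(self):
        enc, cal, _ = generate_encounters(small_config(seed=3))
        obs = build_census(enc, cal)
        feat = ExogFeature("predicted_census", obs.values, "schedule")  # no forecaster
        spec = SarimaxSpec(P=1, D=1, Q=0, m=7, exog_names=("predicted_census",))
        ev = run_model(obs, "sarimax", [feat], "same_day", self.split(), spec=spec)
        summary = ev.audit.verify()
        assert summary["schedule_known"] == 25  # one per test day
        with pytest.raises(LeakageError):
            run_model(obs, "sarimax", [feat], "two_week", self.split(), spec=spec)

    def test_tampered_audit_entry_is_caught(self):
        audit = CutoffAudit()
        feat = ExogFeature("x", np.zeros(10), "observed")
        audit.record(target_day=9, cutoff=5, protocol="two_week", feature=feat, day=8, status="observed_past")
        with pytest.raises(LeakageError):
            audit.verify()

    def test_forecast_fed_counts_logged_for_lagged_counts(self):
        enc, cal, _ = generate_encounters(small_config(seed=3))
        obs = build_census(enc, cal)
        counts = build_daily_counts(enc, cal)
        vol = VolumeForecaster(counts, cal.holiday_indicator.astype(float))
        lag7 = np.concatenate([counts.values[:7], counts.values[:-7]])
        feat = ExogFeature("surgery_count_lag7", lag7, "observed", known_lag=7,
                           forecaster=lambda cutoff, days: vol.forecast(cutoff, days - 7))
        spec = SarimaxSpec(P=1, D=1, Q=0, m=7, exog_names=("surgery_count_lag7",))
        ev = run_model(obs, "sarimax", [feat], "two_week", self.split(), spec=spec)
        summary = ev.audit.verify()
        # the last 7 days of each 14-day path need forecast-fed lagged counts
        assert summary["forecast_fed"] == 25 * 7


class TestRunModel:
    def split(self):
        return SplitSpec(train_end_day=90, val_end_day=115, n_days=140)

    def test_deterministic_weekly_census_long_term_rmse_zero(self):
        cal = generate_calendar(140, 0, frozenset())
        census = DailySeries(cal, np.tile([30.0, 32, 34, 36, 38, 20, 15], 20), "census")
        spec = SarimaxSpec(P=0, D=1, Q=1, m=7)
        ev = run_model(census, "sarimax", [], "long_term", self.split(), spec=spec)
        assert ev.rmse == pytest.approx(0.0, abs=1e-5)
        assert len(ev.records) == 25

    def test_rmse_and_sd_definitions(self):
        cal = generate_calendar(140, 0, frozenset())
        rng = np.random.default_rng(0)
        census = DailySeries(cal, np.tile([30.0, 32, 34, 36, 38, 20, 15], 20) + rng.normal(0, 2, 140), "c")
        spec = SarimaxSpec(P=0, D=1, Q=1, m=7)
        ev = run_model(census, "sarimax", [], "long_term", self.split(), spec=spec)
        err = ev.records["error"].to_numpy()
        assert ev.rmse == pytest.approx(float(np.sqrt(np.mean(err**2))))
        assert ev.sd == pytest.approx(float(np.std(np.abs(err), ddof=1)))

    def test_var_long_term_runs_and_other_protocols_rejected(self):
        enc, cal, _ = generate_encounters(small_config(seed=7))
        obs = build_census(enc, cal)
        counts = build_daily_counts(enc, cal)
        hol = ExogFeature("holidays", cal.holiday_indicator.astype(float), "calendar")
        ev = run_model(obs, "var", [hol], "long_term", self.split(), counts=counts)
        assert np.isfinite(ev.rmse) and len(ev.records) == 25
        with pytest.raises(ValueError):
            run_model(obs, "var", [hol], "same_day", self.split(), counts=counts)


class TestGridAndReports:
    def test_grid_rows_and_audits(self, split):
        enc, cal, _ = generate_encounters(small_config(seed=9, n_days=365, weekday_volume_mean=30.0,
                                                       weekend_volume_mean=15.0, holiday_volume_mean=10.0,
                                                       holidays=frozenset({10, 75, 180, 300})))
        fit_window = enc[enc["day_index"] < split.val_end_day]
        historic = compute_historic_mean_los(fit_window)
        pred = historic.lookup(enc["surgery_type"]) * 0.9
        grid = run_model_grid(enc, cal, split, pred, historic,
                               los_fit_window_observed=fit_window["los_days"].to_numpy(float))
        assert len(grid) == 11
        protocols = {(ev.protocol, ev.model) for ev in grid}
        assert ("long_term", "sarima") in protocols and ("long_term", "var") in protocols
        assert ("two_week", "ols") in protocols
        for ev in grid:
            ev.audit.verify()
            assert np.isfinite(ev.rmse)
            d = ev.to_dict()
            assert set(d) >= {"model", "spec", "exog", "protocol", "rmse", "sd"}

    def test_relative_error_report(self):
        ev = type("E", (), {"rmse": 22.67})()
        rep = relative_error_report(ev, capacity_reference=839.0)
        assert rep["relative_error_pct"] == pytest.approx(100 * 22.67 / 839.0)
        assert relative_error_report(type("E", (), {"rmse": 0.0})(), 100.0)["relative_error_pct"] == 0.0
        full = relative_error_report(type("E", (), {"rmse": 100.0})(), 100.0)
        assert full["relative_error_pct"] == pytest.approx(100.0)
        with pytest.raises(ValueError):
            relative_error_report(ev, 0.0)


class TestFeedForward:
    def test_volume_forecaster_refuses_past_days(self):
        enc, cal, _ = generate_encounters(small_config(seed=1))
        counts = build_daily_counts(enc, cal)
        vol = VolumeForecaster(counts, cal.holiday_indicator.astype(float))
        with pytest.raises(ValueError):
            vol.forecast(100, np.array([99]))

    def test_known_contribution_counts_scheduled_cases(self):
        cal = generate_calendar(20, 0, frozenset())
        t = cases([2, 5, 15], [4, 3, 2])
        counts = build_daily_counts(t, cal)
        vol = VolumeForecaster(counts, np.zeros(20))
        ff = CensusFeedForward(t, cal, t["los_days"].to_numpy(float), vol, np.array([2.0, 2.0, 3.0]))
        known = ff._known_contribution(cutoff=6, days=np.array([6, 7, 8]))
        # the day-5 case (3 nights) occupies nights 5-7; gone by night 8
        assert known.tolist() == [1.0, 1.0, 0.0]
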