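"""Wearable stream processing: validity filter, cosinor fits, activity
bouts, heart-rate texture, daily table assembly and two-stage imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adhersense.wearable import (
    activity_bouts,
    build_wearable_daily,
    cosinor_fit,
    hr_texture,
    impute_wearable,
    valid_day_filter,
)


def _stream(pid, day, hr_present_minutes, steps=None):
    ts = pd.date_range(day, periods=1440, freq="min")
    hr = np.full(1440, 70.0)
    hr[hr_present_minutes:] = np.nan
    return pd.DataFrame(
        {
            "participant_id": pid,
            "timestamp": ts,
            "steps": np.zeros(1440) if steps is None else steps,
            "heart_rate": hr,
            "sleep_flag": 0.0,
        }
    )


class TestValidDay:
    @pytest.mark.parametrize("wear, valid", [(480, True), (479, False), (1440, True)])
    def test_eight_hour_boundary(self, wear, valid):
        flags = valid_day_filter(_stream("p", "2024-01-01", wear))
        assert flags["wear_minutes"].item() == wear
        assert bool(flags["valid"].item()) == valid


class TestCosinor:
    def test_noiseless_closed_form(self):
        t = np.arange(1440, dtype=float)
        y = 10 + 5 * np.cos(2 * np.pi * (t - 14 * 60) / 1440)
        fit = cosinor_fit(y, t)
        assert fit.mesor == pytest.approx(10.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(5.0, abs=1e-6)
        assert fit.acrophase == pytest.approx(14.0, abs=0.02)

    def test_constant_series(self):
        fit = cosinor_fit(np.full(1440, 7.3))
        assert fit.mesor == pytest.approx(7.3)
        assert fit.amplitude == 0.0
        assert fit.acrophase == 0.0

    def test_noisy_recovery_within_3se(self):
        # linearized cosinor: SEs come from the sin/cos regression itself
        rng = np.random.default_rng(7)
        t = np.arange(1440, dtype=float)
        w = 2 * np.pi / 1440
        y = 10 + 5 * np.cos(w * (t - 14 * 60)) + rng.normal(0, 1, 1440)
        X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma2 = res[0] / (len(t) - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        fit = cosinor_fit(y, t)
        assert abs(fit.mesor - 10) < 3 * se[0]
        a_true, b_true = 5 * np.cos(w * 14 * 60), 5 * np.sin(w * 14 * 60)
        assert abs(fit.amplitude - 5) < 3 * np.hypot(se[1], se[2])
        assert abs(fit.acrophase - 14.0) < 0.2

    def test_wraps_acrophase(self):
        t = np.arange(1440, dtype=float)
        y = 3 + 2 * np.cos(2 * np.pi * (t - 23.5 * 60) / 1440)
        assert cosinor_fit(y, t).acrophase == pytest.approx(23.5, abs=0.02)

    def test_insufficient_phases_rejected(self):
        with pytest.raises(ValueError):
            cosinor_fit([1.0, 2.0], [0.0, 1.0])


class TestActivityBouts:
    @pytest.mark.parametrize(
        "steps, kwargs, expected",
        [
            ([0, 0, 120, 130, 0, 110, 0], dict(active_threshold=100, min_bout=1), (2, 1.5)),
            (np.zeros(1440), {}, (0, 0.0)),
            (np.full(600, 150.0), dict(active_threshold=100), (1, 600.0)),
            ([120, 0, 120, 120, 0, 120], dict(active_threshold=100, min_bout=2), (1, 2.0)),
        ],
    )
    def test_examples(self, steps, kwargs, expected):
        n, avg = activity_bouts(steps, **kwargs)
        assert (n, avg) == (expected[0], pytest.approx(expected[1]))

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=200), st.integers(1, 5))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_scan(self, active, min_bout):
        steps = [150.0 if a else 0.0 for a in active]
        # oracle: explicit scan over runs
        runs, cur = [], 0
        for a in active:
            if a:
                cur += 1
            elif cur:
                runs.append(cur)
                cur = 0
        if cur:
            runs.append(cur)
        runs = [r for r in runs if r >= min_bout]
        n, avg = activity_bouts(steps, active_threshold=100, min_bout=min_bout)
        assert n == len(runs)
        assert avg == pytest.approx(np.mean(runs) if runs else 0.0)


class TestHrTexture:
    def test_constant_is_fully_homogeneous(self):
        s, k, h = hr_texture(np.full(100, 66.0))
        assert (s, k, h) == (0.0, 0.0, 1.0)

    def test_alternating_two_levels(self):
        # all co-occurrence mass at |i-j| = 1 -> homogeneity 1/(1+1)
        y = np.tile([60.0, 80.0], 50)
        _, _, h = hr_texture(y, n_levels=2)
        assert h == pytest.approx(0.5)

    def test_symmetric_series_zero_skew(self):
        y = np.concatenate([np.arange(50.0, 90.0), np.arange(50.0, 90.0)[::-1]])
        s, _, _ = hr_texture(y)
        assert abs(s) < 1e-12

    def test_homogeneity_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.normal(70, 8, 300)
            _, _, h = hr_texture(y)
            assert 0 < h <= 1

    def test_missing_minutes_skipped(self):
        y = np.array([60.0, np.nan, 60.0, 80.0, np.nan, 80.0] * 20)
        s, k, h = hr_texture(y, n_levels=2)
        assert np.isfinite([s, k, h]).all()


class TestDailyTable:
    def test_total_steps_conserved_and_invalid_day_absent(self):
        ts = pd.date_range("2024-01-01", periods=2880, freq="min")
        steps = np.zeros(2880)
        steps[:1440] = 1000 / 1440  # evenly spread
        hr = np.full(2880, 70.0)
        hr[1440 + 400:] = np.nan  # day 2: only 400 wear minutes
        df = pd.DataFrame(
            {
                "participant_id": "p",
                "timestamp": ts,
                "steps": steps,
                "heart_rate": hr,
                "sleep_flag": 0.0,
            }
        )
        daily = build_wearable_daily(df)
        assert len(daily) == 1
        assert daily["total_steps"].item() == pytest.approx(1000.0)
        assert daily["wear_minutes"].item() == 1440

    def test_cosinor_columns_recover_generating_curve(self):
        t = np.arange(1440, dtype=float)
        steps = 10 + 8 * np.cos(2 * np.pi / 1440 * (t - 15 * 60))
        df = pd.DataFrame(
            {
                "participant_id": "p",
                "timestamp": pd.date_range("2024-01-01", periods=1440, freq="min"),
                "steps": steps,
                "heart_rate": 70.0,
                "sleep_flag": 0.0,
            }
        )
        row = build_wearable_daily(df).iloc[0]
        assert row["cosinor_mesor"] == pytest.approx(10.0, abs=1e-6)
        assert row["cosinor_amplitude"] == pytest.approx(8.0, abs=1e-6)
        assert row["cosinor_acrophase"] == pytest.approx(15.0, abs=0.02)


def _daily_table(values: dict, n_days=10, pid="p"):
    dates = pd.date_range("2024-01-01", periods=n_days, freq="D")
    df = pd.DataFrame({"participant_id": pid, "date": dates})
    for col, vals in values.items():
        df[col] = vals
    return df


class TestImputeWearable:
    def test_linear_midpoint(self):
        t = _daily_table({"a": [10.0, np.nan, 14.0], "b": [1.0, 2.0, 3.0]}, n_days=3)
        out = impute_wearable(t)
        assert out["a"].iloc[1] == pytest.approx(12.0)
        assert out["a"].iloc[0] == 10.0 and out["a"].iloc[2] == 14.0

    def test_fully_observed_unchanged(self):
        t = _daily_table({"a": np.arange(10.0), "b": np.ones(10)})
        out = impute_wearable(t)
        pd.testing.assert_frame_equal(out, t)

    def test_column_over_30pct_dropped(self):
        # leading missingness that interpolation cannot reach
        n = 100
        a = np.arange(float(n))
        bad = a.copy()
        bad[:31] = np.nan  # 31% missing, all at the head
        ok = a.copy()
        ok[40:60] = np.nan  # 20% interior -> interpolated
        t = _daily_table({"bad": bad, "ok": ok, "ref": a}, n_days=n)
        out = impute_wearable(t)
        assert "bad" not in out.columns
        assert "ok" in out.columns and out["ok"].notna().all()

    def test_monotone_gap_filled_between_neighbors(self):
        vals = np.array([1.0, np.nan, np.nan, np.nan, 9.0])
        t = _daily_table({"a": vals, "b": np.arange(5.0)}, n_days=5)
        out = impute_wearable(t)
        inner = out["a"].iloc[1:4]
        assert ((inner > 1.0) & (inner < 9.0)).all()

    def test_keep_columns_pins_schema(self):
        n = 40
        a = np.arange(float(n))
        bad = a.copy()
        bad[: int(0.5 * n)] = np.nan
        t = _daily_table({"bad": bad, "ref": a}, n_days=n)
        out = impute_wearable(t, keep_columns=["bad", "ref"])
        assert "bad" in out.columns and out["bad"].notna().all()
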