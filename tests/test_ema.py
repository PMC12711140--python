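"""EMA prompt calendars, daily panel assembly, rolling-mode /
chained-equation imputation and episodic forward-fill."""

import numpy as np
import pandas as pd
import pytest

from adhersense.ema import (
    SCHEDULES,
    build_daily_panel,
    expected_prompts,
    impute_ema,
    panel_features,
    propagate_episodic,
)


def _range(days, start="2024-01-01"):
    return pd.date_range(start, periods=days, freq="D")


class TestExpectedPrompts:
    def test_28_day_calendar_counts(self):
        cal = expected_prompts(_range(28))
        counts = cal["schedule"].value_counts()
        assert counts["morning"] == 28
        assert counts["evening"] == 28
        assert counts["random"] == 10  # days 1, 4, ..., 28
        assert counts["biweekly"] == 2  # days 1, 15
        assert counts["monthly"] == 1

    def test_single_day_all_schedules_trigger(self):
        cal = expected_prompts(_range(1))
        assert sorted(cal["schedule"]) == sorted(SCHEDULES)

    def test_empty_range(self):
        assert expected_prompts(pd.DatetimeIndex([])).empty

    def test_availability_windows(self):
        cal = expected_prompts(_range(1)).set_index("schedule")
        morning = cal.loc["morning"]
        assert morning["prompt_time"].hour == 9
        assert (morning["window_end"] - morning["prompt_time"]) == pd.Timedelta(hours=4)
        biweekly = cal.loc["biweekly"]
        assert (biweekly["window_end"] - biweekly["prompt_time"]) == pd.Timedelta(days=7)


def _responses(rows):
    return pd.DataFrame(
        rows,
        columns=["participant_id", "schedule", "prompt_date", "prompt_time",
                 "response_time", "item_id", "value"],
    )


ITEM_TYPES = {
    "morning_mood": "numeric",
    "random_side_effects": "categorical",
    "biweekly_support": "numeric",
}


class TestBuildDailyPanel:
    def test_no_responses_all_missing(self):
        r = _responses(
            [("p1", "morning", "2024-01-01", "2024-01-01 09:00", pd.NaT,
              "morning_mood", np.nan)]
        )
        panel = build_daily_panel(r, _range(5), ITEM_TYPES, participants=["p1"])
        assert panel.values.shape == (5, 3)
        assert not panel.observed.any().any()

    def test_single_cell_observed(self):
        r = _responses(
            [("p1", "morning", "2024-01-03", "2024-01-03 09:00",
              "2024-01-03 09:30", "morning_mood", 4.0)]
        )
        panel = build_daily_panel(r, _range(5), ITEM_TYPES, participants=["p1"])
        assert panel.observed.to_numpy().sum() == 1
        assert panel.values.loc[("p1", pd.Timestamp("2024-01-03")), "morning_mood"] == 4.0

    def test_late_response_flagged_not_dropped(self):
        r = _responses(
            [("p1", "morning", "2024-01-01", "2024-01-01 09:00",
              "2024-01-01 13:30", "morning_mood", 2.0)]
        )
        panel = build_daily_panel(r, _range(2), ITEM_TYPES, participants=["p1"])
        key = ("p1", pd.Timestamp("2024-01-01"))
        assert panel.observed.loc[key, "morning_mood"]
        assert panel.out_of_window.loc[key, "morning_mood"]

    def test_duplicate_keeps_last(self):
        r = _responses(
            [
                ("p1", "morning", "2024-01-01", "2024-01-01 09:00",
                 "2024-01-01 09:10", "morning_mood", 1.0),
                ("p1", "morning", "2024-01-01", "2024-01-01 09:00",
                 "2024-01-01 10:00", "morning_mood", 5.0),
            ]
        )
        with pytest.warns(UserWarning, match="duplicate"):
            panel = build_daily_panel(r, _range(1), ITEM_TYPES, participants=["p1"])
        assert panel.values.iloc[0]["morning_mood"] == 5.0

    def test_row_count_is_grid_product(self):
        r = _responses(
            [("p1", "morning", "2024-01-01", "2024-01-01 09:00", pd.NaT,
              "morning_mood", np.nan)]
        )
        panel = build_daily_panel(r, _range(7), ITEM_TYPES,
                                  participants=["p1", "p2", "p3"])
        assert len(panel.values) == 21
        assert len(impute_ema(panel, seed=0).values) == 21


def _cat_panel(seq, pid="p1"):
    """Panel with one categorical daily item observed as given
    (None = missing)."""
    rows = []
    for i, v in enumerate(seq):
        d = pd.Timestamp("2024-01-01") + pd.Timedelta(days=i)
        rows.append(
            (pid, "morning", d, d + pd.Timedelta(hours=9),
             d + pd.Timedelta(hours=10) if v is not None else pd.NaT,
             "morning_cat", v)
        )
    r = _responses(rows)
    return build_daily_panel(
        r, _range(len(seq)), {"morning_cat": "categorical"}, participants=[pid]
    )


class TestImputeEma:
    def test_rolling_mode(self):
        panel = _cat_panel(["A", "A", "B", None])
        out = impute_ema(panel, seed=0)
        assert out.values["morning_cat"].iloc[3] == "A"

    def test_tie_prefers_most_recent(self):
        panel = _cat_panel(["A", "B", None])
        out = impute_ema(panel, seed=0)
        assert out.values["morning_cat"].iloc[2] == "B"

    def test_window_strictly_preceding(self):
        # 7 observed 'B's more than 7 days before the gap are out of
        # window; the most recent observed values dominate
        panel = _cat_panel(["B"] * 3 + ["A"] * 7 + [None])
        out = impute_ema(panel, seed=0)
        assert out.values["morning_cat"].iloc[10] == "A"

    def test_empty_window_falls_back_to_participant_mode(self):
        panel = _cat_panel([None, None, None, None, None, None, None, None, "C", "C"])
        out = impute_ema(panel, seed=0)
        assert out.values["morning_cat"].iloc[0] == "C"

    def test_fully_observed_numeric_unchanged(self):
        rows = []
        for i in range(5):
            d = pd.Timestamp("2024-01-01") + pd.Timedelta(days=i)
            rows.append(("p1", "morning", d, d + pd.Timedelta(hours=9),
                         d + pd.Timedelta(hours=10), "morning_mood", float(i)))
        panel = build_daily_panel(_responses(rows), _range(5),
                                  {"morning_mood": "numeric"}, participants=["p1"])
        out = impute_ema(panel, seed=0)
        assert list(out.values["morning_mood"]) == [0.0, 1.0, 2.0, 3.0, 4.0]

    def test_observed_cells_never_altered(self):
        rows = []
        for i in (0, 2, 4):
            d = pd.Timestamp("2024-01-01") + pd.Timedelta(days=i)
            rows.append(("p1", "morning", d, d + pd.Timedelta(hours=9),
                         d + pd.Timedelta(hours=10), "morning_mood", float(10 + i)))
        panel = build_daily_panel(_responses(rows), _range(5),
                                  {"morning_mood": "numeric"}, participants=["p1"])
        out = impute_ema(panel, seed=0)
        for i in (0, 2, 4):
            assert out.values["morning_mood"].iloc[i] == 10.0 + i
        assert out.values["morning_mood"].notna().all()

    def test_item_without_any_observation_dropped(self):
        r = _responses(
            [("p1", "morning", "2024-01-01", "2024-01-01 09:00", pd.NaT,
              "morning_mood", np.nan),
             ("p1", "morning", "2024-01-01", "2024-01-01 09:00",
              "2024-01-01 09:30", "morning_other", 3.0)]
        )
        panel = build_daily_panel(
            r, _range(3), {"morning_mood": "numeric", "morning_other": "numeric"},
            participants=["p1"],
        )
        with pytest.warns(UserWarning, match="no observed"):
            out = impute_ema(panel, seed=0)
        assert "morning_mood" not in out.values.columns


def _episodic_panel(responses_by_day, schedule, item, n_days):
    rows = []
    trigger = SCHEDULES[schedule].trigger_hour
    for day, value in responses_by_day.items():
        d = pd.Timestamp("2024-01-01") + pd.Timedelta(days=day)
        rows.append(("p1", schedule, d, d + pd.Timedelta(hours=trigger),
                     d + pd.Timedelta(hours=trigger + 1), item, value))
    return build_daily_panel(_responses(rows), _range(n_days),
                             {item: "numeric"}, participants=["p1"])


class TestPropagateEpisodic:
    def test_biweekly_covers_fourteen_days(self):
        # propagation in isolation: the answered prompt covers its day
        # plus 13 more; the day-15 prompt stays missing until imputation
        panel = _episodic_panel({0: 7.0}, "biweekly", "biweekly_support", 20)
        col = propagate_episodic(panel).values["biweekly_support"]
        assert (col.iloc[:14] == 7.0).all()
        assert col.iloc[14:].isna().all()

    def test_random_truncated_at_next_response(self):
        panel = _episodic_panel({0: 1.0, 3: 2.0}, "random", "random_coping", 7)
        out = propagate_episodic(impute_ema(panel, seed=0))
        col = out.values["random_coping"]
        assert list(col.iloc[:3]) == [1.0, 1.0, 1.0]
        assert (col.iloc[3:6] == 2.0).all()

    def test_daily_items_never_forward_filled(self):
        panel = _cat_panel(["A", None, "B"])
        imputed = impute_ema(panel, seed=0)
        before = imputed.values.copy()
        after = propagate_episodic(imputed).values
        pd.testing.assert_frame_equal(before, after)

    def test_propagated_interval_is_constant(self):
        panel = _episodic_panel({0: 4.0, 14: 9.0}, "biweekly", "biweekly_support", 28)
        out = propagate_episodic(impute_ema(panel, seed=0))
        col = out.values["biweekly_support"]
        assert col.iloc[:14].nunique() == 1
        assert col.iloc[14:28].nunique() == 1

    def test_unanswered_prompt_imputed_then_propagated(self):
        # prompt on day 14 unanswered: imputation fills the prompt day,
        # propagation spreads it; panel ends complete
        rows = [("p1", "biweekly", "2024-01-01", "2024-01-01 12:00",
                 "2024-01-01 13:00", "biweekly_support", 5.0),
                ("p1", "biweekly", "2024-01-15", "2024-01-15 12:00",
                 pd.NaT, "biweekly_support", np.nan)]
        panel = build_daily_panel(_responses(rows), _range(28),
                                  {"biweekly_support": "numeric"},
                                  participants=["p1"])
        out = propagate_episodic(impute_ema(panel, seed=0))
        assert out.values["biweekly_support"].notna().all()


class TestPanelFeatures:
    def test_ordinal_encoding(self):
        panel = _cat_panel(["A", "B", "A"])
        out = panel_features(impute_ema(panel, seed=0))
        assert set(out.columns) == {"participant_id", "date", "morning_cat"}
        assert list(out["morning_cat"]) == [0.0, 1.0, 0.0]
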