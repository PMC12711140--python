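"""Ecological momentary assessment (EMA) processing: prompt calendars for
the five delivery schedules, a complete daily response panel, two-stage
imputation (rolling-mode for categorical items, chained-equation for
numeric items) and forward-fill propagation of episodic items.

Schedules (clock times are naive local time):

========  =============  =============  ====================
schedule  trigger        cadence        availability
========  =============  =============  ====================
morning   09:00          daily          until 13:00 (4 h)
evening   19:00          daily          until 00:00 (5 h)
random    19:00          every 3 days   until next prompt (3 d)
biweekly  12:00          every 14 days  7 days
monthly   12:00          every 28 days  7 days
========  =============  =============  ====================

Episodic (random / biweekly / monthly) responses are forward-filled across
their cadence interval (3 / 14 / 28 days: the response day plus
cadence - 1 subsequent days, truncated at the next observed response) to
put every item on a daily grid alongside the morning/evening items.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

__all__ = [
    "EmaSchedule",
    "SCHEDULES",
    "EPISODIC",
    "expected_prompts",
    "EmaPanel",
    "build_daily_panel",
    "impute_ema",
    "propagate_episodic",
    "panel_features",
]


@dataclass(frozen=True)
class EmaSchedule:
    name: str
    trigger_hour: float
    cadence_days: int
    availability_hours: float


SCHEDULES: dict[str, EmaSchedule] = {
    "morning": EmaSchedule("morning", 9.0, 1, 4.0),
    "evening": EmaSchedule("evening", 19.0, 1, 5.0),
    "random": EmaSchedule("random", 19.0, 3, 72.0),
    "biweekly": EmaSchedule("biweekly", 12.0, 14, 168.0),
    "monthly": EmaSchedule("monthly", 12.0, 28, 168.0),
}

#: schedules whose answers are propagated forward across their cadence
EPISODIC = ("random", "biweekly", "monthly")


def expected_prompts(
    date_range: pd.DatetimeIndex,
    schedules: dict[str, EmaSchedule] | None = None,
) -> pd.DataFrame:
    """Prompt calendar over a date range.

    Every schedule triggers on the first day of the range and then at its
    cadence. Columns: schedule, prompt_date, prompt_time, window_end.
    Response-rate summaries are responses / expected prompts.
    """
    schedules = schedules or SCHEDULES
    dates = pd.DatetimeIndex(date_range).normalize().unique().sort_values()
    rows = []
    if len(dates) == 0:
        return pd.DataFrame(columns=["schedule", "prompt_date", "prompt_time", "window_end"])
    for sch in schedules.values():
        for d in dates[:: sch.cadence_days]:
            t = d + pd.Timedelta(hours=sch.trigger_hour)
            rows.append((sch.name, d, t, t + pd.Timedelta(hours=sch.availability_hours)))
    return pd.DataFrame(rows, columns=["schedule", "prompt_date", "prompt_time", "window_end"])


@dataclass
class EmaPanel:
    """Complete participant-day panel of EMA item values.

    values / observed / prompt_day are DataFrames indexed by
    (participant_id, date); columns are item ids. ``observed`` marks cells
    backed by an actual response; ``prompt_day`` marks days on which the
    item's schedule fired a prompt for that participant. ``item_schedule``
    and ``item_type`` ('numeric' | 'categorical') declare each item.
    """

    values: pd.DataFrame
    observed: pd.DataFrame
    prompt_day: pd.DataFrame
    item_schedule: dict[str, str]
    item_type: dict[str, str]
    out_of_window: pd.DataFrame | None = None
    categories: dict[str, list] = field(default_factory=dict)

    @property
    def items(self) -> list[str]:
        return list(self.values.columns)


def build_daily_panel(
    responses: pd.DataFrame,
    date_range: pd.DatetimeIndex,
    item_types: dict[str, str],
    participants=None,
    schedules: dict[str, EmaSchedule] | None = None,
) -> EmaPanel:
    """Merge raw responses onto a complete participant x day grid.

    ``responses`` is long format: participant_id, schedule, prompt_date,
    response_time (NaT if unanswered), item_id, value. Unanswered cells
    stay missing with ``observed`` False. Duplicate responses to one
    prompt keep the last by response_time (with a warning). Responses
    after the availability window are retained but flagged in
    ``out_of_window``.
    """
    schedules = schedules or SCHEDULES
    dates = pd.DatetimeIndex(date_range).normalize().unique().sort_values()
    if len(dates) == 0:
        raise ValueError("date_range must be nonempty")
    r = responses.copy()
    r["prompt_date"] = pd.to_datetime(r["prompt_date"]).dt.normalize()
    r["response_time"] = pd.to_datetime(r["response_time"])
    answered = r[r["response_time"].notna()].copy()
    if participants is None:
        participants = sorted(pd.unique(r["participant_id"]))
    idx = pd.MultiIndex.from_product(
        [participants, dates], names=["participant_id", "date"]
    )
    item_ids = sorted(item_types)
    item_schedule = {}
    for it in item_ids:
        sch = pd.unique(r.loc[r["item_id"] == it, "schedule"])
        item_schedule[it] = sch[0] if len(sch) else "morning"

    dup_key = ["participant_id", "schedule", "prompt_date", "item_id"]
    n_before = len(answered)
    answered = answered.sort_values("response_time", kind="stable").drop_duplicates(
        dup_key, keep="last"
    )
    if len(answered) < n_before:
        warnings.warn("duplicate responses to a prompt: keeping the last")

    values = pd.DataFrame(index=idx, columns=item_ids, dtype=object)
    observed = pd.DataFrame(False, index=idx, columns=item_ids)
    oow = pd.DataFrame(False, index=idx, columns=item_ids)
    for row in answered.itertuples(index=False):
        key = (row.participant_id, row.prompt_date)
        if key not in values.index or row.item_id not in values.columns:
            continue
        values.at[key, row.item_id] = row.value
        observed.at[key, row.item_id] = True
        sch = schedules[row.schedule]
        window_end = (
            row.prompt_date
            + pd.Timedelta(hours=sch.trigger_hour + sch.availability_hours)
        )
        if row.response_time > window_end:
            oow.at[key, row.item_id] = True
    for it in item_ids:
        if item_types[it] == "numeric":
            values[it] = pd.to_numeric(values[it], errors="coerce")

    prompt_day = pd.DataFrame(False, index=idx, columns=item_ids)
    cal = expected_prompts(dates, schedules)
    for it in item_ids:
        days = cal.loc[cal["schedule"] == item_schedule[it], "prompt_date"]
        mask = idx.get_level_values("date").isin(set(days))
        prompt_day[it] = mask

    categories = {}
    for it in item_ids:
        if item_types[it] == "categorical":
            obs = values.loc[observed[it], it]
            categories[it] = sorted(pd.unique(obs.dropna()), key=str)
    return EmaPanel(
        values=values,
        observed=observed,
        prompt_day=prompt_day,
        item_schedule=item_schedule,
        item_type=dict(item_types),
        out_of_window=oow,
        categories=categories,
    )


def _rolling_mode_fill(series: pd.Series, window: int = 7) -> pd.Series:
    """Fill NaN with the mode of the strictly preceding ``window`` days;
    ties keep the most recent tied value; empty window falls through."""
    vals = series.to_numpy(dtype=object)
    out = vals.copy()
    for i in range(len(vals)):
        if out[i] is not None and not pd.isna(out[i]):
            continue
        lo = max(0, i - window)
        past = [v for v in vals[lo:i] if v is not None and not pd.isna(v)]
        if not past:
            continue
        counts: dict = {}
        for v in past:
            counts[v] = counts.get(v, 0) + 1
        best = max(counts.values())
        # most recent among tied modes
        for v in reversed(past):
            if counts[v] == best:
                out[i] = v
                break
    return pd.Series(out, index=series.index, dtype=object)


def impute_ema(panel: EmaPanel, seed: int = 0, window: int = 7) -> EmaPanel:
    """Two-stage item-level imputation.

    Categorical items: per participant, missing cells take the mode over
    the 7 days strictly preceding the missing day (ties -> most recent),
    falling back to the participant's overall mode, then the global mode.
    Numeric items: chained-equation iterative imputation (linear
    estimator, 10 iterations, seeded) across EMA items. Episodic items
    are imputed on their prompt days only; the gaps between prompts are
    the propagation step's job. Observed cells are never altered; items
    with no observed value anywhere are dropped with a warning.
    """
    values = panel.values.copy()
    empty = [it for it in values.columns if not panel.observed[it].any()]
    if empty:
        warnings.warn(f"EMA items with no observed responses dropped: {empty}")
        values = values.drop(columns=empty)
    items = list(values.columns)
    cat_items = [it for it in items if panel.item_type[it] == "categorical"]
    num_items = [it for it in items if panel.item_type[it] == "numeric"]

    for it in cat_items:
        col = values[it]
        filled = col.groupby(level="participant_id", group_keys=False).apply(
            _rolling_mode_fill, window=window
        )
        # fall back: participant mode, then global mode (observed values only)
        obs = panel.values.loc[panel.observed[it], it]
        global_mode = obs.mode().iloc[0] if len(obs) else np.nan
        part_mode = obs.groupby(level="participant_id").agg(
            lambda s: s.mode().iloc[0]
        )
        still = filled.isna()
        if still.any():
            pids = filled.index.get_level_values("participant_id")
            fb = pd.Series(
                [part_mode.get(p, global_mode) for p in pids], index=filled.index
            )
            filled = filled.where(~still, fb)
        values[it] = filled

    if num_items:
        mat = values[num_items].to_numpy(dtype=float)
        mask_fill = ~np.isfinite(mat)
        if mask_fill.any():
            imputer = IterativeImputer(max_iter=10, random_state=seed)
            mat_imp = imputer.fit_transform(mat)
            values[num_items] = np.where(mask_fill, mat_imp, mat)

    # episodic items stay defined on prompt days only at this stage
    for it in items:
        if panel.item_schedule[it] in EPISODIC:
            values.loc[~panel.prompt_day[it], it] = np.nan
    return EmaPanel(
        values=values,
        observed=panel.observed[items].copy(),
        prompt_day=panel.prompt_day[items].copy(),
        item_schedule={k: panel.item_schedule[k] for k in items},
        item_type={k: panel.item_type[k] for k in items},
        out_of_window=None if panel.out_of_window is None else panel.out_of_window[items].copy(),
        categories={k: v for k, v in panel.categories.items() if k in items},
    )


def propagate_episodic(panel: EmaPanel) -> EmaPanel:
    """Forward-fill episodic items across their cadence interval.

    Each random / biweekly / monthly value covers its day plus
    cadence - 1 subsequent days (3 / 14 / 28-day footprints), truncated
    whenever a newer value appears. Daily morning/evening items are never
    forward-filled: their gaps belong to the imputation stage.
    """
    values = panel.values.copy()
    for it in panel.items:
        sch_name = panel.item_schedule[it]
        if sch_name not in EPISODIC:
            continue
        limit = SCHEDULES[sch_name].cadence_days - 1
        values[it] = values.groupby(level="participant_id", group_keys=False)[
            it
        ].apply(lambda s: s.ffill(limit=limit) if limit > 0 else s)
    out = EmaPanel(
        values=values,
        observed=panel.observed.copy(),
        prompt_day=panel.prompt_day.copy(),
        item_schedule=dict(panel.item_schedule),
        item_type=dict(panel.item_type),
        out_of_window=None if panel.out_of_window is None else panel.out_of_window.copy(),
        categories=dict(panel.categories),
    )
    return out


def panel_features(panel: EmaPanel) -> pd.DataFrame:
    """Numeric daily feature table from a completed panel.

    Categorical items are ordinal-encoded by their sorted observed
    categories. Returns columns participant_id, date, one column per item.
    """
    df = panel.values.copy()
    for it in panel.items:
        if panel.item_type[it] == "categorical":
            cats = panel.categories.get(it) or sorted(
                pd.unique(df[it].dropna()), key=str
            )
            mapping = {c: i for i, c in enumerate(cats)}
            df[it] = df[it].map(mapping)
        df[it] = pd.to_numeric(df[it], errors="coerce")
    return df.reset_index()
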