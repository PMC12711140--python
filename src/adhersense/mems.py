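"""Daily adherence labeling and dosing-context features from MEMS
bottle-opening event logs.

A smart pill bottle timestamps each opening; opening is treated as a proxy
for taking a once-daily dose. A day is *adherent* when the time elapsed
since the previous dose falls within a clinically acceptable window of
18-30 hours (24 +/- 6 h), bounds inclusive. Days with no opening, or whose
openings all fall outside the window relative to the previous dose, are
non-adherent. The first day with a dose has no prior reference and is
excluded from the label series.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "dedupe_events",
    "inter_dose_intervals",
    "label_daily_adherence",
    "dosing_features",
    "ADHERENT_WINDOW_HOURS",
]

#: inclusive inter-dose interval window, hours
ADHERENT_WINDOW_HOURS = (18.0, 30.0)

_EVENT_COLS = ["participant_id", "opened_at"]


def _check_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = set(_EVENT_COLS) - set(events.columns)
    if missing:
        raise ValueError(f"event log missing columns: {sorted(missing)}")
    out = events[_EVENT_COLS].copy()
    out["opened_at"] = pd.to_datetime(out["opened_at"])
    return out


def dedupe_events(raw: pd.DataFrame, collapse_window: float = 60.0) -> pd.DataFrame:
    """Collapse bursts of openings into single dosing events.

    Within each participant, an event closer than ``collapse_window``
    minutes to the previously *retained* event is dropped (earliest kept).
    With window 0, only exactly duplicated timestamps merge. Openings a few
    minutes apart are usually one dosing occasion (cap re-seated, pill
    counted), so the default is 60 min.
    """
    if collapse_window < 0:
        raise ValueError("collapse_window must be >= 0")
    ev = _check_events(raw).sort_values(_EVENT_COLS, kind="stable")
    if ev.empty:
        return ev.reset_index(drop=True)
    keep_parts = []
    thr = pd.Timedelta(minutes=collapse_window)
    for _, g in ev.groupby("participant_id", sort=True):
        times = g["opened_at"].to_numpy()
        keep = np.zeros(len(times), dtype=bool)
        last = None
        for i, t in enumerate(times):
            if last is None or (t - last) > thr or (collapse_window == 0 and t != last):
                keep[i] = True
                last = t
        keep_parts.append(g.loc[keep])
    return pd.concat(keep_parts, ignore_index=True)


def inter_dose_intervals(log: pd.DataFrame) -> pd.DataFrame:
    """Hours between consecutive openings per participant.

    The first event per participant gets NaN. Requires a sorted
    (deduplicated) log; raises otherwise.
    """
    ev = _check_events(log)
    if not ev.empty:
        for _, g in ev.groupby("participant_id", sort=False):
            if not g["opened_at"].is_monotonic_increasing:
                raise ValueError("event log must be sorted by time within participant")
    delta = ev.groupby("participant_id")["opened_at"].diff()
    out = ev.copy()
    out["hours_since_previous"] = delta.dt.total_seconds() / 3600.0
    return out


def label_daily_adherence(log: pd.DataFrame, day_grid: pd.DatetimeIndex) -> pd.DataFrame:
    """Binary daily adherence labels from inter-dose intervals.

    Parameters
    ----------
    log
        Deduplicated event log.
    day_grid
        Calendar days (midnight boundaries, naive local time) to label;
        must cover all events.

    Returns
    -------
    DataFrame with columns ``participant_id, date, label, interval_hours``.
    ``label`` is 1 iff at least one opening that day follows the previous
    dose by 18-30 h inclusive. ``interval_hours`` is the qualifying
    interval when adherent, otherwise the day's first interval, NaN on
    doseless days. Per participant, days up to and including the first
    dose day are excluded (no prior dose to measure from); participants
    with no events contribute no rows.
    """
    if len(day_grid) == 0:
        raise ValueError("day_grid must be nonempty")
    grid = pd.DatetimeIndex(day_grid).normalize().unique().sort_values()
    iv = inter_dose_intervals(log)
    lo, hi = ADHERENT_WINDOW_HOURS
    rows = []
    for pid, g in iv.groupby("participant_id", sort=True):
        ev_dates = g["opened_at"].dt.normalize()
        if ev_dates.min() < grid[0] or ev_dates.max() > grid[-1]:
            raise ValueError(f"events for participant {pid!r} outside day_grid")
        first_day = ev_dates.iloc[0]
        by_day = g.assign(date=ev_dates).groupby("date")["hours_since_previous"]
        day_ivs = {d: s.to_numpy() for d, s in by_day}
        for d in grid[grid > first_day]:
            ivs = day_ivs.get(d)
            if ivs is None or len(ivs) == 0:
                rows.append((pid, d, 0, np.nan))
                continue
            ok = [h for h in ivs if np.isfinite(h) and lo <= h <= hi]
            if ok:
                rows.append((pid, d, 1, float(ok[0])))
            else:
                finite = [h for h in ivs if np.isfinite(h)]
                rows.append((pid, d, 0, float(finite[0]) if finite else np.nan))
    return pd.DataFrame(rows, columns=["participant_id", "date", "label", "interval_hours"])


def dosing_features(log: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Daily dosing-context features aligned to the label grid.

    One row per (participant, date) in ``labels``:

    - ``dose_hour``: clock hour of the first opening that day (NaN if none)
    - ``morning_dose`` (first opening before 12:00), ``evening_dose``
      (any opening at/after 17:00)
    - ``is_weekend``, ``took_today`` (any opening)
    - ``timing_sd_7d``: sample SD of dose hours over the trailing 7 days
      with doses, 0 with fewer than two doses — the timing-regularity cue
    - ``streak_length``: consecutive adherent days ending today — the
      recency-of-adherence cue
    """
    ev = _check_events(log)
    ev["date"] = ev["opened_at"].dt.normalize()
    ev["hour"] = (
        ev["opened_at"].dt.hour
        + ev["opened_at"].dt.minute / 60.0
        + ev["opened_at"].dt.second / 3600.0
    )
    per_day = ev.groupby(["participant_id", "date"]).agg(
        dose_hour=("hour", "first"),
        evening_dose=("hour", lambda h: int((h >= 17.0).any())),
        n_open=("hour", "size"),
    )
    out_parts = []
    for pid, g in labels.groupby("participant_id", sort=True):
        g = g.sort_values("date").copy()
        key = pd.MultiIndex.from_product([[pid], g["date"]])
        day = per_day.reindex(key).reset_index(drop=True)
        g["dose_hour"] = day["dose_hour"].to_numpy()
        g["took_today"] = day["n_open"].fillna(0).gt(0).astype(int).to_numpy()
        g["morning_dose"] = (g["dose_hour"] < 12.0).fillna(False).astype(int)
        g["evening_dose"] = day["evening_dose"].fillna(0).astype(int).to_numpy()
        g["is_weekend"] = (g["date"].dt.dayofweek >= 5).astype(int)
        # trailing-7-calendar-day SD over days with doses, computed on the
        # full dose history (the first dose day precedes the label grid)
        pev = per_day.loc[pid, "dose_hour"] if pid in per_day.index.get_level_values(0) else pd.Series(dtype=float)
        full_days = pd.date_range(
            min(pev.index.min(), g["date"].min()) if len(pev) else g["date"].min(),
            g["date"].max(),
            freq="D",
        )
        hist = pev.reindex(full_days)
        sd_full = hist.rolling(window=7, min_periods=2).std()
        g["timing_sd_7d"] = sd_full.reindex(g["date"]).fillna(0.0).to_numpy()
        streak, run = [], 0
        for lab in g["label"]:
            run = run + 1 if lab == 1 else 0
            streak.append(run)
        g["streak_length"] = streak
        out_parts.append(g)
    out = pd.concat(out_parts, ignore_index=True)
    cols = [
        "participant_id", "date", "dose_hour", "morning_dose", "evening_dose",
        "is_weekend", "took_today", "timing_sd_7d", "streak_length", "label",
        "interval_hours",
    ]
    return out[cols]
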