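"""Synthetic multimodal cohort generator.

Emulates the four data streams of a mobile-sensing adherence study —
MEMS bottle-opening logs, minute-level wearable streams, schedule-based
EMA responses and a baseline survey — from one latent generative model so
that every downstream stage has recoverable ground truth:

- next-day adherence is Bernoulli on a logit scale combining the base
  rate, a participant random intercept, yesterday's outcome (recency),
  a weekend decrement and a latent AR(1) mood/symptom state;
- adherent days emit one bottle opening around the configured dosing hour
  (non-adherent days emit none, apart from an optional spurious rate);
- steps follow a 24-h cosinor mean curve plus AR(1) noise, heart rate
  tracks steps plus its own circadian term, sleep flags cover the night;
  per-day non-wear gaps blank the heart-rate channel;
- EMA items are noisy readouts of the latent state (plus a categorical
  side-effect item and adherence-linked forgetting items), delivered on
  the five schedules with per-prompt nonresponse;
- baseline features are noisy readouts of the participant intercept.

All timestamps are naive local time with day boundaries at midnight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import CohortConfig
from .ema import SCHEDULES, expected_prompts

__all__ = ["SyntheticCohort", "simulate_cohort", "truth_labels", "write_cohort",
           "EMA_ITEMS"]


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SyntheticCohort:
    """Container for the four generated streams plus latent ground truth."""

    mems: pd.DataFrame       # participant_id, opened_at
    wearable: pd.DataFrame   # participant_id, timestamp, steps, heart_rate, sleep_flag
    ema: pd.DataFrame        # long responses keyed by schedule/prompt_date/item
    baseline: pd.DataFrame   # one row per participant
    truth: pd.DataFrame      # participant_id, date, adherent, state, p_adherent
    config: CohortConfig

    @property
    def dates(self) -> pd.DatetimeIndex:
        start = pd.Timestamp(self.config.start_date)
        return pd.date_range(start, periods=self.config.n_days, freq="D")


#: schematic EMA battery: (item_id, schedule, type, loading on latent state)
EMA_ITEMS = [
    ("morning_mood", "morning", "numeric", 0.8),
    ("morning_anxiety", "morning", "numeric", -0.7),
    ("morning_excited", "morning", "numeric", 0.5),
    ("evening_sadness", "evening", "numeric", -0.8),
    ("evening_stress", "evening", "numeric", -0.6),
    ("evening_social_interactions", "evening", "numeric", 0.4),
    ("evening_forgot_medication", "evening", "categorical", 0.0),
    ("random_side_effects", "random", "categorical", 0.0),
    ("random_coping", "random", "numeric", 0.5),
    ("biweekly_joint_pain", "biweekly", "numeric", -0.5),
    ("biweekly_social_support", "biweekly", "numeric", 0.6),
    ("biweekly_forgot_past2wk", "biweekly", "numeric", 0.0),
    ("monthly_qol", "monthly", "numeric", 0.7),
]

EMA_ITEM_TYPES = {item: kind for item, _, kind, _ in EMA_ITEMS}

_SIDE_EFFECT_LEVELS = np.array(["none", "mild", "moderate", "severe"])


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort; deterministic given ``config`` (same seed ->
    byte-identical tables)."""
    rng = np.random.default_rng(config.seed)
    n, T = config.n_participants, config.n_days
    start = pd.Timestamp(config.start_date)
    dates = pd.date_range(start, periods=T, freq="D")
    is_weekend = np.asarray(dates.dayofweek >= 5)

    base = config.adherence_base_rate
    degenerate = base in (0.0, 1.0)
    if not degenerate:
        b0 = _logit(base)
        penalized = max(base - config.weekend_penalty, 1e-9)
        bw = _logit(penalized) - b0 if config.weekend_penalty > 0 else 0.0
    intercepts = rng.normal(0.0, config.participant_sd, size=n)

    truth_rows = []
    mems_rows = []
    wear_frames = []
    ema_rows = []
    base_rows = []

    cal = expected_prompts(dates) if T > 0 else None
    minute_of_day = np.arange(1440)
    hour_of_day = minute_of_day / 60.0
    w24 = 2.0 * np.pi / 24.0
    # steps mean curve: mesor == amplitude so the trough touches zero
    step_mean = config.circadian_amplitude_steps * (
        1.0 + np.cos(w24 * (hour_of_day - config.circadian_acrophase))
    )
    hr_circ = 5.0 * np.cos(w24 * (hour_of_day - (config.circadian_acrophase + 2.0) % 24))
    asleep = (hour_of_day >= 23.0) | (hour_of_day < 7.0)

    for i in range(n):
        pid = i
        # latent AR(1) state, stationary SD 1
        eps = rng.normal(0.0, 1.0, size=T)
        state = np.empty(T)
        prev_s = rng.normal()
        for d in range(T):
            prev_s = config.state_ar * prev_s + np.sqrt(1 - config.state_ar**2) * eps[d]
            state[d] = prev_s
        # adherence chain
        adherent = np.zeros(T, dtype=int)
        p_adh = np.zeros(T)
        prev = base  # day 0: persistence term centered away
        for d in range(T):
            if degenerate:
                p = base
                if base == 1.0 and is_weekend[d]:
                    p = 1.0 - config.weekend_penalty
            else:
                logit = (
                    b0
                    + intercepts[i]
                    + config.beta_persist * (prev - base)
                    + (bw if is_weekend[d] else 0.0)
                    + config.state_effect * state[d]
                )
                p = _sigmoid(logit)
            p_adh[d] = p
            u = rng.random()
            adherent[d] = int(u < p)
            prev = float(adherent[d])
        for d in range(T):
            truth_rows.append((pid, dates[d], adherent[d], state[d], p_adh[d]))

        # MEMS events
        for d in range(T):
            if adherent[d]:
                hour = config.dosing_hour_mean + config.dosing_hour_sd * rng.normal()
                hour = float(np.clip(hour, 0.0, 23.999))
                ts = dates[d] + pd.Timedelta(minutes=round(hour * 60.0))
                mems_rows.append((pid, ts))
            elif config.spurious_open_rate > 0 and rng.random() < config.spurious_open_rate:
                ts = dates[d] + pd.Timedelta(minutes=int(rng.integers(0, 1440)))
                mems_rows.append((pid, ts))

        # wearable minute stream
        if T > 0:
            gain = np.exp(0.15 * state)  # good days are more active
            L = T * 1440
            ar = 0.9
            c = np.sqrt(1.0 - ar**2)
            noise_s = lfilter([c], [1.0, -ar], rng.normal(0.0, config.step_noise_sd, L))
            noise_h = lfilter([c], [1.0, -ar], rng.normal(0.0, config.hr_noise_sd, L))
            mean_curve = np.tile(step_mean, T) * np.repeat(gain, 1440)
            steps = np.clip(mean_curve + noise_s, 0.0, None)
            asleep_all = np.tile(asleep, T)
            steps[asleep_all] = 0.0
            hr = (
                60.0
                + np.tile(hr_circ, T)
                + 0.05 * steps
                + 2.0 * np.repeat(state, 1440)
                + noise_h
            )
            steps = steps.astype(np.float32)
            hr = hr.astype(np.float32)
            sleep = np.tile(asleep.astype(np.float32), T)
            # non-wear gaps: blank HR (and steps) for a contiguous stretch
            gap_days = rng.random(T) < config.wear_gap_rate
            for d in np.flatnonzero(gap_days):
                length = int(rng.integers(120, 1200))
                startm = int(rng.integers(0, 1440 - min(length, 1439)))
                sl = slice(d * 1440 + startm, d * 1440 + min(startm + length, 1440))
                hr[sl] = np.nan
                steps[sl] = np.nan
                sleep[sl] = np.nan
            ts_index = pd.date_range(start, periods=T * 1440, freq="min")
            wear_frames.append(
                pd.DataFrame(
                    {
                        "participant_id": np.full(T * 1440, pid, dtype=np.int32),
                        "timestamp": ts_index,
                        "steps": steps,
                        "heart_rate": hr,
                        "sleep_flag": sleep,
                    }
                )
            )

        # EMA responses
        if cal is not None:
            date_pos = {d: k for k, d in enumerate(dates)}
            for prow in cal.itertuples(index=False):
                d_idx = date_pos[prow.prompt_date]
                answered = rng.random() >= config.ema_nonresponse_rate
                sch = SCHEDULES[prow.schedule]
                if answered:
                    delay_h = float(rng.uniform(0.0, sch.availability_hours))
                    resp_time = prow.prompt_time + pd.Timedelta(minutes=round(delay_h * 60))
                else:
                    resp_time = pd.NaT
                for item_id, schedule, kind, loading in EMA_ITEMS:
                    if schedule != prow.schedule:
                        continue
                    if not answered:
                        value = np.nan
                    elif item_id == "evening_forgot_medication":
                        p_yes = 0.7 if adherent[d_idx] == 0 else 0.1
                        value = "yes" if rng.random() < p_yes else "no"
                    elif item_id == "random_side_effects":
                        z = -state[d_idx] + rng.normal(0.0, 0.5)
                        level = int(np.clip(np.digitize(z, [-0.5, 0.5, 1.5]), 0, 3))
                        value = _SIDE_EFFECT_LEVELS[level]
                    elif item_id == "biweekly_forgot_past2wk":
                        lo = max(0, d_idx - 13)
                        value = float(np.sum(adherent[lo:d_idx + 1] == 0))
                    elif item_id == "biweekly_social_support":
                        value = float(
                            np.clip(3.0 + 1.2 * intercepts[i] + 0.3 * state[d_idx]
                                    + rng.normal(0.0, 0.4), 1.0, 5.0)
                        )
                    else:
                        value = float(
                            np.clip(3.0 + loading * state[d_idx] + rng.normal(0.0, 0.5),
                                    1.0, 5.0)
                        )
                    ema_rows.append(
                        (pid, prow.schedule, prow.prompt_date, prow.prompt_time,
                         resp_time, item_id, value)
                    )

        # baseline survey: noisy readouts of the participant intercept
        base_rows.append(
            {
                "participant_id": pid,
                "age": float(np.round(rng.uniform(35, 70), 1)),
                "self_efficacy": float(3.0 + 1.5 * intercepts[i] + rng.normal(0.0, 0.3)),
                "medication_beliefs": float(3.0 + 0.8 * intercepts[i] + rng.normal(0.0, 0.4)),
                "comorbidities": int(rng.poisson(2.0)),
                "baseline_mood": float(3.0 + 0.5 * intercepts[i] + rng.normal(0.0, 0.5)),
            }
        )

    mems = pd.DataFrame(mems_rows, columns=["participant_id", "opened_at"])
    if not mems.empty:
        mems = mems.sort_values(["participant_id", "opened_at"]).reset_index(drop=True)
    wearable = (
        pd.concat(wear_frames, ignore_index=True)
        if wear_frames
        else pd.DataFrame(
            columns=["participant_id", "timestamp", "steps", "heart_rate", "sleep_flag"]
        )
    )
    ema_df = pd.DataFrame(
        ema_rows,
        columns=["participant_id", "schedule", "prompt_date", "prompt_time",
                 "response_time", "item_id", "value"],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["participant_id", "date", "adherent", "state", "p_adherent"]
    )
    baseline = pd.DataFrame(base_rows)
    if baseline.empty:
        baseline = pd.DataFrame(
            columns=["participant_id", "age", "self_efficacy", "medication_beliefs",
                     "comorbidities", "baseline_mood"]
        )
    return SyntheticCohort(
        mems=mems, wearable=wearable, ema=ema_df, baseline=baseline, truth=truth,
        config=config,
    )


def truth_labels(cohort: SyntheticCohort) -> pd.DataFrame:
    """Latent per-day adherence indicators (for parameter-recovery tests;
    the pipeline's operational labels come from the MEMS interval rule)."""
    if cohort.truth is None or not {"participant_id", "date", "adherent"} <= set(
        getattr(cohort.truth, "columns", [])
    ):
        raise ValueError("cohort lacks a truth table")
    out = cohort.truth[["participant_id", "date", "adherent"]].copy()
    return out.rename(columns={"adherent": "label"})


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write each stream as CSV plus a JSON sidecar echoing the config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.mems.to_csv(out / "mems_events.csv", index=False)
    cohort.wearable.to_csv(out / "wearable_minutes.csv", index=False)
    cohort.ema.to_csv(out / "ema_responses.csv", index=False)
    cohort.baseline.to_csv(out / "baseline_survey.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)
    (out / "config.json").write_text(json.dumps(cohort.config.to_dict(), indent=2))
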