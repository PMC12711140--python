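"""Missing-data stress tests.

EMA and wearable feature cells are removed *before* imputation under two
regimes — feature-level MCAR at rates 0.1-0.5, and structured 3-day gaps
in 10% of participant-weeks — after which imputation, windowing and
prediction are re-run with the cached Tier-1 fold models and fold fusion
weights. The reported quantity is the change in macro balanced accuracy
of the optimized fusion relative to the unperturbed baseline run; a
robust pipeline degrades only slightly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ema as ema_mod
from . import wearable as wear_mod
from .experiment import ExperimentResult, predict_with_cached_models
from .fusion import fuse
from .metrics import macro_balanced_accuracy
from .windows import align_predictions

__all__ = ["MCAR_RATES", "mask_mcar", "mask_structured_gaps", "stress_test"]

MCAR_RATES = (0.1, 0.2, 0.3, 0.4, 0.5)
_KEYS = ("participant_id", "date")


def _feature_cols(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in _KEYS]


def mask_mcar(table: pd.DataFrame, rate: float, rng) -> pd.DataFrame:
    """Blank a fraction ``rate`` of feature cells completely at random."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    out = table.copy()
    cols = _feature_cols(out)
    mask = rng.random((len(out), len(cols))) < rate
    vals = out[cols].to_numpy(dtype=float)
    vals[mask] = np.nan
    out[cols] = vals
    return out


def mask_structured_gaps(
    table: pd.DataFrame,
    rng,
    week_rate: float = 0.10,
    gap_days: int = 3,
) -> pd.DataFrame:
    """Blank all feature cells in ``gap_days`` consecutive days for a
    fraction ``week_rate`` of participant-weeks (device-off / survey-
    fatigue episodes rather than cell-level noise)."""
    out = table.copy()
    cols = _feature_cols(out)
    dates = pd.to_datetime(out["date"])
    week = dates.dt.isocalendar().week.astype(int) + 100 * dates.dt.isocalendar().year.astype(int)
    out["_week"] = week.to_numpy()
    drop = np.zeros(len(out), dtype=bool)
    for (pid, wk), g in out.groupby(["participant_id", "_week"]):
        if rng.random() >= week_rate:
            continue
        days = np.sort(pd.to_datetime(g["date"]).unique())
        if len(days) == 0:
            continue
        start = rng.integers(0, max(len(days) - gap_days + 1, 1))
        gap = set(days[start:start + gap_days])
        drop |= (out["participant_id"] == pid).to_numpy() & dates.isin(gap).to_numpy()
    vals = out[cols].to_numpy(dtype=float)
    vals[drop] = np.nan
    out[cols] = vals
    return out.drop(columns="_week")


@dataclass
class StressRegime:
    name: str
    kind: str      # "mcar" | "gaps" | "none"
    rate: float = 0.0


def _default_regimes() -> list[StressRegime]:
    regs = [StressRegime(f"mcar_{int(r*100)}", "mcar", r) for r in MCAR_RATES]
    regs.append(StressRegime("gaps_3d_10pct", "gaps", 0.10))
    return regs


def stress_test(
    result: ExperimentResult,
    dates: pd.DatetimeIndex,
    regimes: list[StressRegime] | None = None,
    seed: int = 0,
    modalities=("mems", "ema", "wearable"),
) -> pd.DataFrame:
    """Degradation table: optimized-fusion macro BA per masking regime.

    Masking touches the EMA and wearable raw tables only (MEMS is the
    outcome source and is never masked). Each regime re-runs imputation
    and windowing, re-predicts with the cached fold models, re-fuses with
    the cached per-fold optimized weights and reports macro BA and its
    change versus the unperturbed run.
    """
    regimes = regimes or _default_regimes()
    fus_res = result.fusion[(tuple(modalities), "optimized")]
    baseline_ba = fus_res.report.macro_ba
    prob_order = list(modalities)
    lab = result.labels.copy()
    rows = [{"regime": "baseline", "macro_ba": baseline_ba, "delta": 0.0}]
    for ri, reg in enumerate(regimes):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, ri]).generate_state(1)[0] % (2**31)
        )
        if reg.kind == "none" or (reg.kind == "mcar" and reg.rate == 0.0):
            # identity regime: nothing was masked, so the completed tables
            # are exactly the baseline ones and the degradation is 0
            masked_ema = None
            masked_wear = None
        elif reg.kind == "mcar":
            masked_ema = mask_mcar(result.daily_raw["ema"], reg.rate, rng)
            masked_wear = mask_mcar(result.daily_raw["wearable"], reg.rate, rng)
        elif reg.kind == "gaps":
            masked_ema = mask_structured_gaps(result.daily_raw["ema"], rng, reg.rate)
            masked_wear = mask_structured_gaps(result.daily_raw["wearable"], rng, reg.rate)
        else:
            raise ValueError(f"unknown regime kind {reg.kind!r}")
        if masked_wear is None:
            wear_done = result.daily["wearable"]
            ema_done = result.daily["ema"]
        else:
            wear_done = wear_mod.impute_wearable(
                masked_wear, seed=result.seed, keep_columns=result.wearable_columns
            )
            ema_done = _reimpute_ema_features(masked_ema, dates, result.seed)
        daily = {
            "mems": result.daily["mems"],
            "ema": ema_done,
            "wearable": wear_done,
        }
        preds = predict_with_cached_models(result, daily, modalities)
        joined = align_predictions({m: preds[m] for m in prob_order}).merge(
            lab[["participant_id", "date", "label"]], on=["participant_id", "date"]
        )
        fused = np.empty(len(joined))
        for pid, w in fus_res.fold_weights.items():
            m = (joined["participant_id"] == pid).to_numpy()
            if m.any():
                fused[m] = fuse(
                    joined.loc[m, [f"prob_{x}" for x in prob_order]].to_numpy(), w
                )
        ba = macro_balanced_accuracy(joined["label"], (fused >= 0.5).astype(int))
        rows.append({"regime": reg.name, "macro_ba": ba, "delta": ba - baseline_ba})
    return pd.DataFrame(rows)


def _reimpute_ema_features(
    masked_features: pd.DataFrame,
    dates: pd.DatetimeIndex,
    seed: int,
) -> pd.DataFrame:
    """Rebuild a completed EMA feature table from a masked feature table.

    The masked table is already ordinal-encoded, so all items are treated
    as numeric for re-imputation; episodic cadence structure is restored
    by re-deriving prompt-day masks before propagation.
    """
    item_cols = [c for c in masked_features.columns if c not in _KEYS]
    idx = pd.MultiIndex.from_frame(
        masked_features[list(_KEYS)].assign(
            date=pd.to_datetime(masked_features["date"]).dt.normalize()
        )
    )
    values = masked_features[item_cols].copy()
    values.index = idx
    observed = values.notna()
    cal = ema_mod.expected_prompts(pd.DatetimeIndex(dates))
    prompt_day = pd.DataFrame(False, index=idx, columns=item_cols)
    schedules = {}
    for it in item_cols:
        sch = next(
            (s for s in ema_mod.SCHEDULES if it.startswith(s)), "morning"
        )
        schedules[it] = sch
        days = set(cal.loc[cal["schedule"] == sch, "prompt_date"])
        prompt_day[it] = idx.get_level_values("date").isin(days)
    panel = ema_mod.EmaPanel(
        values=values,
        observed=observed,
        prompt_day=prompt_day,
        item_schedule=schedules,
        item_type={it: "numeric" for it in item_cols},
    )
    done = ema_mod.propagate_episodic(ema_mod.impute_ema(panel, seed=seed))
    return ema_mod.panel_features(done)
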