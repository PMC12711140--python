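"""Fixed-length daily-feature sequences aligned to next-day adherence
labels, and key-aligned joining of per-modality predictions for fusion.

A sample for target date ``d`` stacks the feature rows of the
``window_len`` consecutive calendar days immediately preceding ``d``
(days d-L .. d-1) and pairs them with the label at ``d``; every feature
in a window therefore strictly precedes its target (no leakage). Days
with any missing feature are unusable, so windows containing them are
dropped rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WindowedDataset", "build_windows", "align_predictions",
           "WINDOW_RANGE"]

WINDOW_RANGE = (2, 7)


@dataclass
class WindowedDataset:
    """Sequences (n_samples, window_len, n_features) with next-day labels
    and (participant_id, target_date) keys."""

    X: np.ndarray
    y: np.ndarray
    keys: pd.DataFrame
    feature_names: list[str]
    window_len: int

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def participants(self) -> np.ndarray:
        return np.unique(self.keys["participant_id"].to_numpy())

    def subset(self, mask) -> "WindowedDataset":
        mask = np.asarray(mask)
        return WindowedDataset(
            X=self.X[mask],
            y=self.y[mask],
            keys=self.keys.loc[mask].reset_index(drop=True),
            feature_names=list(self.feature_names),
            window_len=self.window_len,
        )

    def select_features(self, idx) -> "WindowedDataset":
        idx = np.asarray(idx)
        return WindowedDataset(
            X=self.X[:, :, idx],
            y=self.y,
            keys=self.keys,
            feature_names=[self.feature_names[i] for i in idx],
            window_len=self.window_len,
        )


def build_windows(
    daily: pd.DataFrame,
    labels: pd.DataFrame,
    window_len: int,
    feature_cols: list[str] | None = None,
) -> WindowedDataset:
    """Assemble windows from a daily feature table and a label series.

    ``daily`` needs participant_id, date and feature columns; ``labels``
    needs participant_id, date, label. A sample exists for target date d
    iff all of d-window_len .. d-1 have complete feature rows and d has a
    label. Standardization is deliberately not applied here (it belongs
    inside each training fold).
    """
    lo, hi = WINDOW_RANGE
    if not lo <= window_len <= hi:
        raise ValueError(f"window_len must be in [{lo}, {hi}], got {window_len}")
    if feature_cols is None:
        feature_cols = [
            c for c in daily.columns
            if c not in ("participant_id", "date", "label", "interval_hours")
        ]
    d = daily.copy()
    d["date"] = pd.to_datetime(d["date"]).dt.normalize()
    lab = labels.copy()
    lab["date"] = pd.to_datetime(lab["date"]).dt.normalize()
    one_day = pd.Timedelta(days=1)
    X_parts, y_parts, key_rows = [], [], []
    for pid, g in d.groupby("participant_id", sort=True):
        g = g.sort_values("date")
        complete = g.dropna(subset=feature_cols)
        feat = {row_date: vals for row_date, vals in zip(
            complete["date"], complete[feature_cols].to_numpy(dtype=float))}
        plab = lab[lab["participant_id"] == pid]
        for ld, lv in zip(plab["date"], plab["label"]):
            days = [ld - one_day * k for k in range(window_len, 0, -1)]
            if all(day in feat for day in days):
                X_parts.append(np.stack([feat[day] for day in days]))
                y_parts.append(int(lv))
                key_rows.append((pid, ld))
    n = len(X_parts)
    X = (
        np.stack(X_parts)
        if n
        else np.empty((0, window_len, len(feature_cols)))
    )
    return WindowedDataset(
        X=X,
        y=np.asarray(y_parts, dtype=int),
        keys=pd.DataFrame(key_rows, columns=["participant_id", "target_date"]),
        feature_names=list(feature_cols),
        window_len=window_len,
    )


def align_predictions(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Inner-join per-modality prediction tables on (participant_id, date).

    Each table needs participant_id, date, probability (and may carry
    fold_id). Output has one ``prob_<modality>`` column per input table;
    only keys present in every modality survive. Raises on duplicate keys
    or an empty intersection.
    """
    if not tables:
        raise ValueError("no prediction tables given")
    merged = None
    for name, t in tables.items():
        tt = t.copy()
        tt["date"] = pd.to_datetime(tt["date"]).dt.normalize()
        if tt.duplicated(["participant_id", "date"]).any():
            raise ValueError(f"duplicate (participant, date) keys in {name!r}")
        keep = ["participant_id", "date", "probability"] + (
            ["fold_id"] if "fold_id" in tt.columns and merged is None else []
        )
        tt = tt[keep].rename(columns={"probability": f"prob_{name}"})
        merged = tt if merged is None else merged.merge(
            tt, on=["participant_id", "date"], how="inner"
        )
    if merged.empty:
        raise ValueError("empty intersection across modalities")
    return merged.sort_values(["participant_id", "date"]).reset_index(drop=True)
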