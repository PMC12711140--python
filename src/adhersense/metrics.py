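"""Imbalance-aware evaluation: macro balanced accuracy, macro F1,
majority baseline, participant-level bootstrap CIs and subgroup reports.

Adherence datasets are typically dominated by adherent days, so plain
accuracy rewards ignoring the minority (non-adherent) class. Both metrics
here weight the two classes equally: macro balanced accuracy averages
(sensitivity + specificity)/2 over classes, and macro F1 averages the
per-class F1 scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "macro_balanced_accuracy",
    "macro_f1",
    "MajorityPredictor",
    "majority_baseline",
    "bootstrap_ci",
    "MetricReport",
    "metric_report",
    "subgroup_report",
]


def _as_binary(y) -> np.ndarray:
    a = np.asarray(y).astype(int).ravel()
    if not np.isin(a, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return a


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, positive: int):
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    return tp, fp, tn, fn


def macro_balanced_accuracy(y_true, y_pred) -> float:
    """Mean over classes of (TP/(TP+FN) + TN/(TN+FP)) / 2.

    For binary labels this reduces to the usual balanced accuracy,
    (sensitivity + specificity)/2, since the two per-class terms coincide.
    Raises if ``y_true`` contains a single class (specificity undefined).
    """
    yt, yp = _as_binary(y_true), _as_binary(y_pred)
    if yt.size == 0:
        raise ValueError("empty label vector")
    if np.unique(yt).size < 2:
        raise ValueError("macro balanced accuracy needs both classes in y_true")
    vals = []
    for c in (0, 1):
        tp, fp, tn, fn = _confusion(yt, yp, c)
        vals.append(0.5 * (tp / (tp + fn) + tn / (tn + fp)))
    return float(np.mean(vals))


def macro_f1(y_true, y_pred) -> float:
    """Mean of per-class F1; a class with no true and no predicted
    positives contributes 0 by convention."""
    yt, yp = _as_binary(y_true), _as_binary(y_pred)
    if yt.size == 0:
        raise ValueError("empty label vector")
    f1s = []
    for c in (0, 1):
        tp, fp, tn, fn = _confusion(yt, yp, c)
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom > 0 else 0.0)
    return float(np.mean(f1s))


@dataclass
class MajorityPredictor:
    """Non-informative reference: always predicts the modal training class.

    Ignoring one class entirely yields a macro balanced accuracy of exactly
    0.50 on any test set containing both classes, whatever the imbalance.
    """

    majority_class: int

    def predict(self, n: int) -> np.ndarray:
        return np.full(int(n), self.majority_class, dtype=int)

    def predict_proba(self, n: int) -> np.ndarray:
        p = np.full(int(n), float(self.majority_class))
        return np.column_stack([1 - p, p])


def majority_baseline(y_train) -> MajorityPredictor:
    y = _as_binary(y_train)
    if y.size == 0:
        raise ValueError("empty training labels")
    n1 = int(y.sum())
    # tie broken toward the positive (adherent) class
    return MajorityPredictor(1 if n1 * 2 >= y.size else 0)


def bootstrap_ci(
    y_true,
    y_pred,
    participant_ids,
    metric=macro_balanced_accuracy,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Participant-level percentile bootstrap CI for a metric.

    Participants are resampled with replacement; the metric is recomputed
    on the pooled resampled predictions. Resamples on which the metric is
    undefined (single-class pooled truth) are skipped. Deterministic given
    ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    yt, yp = _as_binary(y_true), _as_binary(y_pred)
    pid = np.asarray(participant_ids)
    uniq = np.unique(pid)
    if uniq.size < 2:
        raise ValueError("bootstrap needs at least 2 participants")
    groups = {p: np.flatnonzero(pid == p) for p in uniq}
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_boot):
        chosen = rng.choice(uniq, size=uniq.size, replace=True)
        idx = np.concatenate([groups[p] for p in chosen])
        try:
            stats.append(metric(yt[idx], yp[idx]))
        except ValueError:
            continue
    stats = np.asarray(stats)
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class MetricReport:
    macro_ba: float | None
    macro_f1: float
    ci: dict = field(default_factory=dict)  # metric name -> (low, high)
    n_samples: int = 0
    n_participants: int = 0
    per_class: dict = field(default_factory=dict)  # class -> dict(TP,FP,TN,FN)
    flags: list = field(default_factory=list)


def metric_report(
    y_true,
    y_pred,
    participant_ids=None,
    n_boot: int = 1000,
    seed: int = 0,
) -> MetricReport:
    """Point estimates plus (when >=2 participants) bootstrap 95% CIs."""
    yt, yp = _as_binary(y_true), _as_binary(y_pred)
    per_class = {}
    for c in (0, 1):
        tp, fp, tn, fn = _confusion(yt, yp, c)
        per_class[c] = {"TP": tp, "FP": fp, "TN": tn, "FN": fn}
    flags = []
    if np.unique(yt).size < 2:
        ba = None
        flags.append("single_class")
    else:
        ba = macro_balanced_accuracy(yt, yp)
    f1 = macro_f1(yt, yp)
    rep = MetricReport(
        macro_ba=ba,
        macro_f1=f1,
        n_samples=yt.size,
        per_class=per_class,
        flags=flags,
    )
    if participant_ids is not None:
        uniq = np.unique(np.asarray(participant_ids))
        rep.n_participants = uniq.size
        if uniq.size >= 2 and ba is not None:
            rep.ci["macro_ba"] = bootstrap_ci(
                yt, yp, participant_ids, macro_balanced_accuracy, n_boot, seed
            )
            rep.ci["macro_f1"] = bootstrap_ci(
                yt, yp, participant_ids, macro_f1, n_boot, seed
            )
    return rep


def subgroup_report(
    y_true,
    y_pred,
    participant_ids,
    grouping: dict,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Per-group MetricReport; used for subgroup sensitivity checks
    (e.g. age < 50 vs >= 50). Groups whose pooled truth is single-class are
    flagged and reported without balanced accuracy; empty groups are
    omitted with a warning.
    """
    yt, yp = _as_binary(y_true), _as_binary(y_pred)
    pid = np.asarray(participant_ids)
    missing = set(pid) - set(grouping)
    if missing:
        raise ValueError(f"participants without a group: {sorted(missing)[:5]}")
    out = {}
    groups = sorted(set(grouping.values()), key=str)
    for g in groups:
        mask = np.array([grouping[p] == g for p in pid])
        if not mask.any():
            warnings.warn(f"subgroup {g!r} is empty; omitted")
            continue
        n_part = np.unique(pid[mask]).size
        rep = metric_report(
            yt[mask],
            yp[mask],
            pid[mask] if n_part >= 2 else None,
            n_boot=n_boot,
            seed=seed,
        )
        rep.n_participants = n_part
        if n_part < 2:
            rep.flags.append("single_participant")
        out[g] = rep
    return out


def report_table(reports: dict) -> pd.DataFrame:
    """Flatten {name: MetricReport} into a tidy table."""
    rows = []
    for name, r in reports.items():
        rows.append(
            {
                "name": name,
                "macro_ba": r.macro_ba,
                "macro_f1": r.macro_f1,
                "ba_ci_low": r.ci.get("macro_ba", (np.nan, np.nan))[0],
                "ba_ci_high": r.ci.get("macro_ba", (np.nan, np.nan))[1],
                "n_samples": r.n_samples,
                "n_participants": r.n_participants,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)
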