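"""Tier-2 soft-voting fusion of modality probabilities.

The fused adherence probability is a convex combination
``fused = sum_m w_m * p_m`` with ``sum_m w_m = 1`` and ``w_m >= 0``
(nonnegativity keeps the output a probability). In *optimized* mode the
weight vector is chosen, within each LOPO fold and using only that
fold's training participants, from a simplex grid to maximize the macro
balanced accuracy of the thresholded fused probabilities; *uniform* mode
uses ``w_m = 1/M``. Comparing modality subsets against the full fusion
is the perturbation-style ablation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .metrics import macro_balanced_accuracy, macro_f1, metric_report
from .windows import align_predictions

__all__ = [
    "FusionWeights",
    "fuse",
    "simplex_grid",
    "optimize_weights",
    "run_fusion_experiment",
    "FusionResult",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class FusionWeights:
    """Per-modality convex weights on the probability simplex."""

    modalities: tuple
    weights: tuple
    resolution: float

    def __post_init__(self):
        if len(self.modalities) != len(self.weights):
            raise ValueError("one weight per modality required")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be nonnegative")
        if abs(sum(self.weights) - 1.0) > _SUM_TOL:
            raise ValueError("weights must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def fuse(probs, weights: FusionWeights) -> np.ndarray:
    """Convex combination of per-modality probabilities.

    ``probs`` is (n_samples, n_modalities) or a length-M vector for a
    single sample; column order must match ``weights.modalities``.
    """
    P = np.atleast_2d(np.asarray(probs, dtype=float))
    if P.shape[1] != len(weights.modalities):
        raise ValueError(
            f"expected {len(weights.modalities)} modality columns, got {P.shape[1]}"
        )
    if ((P < 0) | (P > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    out = P @ weights.as_array()
    return out if np.asarray(probs).ndim > 1 else float(out[0])


def simplex_grid(n_modalities: int, resolution: float) -> np.ndarray:
    """All nonnegative weight vectors with entries that are multiples of
    ``resolution`` and sum to 1 (includes every vertex, and the uniform
    vector whenever it is representable)."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    frac = Fraction(resolution).limit_denominator(10**6)
    steps = Fraction(1, 1) / frac
    if steps.denominator != 1:
        raise ValueError("resolution must divide 1 evenly")
    k = int(steps)
    def compositions(total, parts):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest
    vecs = np.array(sorted(compositions(k, n_modalities)), dtype=float) / k
    return vecs


def optimize_weights(
    train_probs,
    train_labels,
    modalities,
    resolution: float = 0.05,
    threshold: float = 0.5,
) -> FusionWeights:
    """Grid search on the simplex for the weights maximizing training
    macro balanced accuracy of the thresholded fused probability.

    Ties are broken toward the uniform vector (Euclidean distance), then
    lexicographically; the uniform baseline is therefore returned when
    nothing beats it. Raises on single-class training labels.
    """
    P = np.asarray(train_probs, dtype=float)
    y = np.asarray(train_labels).astype(int).ravel()
    if np.unique(y).size < 2:
        raise ValueError("weight optimization needs both classes in training labels")
    M = P.shape[1]
    if M != len(modalities):
        raise ValueError("probability columns must match modalities")
    grid = simplex_grid(M, resolution)
    uniform = np.full(M, 1.0 / M)
    best = None
    for w in grid:
        fused = P @ w
        pred = (fused >= threshold).astype(int)
        ba = macro_balanced_accuracy(y, pred)
        key = (-ba, float(np.sum((w - uniform) ** 2)), tuple(w))
        if best is None or key < best[0]:
            best = (key, w)
    return FusionWeights(
        modalities=tuple(modalities), weights=tuple(best[1]), resolution=resolution
    )


@dataclass
class FusionResult:
    fused: pd.DataFrame          # participant_id, date, label, fused_prob, fold_id
    fold_weights: dict           # fold_id -> FusionWeights
    report: object               # MetricReport on pooled out-of-fold predictions
    combination: tuple
    mode: str


def run_fusion_experiment(
    fold_predictions: dict[str, pd.DataFrame],
    labels: pd.DataFrame,
    combination,
    mode: str = "optimized",
    resolution: float = 0.05,
    threshold: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
) -> FusionResult:
    """Fold-wise fusion of out-of-fold Tier-1 predictions.

    For each outer fold, weights come from the training participants'
    pooled out-of-fold predictions (optimized mode) or are uniform; fused
    probabilities are emitted for the held-out participant only, so no
    participant's predictions ever rely on weights fitted with their own
    data. Returns the fused table, per-fold weights and a pooled metric
    report.
    """
    combination = tuple(combination)
    missing = [m for m in combination if m not in fold_predictions]
    if missing:
        raise ValueError(f"missing modality prediction tables: {missing}")
    if mode not in ("uniform", "optimized"):
        raise ValueError(f"unknown mode {mode!r}")
    joined = align_predictions({m: fold_predictions[m] for m in combination})
    lab = labels.copy()
    lab["date"] = pd.to_datetime(lab["date"]).dt.normalize()
    joined = joined.merge(
        lab[["participant_id", "date", "label"]], on=["participant_id", "date"],
        how="inner",
    )
    prob_cols = [f"prob_{m}" for m in combination]
    participants = np.unique(joined["participant_id"])
    uniform = FusionWeights(
        combination, tuple(np.full(len(combination), 1.0 / len(combination))),
        resolution,
    )
    out_rows = []
    fold_weights = {}
    for held_out in participants:
        test = joined[joined["participant_id"] == held_out]
        train = joined[joined["participant_id"] != held_out]
        if mode == "optimized":
            w = optimize_weights(
                train[prob_cols].to_numpy(),
                train["label"].to_numpy(),
                combination,
                resolution=resolution,
                threshold=threshold,
            )
        else:
            w = uniform
        fold_weights[held_out] = w
        fused = fuse(test[prob_cols].to_numpy(), w)
        for (pid, date, label), fp in zip(
            test[["participant_id", "date", "label"]].itertuples(index=False),
            np.atleast_1d(fused),
            strict=True,
        ):
            out_rows.append((pid, date, int(label), float(fp), held_out))
    fused_df = pd.DataFrame(
        out_rows, columns=["participant_id", "date", "label", "fused_prob", "fold_id"]
    )
    pred = (fused_df["fused_prob"] >= threshold).astype(int)
    report = metric_report(
        fused_df["label"], pred, fused_df["participant_id"], n_boot=n_boot, seed=seed
    )
    return FusionResult(
        fused=fused_df,
        fold_weights=fold_weights,
        report=report,
        combination=combination,
        mode=mode,
    )
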