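"""Tier-1 modality-specific sequence models under nested
leave-one-participant-out (LOPO) cross-validation, with inner-fold
random-forest feature ranking and joint grid search, plus the static
baseline-survey model.

Outer loop: each fold holds out every sample of one participant. Inner
loop: grouped 3-fold over the training participants. Within each inner
split a random forest ranks features on the most recent day of each
window; candidate subset sizes and LSTM hyperparameters are searched
jointly on inner balanced accuracy; the winner is refit on the full
outer-training set and emits probabilities for the held-out participant
only. All standardization, ranking and tuning use training participants
exclusively; the per-fold audit trail records what touched what.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestClassifier
from sklearn.model_selection import GroupKFold

from .lstm import LSTMClassifier
from .metrics import macro_balanced_accuracy
from .windows import WindowedDataset

__all__ = [
    "HyperGrid",
    "rank_features",
    "fit_sequence_classifier",
    "SequenceModel",
    "nested_lopo",
    "FoldInfo",
    "fit_static_baseline",
]


@dataclass(frozen=True)
class HyperGrid:
    """Joint search space: LSTM hyperparameters x feature-subset sizes."""

    n_units: tuple = (16, 32, 64)
    dropout: tuple = (0.0, 0.2, 0.5)
    l2: tuple = (1e-4, 1e-3)
    feature_subset_sizes: tuple = (10, 20, 50)
    epochs_max: int = 100
    learning_rate: float = 0.02

    def __post_init__(self):
        for name in ("n_units", "dropout", "l2", "feature_subset_sizes"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be a nonempty set")
        if any(not 0.0 <= d < 1.0 for d in self.dropout):
            raise ValueError("dropout values must be in [0, 1)")
        if any(v < 0 for v in self.l2):
            raise ValueError("l2 values must be nonnegative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def expand(self) -> list[dict]:
        return [
            {"n_units": u, "dropout": d, "l2": r}
            for u, d, r in itertools.product(self.n_units, self.dropout, self.l2)
        ]

    @classmethod
    def reduced(cls) -> "HyperGrid":
        """Desk-scale grid for scaled-down studies and CI runs."""
        return cls(
            n_units=(16,),
            dropout=(0.0, 0.3),
            l2=(1e-3,),
            feature_subset_sizes=(8,),
            epochs_max=60,
            learning_rate=0.02,
        )


def _child_seed(seed: int, *parts: int) -> int:
    return int(np.random.SeedSequence([seed, *parts]).generate_state(1)[0] % (2**31))


def rank_features(
    last_day_features: np.ndarray,
    labels: np.ndarray,
    seed: int,
    feature_names: list[str] | None = None,
    n_estimators: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Random-forest impurity ranking of the most recent day's features.

    Returns (order, importances) with ``order`` the feature indices in
    decreasing importance. Deterministic given seed; raises on
    single-class labels.
    """
    X = np.asarray(last_day_features, dtype=float)
    y = np.asarray(labels).astype(int).ravel()
    if np.unique(y).size < 2:
        raise ValueError("feature ranking needs both classes present")
    rf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    rf.fit(X, y)
    imp = rf.feature_importances_
    order = np.argsort(-imp, kind="stable")
    return order, imp


@dataclass
class SequenceModel:
    """Fitted classifier handle: feature subset + train-fold
    standardization + LSTM. ``predict_proba`` applies all three."""

    clf: LSTMClassifier
    feature_idx: np.ndarray
    mean: np.ndarray
    std: np.ndarray

    def _transform(self, X: np.ndarray) -> np.ndarray:
        Xs = np.asarray(X, dtype=float)[:, :, self.feature_idx]
        return (Xs - self.mean) / self.std

    def predict_proba(self, X) -> np.ndarray:
        return self.clf.predict_proba(self._transform(X))


def fit_sequence_classifier(
    train: WindowedDataset,
    config: dict,
    seed: int,
    feature_idx=None,
    validation: WindowedDataset | None = None,
    epochs_max: int = 100,
    learning_rate: float = 0.02,
) -> SequenceModel:
    """Standardize on the training windows only, then fit the LSTM.

    ``config`` carries n_units / dropout / l2. Standardization statistics
    are per feature over all training days; near-constant features get
    unit scale. Class imbalance is handled by inverse-frequency weights.
    """
    idx = (
        np.arange(train.X.shape[2])
        if feature_idx is None
        else np.asarray(feature_idx)
    )
    Xt = train.X[:, :, idx]
    if not np.isfinite(Xt).all():
        raise ValueError("NaN in training windows")
    mean = Xt.reshape(-1, Xt.shape[2]).mean(axis=0)
    std = Xt.reshape(-1, Xt.shape[2]).std(axis=0)
    std = np.where(std < 1e-9, 1.0, std)
    clf = LSTMClassifier(
        n_units=config["n_units"],
        dropout=config["dropout"],
        l2=config["l2"],
        learning_rate=learning_rate,
        max_epochs=epochs_max,
        seed=seed,
    )
    model = SequenceModel(clf=clf, feature_idx=idx, mean=mean, std=std)
    val = None
    if validation is not None:
        val = (model._transform(validation.X), validation.y)
    clf.fit(model._transform(train.X), train.y, validation_data=val)
    return model


@dataclass
class FoldInfo:
    """Audit record of one outer LOPO fold."""

    fold_id: object
    train_participants: list
    chosen_config: dict
    chosen_subset_size: int | None
    feature_idx: list
    scaler_fit_participants: list
    ranking_fit_participants: list | None
    inner_scores: dict = field(default_factory=dict)
    model: SequenceModel | None = None


def nested_lopo(
    data: WindowedDataset,
    grid: HyperGrid,
    seed: int,
    modality: str = "",
    select_features: bool = True,
    inner_k: int = 3,
    keep_models: bool = True,
) -> tuple[pd.DataFrame, list[FoldInfo]]:
    """Nested LOPO: outer leave-one-participant-out, inner grouped k-fold
    grid search scored by balanced accuracy.

    Returns the out-of-fold prediction table (participant_id, date,
    modality, probability, fold_id) and per-fold audit records. A fold
    whose training labels are single-class is skipped with a warning.
    ``select_features=False`` (e.g. the compact MEMS modality) searches
    hyperparameters only.
    """
    participants = data.participants
    if participants.size < 3:
        raise ValueError("nested LOPO needs >= 3 participants")
    pid_arr = data.keys["participant_id"].to_numpy()
    n_feat = data.X.shape[2]
    configs = grid.expand()
    if select_features:
        sizes = sorted({min(s, n_feat) for s in grid.feature_subset_sizes})
        if max(grid.feature_subset_sizes) > n_feat:
            warnings.warn(
                f"feature subset sizes truncated to {n_feat} available features"
            )
    else:
        sizes = [None]

    pred_rows = []
    fold_infos = []
    for fold_idx, held_out in enumerate(participants):
        test_mask = pid_arr == held_out
        train_mask = ~test_mask
        train = data.subset(train_mask)
        test = data.subset(test_mask)
        if np.unique(train.y).size < 2:
            warnings.warn(f"fold {held_out!r}: single-class training labels; skipped")
            continue
        train_pids = train.keys["participant_id"].to_numpy()
        uniq_train = np.unique(train_pids)
        k = min(inner_k, uniq_train.size)
        gkf = GroupKFold(n_splits=k)
        scores = {(sz, ci): [] for sz in sizes for ci in range(len(configs))}
        for split_idx, (itr, iva) in enumerate(
            gkf.split(train.X, train.y, groups=train_pids)
        ):
            inner_train = train.subset(np.isin(np.arange(len(train)), itr))
            inner_val = train.subset(np.isin(np.arange(len(train)), iva))
            if np.unique(inner_train.y).size < 2 or np.unique(inner_val.y).size < 2:
                continue
            if select_features:
                order, _ = rank_features(
                    inner_train.X[:, -1, :],
                    inner_train.y,
                    seed=_child_seed(seed, fold_idx, split_idx),
                )
            for sz in sizes:
                idx = order[:sz] if select_features else np.arange(n_feat)
                for ci, cfg in enumerate(configs):
                    model = fit_sequence_classifier(
                        inner_train,
                        cfg,
                        seed=_child_seed(seed, fold_idx, split_idx, ci),
                        feature_idx=idx,
                        validation=inner_val,
                        epochs_max=grid.epochs_max,
                        learning_rate=grid.learning_rate,
                    )
                    pv = model.predict_proba(inner_val.X)[:, 1]
                    ba = macro_balanced_accuracy(inner_val.y, (pv >= 0.5).astype(int))
                    scores[(sz, ci)].append(ba)
        mean_scores = {
            key: float(np.mean(v)) if v else -np.inf for key, v in scores.items()
        }
        # deterministic argmax: ties go to the earliest (smallest subset,
        # earliest grid entry) key
        ordered = sorted(mean_scores, key=lambda kk: (str(kk[0]), kk[1]))
        best_key = max(ordered, key=lambda kk: mean_scores[kk])
        best_size, best_ci = best_key
        best_cfg = configs[best_ci]
        if select_features:
            order, _ = rank_features(
                train.X[:, -1, :], train.y, seed=_child_seed(seed, fold_idx, 999)
            )
            final_idx = order[:best_size]
        else:
            final_idx = np.arange(n_feat)
        final_model = fit_sequence_classifier(
            train,
            best_cfg,
            seed=_child_seed(seed, fold_idx, 1000 + best_ci),
            feature_idx=final_idx,
            epochs_max=grid.epochs_max,
            learning_rate=grid.learning_rate,
        )
        probs = final_model.predict_proba(test.X)[:, 1]
        for (pid, tdate), p in zip(
            test.keys.itertuples(index=False), probs, strict=True
        ):
            pred_rows.append((pid, tdate, modality, float(p), held_out))
        fold_infos.append(
            FoldInfo(
                fold_id=held_out,
                train_participants=list(uniq_train),
                chosen_config=dict(best_cfg),
                chosen_subset_size=best_size,
                feature_idx=list(map(int, final_idx)),
                scaler_fit_participants=list(uniq_train),
                ranking_fit_participants=list(uniq_train) if select_features else None,
                inner_scores={str(kk): vv for kk, vv in mean_scores.items()},
                model=final_model if keep_models else None,
            )
        )
    preds = pd.DataFrame(
        pred_rows,
        columns=["participant_id", "date", "modality", "probability", "fold_id"],
    )
    return preds, fold_infos


def fit_static_baseline(
    baseline_table: pd.DataFrame,
    labels: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Static adherence probability from the one-shot baseline survey.

    Within each LOPO fold a gradient-boosted regression tree maps the
    training participants' baseline features to their mean adherence
    rate; the held-out participant receives that prediction (clipped to
    [0, 1]) as a constant probability on each of their labeled days.
    """
    feat_cols = [
        c for c in baseline_table.columns if c != "participant_id"
        and pd.api.types.is_numeric_dtype(baseline_table[c])
    ]
    bt = baseline_table.set_index("participant_id")
    rates = labels.groupby("participant_id")["label"].mean()
    pids = [p for p in bt.index if p in rates.index]
    rows = []
    for held_out in pids:
        train_pids = [p for p in pids if p != held_out]
        Xtr = bt.loc[train_pids, feat_cols].to_numpy(dtype=float)
        ytr = rates.loc[train_pids].to_numpy(dtype=float)
        if np.unique(ytr).size == 1 or np.allclose(Xtr.std(axis=0), 0.0):
            pred = float(ytr.mean())
        else:
            gbr = GradientBoostingRegressor(
                n_estimators=200, max_depth=2, learning_rate=0.1, random_state=seed
            )
            gbr.fit(Xtr, ytr)
            pred = float(gbr.predict(bt.loc[[held_out], feat_cols].to_numpy(dtype=float))[0])
        pred = float(np.clip(pred, 0.0, 1.0))
        days = labels.loc[labels["participant_id"] == held_out, "date"]
        for d in days:
            rows.append((held_out, d, "baseline", pred, held_out))
    return pd.DataFrame(
        rows, columns=["participant_id", "date", "modality", "probability", "fold_id"]
    )
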