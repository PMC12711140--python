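"""Feature ranking, sequence-classifier fitting, nested LOPO
cross-validation (fold accounting, leakage, determinism) and the static
baseline-survey model."""

import numpy as np
import pandas as pd
import pytest

from adhersense.metrics import macro_balanced_accuracy
from adhersense.models import (
    HyperGrid,
    fit_sequence_classifier,
    fit_static_baseline,
    nested_lopo,
    rank_features,
)
from adhersense.windows import WindowedDataset


class TestHyperGrid:
    def test_expand_is_cartesian(self):
        g = HyperGrid(n_units=(8, 16), dropout=(0.0,), l2=(1e-3, 1e-2),
                      feature_subset_sizes=(5,))
        cfgs = g.expand()
        assert len(cfgs) == 4
        assert {c["n_units"] for c in cfgs} == {8, 16}

    def test_validation(self):
        with pytest.raises(ValueError):
            HyperGrid(n_units=())
        with pytest.raises(ValueError):
            HyperGrid(dropout=(1.0,))


class TestRankFeatures:
    def test_informative_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        n = 500
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 6))
        X[:, 3] = y + rng.normal(0, 0.05, n)
        order, imp = rank_features(X, y, seed=1)
        assert order[0] == 3
        assert imp[3] > 0.5

    def test_duplicated_informative_features_beat_noise(self):
        rng = np.random.default_rng(1)
        n = 500
        y = rng.integers(0, 2, n)
        sig = y + rng.normal(0, 0.05, n)
        X = np.column_stack([sig, sig, rng.normal(size=(n, 4))])
        order, imp = rank_features(X, y, seed=2)
        assert set(order[:2]) == {0, 1}
        assert min(imp[0], imp[1]) > max(imp[2:])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rank_features(np.zeros((10, 3)), np.ones(10), seed=0)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        X, y = rng.normal(size=(100, 5)), rng.integers(0, 2, 100)
        o1, i1 = rank_features(X, y, seed=4)
        o2, i2 = rank_features(X, y, seed=4)
        assert np.array_equal(o1, o2) and np.array_equal(i1, i2)


def _make_dataset(n_part=5, days=30, n_feat=6, window=2, seed=0,
                  signal=True):
    """Windowed dataset whose label depends on feature 0 of the last day."""
    rng = np.random.default_rng(seed)
    X_rows, y_rows, keys = [], [], []
    for p in range(n_part):
        for d in range(days):
            x = rng.normal(size=(window, n_feat))
            y = int(rng.random() < 0.5)
            if signal:
                x[-1, 0] += 2.5 if y else -2.5
            X_rows.append(x)
            y_rows.append(y)
            keys.append((f"P{p}", pd.Timestamp("2024-01-01") + pd.Timedelta(days=d)))
    return WindowedDataset(
        X=np.stack(X_rows),
        y=np.array(y_rows),
        keys=pd.DataFrame(keys, columns=["participant_id", "target_date"]),
        feature_names=[f"f{i}" for i in range(n_feat)],
        window_len=window,
    )


TINY_GRID = HyperGrid(
    n_units=(8,), dropout=(0.0,), l2=(1e-3,), feature_subset_sizes=(3,),
    epochs_max=30, learning_rate=0.05,
)


class TestFitSequenceClassifier:
    def test_learns_separable_signal(self):
        ds = _make_dataset()
        model = fit_sequence_classifier(
            ds, {"n_units": 8, "dropout": 0.0, "l2": 1e-3}, seed=0,
            epochs_max=40, learning_rate=0.05,
        )
        pred = (model.predict_proba(ds.X)[:, 1] >= 0.5).astype(int)
        assert macro_balanced_accuracy(ds.y, pred) > 0.95

    def test_nan_rejected(self):
        ds = _make_dataset()
        ds.X[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_sequence_classifier(ds, {"n_units": 4, "dropout": 0, "l2": 0}, seed=0)


class TestNestedLopo:
    def test_fold_accounting_and_coverage(self):
        ds = _make_dataset(n_part=5, days=15)
        preds, infos = nested_lopo(ds, TINY_GRID, seed=0, modality="toy")
        assert len(infos) == 5
        # union of prediction keys covers every sample exactly once
        got = set(zip(preds["participant_id"], preds["date"]))
        want = set(zip(ds.keys["participant_id"], ds.keys["target_date"]))
        assert got == want

    def test_leakage_audit(self):
        ds = _make_dataset(n_part=4, days=12)
        preds, infos = nested_lopo(ds, TINY_GRID, seed=1, modality="toy")
        for info in infos:
            assert info.fold_id not in info.train_participants
            assert info.fold_id not in info.scaler_fit_participants
            if info.ranking_fit_participants is not None:
                assert info.fold_id not in info.ranking_fit_participants
        # predictions for a participant come only from their own fold
        assert (preds["participant_id"] == preds["fold_id"]).all()

    def test_grid_containment(self):
        ds = _make_dataset(n_part=4, days=12)
        _, infos = nested_lopo(ds, TINY_GRID, seed=2, modality="toy")
        cfgs = TINY_GRID.expand()
        for info in infos:
            assert info.chosen_config in cfgs
            assert info.chosen_subset_size in TINY_GRID.feature_subset_sizes

    def test_deterministic_given_seed(self):
        ds = _make_dataset(n_part=4, days=10)
        p1, _ = nested_lopo(ds, TINY_GRID, seed=3, modality="toy", keep_models=False)
        p2, _ = nested_lopo(ds, TINY_GRID, seed=3, modality="toy", keep_models=False)
        pd.testing.assert_frame_equal(p1, p2)

    def test_subset_truncation_warns(self):
        ds = _make_dataset(n_part=3, days=12, n_feat=2)
        grid = HyperGrid(n_units=(8,), dropout=(0.0,), l2=(1e-3,),
                         feature_subset_sizes=(10,), epochs_max=20)
        with pytest.warns(UserWarning, match="truncated"):
            nested_lopo(ds, grid, seed=4, modality="toy", keep_models=False)

    def test_too_few_participants_rejected(self):
        ds = _make_dataset(n_part=2, days=10)
        with pytest.raises(ValueError):
            nested_lopo(ds, TINY_GRID, seed=0)

    def test_probabilities_in_unit_interval(self):
        ds = _make_dataset(n_part=4, days=10, signal=False)
        preds, _ = nested_lopo(ds, TINY_GRID, seed=5, modality="toy",
                               keep_models=False)
        assert preds["probability"].between(0, 1).all()


class TestStaticBaseline:
    def _labels(self, rates, days=30):
        rows = []
        rng = np.random.default_rng(0)
        for pid, r in enumerate(rates):
            for d in range(days):
                rows.append((pid, pd.Timestamp("2024-01-01") + pd.Timedelta(days=d),
                             int(rng.random() < r)))
        return pd.DataFrame(rows, columns=["participant_id", "date", "label"])

    def test_identical_baselines_predict_training_mean(self):
        rates = [0.3, 0.5, 0.7, 0.9]
        labels = self._labels(rates)
        baseline = pd.DataFrame({"participant_id": range(4), "x": 1.0})
        preds = fit_static_baseline(baseline, labels, seed=0)
        emp = labels.groupby("participant_id")["label"].mean()
        for pid in range(4):
            expect = emp.drop(pid).mean()
            got = preds.loc[preds["participant_id"] == pid, "probability"].iloc[0]
            assert got == pytest.approx(expect, abs=1e-9)

    def test_oracle_feature_recovers_rates(self):
        rng = np.random.default_rng(1)
        rates = rng.uniform(0.2, 0.9, 20)
        labels = self._labels(rates, days=200)
        emp = labels.groupby("participant_id")["label"].mean()
        baseline = pd.DataFrame(
            {"participant_id": range(20), "oracle": emp.to_numpy()}
        )
        preds = fit_static_baseline(baseline, labels, seed=1)
        per_part = preds.drop_duplicates("participant_id").set_index("participant_id")
        rmse = np.sqrt(np.mean((per_part["probability"] - emp) ** 2))
        assert rmse < 0.05

    def test_bounded_and_constant_per_participant(self):
        rates = [0.2, 0.5, 0.8]
        labels = self._labels(rates)
        rng = np.random.default_rng(2)
        baseline = pd.DataFrame(
            {"participant_id": range(3), "a": rng.normal(size=3),
             "b": rng.normal(size=3)}
        )
        preds = fit_static_baseline(baseline, labels, seed=2)
        assert preds["probability"].between(0, 1).all()
        assert (preds.groupby("participant_id")["probability"].nunique() == 1).all()
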