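"""A compact LSTM binary classifier in numpy.

Sequence windows here are short (2-7 days) and narrow (tens of
features), far below the scale where a deep-learning framework earns its
complexity; a single-layer LSTM with manual backpropagation through time
and Adam updates trains in milliseconds and is bit-reproducible given a
seed. Gradients are verified against finite differences in the test
suite.

Architecture: one LSTM layer over the window; the final hidden state
(with optional inverted dropout during training) feeds a logistic output
unit. Loss is weighted binary cross-entropy plus an l2 penalty on the
recurrent and output weights. Class imbalance is handled by
inverse-frequency sample weights (``class_weight='balanced'``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMClassifier"]


def _sigmoid(x):
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500))),
                    np.exp(np.clip(x, -500, 500)) / (1.0 + np.exp(np.clip(x, -500, 500))))


class LSTMClassifier:
    """Single-layer LSTM + logistic head, trained with Adam.

    Parameters
    ----------
    n_units : hidden state size.
    dropout : inverted-dropout rate on the final hidden state (training
        only).
    l2 : coefficient of the l2 penalty on weight matrices.
    learning_rate, max_epochs, batch_size : Adam schedule.
    patience : early-stopping patience, measured on validation balanced
        accuracy when a validation set is passed to :meth:`fit`, else on
        training loss. Best weights are restored.
    class_weight : ``'balanced'`` or None.
    seed : controls initialization, shuffling and dropout masks; fixed
        seed + single-threaded numpy gives identical fits.
    """

    def __init__(
        self,
        n_units: int = 32,
        dropout: float = 0.0,
        l2: float = 1e-4,
        learning_rate: float = 0.01,
        max_epochs: int = 100,
        batch_size: int = 256,
        patience: int = 10,
        class_weight: str | None = "balanced",
        seed: int = 0,
    ):
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.n_units = int(n_units)
        self.dropout = float(dropout)
        self.l2 = float(l2)
        self.learning_rate = float(learning_rate)
        self.max_epochs = int(max_epochs)
        self.batch_size = int(batch_size)
        self.patience = int(patience)
        self.class_weight = class_weight
        self.seed = int(seed)
        self.params_: dict | None = None

    # ------------------------------------------------------------------ core

    def _init_params(self, n_features: int, rng) -> dict:
        H, F = self.n_units, n_features
        scale = 1.0 / np.sqrt(H + F)
        p = {
            "W": rng.normal(0.0, scale, size=(H + F, 4 * H)),
            "b": np.zeros(4 * H),
            "w_out": rng.normal(0.0, 1.0 / np.sqrt(H), size=H),
            "b_out": 0.0,
        }
        p["b"][H:2 * H] = 1.0  # forget-gate bias init
        return p

    def _forward(self, params, X):
        """Returns (prob, caches) for a batch X of shape (n, T, F)."""
        n, T, F = X.shape
        H = self.n_units
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        caches = []
        for t in range(T):
            z = np.concatenate([h, X[:, t, :]], axis=1)
            a = z @ params["W"] + params["b"]
            ai, af, ao, ag = np.split(a, 4, axis=1)
            i, f, o = _sigmoid(ai), _sigmoid(af), _sigmoid(ao)
            g = np.tanh(ag)
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            caches.append((z, i, f, o, g, c, c_new))
            h, c = h_new, c_new
        return h, caches

    def _loss_and_grads(self, params, X, y, sample_weight, dropout_mask=None):
        n = X.shape[0]
        H = self.n_units
        sw = sample_weight / sample_weight.sum()
        hT, caches = self._forward(params, X)
        hd = hT if dropout_mask is None else hT * dropout_mask
        logits = hd @ params["w_out"] + params["b_out"]
        p = _sigmoid(logits)
        eps = 1e-12
        loss = -np.sum(sw * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        loss += self.l2 * (np.sum(params["W"] ** 2) + np.sum(params["w_out"] ** 2))

        dlogits = sw * (p - y)
        grads = {
            "w_out": hd.T @ dlogits + 2 * self.l2 * params["w_out"],
            "b_out": float(np.sum(dlogits)),
            "W": 2 * self.l2 * params["W"],
            "b": np.zeros_like(params["b"]),
        }
        dh = np.outer(dlogits, params["w_out"])
        if dropout_mask is not None:
            dh = dh * dropout_mask
        dc = np.zeros((n, H))
        for t in range(X.shape[1] - 1, -1, -1):
            z, i, f, o, g, c_prev, c_new = caches[t]
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c**2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            da = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    do * o * (1 - o),
                    dg * (1 - g**2),
                ],
                axis=1,
            )
            grads["W"] += z.T @ da
            grads["b"] += da.sum(axis=0)
            dz = da @ params["W"].T
            dh = dz[:, :H]
            dc = dc * f
        return loss, grads, p

    # ------------------------------------------------------------------- API

    def fit(self, X, y, sample_weight=None, validation_data=None):
        """Train; ``validation_data=(X_val, y_val)`` switches early
        stopping to validation balanced accuracy."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, window_len, n_features)")
        if not np.isfinite(X).all():
            raise ValueError("NaN or inf in input windows")
        n, T, F = X.shape
        rng = np.random.default_rng(self.seed)
        if sample_weight is None:
            if self.class_weight == "balanced":
                n1 = max(y.sum(), 1.0)
                n0 = max((1 - y).sum(), 1.0)
                sample_weight = np.where(y == 1, n / (2 * n1), n / (2 * n0))
            else:
                sample_weight = np.ones(n)
        sample_weight = np.asarray(sample_weight, dtype=float)

        params = self._init_params(F, rng)
        m = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in params.items()}
        v = {k: np.zeros_like(np.asarray(vv, dtype=float)) for k, vv in params.items()}
        beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
        step = 0
        best_score = -np.inf
        best_params = {k: np.copy(pv) for k, pv in params.items()}
        stale = 0
        monitor_val = validation_data is not None
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            for s in range(0, n, self.batch_size):
                idx = order[s:s + self.batch_size]
                mask = None
                if self.dropout > 0:
                    keep = 1.0 - self.dropout
                    mask = (rng.random((idx.size, self.n_units)) < keep) / keep
                _, grads, _ = self._loss_and_grads(
                    params, X[idx], y[idx], sample_weight[idx], mask
                )
                step += 1
                for k in params:
                    g = grads[k]
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * np.square(g)
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v[k] / (1 - beta2**step)
                    params[k] = params[k] - self.learning_rate * mhat / (
                        np.sqrt(vhat) + adam_eps
                    )
            if monitor_val:
                Xv, yv = validation_data
                self.params_ = params
                pv = self._predict_proba_pos(np.asarray(Xv, dtype=float))
                score = _balanced_accuracy(np.asarray(yv).ravel(), pv >= 0.5)
            else:
                loss, _, _ = self._loss_and_grads(params, X, y, sample_weight)
                score = -loss
            if score > best_score + 1e-9:
                best_score = score
                best_params = {k: np.copy(pv) for k, pv in params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        self.params_ = best_params
        return self

    def _predict_proba_pos(self, X):
        h, _ = self._forward(self.params_, X)
        return _sigmoid(h @ self.params_["w_out"] + self.params_["b_out"])

    def predict_proba(self, X):
        if self.params_ is None:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("NaN or inf in input windows")
        p1 = self._predict_proba_pos(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X, threshold: float = 0.5):
        # ties at the threshold go to the positive class
        return (self.predict_proba(X)[:, 1] >= threshold).astype(int)


def _balanced_accuracy(y_true, y_pred):
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    vals = []
    for c in (0, 1):
        mask = y_true == c
        if mask.any():
            vals.append(np.mean(y_pred[mask] == c))
    return float(np.mean(vals))
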