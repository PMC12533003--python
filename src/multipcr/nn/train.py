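"""Adam optimiser and the class-weighted binary cross-entropy training loop."""

from __future__ import annotations

import numpy as np

from .layers import Sequential


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, np.ndarray]:
    """Weighted binary cross-entropy on logits.

    Returns (mean weighted loss, gradient w.r.t. logits).
    """
    # log(1 + exp(-|z|)) + max(z, 0) - z*y  is the stable form of the loss.
    loss = np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - z * y
    wsum = w.sum()
    dz = w * (sigmoid(z) - y) / wsum
    return float((w * loss).sum() / wsum), dz


class Adam:
    def __init__(self, params: list[dict], lr: float = 1e-3, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]
            if self.wd:
                g = g + self.wd * p["value"]
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p["value"] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def class_weights(y: np.ndarray) -> tuple[float, float]:
    """(negative weight, positive weight): positive class is up-weighted by the
    negative/positive frequency ratio."""
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for training")
    return 1.0, n_neg / n_pos


def predict_scores(model: Sequential, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
    """Sigmoid scores in [0, 1], evaluated in inference mode."""
    out = []
    for i in range(0, len(X), batch_size):
        out.append(sigmoid(model.forward(X[i : i + batch_size], train=False)))
    return np.concatenate(out)


def fit(
    model: Sequential,
    X: np.ndarray,
    y: np.ndarray,
    lr: float = 1e-3,
    batch_size: int = 128,
    epochs: int = 50,
    weight_decay: float = 0.0,
    seed: int | None = None,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    patience: int = 10,
    grad_clip: float | None = 5.0,
    val_metric=None,
) -> dict:
    """Minibatch Adam training with weighted BCE.

    With a validation set, training stops early when ``val_metric`` (default
    AUPRC) has not improved for ``patience`` epochs, and the best weights are
    restored.  Returns a history dict.
    """
    y = np.asarray(y, dtype=float)
    w_neg, w_pos = class_weights(y)
    weights = np.where(y == 1, w_pos, w_neg)
    rng = np.random.default_rng(seed)
    opt = Adam(model.params(), lr=lr, weight_decay=weight_decay)
    if val_metric is None:
        from ..classify import auprc

        val_metric = auprc
    history = {"loss": [], "val_metric": []}
    best_val = -np.inf
    best_weights = None
    stale = 0
    for epoch in range(epochs):
        order = rng.permutation(len(X))
        losses = []
        for i in range(0, len(X), batch_size):
            idx = order[i : i + batch_size]
            if len(idx) < 2:
                continue  # batch statistics need at least two samples
            z = model.forward(X[idx], train=True)
            loss, dz = bce_with_logits(z, y[idx], weights[idx])
            model.backward(dz)
            if grad_clip is not None:
                norm = np.sqrt(sum(float((p["grad"] ** 2).sum()) for p in model.params()))
                if norm > grad_clip:
                    for p in model.params():
                        p["grad"] *= grad_clip / norm
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        if X_val is not None and y_val is not None:
            score = val_metric(predict_scores(model, X_val), y_val)
            history["val_metric"].append(float(score))
            if score > best_val:
                best_val = score
                best_weights = model.get_weights()
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
    if best_weights is not None:
        model.set_weights(best_weights)
    history["best_val"] = float(best_val) if best_val > -np.inf else None
    return history
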