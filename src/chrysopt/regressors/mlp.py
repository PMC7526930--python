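"""Multi-layer perceptron regressor (seeded mini-batch gradient descent).

One hidden layer of sigmoid units and a linear output, trained on squared
error.  Sized for small tabular protocol datasets, not deep learning: the
default 11-10-1 network has ~130 parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chrysopt.regressors.base import SCHEMA_TAG, TrainingError, check_features

__all__ = ["MLPConfig", "MLPModel", "fit_mlp"]


@dataclass(frozen=True)
class MLPConfig:
    hidden_units: int = 10
    activation: str = "sigmoid"  # sigmoid | tanh
    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 500
    batch_size: int = 16
    early_stopping: bool = False  # 10% internal holdout, off by default
    patience: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("counts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.activation not in ("sigmoid", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    return np.tanh(z)


def _act_grad(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return a * (1.0 - a)
    return 1.0 - a * a


@dataclass
class MLPModel:
    model_kind: str
    n_features: int
    config: MLPConfig
    w1: np.ndarray  # (d, h)
    b1: np.ndarray  # (h,)
    w2: np.ndarray  # (h,)
    b2: float
    loss_history: list[float] = field(default_factory=list)
    epochs_run: int = 0

    def predict(self, features: np.ndarray) -> np.ndarray:
        x = check_features(features, self.n_features)
        h = _act(x @ self.w1 + self.b1, self.config.activation)
        return h @ self.w2 + self.b2

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_TAG,
            "model_kind": "mlp",
            "n_features": self.n_features,
            "config": vars(self.config) | {},
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "loss_history": list(self.loss_history),
            "epochs_run": self.epochs_run,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MLPModel":
        return cls(
            model_kind="mlp",
            n_features=payload["n_features"],
            config=MLPConfig(**payload["config"]),
            w1=np.asarray(payload["w1"], dtype=float),
            b1=np.asarray(payload["b1"], dtype=float),
            w2=np.asarray(payload["w2"], dtype=float),
            b2=float(payload["b2"]),
            loss_history=list(payload["loss_history"]),
            epochs_run=payload["epochs_run"],
        )


def fit_mlp(
    train_features: np.ndarray, train_targets: np.ndarray, config: MLPConfig = MLPConfig()
) -> MLPModel:
    """Train the network by seeded mini-batch gradient descent on MSE.

    Weights are Glorot-initialized from the config seed; the output bias
    starts at the target mean so a constant signal is fit immediately.  The
    per-epoch full-data loss is recorded in ``loss_history``.  A non-finite
    loss aborts with :class:`TrainingError` (advising a smaller learning
    rate) rather than returning a diverged model.
    """
    x = check_features(train_features, np.atleast_2d(train_features).shape[-1])
    y = np.asarray(train_targets, dtype=float).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("features/targets length mismatch")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    d, h = x.shape[1], config.hidden_units
    rng = np.random.default_rng(config.seed)

    # Glorot hidden layer; zero output weights + mean-target bias so the
    # net starts at the constant predictor and classical momentum carries
    # the small pinned learning rate to convergence within the epoch budget.
    limit1 = np.sqrt(6.0 / (d + h))
    w1 = rng.uniform(-limit1, limit1, size=(d, h))
    b1 = np.zeros(h)
    w2 = np.zeros(h)
    b2 = float(y.mean())
    vel = [np.zeros_like(w1), np.zeros_like(b1), np.zeros_like(w2), 0.0]

    # optional early-stopping holdout carved from the training rows
    if config.early_stopping and x.shape[0] >= 10:
        n_hold = max(1, x.shape[0] // 10)
        perm = rng.permutation(x.shape[0])
        hold, keep = perm[:n_hold], perm[n_hold:]
        x_hold, y_hold = x[hold], y[hold]
        x, y = x[keep], y[keep]
    else:
        x_hold = y_hold = None

    n = x.shape[0]
    lr = config.learning_rate
    losses: list[float] = []
    best_hold = np.inf
    stale = 0
    epochs_run = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            a = _act(xb @ w1 + b1, config.activation)
            pred = a @ w2 + b2
            err = pred - yb  # (b,)
            m = len(idx)
            g2 = (2.0 / m) * (a.T @ err)
            gb2 = (2.0 / m) * err.sum()
            da = (2.0 / m) * np.outer(err, w2) * _act_grad(a, config.activation)
            g1 = xb.T @ da
            gb1 = da.sum(axis=0)
            mom = config.momentum
            vel[0] = mom * vel[0] - lr * g1
            vel[1] = mom * vel[1] - lr * gb1
            vel[2] = mom * vel[2] - lr * g2
            vel[3] = mom * vel[3] - lr * gb2
            w1 += vel[0]
            b1 += vel[1]
            w2 += vel[2]
            b2 += vel[3]
        with np.errstate(over="ignore", invalid="ignore"):
            full_pred = _act(x @ w1 + b1, config.activation) @ w2 + b2
            loss = float(np.mean((full_pred - y) ** 2))
        if not np.isfinite(loss):
            raise TrainingError(
                "MLP training diverged (non-finite loss); try a smaller learning rate"
            )
        losses.append(loss)
        epochs_run = epoch + 1
        if x_hold is not None:
            hold_pred = _act(x_hold @ w1 + b1, config.activation) @ w2 + b2
            hold_loss = float(np.mean((hold_pred - y_hold) ** 2))
            if hold_loss < best_hold - 1e-12:
                best_hold = hold_loss
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break

    return MLPModel(
        model_kind="mlp",
        n_features=d,
        config=config,
        w1=w1,
        b1=b1,
        w2=w2,
        b2=b2,
        loss_history=losses,
        epochs_run=epochs_run,
    )
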