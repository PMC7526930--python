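"""First-order Takagi-Sugeno adaptive neuro-fuzzy inference system.

Each rule has a Gaussian membership function per input; the product t-norm
gives the rule's firing strength, which is normalized across rules and
weights a linear consequent.  A grid partition over 11 inputs would need at
least 2^11 rules, so the rule base is scatter-generated instead: one rule
per fuzzy cluster, with clusters found by seeded k-means on the training
features.

Training is hybrid: with premises fixed the consequent coefficients are a
linear least-squares problem solved exactly; premises (membership centers
and widths) then take a gradient step, with the step reverted and the step
size halved whenever it would increase the training loss, so the recorded
epoch losses are non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from chrysopt.regressors.base import SCHEMA_TAG, TrainingError, check_features

__all__ = ["ANFISConfig", "ANFISModel", "fit_anfis"]

_SIGMA_FLOOR = 1e-3


@dataclass(frozen=True)
class ANFISConfig:
    n_rules: int = 4
    membership: str = "gaussian"
    epochs: int = 100
    premise_learning_rate: float = 0.05
    consequent_ridge: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rules < 1 or self.epochs < 1:
            raise ValueError("counts must be positive")
        if self.premise_learning_rate <= 0 or self.consequent_ridge <= 0:
            raise ValueError("learning rate and ridge must be positive")
        if self.membership != "gaussian":
            raise ValueError("only gaussian membership functions are implemented")


def _norm_firing(
    x: np.ndarray, centers: np.ndarray, sigmas: np.ndarray
) -> np.ndarray:
    """Normalized firing strengths, (n, R); rows sum to 1 exactly.

    Computed in log space with max-subtraction so a sample far from every
    cluster underflows gracefully instead of dividing by zero.
    """
    logw = -0.5 * (
        ((x[:, None, :] - centers[None, :, :]) / sigmas[None, :, :]) ** 2
    ).sum(axis=2)
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=1, keepdims=True)


def _consequent_lsq(
    x: np.ndarray, y: np.ndarray, wn: np.ndarray, ridge: float
) -> tuple[np.ndarray, float]:
    """Ridge least-squares consequents given normalized firings; returns
    (theta (R, d+1), training MSE).

    The small ridge keeps the solve well-posed when the rule count times
    (d+1) approaches the number of distinct training rows, where plain
    least squares produces huge consequents and wild extrapolation.
    """
    n, d = x.shape
    r = wn.shape[1]
    xt = np.column_stack([x, np.ones(n)])  # (n, d+1)
    a = (wn[:, :, None] * xt[:, None, :]).reshape(n, r * (d + 1))
    k = a.shape[1]
    # Tikhonov on the slopes, rule biases unpenalized; solved as a stacked
    # least-squares problem (min-norm) so duplicate rules stay well-posed
    damp = np.full(k, np.sqrt(ridge))
    damp[d :: d + 1] = 1e-8
    aug = np.vstack([a, np.diag(damp)])
    rhs = np.concatenate([y, np.zeros(k)])
    theta, *_ = np.linalg.lstsq(aug, rhs, rcond=None)
    loss = float(np.mean((a @ theta - y) ** 2))
    return theta.reshape(r, d + 1), loss


@dataclass
class ANFISModel:
    model_kind: str
    n_features: int
    config: ANFISConfig
    centers: np.ndarray  # (R, d) membership centers
    sigmas: np.ndarray  # (R, d) membership widths
    consequents: np.ndarray  # (R, d+1) linear rule outputs, last = bias
    loss_history: list[float] = field(default_factory=list)

    @property
    def n_rules(self) -> int:
        return self.centers.shape[0]

    def firing_strengths(self, features: np.ndarray) -> np.ndarray:
        x = check_features(features, self.n_features)
        return _norm_firing(x, self.centers, self.sigmas)

    def predict(self, features: np.ndarray) -> np.ndarray:
        x = check_features(features, self.n_features)
        wn = _norm_firing(x, self.centers, self.sigmas)
        f = np.column_stack([x, np.ones(len(x))]) @ self.consequents.T  # (n, R)
        return (wn * f).sum(axis=1)

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_TAG,
            "model_kind": "anfis",
            "n_features": self.n_features,
            "config": vars(self.config) | {},
            "centers": self.centers.tolist(),
            "sigmas": self.sigmas.tolist(),
            "consequents": self.consequents.tolist(),
            "loss_history": list(self.loss_history),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ANFISModel":
        return cls(
            model_kind="anfis",
            n_features=payload["n_features"],
            config=ANFISConfig(**payload["config"]),
            centers=np.asarray(payload["centers"], dtype=float),
            sigmas=np.asarray(payload["sigmas"], dtype=float),
            consequents=np.asarray(payload["consequents"], dtype=float),
            loss_history=list(payload["loss_history"]),
        )


def fit_anfis(
    train_features: np.ndarray,
    train_targets: np.ndarray,
    config: ANFISConfig = ANFISConfig(),
) -> ANFISModel:
    """Hybrid training: exact LSQ consequents + adaptive gradient premises."""
    x = check_features(train_features, np.atleast_2d(train_features).shape[-1])
    y = np.asarray(train_targets, dtype=float).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("features/targets length mismatch")
    n, d = x.shape
    r = min(config.n_rules, len(np.unique(x, axis=0)))

    if r == 1:
        centers = x.mean(axis=0, keepdims=True)
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=r, n_init=4, random_state=config.seed).fit(x)
        centers = km.cluster_centers_.copy()
        labels = km.labels_
    global_sd = np.maximum(x.std(axis=0), 0.2)
    sigmas = np.tile(global_sd, (r, 1))
    for k in range(r):
        members = x[labels == k]
        if len(members) >= 2:
            sd = members.std(axis=0)
            sigmas[k] = np.where(sd > 0.05, sd, sigmas[k])
    sigmas = np.maximum(sigmas, _SIGMA_FLOOR)

    lr = config.premise_learning_rate
    ridge = config.consequent_ridge
    wn = _norm_firing(x, centers, sigmas)
    theta, loss = _consequent_lsq(x, y, wn, ridge)
    if not np.isfinite(loss):
        raise TrainingError("ANFIS consequent solve produced non-finite loss")
    losses = [loss]
    xt = np.column_stack([x, np.ones(n)])
    for _ in range(config.epochs - 1):
        f = xt @ theta.T  # (n, R)
        pred = (wn * f).sum(axis=1)
        err = pred - y
        # d pred / d log w_rk factorizes through the normalized firings
        core = (2.0 / n) * err[:, None] * wn * (f - pred[:, None])  # (n, R)
        diff = x[:, None, :] - centers[None, :, :]  # (n, R, d)
        grad_c = (core[:, :, None] * diff / sigmas[None, :, :] ** 2).sum(axis=0)
        grad_s = (core[:, :, None] * diff**2 / sigmas[None, :, :] ** 3).sum(axis=0)
        stepped = False
        while lr >= 1e-8:
            new_centers = centers - lr * grad_c
            new_sigmas = np.maximum(sigmas - lr * grad_s, _SIGMA_FLOOR)
            new_wn = _norm_firing(x, new_centers, new_sigmas)
            new_theta, new_loss = _consequent_lsq(x, y, new_wn, ridge)
            if np.isfinite(new_loss) and new_loss <= loss + 1e-12:
                centers, sigmas = new_centers, new_sigmas
                wn, theta, loss = new_wn, new_theta, new_loss
                stepped = True
                break
            lr *= 0.5
        losses.append(loss)
        if not stepped:
            break
    while len(losses) < config.epochs:
        losses.append(loss)

    return ANFISModel(
        model_kind="anfis",
        n_features=d,
        config=config,
        centers=centers,
        sigmas=sigmas,
        consequents=theta,
        loss_history=losses,
    )
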