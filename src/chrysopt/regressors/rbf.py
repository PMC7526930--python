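"""Gaussian radial basis function network regressor.

Centers come from seeded k-means on the training features (or the training
points themselves when as many centers as distinct rows are requested).
Kernel widths follow one of two rules: per-center nearest-neighbor widths
sigma_k = kappa * min_{j != k} ||c_k - c_j|| (default; robust when the
feature distribution is clumpy, as dose columns with structural zeros are),
or the classic shared max-pairwise-distance rule sigma = d_max / sqrt(2 c).
The output layer is linear in the basis responses plus, by default, a
linear tail in the raw features (the usual polynomial augmentation, which
lets the network express affine trends that few wide Gaussians represent
poorly in high dimension).  Output weights solve a ridge-regularized linear
least-squares problem in closed form, so the fit is deterministic and the
recorded "loss history" is the single closed-form training MSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from chrysopt.regressors.base import SCHEMA_TAG, check_features

__all__ = ["RBFConfig", "RBFModel", "fit_rbf", "ridge_weights"]


class DegeneracyError(ValueError):
    """More centers requested than distinct training points."""


@dataclass(frozen=True)
class RBFConfig:
    n_centers: int = 15
    width_rule: str = "nearest_neighbor"  # nearest_neighbor | max_pairwise
    width_scale: float = 1.5  # kappa for the nearest-neighbor rule
    linear_tail: bool = True
    ridge: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_centers < 1:
            raise ValueError("n_centers must be positive")
        if self.ridge <= 0 or self.width_scale <= 0:
            raise ValueError("ridge penalty and width scale must be positive")
        if self.width_rule not in ("nearest_neighbor", "max_pairwise"):
            raise ValueError(f"unknown width rule {self.width_rule!r}")


def _design(
    x: np.ndarray, centers: np.ndarray, sigmas: np.ndarray, linear_tail: bool
) -> np.ndarray:
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    phi = np.exp(-d2 / (2.0 * sigmas[None, :] ** 2))
    cols = [phi, x, np.ones((len(x), 1))] if linear_tail else [phi, np.ones((len(x), 1))]
    return np.column_stack(cols)


def ridge_weights(
    phi: np.ndarray, y: np.ndarray, ridge: float, *, skip_last: bool = True
) -> np.ndarray:
    """Closed-form ridge solution (intercept column unpenalized)."""
    k = phi.shape[1]
    penalty = np.eye(k) * ridge
    if skip_last:
        penalty[-1, -1] = 0.0
    return np.linalg.solve(phi.T @ phi + penalty, phi.T @ y)


def _widths(centers: np.ndarray, config: RBFConfig) -> np.ndarray:
    c = len(centers)
    if c == 1:
        return np.ones(1)
    dist = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
    if config.width_rule == "max_pairwise":
        d_max = float(dist.max())
        sigma = d_max / np.sqrt(2.0 * c) if d_max > 0 else 1.0
        return np.full(c, sigma)
    np.fill_diagonal(dist, np.inf)
    nn = dist.min(axis=1)
    nn[~np.isfinite(nn) | (nn <= 0)] = 1.0
    return config.width_scale * nn


@dataclass
class RBFModel:
    model_kind: str
    n_features: int
    config: RBFConfig
    centers: np.ndarray  # (c, d)
    sigmas: np.ndarray  # (c,) per-center kernel widths
    weights: np.ndarray  # (c [+ d] + 1,) last entry = intercept
    loss_history: list[float] = field(default_factory=list)

    def predict(self, features: np.ndarray) -> np.ndarray:
        x = check_features(features, self.n_features)
        return _design(x, self.centers, self.sigmas, self.config.linear_tail) @ self.weights

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_TAG,
            "model_kind": "rbf",
            "n_features": self.n_features,
            "config": vars(self.config) | {},
            "centers": self.centers.tolist(),
            "sigmas": self.sigmas.tolist(),
            "weights": self.weights.tolist(),
            "loss_history": list(self.loss_history),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RBFModel":
        return cls(
            model_kind="rbf",
            n_features=payload["n_features"],
            config=RBFConfig(**payload["config"]),
            centers=np.asarray(payload["centers"], dtype=float),
            sigmas=np.asarray(payload["sigmas"], dtype=float),
            weights=np.asarray(payload["weights"], dtype=float),
            loss_history=list(payload["loss_history"]),
        )


def fit_rbf(
    train_features: np.ndarray, train_targets: np.ndarray, config: RBFConfig = RBFConfig()
) -> RBFModel:
    """Fit the RBF network (k-means centers, closed-form ridge weights).

    When ``n_centers`` equals the number of distinct training rows the
    distinct rows themselves are used as centers, which with a vanishing
    ridge recovers exact interpolation on noiseless data.
    """
    x = check_features(train_features, np.atleast_2d(train_features).shape[-1])
    y = np.asarray(train_targets, dtype=float).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("features/targets length mismatch")
    distinct = np.unique(x, axis=0)
    if config.n_centers > len(distinct):
        raise DegeneracyError(
            f"{config.n_centers} centers requested but only "
            f"{len(distinct)} distinct training points"
        )
    if config.n_centers == len(distinct):
        centers = distinct
    else:
        km = KMeans(
            n_clusters=config.n_centers, n_init=4, random_state=config.seed
        ).fit(x)
        centers = km.cluster_centers_

    sigmas = _widths(centers, config)
    phi = _design(x, centers, sigmas, config.linear_tail)
    weights = ridge_weights(phi, y, config.ridge)
    loss = float(np.mean((phi @ weights - y) ** 2))
    return RBFModel(
        model_kind="rbf",
        n_features=x.shape[1],
        config=config,
        centers=centers,
        sigmas=sigmas,
        weights=weights,
        loss_history=[loss],
    )
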