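"""Prediction stacking, bagging fusion, and fit metrics.

The three member regressors each produce an estimate f_j(x); stacking them
column-wise gives the n x m prediction matrix that fusion consumes.  Fusion
is bootstrap aggregation: every member kind is refit on B bootstrap
resamples of the training rows, a member's prediction is the mean over its
B refits, and the fused prediction is the unweighted mean of the member
predictions (a weighted mean is available behind ``weights``).  The fused
output is therefore always a convex combination of the member outputs.

Fit quality is reported as R^2 (1 - SSE/SST), RMSE and MBE (mean of
predicted minus observed, so over-prediction is positive), with RMSE/MBE in
percentage points of transformation efficiency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from chrysopt.regressors import CONFIG_TYPES, FITTERS
from chrysopt.regressors.base import (
    SCHEMA_TAG,
    ShapeError,
    TrainedModel,
    model_from_dict,
)

__all__ = [
    "PredictionMatrix",
    "BaggedMember",
    "EnsembleModel",
    "FitMetrics",
    "MetricsError",
    "stack_predictions",
    "fit_bagged_ensemble",
    "evaluate",
]

_ENSEMBLE_SCHEMA = "chrysopt-ensemble/1"


class MetricsError(ValueError):
    """Raised when a metric is undefined (constant observations)."""


@dataclass
class PredictionMatrix:
    values: np.ndarray  # (n, m)
    model_ids: tuple[str, ...]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def fuse(self, weights: Sequence[float] | None = None) -> np.ndarray:
        w = (
            np.full(self.m, 1.0 / self.m)
            if weights is None
            else np.asarray(weights, dtype=float) / np.sum(weights)
        )
        return self.values @ w


def stack_predictions(
    models: Sequence[TrainedModel], features: np.ndarray
) -> PredictionMatrix:
    """Column j of the result is model j's estimate on every row."""
    n_feat = {m.n_features for m in models}
    if len(n_feat) > 1:
        raise ShapeError(f"models disagree on feature count: {sorted(n_feat)}")
    cols = [m.predict(features) for m in models]
    values = np.column_stack(cols)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite member prediction")
    return PredictionMatrix(
        values=values, model_ids=tuple(m.model_kind for m in models)
    )


@dataclass
class BaggedMember:
    kind: str
    models: list[TrainedModel]

    @property
    def b(self) -> int:
        return len(self.models)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.mean([m.predict(features) for m in self.models], axis=0)


@dataclass
class EnsembleModel:
    members: dict[str, BaggedMember]
    b: int
    seed: int
    fusion_rule: str = "mean"
    weights: tuple[float, ...] | None = None
    n_features: int = field(init=False)

    def __post_init__(self) -> None:
        kinds = list(self.members)
        self.n_features = self.members[kinds[0]].models[0].n_features

    def member_predictions(self, features: np.ndarray) -> PredictionMatrix:
        values = np.column_stack(
            [m.predict(features) for m in self.members.values()]
        )
        return PredictionMatrix(values=values, model_ids=tuple(self.members))

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.member_predictions(features).fuse(self.weights)

    def to_dict(self) -> dict:
        return {
            "schema": _ENSEMBLE_SCHEMA,
            "b": self.b,
            "seed": self.seed,
            "fusion_rule": self.fusion_rule,
            "weights": list(self.weights) if self.weights else None,
            "members": {
                kind: [m.to_dict() for m in member.models]
                for kind, member in self.members.items()
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "EnsembleModel":
        if payload.get("schema") != _ENSEMBLE_SCHEMA:
            raise ValueError(f"unknown ensemble schema {payload.get('schema')!r}")
        members = {
            kind: BaggedMember(kind, [model_from_dict(d) for d in dicts])
            for kind, dicts in payload["members"].items()
        }
        return cls(
            members=members,
            b=payload["b"],
            seed=payload["seed"],
            fusion_rule=payload["fusion_rule"],
            weights=tuple(payload["weights"]) if payload["weights"] else None,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _bootstrap_indices(rng: np.random.Generator, n: int) -> np.ndarray:
    """Resample with replacement, retrying (bounded) until >= 2 distinct rows."""
    for _ in range(100):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(idx)) >= 2:
            return idx
    raise RuntimeError("could not draw a bootstrap sample with 2 distinct rows")


def fit_bagged_ensemble(
    train_features: np.ndarray,
    train_targets: np.ndarray,
    member_configs: dict[str, object] | None = None,
    b: int = 25,
    seed: int = 0,
    *,
    resample: bool = True,
    weights: Sequence[float] | None = None,
) -> EnsembleModel:
    """Fit B bootstrap refits of each member kind and fuse by averaging.

    ``member_configs`` maps kind ('mlp' | 'rbf' | 'anfis') to its config;
    omitted kinds use their defaults.  ``resample=False`` is a test hook
    that fits every replicate on the full training sample (with B=1 this
    degenerates to the plain mean of the three single models).
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_targets, dtype=float).ravel()
    n = x.shape[0]
    member_configs = dict(member_configs or {})
    seeds = np.random.SeedSequence(seed).spawn(len(FITTERS))
    members: dict[str, BaggedMember] = {}
    for kind_i, kind in enumerate(FITTERS):
        cfg = member_configs.get(kind, CONFIG_TYPES[kind]())
        rng = np.random.default_rng(seeds[kind_i])
        fits: list[TrainedModel] = []
        for rep in range(b):
            idx = _bootstrap_indices(rng, n) if resample else np.arange(n)
            rep_seed = int(rng.integers(0, 2**31 - 1))
            rep_cfg = type(cfg)(**(vars(cfg) | {"seed": rep_seed}))
            fits.append(FITTERS[kind](x[idx], y[idx], rep_cfg))
        members[kind] = BaggedMember(kind, fits)
    return EnsembleModel(
        members=members,
        b=b,
        seed=seed,
        weights=tuple(weights) if weights is not None else None,
    )


@dataclass(frozen=True)
class FitMetrics:
    r2: float
    rmse: float
    mbe: float
    split_name: str

    def as_dict(self) -> dict:
        return {"split": self.split_name, "R2": self.r2, "RMSE": self.rmse, "MBE": self.mbe}


def evaluate(y_obs: np.ndarray, y_pred: np.ndarray, split_name: str = "") -> FitMetrics:
    """R^2 = 1 - SSE/SST, RMSE, and MBE = mean(pred - obs)."""
    y = np.asarray(y_obs, dtype=float).ravel()
    p = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != p.shape:
        raise ShapeError(f"length mismatch: {y.shape} vs {p.shape}")
    if y.size < 2:
        raise MetricsError("need at least 2 observations")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise MetricsError("R^2 undefined for constant observations")
    sse = float(np.sum((y - p) ** 2))
    return FitMetrics(
        r2=1.0 - sse / sst,
        rmse=float(np.sqrt(np.mean((p - y) ** 2))),
        mbe=float(np.mean(p - y)),
        split_name=split_name,
    )
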