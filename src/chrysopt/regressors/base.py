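"""Shared model interface: prediction, validation, JSON serialization."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

SCHEMA_TAG = "chrysopt-model/1"


class TrainingError(RuntimeError):
    """Raised when optimization diverges (non-finite loss)."""


class ShapeError(ValueError):
    """Raised on feature-dimension mismatch at predict time."""


@runtime_checkable
class TrainedModel(Protocol):
    model_kind: str
    n_features: int
    loss_history: list[float]

    def predict(self, features: np.ndarray) -> np.ndarray: ...

    def to_dict(self) -> dict: ...


def check_features(features: np.ndarray, n_features: int) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2 or x.shape[1] != n_features:
        raise ShapeError(
            f"expected features with {n_features} columns, got shape {x.shape}"
        )
    return x


def save_model(model: TrainedModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def model_from_dict(payload: dict) -> TrainedModel:
    from chrysopt.regressors.anfis import ANFISModel
    from chrysopt.regressors.mlp import MLPModel
    from chrysopt.regressors.rbf import RBFModel

    if payload.get("schema") != SCHEMA_TAG:
        raise ValueError(f"unknown model schema {payload.get('schema')!r}")
    kind = payload["model_kind"]
    cls = {"mlp": MLPModel, "rbf": RBFModel, "anfis": ANFISModel}[kind]
    return cls.from_dict(payload)


def load_model(path: str | Path) -> TrainedModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Predict through any trained member model (shape-checked)."""
    return model.predict(features)
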