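"""Variable-sensitivity-error / variable-sensitivity-ratio importance ranking.

VSE for an input is the ensemble's RMSE when that input is "removed"; VSR is
VSE divided by the full-model RMSE, so VSR ~ 1 means the model did not rely
on the variable and VSR >> 1 marks an important one.  "Removal" defaults to
mean substitution (the column is replaced by its training mean, no
retraining); a retrain-without-column policy and an identity no-op hook are
also provided.  Ranks are 1 = most important, descending VSR, ties broken by
the canonical variable order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from chrysopt.ensemble import EnsembleModel, evaluate

__all__ = ["SensitivityReport", "vse", "vsr_report"]


class DegenerateFitError(ValueError):
    """Full-model RMSE is zero; VSR undefined."""


@dataclass
class SensitivityReport:
    table: pd.DataFrame  # index = variable, columns vse, vsr, rank
    full_model_rmse: float
    policy: str

    def rank_of(self, variable: str) -> int:
        return int(self.table.loc[variable, "rank"])

    def ordering(self) -> list[str]:
        return list(self.table.sort_values("rank").index)

    def to_csv(self, path) -> None:
        # two-row layout (VSR, Rank) mirroring the study's sensitivity table
        out = pd.DataFrame(
            [self.table["vsr"].round(4), self.table["rank"]],
            index=["VSR", "Rank"],
        )
        out.to_csv(path)


def _removed_column(
    features: np.ndarray,
    j: int,
    policy: str,
    column_means: np.ndarray | None,
) -> np.ndarray:
    x = features.copy()
    if policy == "identity":
        return x
    if policy == "mean":
        fill = (
            float(column_means[j]) if column_means is not None else float(x[:, j].mean())
        )
        x[:, j] = fill
        return x
    raise ValueError(f"unknown removal policy {policy!r}")


def vse(
    model: EnsembleModel,
    features: np.ndarray,
    targets: np.ndarray,
    variable: str,
    feature_names: Sequence[str],
    policy: str = "mean",
    column_means: np.ndarray | None = None,
    refit: Callable[[np.ndarray], EnsembleModel] | None = None,
) -> float:
    """RMSE of the ensemble with one variable removed.

    ``column_means`` supplies training-split means for the mean-substitution
    policy (defaults to the means of ``features``).  Under ``policy=
    'retrain'`` the caller provides ``refit``, a function fitting a fresh
    ensemble on features with the column dropped.
    """
    if variable not in feature_names:
        raise KeyError(f"unknown variable {variable!r}; expected one of {list(feature_names)}")
    j = list(feature_names).index(variable)
    if policy == "retrain":
        if refit is None:
            raise ValueError("retrain policy requires a refit callable")
        reduced = np.delete(features, j, axis=1)
        pred = refit(reduced).predict(reduced)
    else:
        pred = model.predict(_removed_column(np.asarray(features, float), j, policy, column_means))
    return evaluate(targets, pred, "vse").rmse


def vsr_report(
    model: EnsembleModel,
    features: np.ndarray,
    targets: np.ndarray,
    feature_names: Sequence[str],
    policy: str = "mean",
    column_means: np.ndarray | None = None,
    refit: Callable[[np.ndarray], EnsembleModel] | None = None,
) -> SensitivityReport:
    """Per-variable VSE and VSR with ranks (1 = highest VSR)."""
    full_rmse = evaluate(targets, model.predict(features), "full").rmse
    if full_rmse == 0.0:
        raise DegenerateFitError("full-model RMSE is zero; VSR undefined")
    vses = np.array(
        [
            vse(model, features, targets, name, feature_names, policy, column_means, refit)
            for name in feature_names
        ]
    )
    vsrs = vses / full_rmse
    # stable ranking: descending vsr, ties by canonical variable order
    order = sorted(range(len(feature_names)), key=lambda j: (-vsrs[j], j))
    ranks = np.empty(len(feature_names), dtype=int)
    for pos, j in enumerate(order):
        ranks[j] = pos + 1
    table = pd.DataFrame(
        {"vse": vses, "vsr": vsrs, "rank": ranks}, index=list(feature_names)
    )
    return SensitivityReport(table=table, full_model_rmse=full_rmse, policy=policy)
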