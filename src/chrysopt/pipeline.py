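"""End-to-end study pipeline: ingest -> encode -> split -> fit -> fuse ->
evaluate -> optimize -> rank.

A single top-level seed drives every random stage (split, bootstrap refits,
model initializations, fly flights) through spawned child seeds, so a run is
reproducible end to end.  Because the original study's single random split
and initializations are unrecoverable, the official reproduction mode is a
seed sweep: the same pipeline repeated over many seeds, summarized by
medians and interquartile ranges.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from chrysopt import database
from chrysopt.database import FEATURE_NAMES, ResolutionPolicy
from chrysopt.ensemble import EnsembleModel, FitMetrics, evaluate, fit_bagged_ensemble
from chrysopt.foa import FOAConfig, optimize
from chrysopt.sensitivity import SensitivityReport, vsr_report
from chrysopt.synthetic import SyntheticConfig, generate

__all__ = ["StudyConfig", "StudyReport", "run_study", "seed_sweep"]

__version__ = "0.1.0"

logger = logging.getLogger("chrysopt")
if not logger.handlers:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[chrysopt] %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

_SPLIT_NAMES = ("training", "testing", "validation")
_MODEL_LABELS = {"mlp": "MLP", "rbf": "RBF", "anfis": "ANFIS", "ensemble": "Ensemble"}


@dataclass(frozen=True)
class StudyConfig:
    data: str = "table4"  # 'table4' | 'synthetic'
    resolution: ResolutionPolicy = ResolutionPolicy()
    synthetic: SyntheticConfig | None = None
    member_configs: dict | None = None
    bagging_b: int = 25
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    foa: FOAConfig = FOAConfig()
    sensitivity_policy: str = "mean"
    run_foa: bool = True
    run_sensitivity: bool = True


@dataclass
class StudyReport:
    metrics: dict[str, dict[str, FitMetrics]]  # model -> split -> metrics
    optimum: dict | None
    foa_history: list[float] | None
    sensitivity: SensitivityReport | None
    seed: int
    config_snapshot: dict
    version: str = __version__

    def metric(self, model: str, split: str, name: str) -> float:
        return getattr(self.metrics[model][split], name)

    def scalars(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for model, by_split in self.metrics.items():
            for split_name, m in by_split.items():
                for metric_name in ("r2", "rmse", "mbe"):
                    out[f"{model}_{split_name}_{metric_name}"] = getattr(m, metric_name)
        if self.optimum is not None:
            out["foa_best_efficiency"] = self.optimum["predicted_efficiency"]
        if self.sensitivity is not None:
            for name in self.sensitivity.table.index:
                out[f"vsr_{name}"] = float(self.sensitivity.table.loc[name, "vsr"])
                out[f"rank_{name}"] = float(self.sensitivity.table.loc[name, "rank"])
        return out

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "config": self.config_snapshot,
            "metrics": {
                model: {s: m.as_dict() for s, m in by_split.items()}
                for model, by_split in self.metrics.items()
            },
            "optimum": self.optimum,
            "foa_history": self.foa_history,
            "sensitivity": (
                None
                if self.sensitivity is None
                else {
                    "policy": self.sensitivity.policy,
                    "full_model_rmse": self.sensitivity.full_model_rmse,
                    "table": self.sensitivity.table.to_dict(orient="index"),
                }
            ),
        }
        return json.dumps(payload, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _stage(name: str, t0: float, **info) -> None:
    extra = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("%s done in %.2fs %s", name, time.perf_counter() - t0, extra)


def load_rows(config: StudyConfig, data_seed: int) -> pd.DataFrame:
    """Resolved rows for the configured source (fixture or synthetic)."""
    if config.data == "table4":
        records = database.load_database()
        return database.resolve_records(records, config.resolution)
    if config.data == "synthetic":
        syn = config.synthetic or SyntheticConfig()
        syn = dataclasses.replace(syn, seed=data_seed)
        rows, _ = generate(syn)
        return rows
    raise ValueError(f"unknown data source {config.data!r}")


def run_study(
    config: StudyConfig = StudyConfig(),
    seed: int = 0,
    outdir: str | Path | None = None,
) -> StudyReport:
    """Execute the full study under one seed; optionally write report files."""
    seeds = np.random.SeedSequence(seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seeds]
    data_seed, split_seed, ensemble_seed, foa_seed = sub

    t0 = time.perf_counter()
    rows = load_rows(config, data_seed)
    dataset = database.encode(rows)
    _stage("ingest+encode", t0, rows=len(rows), features=dataset.features.shape[1])

    t0 = time.perf_counter()
    the_split = database.split(dataset, config.fractions, split_seed)
    idx = the_split.as_dict()
    x, y = dataset.features, dataset.targets
    ensemble = fit_bagged_ensemble(
        x[the_split.train_idx],
        y[the_split.train_idx],
        config.member_configs,
        b=config.bagging_b,
        seed=ensemble_seed,
    )
    _stage("fit+fuse", t0, train=len(the_split.train_idx), b=config.bagging_b)

    t0 = time.perf_counter()
    metrics: dict[str, dict[str, FitMetrics]] = {}
    predictors = {k: m.predict for k, m in ensemble.members.items()}
    predictors["ensemble"] = ensemble.predict
    for model_name, predict in predictors.items():
        metrics[model_name] = {
            split_name: evaluate(y[i], predict(x[i]), split_name)
            for split_name, i in idx.items()
        }
    _stage("evaluate", t0, cells=sum(len(v) for v in metrics.values()))

    optimum = None
    history = None
    if config.run_foa:
        t0 = time.perf_counter()
        bounds_map = database.dataset_bounds(rows)
        bounds = [bounds_map[name] for name in FEATURE_NAMES]
        n_strains = len(dataset.strain_codebook)
        foa_cfg = dataclasses.replace(config.foa, dimensions=len(FEATURE_NAMES))

        def objective(candidates: np.ndarray) -> np.ndarray:
            return ensemble.predict(dataset.scale(candidates))

        result = optimize(
            objective,
            bounds,
            categorical_spec={0: n_strains},
            config=foa_cfg,
            rng=np.random.default_rng(foa_seed),
        )
        code_to_strain = {v: k for k, v in dataset.strain_codebook.items()}
        best = result.best_inputs
        optimum = {
            "strain": code_to_strain[int(best[0])],
            **{name: float(best[j]) for j, name in enumerate(FEATURE_NAMES) if j > 0},
            "predicted_efficiency": float(result.best_predicted_efficiency),
            "evaluations": result.evaluations,
        }
        history = result.history
        _stage("foa", t0, evaluations=result.evaluations)

    report_sensitivity = None
    if config.run_sensitivity:
        t0 = time.perf_counter()
        # evaluated on the full database; means from the training split
        train_means = x[the_split.train_idx].mean(axis=0)
        report_sensitivity = vsr_report(
            ensemble,
            x,
            y,
            FEATURE_NAMES,
            policy=config.sensitivity_policy,
            column_means=train_means,
        )
        _stage("sensitivity", t0, variables=len(FEATURE_NAMES))

    report = StudyReport(
        metrics=metrics,
        optimum=optimum,
        foa_history=history,
        sensitivity=report_sensitivity,
        seed=seed,
        config_snapshot=_snapshot(config),
    )
    if outdir is not None:
        write_report(report, outdir)
    return report


def _snapshot(config: StudyConfig) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(config), default=_json_default))


def write_report(report: StudyReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json())
    table1_rows = []
    for model in ("mlp", "rbf", "anfis", "ensemble"):
        row: dict[str, object] = {"Model": _MODEL_LABELS[model]}
        for metric_name, label in (("r2", "R2"), ("rmse", "RMSE"), ("mbe", "MBE")):
            for split_name in _SPLIT_NAMES:
                row[f"{label} {split_name}"] = round(
                    report.metric(model, split_name, metric_name), 4
                )
        table1_rows.append(row)
    pd.DataFrame(table1_rows).to_csv(outdir / "table1.csv", index=False)
    if report.optimum is not None:
        pd.DataFrame([report.optimum]).to_csv(outdir / "table2.csv", index=False)
    if report.foa_history is not None:
        pd.DataFrame(
            {"generation": np.arange(1, len(report.foa_history) + 1),
             "best_smell": report.foa_history}
        ).to_csv(outdir / "convergence.csv", index=False)
    if report.sensitivity is not None:
        report.sensitivity.to_csv(outdir / "table3.csv")


def seed_sweep(
    config: StudyConfig, seeds: Sequence[int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the study per seed; returns (per-run scalars, median/IQR summary)."""
    if len(seeds) < 2:
        raise ValueError("need at least 2 seeds")
    runs = []
    for s in seeds:
        report = run_study(config, seed=int(s))
        scalars = report.scalars()
        scalars["seed"] = int(s)
        if report.optimum is not None:
            scalars["foa_best_strain"] = report.optimum["strain"]
        runs.append(scalars)
    per_run = pd.DataFrame(runs).set_index("seed")
    numeric = per_run.select_dtypes(include=[np.number])
    summary = pd.DataFrame(
        {
            "median": numeric.median(),
            "q25": numeric.quantile(0.25),
            "q75": numeric.quantile(0.75),
        }
    )
    summary["iqr"] = summary["q75"] - summary["q25"]
    return per_run, summary
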