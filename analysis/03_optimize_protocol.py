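"""Maximize predicted transformation efficiency with the fruit-fly optimizer.

Loads the serialized ensemble written by 02_fit_ensemble.py (refitting it if
absent), runs FOA (maxgen=100, sizepop=10, flight range [-10, 10]) over the
11 factors bounded by the observed literature ranges, and writes the decoded
optimal protocol plus the convergence trace.

    python analysis/03_optimize_protocol.py [seed]
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from chrysopt import database
from chrysopt.database import FEATURE_NAMES
from chrysopt.ensemble import EnsembleModel, fit_bagged_ensemble
from chrysopt.foa import FOAConfig, optimize

OUT = Path("results/study")


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = database.resolve_records(database.load_database())
    dataset = database.encode(rows)
    model_path = OUT / "ensemble.json"
    if model_path.exists():
        ens = EnsembleModel.load(model_path)
    else:
        sp = database.split(dataset, seed=seed)
        ens = fit_bagged_ensemble(
            dataset.features[sp.train_idx], dataset.targets[sp.train_idx], seed=seed
        )

    bounds_map = database.dataset_bounds(rows)
    bounds = [bounds_map[name] for name in FEATURE_NAMES]
    result = optimize(
        lambda c: ens.predict(dataset.scale(c)),
        bounds,
        categorical_spec={0: len(dataset.strain_codebook)},
        config=FOAConfig(dimensions=len(FEATURE_NAMES), seed=seed),
    )

    code_to_strain = {v: k for k, v in dataset.strain_codebook.items()}
    optimum = {
        "strain": code_to_strain[int(result.best_inputs[0])],
        **{n: round(float(result.best_inputs[j]), 2)
           for j, n in enumerate(FEATURE_NAMES) if j > 0},
        "predicted_efficiency": round(result.best_predicted_efficiency, 2),
    }
    pd.DataFrame([optimum]).to_csv(OUT / "table2.csv", index=False)
    pd.DataFrame(
        {"generation": np.arange(1, len(result.history) + 1),
         "best_smell": result.history}
    ).to_csv(OUT / "convergence.csv", index=False)
    (OUT / "optimum.json").write_text(json.dumps(optimum, indent=1))

    print(f"seed {seed}: optimal protocol after {result.evaluations} evaluations")
    for key, value in optimum.items():
        print(f"  {key:22s} {value}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
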