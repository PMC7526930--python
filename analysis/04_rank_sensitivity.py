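"""Rank the 11 transformation factors by VSE/VSR sensitivity.

Refits the bagged ensemble on a training split, removes each input in turn
(mean substitution) and reports VSE (RMSE without the variable), VSR
(VSE / full-model RMSE) and the importance rank, evaluated over the whole
database.

    python analysis/04_rank_sensitivity.py [seed]
"""

import sys
from pathlib import Path

from chrysopt import database
from chrysopt.database import FEATURE_NAMES
from chrysopt.ensemble import fit_bagged_ensemble
from chrysopt.sensitivity import vsr_report

OUT = Path("results/study")


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = database.resolve_records(database.load_database())
    ds = database.encode(rows)
    sp = database.split(ds, seed=seed)
    ens = fit_bagged_ensemble(
        ds.features[sp.train_idx], ds.targets[sp.train_idx], seed=seed
    )
    report = vsr_report(
        ens,
        ds.features,
        ds.targets,
        FEATURE_NAMES,
        column_means=ds.features[sp.train_idx].mean(axis=0),
    )
    report.to_csv(OUT / "table3.csv")
    print(f"seed {seed}; full-model RMSE {report.full_model_rmse:.2f} pp")
    print("importance ranking (1 = most important):")
    for name in report.ordering():
        row = report.table.loc[name]
        print(f"  {int(row['rank']):2d}. {name:7s} VSR {row['vsr']:.3f}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
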