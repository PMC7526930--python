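"""Fit the three member models and the bagged ensemble on one split.

Runs a single-seed study (without the optimization / sensitivity stages),
writes the fit-metrics table (the R2/RMSE/MBE grid over training / testing /
validation), the serialized ensemble for downstream scripts, and a
predicted-vs-observed scatter if matplotlib is available.

    python analysis/02_fit_ensemble.py [seed]
"""

import sys
from pathlib import Path

from chrysopt.pipeline import StudyConfig, run_study, write_report

OUT = Path("results/study")


def main(seed: int = 0) -> None:
    config = StudyConfig(run_foa=False, run_sensitivity=False)
    report = run_study(config, seed=seed)
    write_report(report, OUT)

    print(f"seed {seed}; fit metrics written to {OUT/'table1.csv'}:")
    for model, by_split in report.metrics.items():
        cells = "  ".join(
            f"{s}: R2={m.r2:6.3f} RMSE={m.rmse:5.2f}" for s, m in by_split.items()
        )
        print(f"  {model:9s} {cells}")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from chrysopt import database
        from chrysopt.ensemble import fit_bagged_ensemble

        rows = database.resolve_records(database.load_database())
        ds = database.encode(rows)
        sp = database.split(ds, seed=seed)
        ens = fit_bagged_ensemble(
            ds.features[sp.train_idx], ds.targets[sp.train_idx], seed=seed
        )
        ens.save(OUT / "ensemble.json")
        fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharex=True, sharey=True)
        for ax, (name, idx) in zip(axes, sp.as_dict().items()):
            ax.scatter(ds.targets[idx], ens.predict(ds.features[idx]), s=18)
            lim = [0, ds.targets.max() * 1.05]
            ax.plot(lim, lim, "k--", lw=0.8)
            ax.set_title(name)
            ax.set_xlabel("observed efficiency (%)")
        axes[0].set_ylabel("predicted efficiency (%)")
        fig.tight_layout()
        fig.savefig(OUT / "predicted_vs_observed.png", dpi=120)
        print(f"ensemble serialized to {OUT/'ensemble.json'}; scatter written")
    except ImportError:
        print("matplotlib unavailable; skipped the scatter plot")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
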