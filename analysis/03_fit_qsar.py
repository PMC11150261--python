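"""Fit and validate the CoMSIA/PLS model on the benchmark series.

Reads the pseudo-molecules and activities written by 01_simulate_benchmark,
runs the full pipeline (grid → five similarity fields → descriptor
assembly → LOO component selection → NIPALS PLS → validation → contour
maps → SAR table), prints the headline statistics, and writes all run
artifacts plus a predicted-vs-experimental scatter plot under
results/qsar_run/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from chromqsar.dataset import ActivityRecord, Organism, Split
from chromqsar.pipeline import PipelineConfig, run_on_records
from chromqsar.synthetic import read_pseudo_sdf

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    bench = ROOT / "benchmark"
    if not bench.exists():
        raise SystemExit("run analysis/01_simulate_benchmark.py first")
    molecules = read_pseudo_sdf(bench / "molecules.sdf")
    table = pd.read_csv(bench / "activities.csv")
    activities = [
        ActivityRecord(
            compound_id=row.compound_id,
            organism=Organism(row.organism),
            mic=float(row.mic),
            censored=False,
            pmic=float(row.pmic),
            split=Split(row.split),
        )
        for row in table.itertuples()
    ]

    out = ROOT / "qsar_run"
    report = run_on_records(molecules, activities, PipelineConfig(output_dir=out))

    print(f"components selected by LOO: {report.n_components}")
    print(f"training   R2 = {report.r2_train:.3f}   RMSE = {report.rmse_train:.3f}")
    print(f"LOO        Q2 = {report.q2_loo:.3f}")
    print(f"test       Q2 = {report.q2_test:.3f}   R2 = {report.r2_test:.3f}   "
          f"RMSE = {report.rmse_test:.3f}")
    print("field contributions:")
    for field, frac in sorted(report.field_contributions.items(), key=lambda kv: -kv[1]):
        print(f"  {field:<14s} {100 * frac:5.1f} %")

    pve = report.predicted_vs_experimental
    fig, ax = plt.subplots(figsize=(5, 5))
    for split, color in (("train", "tab:blue"), ("test", "tab:red")):
        sub = pve[pve["split"] == split]
        ax.scatter(sub["experimental_pmic"], sub["predicted_pmic"], c=color, s=18, label=split)
    lims = [pve["experimental_pmic"].min() - 0.5, pve["experimental_pmic"].max() + 0.5]
    ax.plot(lims, lims, "k--", lw=0.8)
    ax.set_xlabel("experimental pMIC")
    ax.set_ylabel("predicted pMIC")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "predicted_vs_experimental.png", dpi=120)
    print(f"artifacts written to {out}")


if __name__ == "__main__":
    main()
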