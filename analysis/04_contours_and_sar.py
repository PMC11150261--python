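"""Summarize contour maps and SAR-effect labels from the fitted model.

Reads the artifacts written by 03_fit_qsar: reports per-field favorable/
unfavorable contour sizes from the exported OpenDX masks, tabulates the
per-compound SAR-effect label counts, and recomputes the headline
statistics from the predicted-vs-experimental table alone (the same
recomputation path that applies to any externally supplied table).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from chromqsar.fields import read_dx
from chromqsar.pipeline import recompute_supplementary_stats

RUN = Path(__file__).resolve().parents[1] / "results" / "qsar_run"


def main() -> None:
    if not RUN.exists():
        raise SystemExit("run analysis/03_fit_qsar.py first")

    print("contour map sizes (grid points):")
    for fav in sorted(RUN.glob("contours/*_favorable.dx")):
        field = fav.name.replace("_favorable.dx", "")
        unfav = fav.with_name(f"{field}_unfavorable.dx")
        n_fav = int(read_dx(fav)[0].sum())
        n_unfav = int(read_dx(unfav)[0].sum())
        print(f"  {field:<14s} favorable {n_fav:3d}   unfavorable {n_unfav:3d}")

    sar = pd.read_csv(RUN / "sar_table.tsv", sep="\t")
    print("\nSAR-effect label counts over the series:")
    for col in sar.columns[1:]:
        counts = sar[col].value_counts().to_dict()
        print(f"  {col:<20s} {counts}")

    stats = recompute_supplementary_stats(RUN / "predicted_vs_experimental.tsv")
    print("\nstatistics recomputed from the predicted-vs-experimental table:")
    for key in ("r2_train", "r2_train_pearson", "q2_test", "rmse_train", "rmse_test"):
        print(f"  {key:<18s} {stats[key]:.3f}")


if __name__ == "__main__":
    main()
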