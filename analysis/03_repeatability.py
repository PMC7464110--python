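"""Test-retest repeatability of the GEFC measurements.

Computes ICC(A,1), the 95% coefficient of repeatability, the within-subject
coefficient of variation, the mean absolute intraobserver variability and
Bland-Altman limits of agreement per sector, for both the area fraction and
the green-channel intensity. Tables go to results/; Bland-Altman plots are
rendered to scratch/figures/.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import specfaf as sf
from specfaf.repeatability import bland_altman_summary, paired_from_metrics

ROOT = Path(__file__).resolve().parents[1]
SECTORS = ("macula", "fovea", "parafovea", "perifovea")


def bland_altman_outputs(metrics, metric, results: Path, figures: Path) -> None:
    fig, axes = plt.subplots(1, 4, figsize=(16, 3.6), constrained_layout=True)
    points = []
    for ax, sector in zip(axes, SECTORS):
        ba = bland_altman_summary(paired_from_metrics(metrics, metric, sector))
        pts = ba["points"].assign(sector=sector)
        points.append(pts)
        ax.scatter(pts["mean"], pts["diff"], s=14, color="tab:blue")
        ax.axhline(ba["mean_diff"], color="k")
        for y in (ba["loa_low"], ba["loa_high"]):
            ax.axhline(y, color="k", linestyle="--")
        ax.set_title(sector)
        ax.set_xlabel("mean of sessions")
    axes[0].set_ylabel(f"session 1 - session 2\n({metric})")
    fig.savefig(figures / f"bland_altman_{metric}.png", dpi=120)
    plt.close(fig)
    pd.concat(points).to_csv(
        results / f"bland_altman_points_{metric}.csv", index=False
    )


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--metrics", type=Path, default=ROOT / "results" / "sector_metrics.csv"
    )
    args = parser.parse_args()

    metrics = pd.read_csv(
        args.metrics, dtype={"eye_id": str, "session_id": str}
    )
    results = ROOT / "results"
    figures = ROOT / "scratch" / "figures"
    figures.mkdir(parents=True, exist_ok=True)

    for metric in ("area_fraction_pct", "mean_green_intensity"):
        tab = sf.repeatability_table(metrics, metric)
        out = results / f"repeatability_{metric}.csv"
        tab.to_csv(out)
        print(f"\n=== {metric} ===")
        print(tab.round(3).to_string())
        print(f"-> {out}")
        bland_altman_outputs(metrics, metric, results, figures)
    print(f"\nBland-Altman plots -> {figures}")


if __name__ == "__main__":
    main()
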