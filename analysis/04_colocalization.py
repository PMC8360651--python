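#!/usr/bin/env python
"""Line-profile colocalization of two-channel puncta.

Simulates neurite scenes where a known 80% of red (nanodevice) puncta
have a green (synaptic marker) partner, extracts intensity profiles
along each neurite, detects puncta as profile peaks, and scores percent
colocalization by greedy one-to-one matching, plus a per-ROI Pearson
coefficient.

Writes results/coloc_per_roi.csv and results/coloc_summary.csv.
"""

from pathlib import Path

from vesiph import RunConfig, run_coloc_pipeline

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260921


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = RunConfig(
        mode="coloc",
        seed=SEED,
        coloc={"n_rois": 10, "n_puncta": 100, "true_fraction": 0.8},
    )
    report = run_coloc_pipeline(cfg)
    summary = report.tables["coloc_summary"].iloc[0]
    print(
        f"percent colocalization: {summary['mean_percent_coloc']:.1f} "
        f"+/- {summary['sem_percent_coloc']:.1f} (s.e.m., "
        f"{int(summary['n_rois'])} ROIs; true fraction 80%)"
    )
    print(f"mean Pearson r along neurite band: {summary['mean_pearson_r']:.2f}")
    report.tables["coloc_per_roi"].to_csv(OUT / "coloc_per_roi.csv", index=False)
    report.tables["coloc_summary"].to_csv(OUT / "coloc_summary.csv", index=False)
    print(f"Wrote {OUT / 'coloc_summary.csv'}")


if __name__ == "__main__":
    main()
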