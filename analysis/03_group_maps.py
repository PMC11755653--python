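#!/usr/bin/env python
"""Spatial connectivity maps: group averages and difference schemes.

Computes every subject's pair x band table from the simulated EDFs,
assembles per-band group-mean matrices for the control and apnea groups
and their control-minus-main difference schemes, writes all matrices as
labeled CSV under results/demo/matrices/, and renders heatmaps under
scratch/figures/.  Prints the summary statistic the difference maps are
read for: interhemispheric cells should be control-dominant (positive).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from wbsync import AnalysisConfig
from wbsync.pipeline import cohort_results, subject_pair_table
from wbsync.recordings import CANONICAL_CHANNELS, read_manifest, \
    read_recording, write_matrix
from wbsync.spatial import render_matrix
from wbsync.synthetic import HOMOLOGOUS_PAIRS

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "demo"
FIGURES = ROOT / "scratch" / "figures"


def main() -> None:
    manifest = read_manifest(ROOT / "scratch" / "demo_cohort" / "manifest.csv")
    config = AnalysisConfig()
    frames = []
    for row in manifest.itertuples():
        rec = read_recording(row.path, subject_id=row.subject_id)
        t = subject_pair_table(rec, config)
        t.insert(0, "subject_id", row.subject_id)
        t["ahi"] = row.ahi
        t["group"] = row.group
        frames.append(t)
        print(f"  analyzed {row.subject_id} (AHI {row.ahi:.2f})")
    cohort_table = pd.concat(frames, ignore_index=True)
    cohort_table.to_csv(RESULTS / "cohort_pair_table.csv", index=False)

    res = cohort_results(cohort_table, config)
    matdir = RESULTS / "matrices"
    matdir.mkdir(parents=True, exist_ok=True)
    FIGURES.mkdir(parents=True, exist_ok=True)
    for name, mats in (("control", res.control_matrices),
                       ("main", res.main_matrices),
                       ("difference", res.difference_matrices)):
        for band, m in mats.items():
            write_matrix(m, matdir / f"{name}_{band}.csv")
            render_matrix(m, FIGURES / f"{name}_{band}.png")

    idx = {ch: k for k, ch in enumerate(CANONICAL_CHANNELS)}
    print("\ncontrol-minus-main difference, homologous vs background cells:")
    for band, d in res.difference_matrices.items():
        homo = np.mean([d.values[idx[a], idx[b]] for a, b in HOMOLOGOUS_PAIRS])
        mask = ~np.eye(19, dtype=bool)
        background = (np.nansum(np.where(mask, d.values, 0.0))
                      - sum(2 * d.values[idx[a], idx[b]]
                            for a, b in HOMOLOGOUS_PAIRS)) / (mask.sum() - 16)
        print(f"  {band:>6}: homologous {homo:+.3f}   background {background:+.3f}")


if __name__ == "__main__":
    main()
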