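#!/usr/bin/env python
"""Embryo morphometry over the simulated cohort.

Reads the stacks written by 01_simulate_cohort.py, measures L/W, d/D and the
gastrulation call per embryo, and compares the calls with the imposed truth.
Writes results/morphometry.csv.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd

from gastrulaquant.io import read_stack
from gastrulaquant.pipeline import PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"


def main() -> None:
    stacks = sorted(COHORT.glob("*.tif"))
    if not stacks:
        sys.exit("no cohort found; run analysis/01_simulate_cohort.py first")
    inputs = [(p.stem, p.stem.rsplit("_", 1)[0], read_stack(p)) for p in stacks]
    report = run_pipeline(inputs, PipelineConfig())
    df = report.morphometry
    df.to_csv(ROOT / "results" / "morphometry.csv", index=False)

    truth = pd.read_csv(ROOT / "results" / "cohort_truth.csv")
    merged = df.merge(truth, on="embryo_id")
    err = (merged.d_over_D - merged.true_d_over_D).abs()
    print(f"measured {len(df)} embryos; max |d/D error| = {err.max():.3f}")
    print(merged.groupby("condition_x")[["ratio", "d_over_D", "gastrulating"]]
          .mean().round(3))
    for t in report.tests:
        print(f"{t['conditions']}: Fisher p = {t['fisher_p']:.2e}, "
              f"Mann-Whitney p = {t['mannwhitney_p']:.2e}")


if __name__ == "__main__":
    main()
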