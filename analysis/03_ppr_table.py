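#!/usr/bin/env python
"""Parity progression ratios from open and closed birth intervals.

Two runs:

1. The published PPR grid is summarised the way the original analysis
   summarised it (median over the six truncation windows per transition) —
   the third-to-fourth median, 0.349, is the one value internally
   consistent with its own printed row.
2. The estimator itself runs on a survey-like synthetic cohort (interviews
   uniform over marriage durations, so order-i births form the stationary
   flow the renewal argument assumes).  On the post-reproductive cohort of
   script 01 every open interval exceeds the truncation window and the
   estimator has no data — the same would be true of the original survey.

Writes results/ppr_published_medians.csv and results/ppr_table.csv.
"""

from pathlib import Path

import pandas as pd

from birthspacing import published
from birthspacing._rounding import round_half_up
from birthspacing.ppr import median_over_grid, ppr_table
from birthspacing.simulate import SimulationConfig, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results"
TRANSITIONS = ["marriage_to_1st", "1st_to_2nd", "2nd_to_3rd", "3rd_to_4th"]


def main() -> None:
    OUT.mkdir(exist_ok=True)

    medians = {
        name: round_half_up(median_over_grid(published.ppr_grid_column(i)), 3)
        for i, name in enumerate(TRANSITIONS)
    }
    pd.Series(medians, name="median_ppr").to_csv(OUT / "ppr_published_medians.csv")
    print("medians of the published PPR grid:", medians)
    print("(3rd_to_4th = 0.349 is the internally consistent published value)\n")

    cfg = SimulationConfig(
        n_women=2000,
        seed=20150812,
        interview_window=(0.02, 420.0),
    )
    table = ppr_table(simulate_cohort(cfg))
    table.to_frame().to_csv(OUT / "ppr_table.csv")
    print("estimator on a survey-like synthetic cohort "
          "(generating probabilities 0.95/0.84/0.56/0.35):")
    print(table.to_frame())
    print("\nnote the large cell-level noise: the estimator amplifies "
          "sampling error in p_i(0,C1) roughly 15-40x at these gap lengths")


if __name__ == "__main__":
    main()
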