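#!/usr/bin/env python
"""Descriptive demography of the cohort, next to the published aggregates.

Two kinds of numbers appear below: percentages recomputed exactly from the
published counts (the only raw inputs that survive from the original
survey), and the same summaries computed on the synthetic cohort, which
should land near — not on — the published values.

Writes results/descriptives/.
"""

from pathlib import Path

from birthspacing import published
from birthspacing._rounding import round_half_up
from birthspacing.data_model import read_cohort
from birthspacing.descriptives import (
    median_birth_interval,
    parity_distribution,
    sex_ratio,
)
from birthspacing.pipeline import _write_descriptives

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    cohort_path = OUT / "cohort_812.csv"
    if not cohort_path.exists():
        from birthspacing.simulate import make_fixture

        OUT.mkdir(exist_ok=True)
        make_fixture("paper_like_812", cohort_path)
    records = read_cohort(cohort_path)
    _write_descriptives(records, OUT)
    print(f"reports in {OUT / 'descriptives'}\n")

    n = published.N_WOMEN
    print("share of women reaching each birth order (published counts):")
    for k, count in published.WOMEN_WITH_AT_LEAST.items():
        print(f"  order {k}: {count}/{n} = {round_half_up(100 * count / n)}%")
    infertile = n - published.WOMEN_WITH_AT_LEAST[1]
    print(f"  first infertility rate: {round_half_up(100 * infertile / n)}%\n")

    dist = parity_distribution(records)
    print("synthetic cohort parity distribution:")
    print(dist, "\n")

    print("median birth intervals, years (published: 4.53 / 4.65 / 5.27):")
    for s in (2, 3, 4):
        print(f"  birth {s}: {round_half_up(median_birth_interval(records, s))}")
    print(f"\nsex ratio at first birth (published: 104): "
          f"{round(sex_ratio(records, 1))}")


if __name__ == "__main__":
    main()
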