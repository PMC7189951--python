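"""Descriptive demography of a cohort.

Delivery-wise frequency tables, the parity distribution (share of women who
ever reached each birth order, and the first-infertility rate), median birth
intervals in years, and the sex ratio at each birth order.  Percentages are
rounded half-up to two decimals and the sex ratio to an integer, the
conventions of published fertility tables; medians use the plain
observed-events definition with no censoring adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._rounding import round_half_up
from .data_model import CATEGORICAL_LEVELS, WomanRecord

__all__ = [
    "DescriptivesError",
    "parity_distribution",
    "median_birth_interval",
    "sex_ratio",
    "frequency_table",
]


class DescriptivesError(ValueError):
    """Raised when a descriptive quantity is undefined on the given cohort."""


def parity_distribution(
    records: Sequence[WomanRecord], max_order: int = 4
) -> pd.DataFrame:
    """Counts and percentages of women with at least k children, k = 1..max_order,
    plus the first-infertility rate (share of parity-0 women).

    The percentage base is the whole cohort.  Returns a frame indexed by
    ``">=1" .. ">=k"`` and ``"infertile"`` with columns ``n`` and ``pct``.
    """
    records = list(records)
    n = len(records)
    if n == 0:
        raise DescriptivesError("empty cohort")
    parities = np.array([r.parity for r in records])
    rows = {}
    for k in range(1, max_order + 1):
        count = int((parities >= k).sum())
        rows[f">={k}"] = {"n": count, "pct": round_half_up(100.0 * count / n)}
    infertile = int((parities == 0).sum())
    rows["infertile"] = {"n": infertile, "pct": round_half_up(100.0 * infertile / n)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "parity"
    return out


def median_birth_interval(records: Iterable[WomanRecord], stratum: int) -> float:
    """Median gap time to the ``stratum``-th delivery, in years.

    Uses women who reached that birth (observed events only); the gap opens
    at the previous delivery, or marriage for stratum 1.  Even counts take
    the mean of the central pair.
    """
    if stratum < 1:
        raise ValueError("stratum must be >= 1")
    gaps = [
        r.birth_times[stratum - 1] - (r.birth_times[stratum - 2] if stratum > 1 else 0.0)
        for r in records
        if r.parity >= stratum
    ]
    if not gaps:
        raise DescriptivesError(f"no observed births of order {stratum}")
    return float(np.median(gaps)) / 12.0


def sex_ratio(records: Iterable[WomanRecord], birth_order: int = 1) -> float:
    """Sex ratio (100 x males / females) at a birth order; report as integer.

    Returns the unrounded ratio; raises when no birth of that order has a
    recorded female (the ratio is undefined, reported as missing upstream).
    """
    if birth_order < 1:
        raise ValueError("birth_order must be >= 1")
    males = females = 0
    for r in records:
        if r.parity >= birth_order:
            if r.child_sexes[birth_order - 1] == "male":
                males += 1
            else:
                females += 1
    if females == 0:
        raise DescriptivesError(f"no female births of order {birth_order}")
    return 100.0 * males / females


def frequency_table(
    records: Sequence[WomanRecord],
    covariate: str,
    max_delivery: int = 4,
) -> pd.DataFrame:
    """Delivery-wise frequency distribution of one categorical covariate.

    For delivery s the denominator is the number of women with parity >= s
    (the women contributing that delivery).  Returns a frame indexed by
    level with ``n`` and ``pct`` columns per delivery; within one delivery
    the counts sum to its denominator.
    """
    if covariate not in CATEGORICAL_LEVELS:
        raise KeyError(f"unknown covariate {covariate!r}")
    records = list(records)
    levels = CATEGORICAL_LEVELS[covariate]
    data: dict[str, list] = {}
    for s in range(1, max_delivery + 1):
        members = [r for r in records if r.parity >= s]
        denom = len(members)
        counts = {lvl: 0 for lvl in levels}
        for r in members:
            counts[getattr(r.covariates, covariate)] += 1
        data[f"delivery{s}_n"] = [counts[lvl] for lvl in levels]
        data[f"delivery{s}_pct"] = [
            round_half_up(100.0 * counts[lvl] / denom) if denom else np.nan
            for lvl in levels
        ]
    out = pd.DataFrame(data, index=pd.Index(levels, name=covariate))
    return out
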