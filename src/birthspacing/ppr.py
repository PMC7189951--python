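"""Parity progression ratios from open and closed birth intervals.

The parity progression ratio a_i is the probability that a woman with i
children goes on to have an (i+1)-th.  In a cross-sectional survey it can be
estimated without full event-history follow-up from two interval summaries:

* the truncated mean closed interval
  ``E_C(T*) = integral_0^C [1 - F_i(t)] dt``,
  where F_i is the distribution of closed intervals at transition i
  (empirically, ``mean(min(T_j, C))``), and
* ``p_i(0, C1)``: among women currently at parity i whose open interval lies
  within the window C, the proportion whose open interval is at most C1.

The estimator is::

    a_i = (C1 - p * C) / (p * (E_C - C))

It rests on a renewal argument: if i-th order births arrive uniformly over
the C months before the survey, a woman whose i-th birth was v months ago is
still at parity i with probability (1 - a) + a * S(v), so the expected
occupancy of the window is a * E_C + (1 - a) * C and
``p ~= C1 / (a * E_C + (1 - a) * C)`` for C1 small.  Solving for a gives the
formula above, which hits the two analytic limits exactly: p = C1/C means no
one progresses (a = 0), p = C1/E_C means everyone does (a = 1).

All arithmetic in :func:`ppr_point_estimate` is generic, so exact rational
inputs (``fractions.Fraction``) propagate exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import WomanRecord

__all__ = [
    "EstimationError",
    "IntervalData",
    "PPREstimate",
    "PPRTable",
    "extract_interval_data",
    "truncated_mean_survival",
    "ppr_point_estimate",
    "ppr_table",
    "DEFAULT_C_GRID",
    "DEFAULT_C1",
]

DEFAULT_C1 = 12.0
DEFAULT_C_GRID = (60.0, 72.0, 84.0, 96.0, 108.0, 120.0)


class EstimationError(ValueError):
    """Raised when a PPR cell cannot be estimated from the data at hand."""


@dataclass(frozen=True)
class IntervalData:
    """Interval summaries for one parity transition at one truncation C.

    ``parity_transition`` i counts from 0 (marriage -> first child); the
    opening event of transition i is the i-th birth, or marriage when i = 0.
    """

    parity_transition: int
    closed_intervals: tuple[float, ...]
    open_intervals: tuple[float, ...]
    c1: float
    c: float
    p: float | None  # p_i(0, C1); None when undefined (no open intervals in window)
    n_open_in_window: int

    def __post_init__(self) -> None:
        if not self.c1 < self.c:
            raise EstimationError("C1 must be smaller than C")


@dataclass(frozen=True)
class PPREstimate:
    """Point estimate of one PPR cell: raw value, [0,1]-clamped value, flag."""

    raw: float
    value: float
    in_range: bool


def extract_interval_data(
    records: Iterable[WomanRecord],
    i: int,
    c1: float = DEFAULT_C1,
    c: float = DEFAULT_C_GRID[0],
    denominator: str = "window",
) -> IntervalData:
    """Collect open/closed intervals for parity transition ``i``.

    Closed intervals are t_(i+1) - t_i over women with parity >= i+1 (t_0 = 0
    at marriage); open intervals are interview - t_i over women at parity
    exactly i.  ``p`` is the proportion of open intervals <= C1.

    ``denominator`` selects the base of that proportion: ``"window"`` (the
    default) uses women at parity i whose open interval is <= C — the set the
    renewal argument behind the estimator refers to; ``"all"`` uses every
    woman currently at parity i regardless of how long ago her i-th birth
    was, which only coincides with the former when the survey catches women
    mid-reproduction.
    """
    if i < 0:
        raise ValueError("parity transition must be >= 0")
    if not c1 < c:
        raise ValueError("C1 must be smaller than C")
    if denominator not in ("window", "all"):
        raise ValueError("denominator must be 'window' or 'all'")
    closed: list[float] = []
    open_: list[float] = []
    any_at_parity = False
    for rec in records:
        opening = 0.0 if i == 0 else (rec.birth_times[i - 1] if rec.parity >= i else None)
        if opening is None:
            continue
        if rec.parity >= i + 1:
            closed.append(rec.birth_times[i] - opening)
        elif rec.parity == i:
            any_at_parity = True
            open_.append(rec.interview_time - opening)
    if not any_at_parity and not closed:
        raise EstimationError(f"no women reached parity {i}")
    n_window = sum(1 for v in open_ if v <= c)
    base = n_window if denominator == "window" else len(open_)
    if base == 0:
        p = None
    else:
        p = sum(1 for v in open_ if v <= c1) / base
    return IntervalData(
        parity_transition=i,
        closed_intervals=tuple(closed),
        open_intervals=tuple(open_),
        c1=c1,
        c=c,
        p=p,
        n_open_in_window=n_window,
    )


def truncated_mean_survival(closed_intervals: Sequence[float], c: float):
    """Mean closed interval truncated at C months.

    Equals the integral of the empirical survival function of the intervals
    from 0 to C, i.e. ``mean(min(T_j, C))``; nondecreasing in C and bounded
    by both C and the untruncated mean.
    """
    if len(closed_intervals) == 0:
        raise EstimationError("no closed intervals to integrate")
    if not c > 0:
        raise ValueError("C must be positive")
    total = sum(t if t < c else c for t in closed_intervals)
    return total / len(closed_intervals)


def ppr_point_estimate(p, e_c, c1, c) -> PPREstimate:
    """Point estimate a = (C1 - p*C) / (p * (E_C - C)).

    ``p`` must be in (0, 1]; ``E_C`` in (0, C].  Raises
    :class:`EstimationError` when the cell is undefined (p = 0, or E_C = C
    with a nonzero numerator).  Arithmetic is generic: Fraction inputs give
    exact rational results, floats give floats.
    """
    if not c1 < c:
        raise ValueError("C1 must be smaller than C")
    if p is None or p == 0:
        raise EstimationError("p = 0: no open intervals within C1; cell undefined")
    if not 0 < p <= 1:
        raise EstimationError(f"p must be in (0, 1], got {p}")
    if not 0 < e_c <= c:
        raise EstimationError(f"E_C must be in (0, C], got {e_c}")
    numerator = c1 - p * c
    denominator = p * (e_c - c)
    if denominator == 0:
        if numerator == 0:
            raw = numerator * 0  # 0 of the operand type
        else:
            raise EstimationError("E_C = C: estimator undefined")
    else:
        raw = numerator / denominator
    in_range = 0 <= raw <= 1
    value = min(max(raw, raw * 0), raw * 0 + 1)
    return PPREstimate(raw=raw, value=value, in_range=in_range)


@dataclass(frozen=True)
class PPRTable:
    """PPR estimates on a (parity transition) x (truncation C) grid.

    ``grid`` holds the clamped estimates, ``raw`` the unclamped ones,
    ``in_range`` flags cells whose raw estimate already lay in [0, 1];
    missing cells are NaN (raw) / False.  ``medians`` is the per-transition
    median over the C grid (even count: mean of the central pair), NaN when
    any cell of the row is missing.
    """

    grid: pd.DataFrame
    raw: pd.DataFrame
    in_range: pd.DataFrame
    medians: pd.Series

    def to_frame(self) -> pd.DataFrame:
        """Reporting layout: one row per C plus a medians row, 3 decimals."""
        out = self.grid.T.copy()
        out.loc["median"] = self.medians
        return out.round(3)


def median_over_grid(values: Sequence[float]) -> float:
    """Median over the C-grid cells of one transition (even count: mean of
    the two central values); NaN if any cell is missing."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or np.isnan(arr).any():
        return float("nan")
    return float(np.median(arr))


def ppr_table(
    records: Sequence[WomanRecord],
    transitions: Sequence[int] = (0, 1, 2, 3),
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    c1: float = DEFAULT_C1,
    denominator: str = "window",
) -> PPRTable:
    """Fill the transitions x C grid and per-transition medians.

    Cells where the estimator is undefined (no women at the parity, p = 0,
    or E_C = C) are reported missing (NaN), never as 0.
    """
    records = list(records)
    index = pd.Index(list(transitions), name="parity_transition")
    columns = pd.Index([float(c) for c in c_grid], name="C")
    raw = pd.DataFrame(np.nan, index=index, columns=columns)
    clamped = pd.DataFrame(np.nan, index=index, columns=columns)
    ok = pd.DataFrame(False, index=index, columns=columns)
    for i in transitions:
        for c in columns:
            try:
                data = extract_interval_data(records, i, c1=c1, c=c, denominator=denominator)
                e_c = truncated_mean_survival(data.closed_intervals, c)
                est = ppr_point_estimate(data.p, e_c, c1, c)
            except EstimationError:
                continue
            raw.loc[i, c] = est.raw
            clamped.loc[i, c] = est.value
            ok.loc[i, c] = est.in_range
    medians = pd.Series(
        {i: median_over_grid(clamped.loc[i].to_numpy()) for i in transitions},
        name="median_ppr",
    )
    medians.index.name = "parity_transition"
    return PPRTable(grid=clamped, raw=raw, in_range=ok, medians=medians)
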