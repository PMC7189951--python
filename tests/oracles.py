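"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (literal
risk-set enumeration, direct numerical integration) so they share no code
path with the implementation they check.
"""

from __future__ import annotations

import math

import numpy as np

from birthspacing.data_model import CovariateSet, GapRecord


def brute_force_partial_loglik(beta, gaps, stratum, ties="breslow", variables=None):
    """Literal product-over-events enumeration of the stratified partial
    likelihood: for each event, sum exp(b'x) over every row of the stratum
    whose gap time is at least the event's gap time."""
    rows = [g for g in gaps if g.stratum == stratum]
    beta = np.asarray(beta, dtype=float)

    # encoded covariate vectors in the same order as the implementation
    from birthspacing.data_model import encode_covariates

    xs = {
        id(g): np.array(list(encode_covariates(g.covariates, variables).values()))
        for g in rows
    }
    ll = 0.0
    if ties == "breslow":
        for g in rows:
            if not g.event:
                continue
            num = float(np.dot(beta, xs[id(g)]))
            denom = sum(
                math.exp(float(np.dot(beta, xs[id(l)])))
                for l in rows
                if l.gap_time >= g.gap_time
            )
            ll += num - math.log(denom)
    else:  # efron
        times = sorted({g.gap_time for g in rows if g.event})
        for u in times:
            tied = [g for g in rows if g.event and g.gap_time == u]
            m = len(tied)
            risk = [g for g in rows if g.gap_time >= u]
            s_all = sum(math.exp(float(np.dot(beta, xs[id(l)]))) for l in risk)
            s_tied = sum(math.exp(float(np.dot(beta, xs[id(l)]))) for l in tied)
            for g in tied:
                ll += float(np.dot(beta, xs[id(g)]))
            for k in range(m):
                ll -= math.log(s_all - (k / m) * s_tied)
    return ll


def random_tiny_stratum(rng, max_subjects=8):
    """A random one-stratum cohort of <= max_subjects gap rows with at least
    one event, mixed continuous/binary covariates, occasional ties."""
    n = int(rng.integers(1, max_subjects + 1))
    rows = []
    any_event = False
    for i in range(n):
        cov = CovariateSet(
            woman_age_at_marriage=float(rng.integers(14, 35)),
            woman_education=str(
                rng.choice(["illiterate/primary", "secondary", "high school", "academic"])
            ),
            woman_employment=str(rng.choice(["employed", "unemployed"])),
            husband_age=float(rng.integers(18, 50)),
            husband_education="secondary",
            husband_employment="employed",
            stillbirth=str(rng.choice(["yes", "no"])),
            age_first_pregnancy_band=str(rng.choice(["<=18", ">18"])),
            income_band=str(rng.choice(["<=135", "135-270", ">=270"])),
        )
        # integer gap times force occasional ties
        event = int(rng.random() < 0.7)
        any_event = any_event or event
        rows.append(
            GapRecord(
                woman_id=f"r{i}",
                stratum=1,
                gap_time=float(rng.integers(1, 8)),
                event=event,
                covariates=cov,
            )
        )
    if not any_event:
        rows[0] = GapRecord(
            woman_id="r0", stratum=1, gap_time=rows[0].gap_time, event=1,
            covariates=rows[0].covariates,
        )
    return rows


def empirical_survival_integral(intervals, c, n_grid=200001):
    """Numerical integration of the empirical survival step function of the
    intervals from 0 to c (independent route to the truncated mean)."""
    intervals = np.asarray(intervals, dtype=float)
    ts = np.linspace(0.0, c, n_grid)
    surv = (intervals[None, :] > ts[:, None]).mean(axis=1)
    return float(np.trapezoid(surv, ts))
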