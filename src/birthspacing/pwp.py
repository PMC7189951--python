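"""Prentice-Williams-Peterson gap-time (PWP-GT) model.

The model stratifies recurrent deliveries by birth order: a woman is at risk
for her s-th delivery only after her (s-1)-th, the clock resets to zero at
each delivery, and each stratum s has its own baseline hazard,

    h(u | s, x) = h_0s(u) * exp(b_s' x),

with u the gap time since the previous delivery.  Coefficients are estimated
by maximizing the stratified Cox partial likelihood over the ordered gap
times within each stratum,

    L(b) = prod_s prod_{events i in s} exp(b_s' x_i) / sum_{l in R(u_i, s)} exp(b_s' x_l),

where the risk set R(u, s) holds the stratum-s rows with gap time >= u.
Ties are handled by the Breslow (default) or Efron approximation.  The score
and observed information are analytic; fitting is Newton-Raphson with
step-halving.  Standard errors come from the inverse observed information
and Wald p-values from the normal approximation, matching standard
stratified proportional-hazards software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    CATEGORICAL_LEVELS,
    CONTINUOUS_COVARIATES,
    GapRecord,
    encode_covariates,
    encoded_covariate_names,
)

__all__ = [
    "PWPError",
    "StratumFit",
    "PWPFit",
    "partial_loglik",
    "fit_pwp_gt",
    "wald_table",
    "stratum_design",
]

#: Coefficient magnitude beyond which a monotone likelihood (separation) is
#: declared; on the log-hazard scale this is an astronomically large effect.
SEPARATION_BOUND = 15.0


class PWPError(ValueError):
    """Raised for undefined likelihoods or invalid fitting inputs."""


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def stratum_design(
    gaps: Sequence[GapRecord],
    stratum: int,
    variables: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Arrays (gap times, event indicators, design matrix, column names) for
    the rows of one stratum, dummy-encoded against the reference levels."""
    rows = [g for g in gaps if g.stratum == stratum]
    if not rows:
        raise PWPError(f"stratum {stratum} is empty")
    names = encoded_covariate_names(variables)
    times = np.array([g.gap_time for g in rows], dtype=float)
    events = np.array([g.event for g in rows], dtype=np.int64)
    X = np.array(
        [list(encode_covariates(g.covariates, variables).values()) for g in rows],
        dtype=float,
    )
    return times, events, X, names


def _cox_loglik_arrays(
    beta: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    X: np.ndarray,
    ties: str = "breslow",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, score and observed-information Hessian.

    Vectorized over the risk sets via suffix cumulative sums on the
    time-sorted rows; tie groups share one denominator (Breslow) or averaged
    denominators (Efron).
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    n, p = X.shape
    if events.sum() == 0:
        raise PWPError("no events: partial likelihood undefined")
    order = np.argsort(times, kind="stable")
    t = times[order]
    d = events[order].astype(bool)
    Xs = X[order]
    eta = Xs @ beta if p else np.zeros(n)
    shift = eta.max() if n else 0.0
    w = np.exp(eta - shift)
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]
    # suffix sums: risk set at time t[k] is rows k..n-1 of the sorted arrays
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1] if p else np.zeros((n, 0))
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1] if p else np.zeros((n, 0, 0))

    # first sorted index of each row's time = start of its risk set
    starts = np.searchsorted(t, t, side="left")

    ll = float(eta[d].sum())
    grad = Xs[d].sum(axis=0) if p else np.zeros(0)
    hess = np.zeros((p, p))

    if ties == "breslow":
        ev_starts = starts[d]
        s0 = S0[ev_starts]
        ll -= float(np.sum(np.log(s0) + shift))
        if p:
            m = S1[ev_starts] / s0[:, None]
            grad -= m.sum(axis=0)
            hess -= (
                S2[ev_starts] / s0[:, None, None]
                - m[:, :, None] * m[:, None, :]
            ).sum(axis=0)
    else:  # efron
        uniq, first = np.unique(t, return_index=True)
        for u, start in zip(uniq, first):
            in_group = (t == u) & d
            mseg = int(in_group.sum())
            if mseg == 0:
                continue
            s0d = w[in_group].sum()
            s1d = wx[in_group].sum(axis=0) if p else np.zeros(0)
            s2d = wxx[in_group].sum(axis=0) if p else np.zeros((0, 0))
            frac = np.arange(mseg) / mseg
            s0k = S0[start] - frac * s0d
            ll -= float(np.sum(np.log(s0k) + shift))
            if p:
                s1k = S1[start][None, :] - frac[:, None] * s1d[None, :]
                mk = s1k / s0k[:, None]
                grad -= mk.sum(axis=0)
                s2k = S2[start][None, :, :] - frac[:, None, None] * s2d[None, :, :]
                hess -= (
                    s2k / s0k[:, None, None] - mk[:, :, None] * mk[:, None, :]
                ).sum(axis=0)
    return ll, grad, hess


def partial_loglik(
    beta: Sequence[float],
    gaps: Sequence[GapRecord],
    stratum: int,
    ties: str = "breslow",
    variables: Sequence[str] | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Stratum-s log partial likelihood with analytic gradient and Hessian.

    ``gaps`` may hold several strata; only rows of ``stratum`` enter.  Raises
    :class:`PWPError` if the stratum is empty or has no events.
    """
    times, events, X, names = stratum_design(gaps, stratum, variables)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (X.shape[1],):
        raise ValueError(f"beta must have length {X.shape[1]} ({names})")
    return _cox_loglik_arrays(beta, times, events, X, ties)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _identifiable_columns(X: np.ndarray, events: np.ndarray) -> list[int]:
    """Indices of a full-rank, non-constant subset of design columns.

    Constant columns carry no partial-likelihood information; linearly
    dependent columns are dropped greedily via pivoted QR on the centered
    design.
    """
    n, p = X.shape
    keep = [j for j in range(p) if np.ptp(X[:, j]) > 0]
    if not keep:
        return []
    Xc = X[:, keep] - X[:, keep].mean(axis=0)
    from scipy.linalg import qr

    _, r, piv = qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(n, len(keep)) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    kept = sorted(piv[:rank])
    return [keep[j] for j in kept]


@dataclass(frozen=True)
class StratumFit:
    """Newton-Raphson fit of one stratum's partial likelihood."""

    stratum: int
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    iterations: int
    converged: bool
    separated: bool
    score_norm: float
    dropped: list[str] = field(default_factory=list)
    n_rows: int = 0
    n_events: int = 0

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "HR": self.hazard_ratios,
                "SE": self.se,
                "z": self.z,
                "p": self.p_values,
            },
            index=pd.Index(self.names, name="covariate"),
        )


@dataclass(frozen=True)
class PWPFit:
    """Per-stratum PWP-GT fits plus the encoding and tie method used."""

    strata: dict[int, StratumFit]
    ties: str
    variables: list[str]
    shared_coefficients: bool = False

    @property
    def converged(self) -> bool:
        return all(f.converged for f in self.strata.values())


def _newton(
    times: np.ndarray,
    events: np.ndarray,
    X: np.ndarray,
    ties: str,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, int, bool, bool, float]:
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik_arrays(beta, times, events, X, ties)
    it = 0
    converged = bool(p == 0 or np.max(np.abs(grad)) < tol)
    for it in range(1, max_iter + 1):
        if converged:
            break
        neg_h = -hess
        try:
            delta = np.linalg.solve(neg_h, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.solve(neg_h + 1e-8 * np.eye(p), grad)
        step = 1.0
        for _ in range(40):
            cand = beta + step * delta
            ll_new, grad_new, hess_new = _cox_loglik_arrays(cand, times, events, X, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(grad)) < tol:
            converged = True
    separated = bool(p and np.max(np.abs(beta)) > SEPARATION_BOUND)
    if separated:
        converged = False
    if p:
        try:
            cov = np.linalg.inv(-hess)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    else:
        se = np.zeros(0)
    score_norm = float(np.max(np.abs(grad))) if p else 0.0
    return beta, se, ll, it, converged, separated, score_norm


def fit_pwp_gt(
    gaps: Sequence[GapRecord],
    strata: Sequence[int] | None = None,
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 50,
    variables: Sequence[str] | None = None,
    shared_coefficients: bool = False,
) -> PWPFit:
    """Fit the PWP-GT model, one coefficient vector per stratum.

    Unidentifiable design columns (constant within the stratum, or linearly
    dependent) are dropped with their names recorded in ``dropped``; an
    all-dropped design yields the baseline-only log likelihood.  Monotone
    likelihoods (separation) are flagged, not raised.  With
    ``shared_coefficients=True`` a single coefficient vector is estimated by
    summing the stratum log likelihoods (reported under stratum key 0).
    """
    gaps = list(gaps)
    if strata is None:
        strata = sorted({g.stratum for g in gaps})
    designs = {}
    for s in strata:
        times, events, X, names = stratum_design(gaps, s, variables)
        if events.sum() == 0:
            raise PWPError(f"stratum {s} has no events")
        designs[s] = (times, events, X, names)

    if shared_coefficients:
        names = designs[strata[0]][3]
        keep_sets = [
            set(_identifiable_columns(X, ev)) for _, ev, X, _ in designs.values()
        ]
        keep = sorted(set.union(*keep_sets))
        kept_names = [names[j] for j in keep]
        dropped = [nm for j, nm in enumerate(names) if j not in keep]

        def pooled(beta):
            ll, grad, hess = 0.0, np.zeros(len(keep)), np.zeros((len(keep), len(keep)))
            for times, events, X, _ in designs.values():
                l, g, h = _cox_loglik_arrays(beta, times, events, X[:, keep], ties)
                ll += l
                grad += g
                hess += h
            return ll, grad, hess

        beta, se, ll, it, conv, sep, sn = _newton_generic(
            pooled, len(keep), tol, max_iter
        )
        fit = StratumFit(
            stratum=0,
            names=kept_names,
            beta=beta,
            se=se,
            loglik=ll,
            iterations=it,
            converged=conv,
            separated=sep,
            score_norm=sn,
            dropped=dropped,
            n_rows=sum(len(d[0]) for d in designs.values()),
            n_events=int(sum(d[1].sum() for d in designs.values())),
        )
        return PWPFit(
            strata={0: fit},
            ties=ties,
            variables=list(variables)
            if variables
            else list(CONTINUOUS_COVARIATES) + list(CATEGORICAL_LEVELS),
            shared_coefficients=True,
        )

    fits: dict[int, StratumFit] = {}
    for s in strata:
        times, events, X, names = designs[s]
        keep = _identifiable_columns(X, events)
        dropped = [nm for j, nm in enumerate(names) if j not in keep]
        kept_names = [names[j] for j in keep]
        beta, se, ll, it, conv, sep, sn = _newton(
            times, events, X[:, keep], ties, tol, max_iter
        )
        fits[s] = StratumFit(
            stratum=s,
            names=kept_names,
            beta=beta,
            se=se,
            loglik=ll,
            iterations=it,
            converged=conv,
            separated=sep,
            score_norm=sn,
            dropped=dropped,
            n_rows=len(times),
            n_events=int(events.sum()),
        )
    return PWPFit(
        strata=fits,
        ties=ties,
        variables=list(variables)
        if variables
        else list(CONTINUOUS_COVARIATES) + list(CATEGORICAL_LEVELS),
        shared_coefficients=False,
    )


def _newton_generic(fun, p, tol, max_iter):
    """Newton-Raphson with step-halving on an arbitrary (ll, grad, hess) map."""
    beta = np.zeros(p)
    ll, grad, hess = fun(beta)
    it = 0
    converged = bool(p == 0 or np.max(np.abs(grad)) < tol)
    for it in range(1, max_iter + 1):
        if converged:
            break
        try:
            delta = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.solve(-hess + 1e-8 * np.eye(p), grad)
        step = 1.0
        for _ in range(40):
            cand = beta + step * delta
            ll_new, grad_new, hess_new = fun(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(grad)) < tol:
            converged = True
    separated = bool(p and np.max(np.abs(beta)) > SEPARATION_BOUND)
    if separated:
        converged = False
    if p:
        try:
            se = np.sqrt(np.clip(np.diag(np.linalg.inv(-hess)), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    else:
        se = np.zeros(0)
    return beta, se, ll, it, converged, separated, (
        float(np.max(np.abs(grad))) if p else 0.0
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def wald_table(fit: PWPFit) -> pd.DataFrame:
    """Delivery-by-delivery report rows: variable, level, HR / SE / p.

    Reference levels appear with HR 1.00 and blank SE/p; continuous
    covariates appear as a single per-unit row.  Dropped (unidentifiable)
    columns are blank.  Values are unrounded; the reporting layer rounds.
    """
    rows: list[dict] = []
    strata = sorted(fit.strata)

    def add_row(variable: str, level: str, name: str | None, reference: bool):
        row: dict = {"variable": variable, "level": level}
        for s in strata:
            sf = fit.strata[s]
            prefix = f"stratum{s}_" if not fit.shared_coefficients else ""
            if reference:
                row[f"{prefix}HR"] = 1.0
                row[f"{prefix}SE"] = np.nan
                row[f"{prefix}p"] = np.nan
            elif name in sf.names:
                j = sf.names.index(name)
                row[f"{prefix}HR"] = float(sf.hazard_ratios[j])
                row[f"{prefix}SE"] = float(sf.se[j])
                row[f"{prefix}p"] = float(sf.p_values[j])
            else:
                row[f"{prefix}HR"] = np.nan
                row[f"{prefix}SE"] = np.nan
                row[f"{prefix}p"] = np.nan
        rows.append(row)

    for var in fit.variables:
        if var in CONTINUOUS_COVARIATES:
            add_row(var, "per year", var, reference=False)
        elif var in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[var]
            add_row(var, levels[0], None, reference=True)
            for lvl in levels[1:]:
                add_row(var, lvl, f"{var}[{lvl}]", reference=False)
        else:  # pre-encoded custom column
            add_row(var, "", var, reference=False)
    return pd.DataFrame(rows)
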