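# Methods

This package re-implements a birth-spacing analysis of a post-reproductive
cohort: 812 women aged 45+ from urban health-centre registries, each
contributing her full marriage-to-interview reproductive history.  The raw
woman-level records were never deposited, so the package couples the two
estimators to a synthetic-cohort generator and validates them by parameter
recovery; the only published numbers it reproduces exactly are the
arithmetic descriptives and one internally consistent summary of the
published PPR grid.

## Data model

A woman is `(interview_time, birth_times, child_sexes, covariates)` with all
times in months since marriage.  Covariates are baseline demographics
(ages continuous per year; education, employment, stillbirth history, age
band at first pregnancy, income band categorical) treated as time-fixed:
the survey recorded them once.  Dummy encoding uses the reference levels of
the published hazard-ratio table (illiterate/primary, employed, stillbirth
"yes", ≤18 years, ≤135 US$).

The counting-process expansion produces one row per (woman, birth order):
a woman with parity p gives min(p, S) event rows with gap times
u_s = t_s − t_{s−1} (t_0 = 0 at marriage) and, if p < S, one censored row
in stratum p+1 ending at interview.  The default analysis depth is S = 4
strata — the observed numbers of fifth and later births are too small to
support a stratum of their own.  Censoring happens at the interview; with
a post-reproductive cohort this is effectively the end of exposure.

## PWP gap-time model

Each stratum s has hazard `h_0s(u) exp(b_s' x)` on the gap time u.
Coefficients maximize the stratified Cox partial likelihood with Breslow
tie handling by default (Efron available); the two coincide on continuous
gap times.  Fitting is Newton–Raphson with step-halving, convergence at
score max-norm < 1e-8, at most 50 iterations.  Standard errors are the
inverse observed information; Wald p-values use the normal approximation,
with no multiple-testing correction.  Design columns constant within a
stratum, or linearly dependent (detected by pivoted QR on the centered
design), are dropped and recorded.  A coefficient exceeding 15 in absolute
value flags a monotone likelihood (separation); the fit is returned with
`separated=True` and `converged=False` rather than raising, because rare
covariate levels in the later (smaller) strata make this a routine outcome.
Stratum-specific coefficient vectors are the default, matching the
published per-delivery columns; a pooled shared-coefficient variant is an
option.  Correctness is cross-checked in the tests against literal
risk-set enumeration (to 1e-10) and against an independent stratified
proportional-hazards implementation (to 1e-6).

## Parity progression ratios

The PPR a_i is estimated from interval summaries alone:

    a_i = (C1 − p·C) / (p · (E_C − C)),

with C1 = 12 months, C on the grid {60, 72, 84, 96, 108, 120} months,
E_C the mean closed interval truncated at C (empirically
`mean(min(T_j, C))`), and p the proportion of open intervals ≤ C1 among
women at parity i whose open interval lies within C.  The formula follows
from a renewal argument: if order-i births arrive uniformly over the C
months before interview, the window occupancy of parity i is
a·E_C + (1−a)·C, and p ≈ C1 / occupancy for small C1; solving for a gives
the expression above, which returns exactly 0 when p = C1/C (nobody
progresses) and exactly 1 when p = C1/E_C (everybody does).  The
window-restricted denominator is what that argument requires; an
"all women at parity i" variant is provided but is meaningful only when
interviews catch women mid-reproduction.  Raw estimates outside [0, 1]
(routine under sampling noise) are clamped and flagged, never dropped;
undefined cells (no women at the parity, p = 0, E_C = C) are reported
missing, never as 0.  Per-transition summaries are medians over the C grid
(even count: mean of the central pair), and reported values are rounded
half-up to 3 decimals only at the reporting layer.

F̂_i uses fully observed closed intervals only, with no censoring
correction — the analysis this mirrors applied none, and in a
post-reproductive cohort almost every closed interval is observed.

**Conditioning.**  The estimator amplifies sampling error in p by the
factor C1/(p²(C−E_C)), which is 15–40 under this cohort's gap laws
(medians 54–63 months leave C−E_C small).  With survey-scale samples only
a few dozen women fall in the C1 numerator, so single cells carry standard
errors of 0.3–0.5, and even the median-of-grid summary retains noise of
order 0.1 together with a small downward bias (longer closed intervals are
less likely to be fully observed, deflating E_C).  The recovery analyses
report this honestly: early transitions recover well, the later ones only
within the estimator's intrinsic noise.  Validation therefore also
includes an idealized-regime check (p supplied by the renewal identity,
iid closed intervals) where the formula recovers the generating
probability to ±0.05.

## Synthetic cohorts

The generator mirrors the gap-time hazard model with a per-parity cure
fraction.  Defaults are the study conditions: n = 812; progression
probabilities (0.95, 0.84, 0.56, 0.35); log-normal gap laws with medians
(54, 54, 56, 63) months and log-sd 0.45 (≈90 % of intervals within a
factor ~2 of the median); covariate marginals from the published
first-delivery frequency table, drawn independently (the joint
distribution was never published); income bands, absent from that table,
default to (0.40, 0.45, 0.15); sex draws independent with male probability
104/204; interviews uniform over 260–420 months of marriage, emulating the
post-reproductive design.  Covariate effects enter as proportional-hazards
tilts via inverse-transform sampling (H_0(T) = E·e^{−η}, E ~ Exp(1)), so
the PWP-GT fitter targets exactly the generating coefficients.  The cure
fraction is independent of covariates by default — covariates move timing,
not whether — keeping PPR recovery targets clean; a logistic link on the
cure probability is deliberately out of scope.  All randomness flows from
one seed through a single generator; cohorts are bit-reproducible.

The generator omits mortality, migration, marriage dissolution, twins,
contraception dynamics and calendar-period effects.  Passing recovery
tests therefore demonstrates estimator correctness under the assumed
model, not robustness of the original survey's estimates to real-world
violations of it.

Two interview regimes are used deliberately: the post-reproductive default
(260–420 months) for descriptives and the PWP model, and a survey-like
regime (uniform over 0–420 months) for PPR recovery, because the renewal
assumption — order-i births spread uniformly over the C months before
interview — holds only when interviews catch women mid-reproduction.  On a
post-reproductive cohort every open interval exceeds C and the interval
estimator has no data; this is a structural property of the method, not an
implementation limit.

**Recovery study designs.**  PPR recovery uses 20 replicates of n = 2000
and summarises each transition by the median across replicates of the
per-replicate median-of-grid.  PWP recovery uses three cohorts of
n = 1000 generated with progression probability 1 in the tested stratum:
with a cure fraction present the stratum hazard is a mixture and no longer
proportional, so the Cox estimand is attenuated below the generating
coefficient — "recovering the generating log-HR" is well defined only when
the cohort is generated from the proportional-hazards model itself.  The
type-I-error arm keeps the full defaults (under the null the cure fraction
is independent of the covariate) with 200 replicates.  These sizes keep
the full validation suite to a few minutes on one CPU.

## Descriptives and reporting conventions

Parity distribution percentages use the whole cohort as base; the first
infertility rate is the parity-0 share.  Delivery-wise frequency tables
use women with parity ≥ s as the delivery-s denominator.  Median birth
intervals use observed events only, converted to years by 12 at reporting.
Sex ratio is 100·males/females at a birth order, reported as an integer.
Percentages are rounded half-up to 2 decimals.  Two published
inconsistencies are deliberately not reproduced: 671/812 rounds to 82.64
(the source prints 82.63, a truncation), and the published per-transition
PPR medians 0.955/0.838/0.557 do not equal the medians of their own
printed grid rows (0.956/0.850/0.577 here); only the consistent 0.349 is
treated as reproducible.

## Known limitations

* The PPR estimator is ill-conditioned at survey scale (see above); its
  cell values should be read through the medians and flags.
* No frailty, no robust (sandwich) variance, no baseline-hazard or
  survival-curve estimation, no survey-design weighting.
* Multi-marriage histories and same-time twins are outside the data model.
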