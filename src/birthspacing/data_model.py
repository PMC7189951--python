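"""Domain types and CSV I/O for woman-level reproductive histories.

The atomic observational unit is a :class:`WomanRecord`: one woman's ordered
birth times (months since marriage), the sexes of her children, the interview
time that right-censors her history, and a set of baseline demographic
covariates.  The counting-process expansion :func:`expand_to_strata` turns a
cohort of such records into the gap-time rows (:class:`GapRecord`) on which
the recurrent-event model operates: a woman enters stratum ``s`` (waiting for
her ``s``-th delivery) only after her ``(s-1)``-th, and the clock resets to
zero at every delivery.

Times are in months with origin at marriage; conversion to years (factor 12)
happens only at the reporting layer.  Covariates are treated as fixed per
woman: the surveys this models record baseline demographics only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CovariateSet",
    "WomanRecord",
    "GapRecord",
    "CohortValidationError",
    "CATEGORICAL_LEVELS",
    "CONTINUOUS_COVARIATES",
    "MAX_PARITY",
    "read_cohort",
    "write_cohort",
    "expand_to_strata",
    "encode_covariates",
    "encoded_covariate_names",
]

#: Maximum parity accepted on read; higher-order births are a validation error.
MAX_PARITY = 7

#: Levels of each categorical covariate, reference level first (the reference
#: is the level against which hazard ratios are reported).
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "woman_education": ("illiterate/primary", "secondary", "high school", "academic"),
    "woman_employment": ("employed", "unemployed"),
    "husband_education": ("illiterate/primary", "secondary", "high school", "academic"),
    "husband_employment": ("employed", "unemployed"),
    "stillbirth": ("yes", "no"),
    "age_first_pregnancy_band": ("<=18", ">18"),
    "income_band": ("<=135", "135-270", ">=270"),
}

#: Continuous covariates, entered per year.
CONTINUOUS_COVARIATES: tuple[str, ...] = ("woman_age_at_marriage", "husband_age")

SEXES = ("male", "female")

SCHEMA_VERSION = "1"


class CohortValidationError(ValueError):
    """Raised when a record or CSV row violates the cohort invariants."""


@dataclass(frozen=True)
class CovariateSet:
    """Baseline demographic covariates for one woman.

    Ages are in years; the categorical fields must take one of the levels in
    :data:`CATEGORICAL_LEVELS`.  Income bands are monthly household income in
    US$.
    """

    woman_age_at_marriage: float
    woman_education: str
    woman_employment: str
    husband_age: float
    husband_education: str
    husband_employment: str
    stillbirth: str
    age_first_pregnancy_band: str
    income_band: str

    def __post_init__(self) -> None:
        for name in CONTINUOUS_COVARIATES:
            value = getattr(self, name)
            if not value > 0:
                raise CohortValidationError(f"{name} must be positive, got {value!r}")
        for name, levels in CATEGORICAL_LEVELS.items():
            value = getattr(self, name)
            if value not in levels:
                raise CohortValidationError(
                    f"{name} must be one of {levels}, got {value!r}"
                )


@dataclass(frozen=True)
class WomanRecord:
    """One woman's reproductive history.

    ``birth_times`` are months since marriage, strictly increasing and within
    ``(0, interview_time]``; ``child_sexes`` matches it element-wise.  Parity
    is ``len(birth_times)`` and may not exceed :data:`MAX_PARITY`.
    """

    woman_id: str
    interview_time: float
    birth_times: tuple[float, ...]
    child_sexes: tuple[str, ...]
    covariates: CovariateSet

    def __post_init__(self) -> None:
        object.__setattr__(self, "birth_times", tuple(float(t) for t in self.birth_times))
        object.__setattr__(self, "child_sexes", tuple(self.child_sexes))
        if not self.interview_time > 0:
            raise CohortValidationError(
                f"woman {self.woman_id}: interview_time must be > 0"
            )
        if len(self.birth_times) != len(self.child_sexes):
            raise CohortValidationError(
                f"woman {self.woman_id}: child_sexes length "
                f"{len(self.child_sexes)} != birth_times length {len(self.birth_times)}"
            )
        if len(self.birth_times) > MAX_PARITY:
            raise CohortValidationError(
                f"woman {self.woman_id}: parity {len(self.birth_times)} exceeds "
                f"{MAX_PARITY}"
            )
        prev = 0.0
        for t in self.birth_times:
            if not t > prev:
                raise CohortValidationError(
                    f"woman {self.woman_id}: birth times must be strictly "
                    f"increasing and > 0, got {self.birth_times}"
                )
            prev = t
        if self.birth_times and self.birth_times[-1] > self.interview_time:
            raise CohortValidationError(
                f"woman {self.woman_id}: birth at {self.birth_times[-1]} after "
                f"interview at {self.interview_time}"
            )
        for sex in self.child_sexes:
            if sex not in SEXES:
                raise CohortValidationError(
                    f"woman {self.woman_id}: unknown child sex {sex!r}"
                )

    @property
    def parity(self) -> int:
        return len(self.birth_times)


@dataclass(frozen=True)
class GapRecord:
    """One (woman, stratum) gap-time row after counting-process expansion.

    ``stratum`` is the birth order being waited for (1 = first delivery);
    ``gap_time`` is months since the previous delivery (marriage for
    stratum 1); ``event`` is 1 if the birth was observed, 0 if the row is
    censored at interview.
    """

    woman_id: str
    stratum: int
    gap_time: float
    event: int
    covariates: CovariateSet

    def __post_init__(self) -> None:
        if self.stratum < 1:
            raise CohortValidationError("stratum must be >= 1")
        if self.gap_time < 0:
            raise CohortValidationError("gap_time must be >= 0")
        if self.event not in (0, 1):
            raise CohortValidationError("event must be 0 or 1")


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_HEADER = [
    "woman_id",
    "interview_time",
    "birth_times",
    "child_sexes",
    "woman_age_at_marriage",
    "woman_education",
    "woman_employment",
    "husband_age",
    "husband_education",
    "husband_employment",
    "stillbirth",
    "age_first_pregnancy_band",
    "income_band",
]


def write_cohort(records: Sequence[WomanRecord], path: str | Path) -> Path:
    """Write a cohort to CSV (UTF-8, comma-separated, header mandatory).

    Birth times and child sexes are semicolon-joined lists inside one cell;
    a parity-0 woman has empty cells there.  ``read_cohort`` inverts this
    exactly (field-for-field round trip).
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for rec in records:
            cov = rec.covariates
            writer.writerow(
                [
                    rec.woman_id,
                    repr(rec.interview_time),
                    ";".join(repr(t) for t in rec.birth_times),
                    ";".join(rec.child_sexes),
                    repr(cov.woman_age_at_marriage),
                    cov.woman_education,
                    cov.woman_employment,
                    repr(cov.husband_age),
                    cov.husband_education,
                    cov.husband_employment,
                    cov.stillbirth,
                    cov.age_first_pregnancy_band,
                    cov.income_band,
                ]
            )
    return path


def read_cohort(path: str | Path, schema_version: str = SCHEMA_VERSION) -> list[WomanRecord]:
    """Read and validate a cohort CSV written in the dialect above.

    Raises :class:`CohortValidationError` naming the offending row and field
    for any malformed row; an empty file with only a header yields ``[]``.
    """
    if schema_version != SCHEMA_VERSION:
        raise CohortValidationError(f"unknown schema version {schema_version!r}")
    path = Path(path)
    records: list[WomanRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortValidationError(f"{path}: empty file, header required")
        if header != _HEADER:
            raise CohortValidationError(
                f"{path}: header mismatch; expected {_HEADER}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_HEADER):
                raise CohortValidationError(
                    f"{path}:{lineno}: expected {len(_HEADER)} fields, got {len(row)}"
                )
            cells = dict(zip(_HEADER, row))
            try:
                covariates = CovariateSet(
                    woman_age_at_marriage=float(cells["woman_age_at_marriage"]),
                    woman_education=cells["woman_education"],
                    woman_employment=cells["woman_employment"],
                    husband_age=float(cells["husband_age"]),
                    husband_education=cells["husband_education"],
                    husband_employment=cells["husband_employment"],
                    stillbirth=cells["stillbirth"],
                    age_first_pregnancy_band=cells["age_first_pregnancy_band"],
                    income_band=cells["income_band"],
                )
                birth_times = tuple(
                    float(t) for t in cells["birth_times"].split(";") if t != ""
                )
                child_sexes = tuple(
                    s for s in cells["child_sexes"].split(";") if s != ""
                )
                record = WomanRecord(
                    woman_id=cells["woman_id"],
                    interview_time=float(cells["interview_time"]),
                    birth_times=birth_times,
                    child_sexes=child_sexes,
                    covariates=covariates,
                )
            except (ValueError, CohortValidationError) as exc:
                raise CohortValidationError(f"{path}:{lineno}: {exc}") from exc
            records.append(record)
    return records


# ---------------------------------------------------------------------------
# Counting-process expansion
# ---------------------------------------------------------------------------


def expand_to_strata(
    records: Iterable[WomanRecord], max_stratum: int = 4
) -> list[GapRecord]:
    """Expand woman records into conditional gap-time rows.

    A woman with parity ``p`` contributes ``min(p, max_stratum)`` event rows
    (gap = time since previous delivery, marriage for the first) and, if
    ``p < max_stratum``, exactly one censored row in stratum ``p + 1`` with
    gap equal to the open interval to interview.  This is the conditional
    risk-set structure of the gap-time recurrent-event model: no woman
    appears in stratum ``s`` without an event in every stratum below it.
    """
    if max_stratum < 1:
        raise ValueError("max_stratum must be >= 1")
    gaps: list[GapRecord] = []
    for rec in records:
        prev = 0.0
        for s, t in enumerate(rec.birth_times[:max_stratum], start=1):
            gaps.append(
                GapRecord(
                    woman_id=rec.woman_id,
                    stratum=s,
                    gap_time=t - prev,
                    event=1,
                    covariates=rec.covariates,
                )
            )
            prev = t
        if rec.parity < max_stratum:
            gaps.append(
                GapRecord(
                    woman_id=rec.woman_id,
                    stratum=rec.parity + 1,
                    gap_time=rec.interview_time - prev,
                    event=0,
                    covariates=rec.covariates,
                )
            )
    return gaps


# ---------------------------------------------------------------------------
# Covariate encoding
# ---------------------------------------------------------------------------


def encoded_covariate_names(
    variables: Sequence[str] | None = None,
) -> list[str]:
    """Names of the encoded design columns, in a stable order.

    Continuous covariates map to themselves; categoricals to one dummy per
    non-reference level, named ``variable[level]``.
    """
    if variables is None:
        variables = list(CONTINUOUS_COVARIATES) + list(CATEGORICAL_LEVELS)
    names: list[str] = []
    for var in variables:
        if var in CONTINUOUS_COVARIATES:
            names.append(var)
        elif var in CATEGORICAL_LEVELS:
            names.extend(f"{var}[{lvl}]" for lvl in CATEGORICAL_LEVELS[var][1:])
        else:
            raise KeyError(f"unknown covariate {var!r}")
    return names


def encode_covariates(
    cov: CovariateSet, variables: Sequence[str] | None = None
) -> dict[str, float]:
    """Dummy-encode one covariate set against the reference levels."""
    if variables is None:
        variables = list(CONTINUOUS_COVARIATES) + list(CATEGORICAL_LEVELS)
    encoded: dict[str, float] = {}
    for var in variables:
        if var in CONTINUOUS_COVARIATES:
            encoded[var] = float(getattr(cov, var))
        elif var in CATEGORICAL_LEVELS:
            value = getattr(cov, var)
            for lvl in CATEGORICAL_LEVELS[var][1:]:
                encoded[f"{var}[{lvl}]"] = 1.0 if value == lvl else 0.0
        else:
            raise KeyError(f"unknown covariate {var!r}")
    return encoded
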