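"""Participant records and cohort CSV input/output.

A record carries one participant's demographics, self-reported (and
optionally measured) anthropometrics, the psychosocial covariates used by
the correction models, and a sampling weight.  Heights and weights are held
internally in metric units (centimetres, kilograms) regardless of the unit
system the data arrived in; the source unit system is recorded so that
imperial model equations can be applied without ambiguity.

Covariates may be absent (``None``): the fitting and application code uses a
complete-case policy and raises :class:`~bmicorrect.errors.MissingDataError`
naming the field when a required covariate is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import math

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError
from .growth_reference import SEXES, WeightStatus

__all__ = [
    "AnthropometricRecord",
    "BODY_SIZE_LEVELS",
    "RACE_LEVELS",
    "PARENT_ED_LEVELS",
    "CM_PER_INCH",
    "KG_PER_POUND",
    "read_cohort_csv",
    "write_cohort_csv",
    "records_to_frame",
]

CM_PER_INCH = 2.54
KG_PER_POUND = 0.45359237

#: Body-size self-estimation, already collapsed to three levels (the five
#: response options "very/slightly underweight" and "very/slightly
#: overweight" are merged upstream).
BODY_SIZE_LEVELS = ("UW", "AboutRight", "OW")

RACE_LEVELS = ("White", "Hispanic", "Black", "Asian", "Other")

PARENT_ED_LEVELS = ("HS_or_less", "Some_college", "College_plus")


def _check_range(name, value, lo, hi):
    if value is not None and not (lo <= value <= hi):
        raise DomainError(f"{name} must be in [{lo}, {hi}], got {value}")


def _check_level(name, value, levels):
    if value is not None and value not in levels:
        raise DomainError(f"{name} must be one of {levels}, got {value!r}")


@dataclass
class AnthropometricRecord:
    """One participant.  Heights in cm, weights in kg (metric canonical)."""

    id: str
    sex: str
    age_months: float
    sr_height_cm: float
    sr_weight_kg: float
    measured_height_cm: Optional[float] = None
    measured_weight_kg: Optional[float] = None
    puberty: Optional[int] = None
    body_size_estimation: Optional[str] = None
    dieting: Optional[bool] = None
    cesd: Optional[float] = None
    self_rated_health: Optional[float] = None
    self_esteem: Optional[float] = None
    race_ethnicity: Optional[str] = None
    parent_education: Optional[str] = None
    sample_weight: float = 1.0
    #: Weight status of the self-reported BMI; derived lazily from a growth
    #: reference when needed by a model.
    sr_weight_status: Optional[WeightStatus] = None
    source_units: str = "metric"

    def __post_init__(self):
        if self.sex not in SEXES:
            raise DomainError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not (self.age_months > 0):
            raise DomainError(f"age_months must be positive, got {self.age_months}")
        for name in ("sr_height_cm", "sr_weight_kg"):
            v = getattr(self, name)
            if not (v > 0):
                raise DomainError(f"{name} must be positive, got {v}")
        for name in ("measured_height_cm", "measured_weight_kg"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise DomainError(f"{name} must be positive, got {v}")
        if not (self.sample_weight > 0):
            raise DomainError(f"sample_weight must be positive, got {self.sample_weight}")
        if self.puberty is not None and self.puberty not in (1, 2, 3, 4, 5):
            raise DomainError(f"puberty must be an integer 1-5, got {self.puberty}")
        _check_level("body_size_estimation", self.body_size_estimation, BODY_SIZE_LEVELS)
        _check_level("race_ethnicity", self.race_ethnicity, RACE_LEVELS)
        _check_level("parent_education", self.parent_education, PARENT_ED_LEVELS)
        _check_range("cesd", self.cesd, 0, 60)
        _check_range("self_rated_health", self.self_rated_health, 1, 5)
        _check_range("self_esteem", self.self_esteem, 1, 5)

    def with_sr_weight_status(self, status: WeightStatus) -> "AnthropometricRecord":
        return replace(self, sr_weight_status=status)


# ---------------------------------------------------------------------------
# Cohort CSV schema
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "id",
    "sex",
    "age_months",
    "sr_height",
    "sr_weight",
    "measured_height",
    "measured_weight",
    "puberty",
    "body_size_estimation",
    "dieting",
    "cesd",
    "self_rated_health",
    "self_esteem",
    "race_ethnicity",
    "parent_education",
    "sample_weight",
]


def _to_metric_height(v, units):
    return v * CM_PER_INCH if units == "imperial" else v


def _to_metric_weight(v, units):
    return v * KG_PER_POUND if units == "imperial" else v


def _from_metric_height(v, units):
    return v / CM_PER_INCH if units == "imperial" else v


def _from_metric_weight(v, units):
    return v / KG_PER_POUND if units == "imperial" else v


def _opt(v, cast=float):
    if v is None:
        return None
    if isinstance(v, float) and math.isnan(v):
        return None
    if isinstance(v, str) and v.strip() == "":
        return None
    return cast(v)


def read_cohort_csv(path, units: str = "metric") -> list[AnthropometricRecord]:
    """Load a cohort CSV, converting heights/weights to metric.

    ``units`` declares the unit system of the file's height/weight columns
    (``metric``: cm and kg; ``imperial``: inches and pounds).  Row-level
    validation failures are collected and reported together.
    """
    if units not in ("metric", "imperial"):
        raise SchemaError(f"units must be 'metric' or 'imperial', got {units!r}")
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns and c not in
               ("measured_height", "measured_weight")]
    if missing:
        raise SchemaError(f"cohort CSV missing required columns: {missing}")
    records = []
    failures = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            records.append(
                AnthropometricRecord(
                    id=str(row["id"]),
                    sex=str(row["sex"]).strip().lower(),
                    age_months=float(row["age_months"]),
                    sr_height_cm=_to_metric_height(float(row["sr_height"]), units),
                    sr_weight_kg=_to_metric_weight(float(row["sr_weight"]), units),
                    measured_height_cm=_opt(row.get("measured_height"),
                                            lambda v: _to_metric_height(float(v), units)),
                    measured_weight_kg=_opt(row.get("measured_weight"),
                                            lambda v: _to_metric_weight(float(v), units)),
                    puberty=_opt(row.get("puberty"), lambda v: int(float(v))),
                    body_size_estimation=_opt(row.get("body_size_estimation"), str),
                    dieting=_opt(row.get("dieting"), lambda v: bool(int(float(v)))),
                    cesd=_opt(row.get("cesd")),
                    self_rated_health=_opt(row.get("self_rated_health")),
                    self_esteem=_opt(row.get("self_esteem")),
                    race_ethnicity=_opt(row.get("race_ethnicity"), str),
                    parent_education=_opt(row.get("parent_education"), str),
                    sample_weight=float(row["sample_weight"]),
                    source_units=units,
                )
            )
        except (DomainError, ValueError, TypeError) as exc:
            failures.append((i + 2, str(exc)))  # +2: header + 1-based
    if failures:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in failures[:10])
        raise SchemaError(
            f"{len(failures)} invalid row(s) in {path}: {detail}"
        )
    return records


def records_to_frame(records, units: str = "metric") -> pd.DataFrame:
    """Cohort as a DataFrame in the requested unit system (CSV layout)."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "sex": r.sex,
                "age_months": r.age_months,
                "sr_height": _from_metric_height(r.sr_height_cm, units),
                "sr_weight": _from_metric_weight(r.sr_weight_kg, units),
                "measured_height": (
                    _from_metric_height(r.measured_height_cm, units)
                    if r.measured_height_cm is not None else np.nan
                ),
                "measured_weight": (
                    _from_metric_weight(r.measured_weight_kg, units)
                    if r.measured_weight_kg is not None else np.nan
                ),
                "puberty": r.puberty if r.puberty is not None else np.nan,
                "body_size_estimation": r.body_size_estimation or "",
                "dieting": int(r.dieting) if r.dieting is not None else np.nan,
                "cesd": r.cesd if r.cesd is not None else np.nan,
                "self_rated_health": (
                    r.self_rated_health if r.self_rated_health is not None else np.nan
                ),
                "self_esteem": r.self_esteem if r.self_esteem is not None else np.nan,
                "race_ethnicity": r.race_ethnicity or "",
                "parent_education": r.parent_education or "",
                "sample_weight": r.sample_weight,
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort_csv(records, path, units: str = "metric") -> None:
    records_to_frame(records, units).to_csv(path, index=False, float_format="%.6f")
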