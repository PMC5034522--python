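"""BMI computation and BMI-for-age weight-status classification.

Pediatric weight status is derived from sex- and age-specific growth
references via the LMS method: a reference table gives, for each sex and age
in months, the Box-Cox power ``L``, the median ``M`` and the coefficient of
variation ``S`` of BMI in the reference population.  A measured BMI ``x``
maps to a z-score

    z = ((x / M)**L - 1) / (L * S)      if L != 0
    z = ln(x / M) / S                   if L == 0

and the percentile is ``100 * Phi(z)``.  Categories follow the conventional
half-open percentile cutoffs for participants under 20 years of age
(underweight < 5th, healthy weight 5th to < 85th, overweight 85th to < 95th,
obesity >= 95th) and fixed adult BMI cutoffs (18.5 / 25 / 30, lower bound
inclusive) at 240 months and older.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, RangeError, SchemaError

__all__ = [
    "WeightStatus",
    "GrowthReferenceTable",
    "compute_bmi",
    "lms_zscore",
    "lms_inverse",
    "interpolate_lms",
    "percentile_from_z",
    "classify_weight_status",
    "ADULT_AGE_MONTHS",
    "ADULT_BMI_CUTOFFS",
    "PEDIATRIC_PERCENTILE_CUTOFFS",
]

SEXES = ("male", "female")

#: Age (months) at and above which adult BMI cutoffs replace percentiles.
ADULT_AGE_MONTHS = 240.0

#: Adult BMI cutoffs (kg/m^2), lower bound inclusive: UW < 18.5 <= HW < 25 <= OW < 30 <= OB.
ADULT_BMI_CUTOFFS = (18.5, 25.0, 30.0)

#: Pediatric percentile cutoffs, lower bound inclusive for the upper class.
PEDIATRIC_PERCENTILE_CUTOFFS = (5.0, 85.0, 95.0)

#: Conversion factor for BMI from pounds and inches.
IMPERIAL_BMI_FACTOR = 703.0


class WeightStatus(enum.IntEnum):
    """Ordered weight-status categories: UW < HW < OW < OB."""

    UW = 0
    HW = 1
    OW = 2
    OB = 3

    @classmethod
    def from_label(cls, label: str) -> "WeightStatus":
        try:
            return cls[str(label).strip()]
        except KeyError:
            raise DomainError(f"unknown weight status label: {label!r}") from None


#: Fixed display/order convention used by classification tables.
STATUS_ORDER = (WeightStatus.UW, WeightStatus.HW, WeightStatus.OW, WeightStatus.OB)


def compute_bmi(weight: float, height: float, unit_system: str = "metric") -> float:
    """Body mass index.

    Parameters
    ----------
    weight, height
        Metric: kilograms and metres.  Imperial: pounds and inches
        (the conventional 703 * lb / in^2 formula).
    """
    if not (weight > 0) or not (height > 0):
        raise DomainError(
            f"weight and height must be positive, got weight={weight}, height={height}"
        )
    if unit_system == "metric":
        return weight / height**2
    if unit_system == "imperial":
        return IMPERIAL_BMI_FACTOR * weight / height**2
    raise DomainError(f"unknown unit system: {unit_system!r}")


def lms_zscore(x: float, L: float, M: float, S: float) -> float:
    """LMS z-score of a measurement against reference parameters."""
    if not (x > 0) or not (M > 0) or not (S > 0):
        raise DomainError(f"x, M and S must be positive, got x={x}, M={M}, S={S}")
    if L == 0:
        return math.log(x / M) / S
    return ((x / M) ** L - 1.0) / (L * S)


def lms_inverse(z: float, L: float, M: float, S: float) -> float:
    """Measurement value at z-score ``z`` (inverse of :func:`lms_zscore`)."""
    if not (M > 0) or not (S > 0):
        raise DomainError(f"M and S must be positive, got M={M}, S={S}")
    if L == 0:
        return M * math.exp(S * z)
    base = 1.0 + L * S * z
    if base <= 0:
        raise DomainError(f"z={z} outside the support of the LMS distribution")
    return M * base ** (1.0 / L)


def percentile_from_z(z: float) -> float:
    """Percentile (0-100) corresponding to a standard-normal z-score."""
    if not math.isfinite(z):
        raise DomainError(f"z must be finite, got {z}")
    return 100.0 * float(stats.norm.cdf(z))


@dataclass(frozen=True)
class GrowthReferenceTable:
    """Sex- and age-indexed LMS reference for BMI-for-age.

    ``rows`` holds tuples ``(sex, age_months, L, M, S)``.  Within each sex
    the ages must be strictly increasing, with M > 0 and S > 0 throughout.
    Lookups outside the covered age interval raise :class:`RangeError`.
    """

    rows: tuple = field(repr=False)

    def __post_init__(self):
        by_sex: dict[str, list] = {}
        for row in self.rows:
            sex, age, L, M, S = row
            if sex not in SEXES:
                raise SchemaError(f"unknown sex {sex!r} in growth reference")
            if age < 24:
                raise SchemaError(f"growth reference ages must be >= 24 months, got {age}")
            if not (M > 0 and S > 0):
                raise SchemaError(f"M and S must be positive at (sex={sex}, age={age})")
            by_sex.setdefault(sex, []).append((float(age), float(L), float(M), float(S)))
        if not by_sex:
            raise SchemaError("growth reference table is empty")
        arrays = {}
        for sex, entries in by_sex.items():
            ages = np.array([e[0] for e in entries])
            if np.any(np.diff(ages) <= 0):
                raise SchemaError(f"ages must be strictly increasing within sex {sex!r}")
            arrays[sex] = tuple(
                np.array([e[i] for e in entries]) for i in range(4)
            )  # ages, L, M, S
        object.__setattr__(self, "_by_sex", arrays)

    # -- coverage -----------------------------------------------------------

    def age_range(self, sex: str) -> tuple[float, float]:
        ages = self._sex_arrays(sex)[0]
        return float(ages[0]), float(ages[-1])

    @property
    def min_age(self) -> float:
        return min(self.age_range(s)[0] for s in self._by_sex)

    @property
    def max_age(self) -> float:
        return max(self.age_range(s)[1] for s in self._by_sex)

    def _sex_arrays(self, sex: str):
        try:
            return self._by_sex[sex]
        except KeyError:
            raise SchemaError(f"growth reference has no rows for sex {sex!r}") from None

    # -- lookup -------------------------------------------------------------

    def lookup(self, sex: str, age_months: float) -> tuple[float, float, float]:
        """(L, M, S) at the given sex and age, linearly interpolated in age."""
        ages, L, M, S = self._sex_arrays(sex)
        if age_months < ages[0] or age_months > ages[-1]:
            raise RangeError(
                f"age {age_months} months outside the covered interval "
                f"[{ages[0]}, {ages[-1]}] for sex {sex!r}"
            )
        return (
            float(np.interp(age_months, ages, L)),
            float(np.interp(age_months, ages, M)),
            float(np.interp(age_months, ages, S)),
        )

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_csv(cls, path, sex_coding: str = "auto") -> "GrowthReferenceTable":
        """Read a reference table with header ``sex,agemos,L,M,S``.

        ``sex`` may be coded ``1`` = male / ``2`` = female (the CDC dialect)
        or as ``male`` / ``female`` strings; ``sex_coding`` is one of
        ``"cdc"``, ``"labels"`` or ``"auto"``.
        """
        df = pd.read_csv(path)
        required = {"sex", "agemos", "L", "M", "S"}
        if not required.issubset(df.columns):
            raise SchemaError(
                f"growth reference CSV must have columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        raw = df["sex"]
        if sex_coding == "auto":
            sex_coding = "labels" if raw.dtype == object else "cdc"
        if sex_coding == "cdc":
            mapping = {1: "male", 2: "female"}
            sexes = raw.map(lambda v: mapping.get(int(v)))
        elif sex_coding == "labels":
            sexes = raw.map(lambda v: str(v).strip().lower())
        else:
            raise SchemaError(f"unknown sex_coding {sex_coding!r}")
        if sexes.isna().any() or not set(sexes) <= set(SEXES):
            raise SchemaError("sex column must code male/female (1/2)")
        rows = tuple(
            (s, float(a), float(l), float(m), float(v))
            for s, a, l, m, v in zip(sexes, df["agemos"], df["L"], df["M"], df["S"])
        )
        return cls(rows=rows)

    def to_csv(self, path, sex_coding: str = "cdc") -> None:
        code = {"male": 1, "female": 2} if sex_coding == "cdc" else {s: s for s in SEXES}
        df = pd.DataFrame(
            [(code[s], a, l, m, v) for (s, a, l, m, v) in self.rows],
            columns=["sex", "agemos", "L", "M", "S"],
        )
        df.to_csv(path, index=False)


def interpolate_lms(
    table: GrowthReferenceTable, sex: str, age_months: float
) -> tuple[float, float, float]:
    """Component-wise linear interpolation of (L, M, S) in age."""
    return table.lookup(sex, age_months)


def bmi_percentile(
    bmi: float, age_months: float, sex: str, table: GrowthReferenceTable
) -> float:
    """BMI-for-age percentile for a participant under 20 years."""
    L, M, S = table.lookup(sex, age_months)
    return percentile_from_z(lms_zscore(bmi, L, M, S))


def classify_weight_status(
    bmi: float,
    age_months: float,
    sex: str,
    table: GrowthReferenceTable | None = None,
) -> WeightStatus:
    """Four-category weight status from BMI, age and sex.

    Under 240 months the classification uses BMI-for-age percentiles from
    ``table``; at 240 months and older it uses the adult cutoffs and no
    table is needed.
    """
    if not (bmi > 0):
        raise DomainError(f"bmi must be positive, got {bmi}")
    if age_months >= ADULT_AGE_MONTHS:
        lo, mid, hi = ADULT_BMI_CUTOFFS
        if bmi < lo:
            return WeightStatus.UW
        if bmi < mid:
            return WeightStatus.HW
        if bmi < hi:
            return WeightStatus.OW
        return WeightStatus.OB
    if table is None:
        raise RangeError(
            f"a growth reference table is required for age {age_months} < "
            f"{ADULT_AGE_MONTHS} months"
        )
    pct = bmi_percentile(bmi, age_months, sex, table)
    p5, p85, p95 = PEDIATRIC_PERCENTILE_CUTOFFS
    if pct < p5:
        return WeightStatus.UW
    if pct < p85:
        return WeightStatus.HW
    if pct < p95:
        return WeightStatus.OW
    return WeightStatus.OB
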