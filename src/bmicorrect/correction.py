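"""Linear correction models for self-reported height and weight.

The correction is a two-stage procedure.  On data where both measured and
self-reported anthropometrics exist, measured weight and measured height are
each regressed (weighted least squares, probability weights) on the
self-reported value plus demographic, biometric and psychosocial covariates;
whole predictor blocks are then kept or dropped by backward elimination on
AIC, and two-way interactions among the retained predictors are screened by
the same rule.  The fitted equations are then applied to records that have
only self-reported values, yielding corrected height and weight from which a
corrected BMI and weight status are computed.

Published coefficient sets for both outcomes are bundled
(:func:`published_models`); they are expressed in imperial units (pounds,
inches) and carry the printed two-decimal precision, so predictions from
them have rounding error of order 0.005 times the covariate magnitudes.

Categorical predictors use dummy coding against fixed reference levels:
healthy weight (self-reported weight status), "about right" (body-size
estimation), White (race/ethnicity), male (sex) and a college degree
(parent education).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    DataError,
    DomainError,
    MissingDataError,
    SingularDesignError,
    UnitError,
)
from .growth_reference import (
    GrowthReferenceTable,
    WeightStatus,
    classify_weight_status,
    compute_bmi,
)
from .records import (
    AnthropometricRecord,
    BODY_SIZE_LEVELS,
    CM_PER_INCH,
    KG_PER_POUND,
    PARENT_ED_LEVELS,
    RACE_LEVELS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Term",
    "CorrectionModel",
    "FitResult",
    "CorrectedValues",
    "MODEL_FORMAT_VERSION",
    "CANDIDATE_BLOCKS",
    "derive_sr_weight_status",
    "record_values",
    "design_vector",
    "apply_model",
    "correct_record",
    "correct_cohort",
    "build_design",
    "fit_wls",
    "aic_select",
    "screen_interactions",
    "published_models",
]

MODEL_FORMAT_VERSION = 1

# ---------------------------------------------------------------------------
# Predictor vocabulary
# ---------------------------------------------------------------------------

#: Continuous predictors, passed through in the model's unit system.
CONTINUOUS_PREDICTORS = (
    "sr_weight",
    "sr_height",
    "age_months",
    "puberty",
    "cesd",
    "self_rated_health",
    "self_esteem",
)

#: 0/1 predictors.
BINARY_PREDICTORS = ("dieting",)

#: Categorical predictors: name -> (non-reference levels, reference level).
CATEGORICAL_PREDICTORS = {
    "sr_weight_status": (("UW", "OW", "OB"), "HW"),
    "body_size_estimation": (("UW", "OW"), "AboutRight"),
    "race_ethnicity": (("Hispanic", "Black", "Asian", "Other"), "White"),
    "sex": (("female",), "male"),
    "parent_education": (("HS_or_less", "Some_college"), "College_plus"),
}

#: Grouped levels: an indicator that fires for any member of the group.  The
#: published height equation carries a single parent-education term against
#: the college-degree reference, pooling the two lower levels.
LEVEL_GROUPS = {"Less_than_college": ("HS_or_less", "Some_college")}

#: Candidate predictor blocks in their canonical (deterministic) order; a
#: categorical block enters or leaves selection with all of its dummies.
CANDIDATE_BLOCKS = (
    "sr_weight",
    "sr_height",
    "age_months",
    "puberty",
    "sr_weight_status",
    "body_size_estimation",
    "dieting",
    "cesd",
    "self_rated_health",
    "self_esteem",
    "race_ethnicity",
    "sex",
    "parent_education",
)


def block_columns(block: str) -> list[str]:
    """Design-matrix column names belonging to a predictor block."""
    if block in CATEGORICAL_PREDICTORS:
        levels, _ref = CATEGORICAL_PREDICTORS[block]
        return [f"{block}[{lvl}]" for lvl in levels]
    if block in CONTINUOUS_PREDICTORS or block in BINARY_PREDICTORS:
        return [block]
    raise DomainError(f"unknown predictor block: {block!r}")


def default_candidate_blocks(outcome: str) -> list[str]:
    """All candidate blocks for an outcome (the self-report analogue of the
    other outcome is excluded, mirroring separate height/weight equations)."""
    drop = "sr_height" if outcome == "weight" else "sr_weight"
    return [b for b in CANDIDATE_BLOCKS if b != drop]


def mandatory_block(outcome: str) -> str:
    return "sr_weight" if outcome == "weight" else "sr_height"


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Term:
    """One named coefficient.

    ``predictor`` is a block name, or ``"a*b"`` for a two-way interaction;
    ``level`` is ``None`` for continuous/binary predictors, a category label
    for a dummy, and for interactions a ``*``-joined pair with empty slots
    for continuous components (e.g. ``"UW*"``).
    """

    predictor: str
    level: Optional[str]
    coefficient: float

    @property
    def column(self) -> str:
        parts = self.predictor.split("*")
        if self.level is None:
            levels = [None] * len(parts)
        else:
            levels = [l if l else None for l in self.level.split("*")]
        return "*".join(
            p if l is None else f"{p}[{l}]" for p, l in zip(parts, levels)
        )

    @classmethod
    def from_column(cls, column: str, coefficient: float) -> "Term":
        preds, levels = [], []
        for part in column.split("*"):
            if part.endswith("]") and "[" in part:
                p, lvl = part[:-1].split("[", 1)
                preds.append(p)
                levels.append(lvl)
            else:
                preds.append(part)
                levels.append(None)
        predictor = "*".join(preds)
        if all(l is None for l in levels):
            level = None
        else:
            level = "*".join(l or "" for l in levels)
        return cls(predictor=predictor, level=level, coefficient=coefficient)


@dataclass
class CorrectionModel:
    """A correction equation for one outcome (height or weight).

    The equation is ``prediction = intercept + sum(coefficient * term
    value)`` in the model's own unit system.  ``reference_levels`` records
    the omitted category of each categorical predictor; no term may
    reference its predictor's reference level.
    """

    outcome: str
    unit_system: str
    intercept: float
    terms: tuple[Term, ...]
    reference_levels: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.outcome not in ("height", "weight"):
            raise DomainError(f"outcome must be height or weight, got {self.outcome!r}")
        if self.unit_system not in ("metric", "imperial"):
            raise UnitError(f"unknown unit system {self.unit_system!r}")
        self.terms = tuple(self.terms)
        for t in self.terms:
            if t.level is not None and "*" not in t.predictor:
                ref = self.reference_levels.get(t.predictor)
                if ref is not None and t.level == ref:
                    raise DomainError(
                        f"term {t.predictor}[{t.level}] references the reference level"
                    )

    # -- serialization ------------------------------------------------------
    # Coefficients are written as decimal strings (repr of the float), which
    # round-trips bit-exactly through JSON.

    def to_dict(self) -> dict:
        return {
            "format": MODEL_FORMAT_VERSION,
            "outcome": self.outcome,
            "unit_system": self.unit_system,
            "intercept": repr(float(self.intercept)),
            "terms": [
                {
                    "predictor": t.predictor,
                    "level": t.level,
                    "coefficient": repr(float(t.coefficient)),
                }
                for t in self.terms
            ],
            "reference_levels": dict(self.reference_levels),
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrectionModel":
        if d.get("format") != MODEL_FORMAT_VERSION:
            raise DomainError(f"unsupported model format: {d.get('format')!r}")
        return cls(
            outcome=d["outcome"],
            unit_system=d["unit_system"],
            intercept=float(d["intercept"]),
            terms=tuple(
                Term(t["predictor"], t["level"], float(t["coefficient"]))
                for t in d["terms"]
            ),
            reference_levels=dict(d.get("reference_levels", {})),
            provenance=dict(d.get("provenance", {})),
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "CorrectionModel":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            s = str(source)
            if s.lstrip().startswith("{"):
                d = json.loads(s)
            else:
                with open(s) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)


@dataclass
class FitResult:
    """A fitted correction model plus fit diagnostics.

    AIC follows the convention ``2k - 2 loglik`` with ``k`` counting the
    intercept, the slopes and the error variance; the Gaussian log-likelihood
    treats the sampling weights as probability weights normalised to sum to
    the number of observations used.
    """

    model: CorrectionModel
    coefficient_ses: dict
    loglik: float
    aic: float
    r2: float
    n_used: int

    def __post_init__(self):
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise DataError(f"R^2 out of range: {self.r2}")


@dataclass(frozen=True)
class CorrectedValues:
    """Output of applying the correction to one record (metric units)."""

    height_cm: float
    weight_kg: float
    bmi: float
    status: WeightStatus


# ---------------------------------------------------------------------------
# Encoding records into design vectors
# ---------------------------------------------------------------------------


def derive_sr_weight_status(
    record: AnthropometricRecord, growth_ref: GrowthReferenceTable | None
) -> WeightStatus:
    """Weight status implied by the self-reported BMI."""
    bmi = compute_bmi(record.sr_weight_kg, record.sr_height_cm / 100.0, "metric")
    return classify_weight_status(bmi, record.age_months, record.sex, growth_ref)


def record_values(
    record: AnthropometricRecord,
    unit_system: str,
    growth_ref: GrowthReferenceTable | None = None,
) -> dict:
    """Predictor name -> value mapping for one record.

    Self-reported height and weight are converted into ``unit_system``.
    Missing covariates map to ``None``; the self-reported weight status is
    derived from ``growth_ref`` when not already set on the record.
    """
    if unit_system == "imperial":
        sr_h = record.sr_height_cm / CM_PER_INCH
        sr_w = record.sr_weight_kg / KG_PER_POUND
    elif unit_system == "metric":
        sr_h = record.sr_height_cm
        sr_w = record.sr_weight_kg
    else:
        raise UnitError(f"unknown unit system {unit_system!r}")
    status = record.sr_weight_status
    if status is None and growth_ref is not None:
        status = derive_sr_weight_status(record, growth_ref)
    return {
        "sr_weight": sr_w,
        "sr_height": sr_h,
        "age_months": record.age_months,
        "puberty": record.puberty,
        "cesd": record.cesd,
        "self_rated_health": record.self_rated_health,
        "self_esteem": record.self_esteem,
        "dieting": None if record.dieting is None else float(record.dieting),
        "sr_weight_status": None if status is None else status.name,
        "body_size_estimation": record.body_size_estimation,
        "race_ethnicity": record.race_ethnicity,
        "sex": record.sex,
        "parent_education": record.parent_education,
    }


def _component_value(values: dict, predictor: str, level: Optional[str]) -> float:
    if predictor not in values:
        raise MissingDataError(f"unknown predictor {predictor!r}")
    v = values[predictor]
    if v is None or (isinstance(v, float) and np.isnan(v)):
        raise MissingDataError(f"record is missing required covariate {predictor!r}")
    if level is None:
        return float(v)
    if level in LEVEL_GROUPS:
        return 1.0 if v in LEVEL_GROUPS[level] else 0.0
    return 1.0 if v == level else 0.0


def term_value(values: dict, term: Term) -> float:
    """Numeric value of one model term for a record's value mapping."""
    preds = term.predictor.split("*")
    if term.level is None:
        levels = [None] * len(preds)
    else:
        levels = [l if l else None for l in term.level.split("*")]
    out = 1.0
    for p, l in zip(preds, levels):
        out *= _component_value(values, p, l)
    return out


def design_vector(record_or_values, model: CorrectionModel,
                  growth_ref: GrowthReferenceTable | None = None) -> np.ndarray:
    """Design vector of a record against a model's term list.

    Ordering matches ``model.terms`` exactly.  Accepts either a record or a
    pre-built predictor-value mapping (as from :func:`record_values`).
    """
    if isinstance(record_or_values, AnthropometricRecord):
        values = record_values(record_or_values, model.unit_system, growth_ref)
    else:
        values = record_or_values
    return np.array([term_value(values, t) for t in model.terms])


def apply_model(model: CorrectionModel, record_or_values,
                growth_ref: GrowthReferenceTable | None = None) -> float:
    """Predicted (corrected) outcome in the model's unit system."""
    x = design_vector(record_or_values, model, growth_ref)
    coefs = np.array([t.coefficient for t in model.terms])
    return float(model.intercept + x @ coefs)


def correct_record(
    record: AnthropometricRecord,
    weight_model: CorrectionModel,
    height_model: CorrectionModel,
    growth_ref: GrowthReferenceTable | None = None,
) -> CorrectedValues:
    """Corrected height, weight, BMI and weight status for one record."""
    if weight_model.unit_system != height_model.unit_system:
        raise UnitError(
            "weight and height models use different unit systems: "
            f"{weight_model.unit_system!r} vs {height_model.unit_system!r}"
        )
    units = weight_model.unit_system
    values = record_values(record, units, growth_ref)
    w = apply_model(weight_model, values)
    h = apply_model(height_model, values)
    if units == "imperial":
        w_kg, h_cm = w * KG_PER_POUND, h * CM_PER_INCH
    else:
        w_kg, h_cm = w, h
    if not (w_kg > 0 and h_cm > 0):
        raise DomainError(
            f"corrected values must be positive, got weight={w_kg} kg, height={h_cm} cm"
        )
    bmi = compute_bmi(w_kg, h_cm / 100.0, "metric")
    status = classify_weight_status(bmi, record.age_months, record.sex, growth_ref)
    return CorrectedValues(height_cm=h_cm, weight_kg=w_kg, bmi=bmi, status=status)


def correct_cohort(
    records: Sequence[AnthropometricRecord],
    weight_model: CorrectionModel,
    height_model: CorrectionModel,
    growth_ref: GrowthReferenceTable | None = None,
) -> tuple[list[Optional[CorrectedValues]], int]:
    """Apply the correction to every record, complete cases only.

    Returns one entry per record (``None`` where covariates were missing)
    plus the count of dropped records.
    """
    out: list[Optional[CorrectedValues]] = []
    dropped = 0
    for r in records:
        try:
            out.append(correct_record(r, weight_model, height_model, growth_ref))
        except MissingDataError:
            out.append(None)
            dropped += 1
    if dropped:
        logger.info("correct_cohort: dropped %d incomplete record(s)", dropped)
    return out, dropped


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class DesignData:
    """Assembled regression inputs for one outcome."""

    y: np.ndarray
    X: pd.DataFrame
    w: np.ndarray
    block_cols: dict
    n_dropped: int
    outcome: str
    unit_system: str
    reference_levels: dict


def _outcome_value(record: AnthropometricRecord, outcome: str, unit_system: str):
    if outcome == "weight":
        v = record.measured_weight_kg
        if v is not None and unit_system == "imperial":
            v = v / KG_PER_POUND
    else:
        v = record.measured_height_cm
        if v is not None and unit_system == "imperial":
            v = v / CM_PER_INCH
    return v


def build_design(
    records: Sequence[AnthropometricRecord],
    blocks: Sequence[str],
    outcome: str,
    unit_system: str = "metric",
    growth_ref: GrowthReferenceTable | None = None,
) -> DesignData:
    """Design matrix, outcome vector and weights for a block set.

    Complete-case policy: records missing the outcome or any covariate
    required by ``blocks`` are excluded (the count is reported, never
    imputed).  Columns with zero variance in the retained data are dropped
    so that, e.g., a single-sex cohort does not make the sex dummy collinear
    with the intercept; a block whose columns all vanish is removed.
    """
    blocks = list(blocks)
    cols_per_block = {b: block_columns(b) for b in blocks}
    rows, ys, ws = [], [], []
    n_dropped = 0
    for r in records:
        y = _outcome_value(r, outcome, unit_system)
        if y is None:
            n_dropped += 1
            continue
        values = record_values(r, unit_system, growth_ref)
        try:
            row = {}
            for b in blocks:
                if b in CATEGORICAL_PREDICTORS:
                    levels, _ = CATEGORICAL_PREDICTORS[b]
                    for lvl in levels:
                        row[f"{b}[{lvl}]"] = _component_value(values, b, lvl)
                else:
                    row[b] = _component_value(values, b, None)
        except MissingDataError:
            n_dropped += 1
            continue
        rows.append(row)
        ys.append(float(y))
        ws.append(float(r.sample_weight))
    if not rows:
        raise DataError("no complete cases available for fitting")
    if n_dropped:
        logger.info("build_design: dropped %d incomplete record(s)", n_dropped)
    X = pd.DataFrame(rows)
    # drop zero-variance columns (and empty blocks)
    keep_cols = [c for c in X.columns if X[c].nunique() > 1]
    block_cols = {}
    for b in blocks:
        cols = [c for c in cols_per_block[b] if c in keep_cols]
        if cols:
            block_cols[b] = cols
    ordered = [c for b in block_cols for c in block_cols[b]]
    refs = {
        b: CATEGORICAL_PREDICTORS[b][1]
        for b in block_cols
        if b in CATEGORICAL_PREDICTORS
    }
    return DesignData(
        y=np.asarray(ys),
        X=X[ordered],
        w=np.asarray(ws),
        block_cols=block_cols,
        n_dropped=n_dropped,
        outcome=outcome,
        unit_system=unit_system,
        reference_levels=refs,
    )


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    from scipy import linalg

    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return [names[i] for i in piv[rank:]]


def fit_wls(
    y,
    X: pd.DataFrame,
    w=None,
    *,
    outcome: str = "weight",
    unit_system: str = "metric",
    reference_levels: Optional[dict] = None,
    provenance: Optional[dict] = None,
) -> FitResult:
    """Probability-weighted least squares with Gaussian AIC and weighted R^2.

    Weights are normalised to sum to ``n``; the log-likelihood is the
    weighted Gaussian log-likelihood at the plug-in variance estimate and
    ``k`` counts intercept + slopes + error variance.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if w is None:
        w = np.ones(n)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise DataError("all weights must be positive")
    if len(X) != n or len(w) != n:
        raise DataError("y, X and w must have equal length")
    p = X.shape[1]
    if n <= p + 2:
        raise DataError(f"too few observations (n={n}) for {p} predictors")
    names = ["Intercept"] + list(X.columns)
    M = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(M) < M.shape[1]:
        bad = _collinear_columns(M, names)
        raise SingularDesignError(
            f"design matrix is rank deficient; collinear columns: {bad}", columns=bad
        )
    wn = w * (n / w.sum())
    res = sm.WLS(y, M, weights=wn).fit()
    resid = y - res.fittedvalues
    sigma2 = float(wn @ resid**2) / n
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    k = p + 2  # intercept + slopes + error variance
    aic = 2.0 * k - 2.0 * loglik
    ybar = float(wn @ y) / n
    sst = float(wn @ (y - ybar) ** 2)
    r2 = 1.0 - (float(wn @ resid**2) / sst) if sst > 0 else 0.0
    coefs = dict(zip(names, res.params))
    ses = dict(zip(names, res.bse))
    prov = {"source": "refit", "n": n, "AIC": aic, "R2": r2}
    if provenance:
        prov.update(provenance)
    model = CorrectionModel(
        outcome=outcome,
        unit_system=unit_system,
        intercept=float(coefs["Intercept"]),
        terms=tuple(
            Term.from_column(c, float(coefs[c])) for c in X.columns
        ),
        reference_levels=dict(reference_levels or {}),
        provenance=prov,
    )
    return FitResult(
        model=model,
        coefficient_ses=ses,
        loglik=float(loglik),
        aic=float(aic),
        r2=float(min(max(r2, 0.0), 1.0)),
        n_used=n,
    )


def _fit_subset(dd: DesignData, cols: Sequence[str], provenance=None) -> FitResult:
    return fit_wls(
        dd.y,
        dd.X[list(cols)],
        dd.w,
        outcome=dd.outcome,
        unit_system=dd.unit_system,
        reference_levels=dd.reference_levels,
        provenance=provenance,
    )


def aic_select(
    candidate_blocks: Sequence[str],
    data: Sequence[AnthropometricRecord] | DesignData,
    outcome: str = "weight",
    *,
    unit_system: str = "metric",
    growth_ref: GrowthReferenceTable | None = None,
    mandatory: Optional[Sequence[str]] = None,
) -> FitResult:
    """Backward block-wise AIC elimination.

    Starting from the full model, the single block whose removal lowers AIC
    the most is dropped, repeatedly, until no removal lowers AIC (on an exact
    tie the block is kept).  The self-report analogue of the outcome is
    always retained.  Blocks are evaluated in their given order, which makes
    the procedure deterministic.
    """
    if not candidate_blocks:
        raise DataError("at least one candidate block is required")
    if isinstance(data, DesignData):
        dd = data
    else:
        dd = build_design(data, candidate_blocks, outcome, unit_system, growth_ref)
    if mandatory is None:
        mandatory = [mandatory_block(outcome)]
    mandatory = [b for b in mandatory if b in dd.block_cols]
    active = [b for b in candidate_blocks if b in dd.block_cols]
    trace = []

    def cols_for(blocks):
        return [c for b in blocks for c in dd.block_cols[b]]

    current = _fit_subset(dd, cols_for(active))
    full_aic = current.aic
    improved = True
    while improved:
        improved = False
        best_block, best_fit = None, None
        for b in active:
            if b in mandatory:
                continue
            trial_blocks = [x for x in active if x != b]
            try:
                trial = _fit_subset(dd, cols_for(trial_blocks))
            except SingularDesignError:
                continue
            if trial.aic < current.aic and (
                best_fit is None or trial.aic < best_fit.aic
            ):
                best_block, best_fit = b, trial
        if best_block is not None:
            active = [x for x in active if x != best_block]
            trace.append({"removed": best_block, "aic": best_fit.aic})
            current = best_fit
            improved = True
    prov = {
        "method": "aic_select",
        "blocks_retained": list(active),
        "blocks_removed": [t["removed"] for t in trace],
        "full_model_aic": full_aic,
        "n": current.n_used,
        "AIC": current.aic,
        "R2": current.r2,
    }
    current.model.provenance.update(prov)
    return current


def _interaction_block(X: pd.DataFrame, block_cols: dict, current_cols, a: str,
                       b: str):
    """Product columns for the pair (a, b), pruned of degenerate members."""
    Xb = X[list(current_cols)].to_numpy(dtype=float)
    M = np.column_stack([np.ones(len(X)), Xb])
    out_names, out_cols = [], []
    for ca in block_cols[a]:
        for cb in block_cols[b]:
            col = X[ca].to_numpy(dtype=float) * X[cb].to_numpy(dtype=float)
            if np.ptp(col) == 0:
                continue
            # drop columns linearly dependent on the current design
            resid = col - M @ np.linalg.lstsq(M, col, rcond=None)[0]
            denom = np.linalg.norm(col) or 1.0
            if np.linalg.norm(resid) / denom < 1e-8:
                continue
            out_names.append(f"{ca}*{cb}")
            out_cols.append(col)
            M = np.column_stack([M, col])
    return out_names, out_cols


def screen_interactions(
    selected: FitResult,
    data: Sequence[AnthropometricRecord],
    *,
    unit_system: Optional[str] = None,
    growth_ref: GrowthReferenceTable | None = None,
) -> FitResult:
    """Greedy AIC screening of two-way interactions among retained blocks.

    All pairwise products of the predictors retained by
    :func:`aic_select` (dummy x dummy, dummy x continuous, continuous x
    continuous) are candidate blocks; one is added per round if and only if
    it lowers AIC, until none does.  With fewer than two retained blocks the
    input is returned unchanged.
    """
    blocks = list(selected.model.provenance.get("blocks_retained", []))
    if len(blocks) < 2:
        return selected
    outcome = selected.model.outcome
    units = unit_system or selected.model.unit_system
    dd = build_design(data, blocks, outcome, units, growth_ref)
    base_cols = [c for b in dd.block_cols for c in dd.block_cols[b]]
    X = dd.X.copy()
    current_cols = list(base_cols)
    current = _fit_subset(dd, current_cols)
    pairs = list(itertools.combinations([b for b in blocks if b in dd.block_cols], 2))
    kept_pairs = []
    improved = True
    while improved and pairs:
        improved = False
        best = None  # (aic, pair, names, cols)
        for pair in pairs:
            names, cols = _interaction_block(X, dd.block_cols, current_cols, *pair)
            if not names:
                continue
            Xt = X[current_cols].copy()
            for nm, col in zip(names, cols):
                Xt[nm] = col
            try:
                trial = fit_wls(
                    dd.y, Xt, dd.w,
                    outcome=outcome, unit_system=units,
                    reference_levels=dd.reference_levels,
                )
            except SingularDesignError:
                continue
            if trial.aic < current.aic and (best is None or trial.aic < best[0]):
                best = (trial.aic, pair, names, cols)
        if best is not None:
            _, pair, names, cols = best
            for nm, col in zip(names, cols):
                X[nm] = col
            current_cols = current_cols + names
            current = fit_wls(
                dd.y, X[current_cols], dd.w,
                outcome=outcome, unit_system=units,
                reference_levels=dd.reference_levels,
            )
            kept_pairs.append(pair)
            pairs = [p for p in pairs if p != pair]
            improved = True
    prov = dict(selected.model.provenance)
    prov.update(
        {
            "method": "aic_select+interactions",
            "interactions_kept": [list(p) for p in kept_pairs],
            "n": current.n_used,
            "AIC": current.aic,
            "R2": current.r2,
        }
    )
    current.model.provenance = prov
    return current


# ---------------------------------------------------------------------------
# Published coefficient sets
# ---------------------------------------------------------------------------

_PUBLISHED_WEIGHT = {
    "intercept": "8.20",
    "terms": [
        ("sr_weight", None, "0.95"),
        ("age_months", None, "-0.01"),
        ("puberty", None, "0.22"),
        ("sr_weight_status", "UW", "3.67"),
        ("sr_weight_status", "OW", "2.46"),
        ("sr_weight_status", "OB", "2.86"),
        ("body_size_estimation", "UW", "-1.76"),
        ("body_size_estimation", "OW", "3.68"),
        ("dieting", None, "0.93"),
        ("cesd", None, "-0.04"),
        ("self_rated_health", None, "-0.39"),
        ("self_esteem", None, "0.35"),
    ],
    "reference_levels": {
        "sr_weight_status": "HW",
        "body_size_estimation": "AboutRight",
    },
}

_PUBLISHED_HEIGHT = {
    "intercept": "9.53",
    "terms": [
        ("sr_height", None, "0.85"),
        ("age_months", None, "0.00"),
        ("puberty", None, "0.05"),
        ("sr_weight_status", "UW", "-0.92"),
        ("sr_weight_status", "OW", "0.17"),
        ("sr_weight_status", "OB", "0.40"),
        ("body_size_estimation", "UW", "0.13"),
        ("body_size_estimation", "OW", "-0.11"),
        ("dieting", None, "-0.08"),
        ("cesd", None, "-0.01"),
        ("self_rated_health", None, "-0.04"),
        ("self_esteem", None, "-0.06"),
        ("race_ethnicity", "Hispanic", "-0.23"),
        ("race_ethnicity", "Black", "0.03"),
        ("race_ethnicity", "Asian", "-0.29"),
        ("race_ethnicity", "Other", "0.02"),
        ("sex", "female", "0.65"),
        ("parent_education", "Less_than_college", "0.08"),
    ],
    "reference_levels": {
        "sr_weight_status": "HW",
        "body_size_estimation": "AboutRight",
        "race_ethnicity": "White",
        "sex": "male",
        "parent_education": "College_plus",
    },
}


def published_models() -> tuple[CorrectionModel, CorrectionModel]:
    """The bundled published correction equations (weight, height).

    Both are in imperial units (pounds, inches).  The weight equation
    retains nine predictor blocks -- race/ethnicity, sex and parent
    education were eliminated during its block-wise AIC selection -- while
    the height equation retains all candidates, including race levels that
    are individually non-significant but whose class variable contributed.
    Coefficients are stored at the printed two-decimal precision.
    """

    def build(spec, outcome):
        return CorrectionModel(
            outcome=outcome,
            unit_system="imperial",
            intercept=float(spec["intercept"]),
            terms=tuple(
                Term(p, lvl, float(c)) for p, lvl, c in spec["terms"]
            ),
            reference_levels=dict(spec["reference_levels"]),
            provenance={"source": "published_table2"},
        )

    return build(_PUBLISHED_WEIGHT, "weight"), build(_PUBLISHED_HEIGHT, "height")
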