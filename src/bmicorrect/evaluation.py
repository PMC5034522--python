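"""Correction-quality metrics.

Three families of output quantify how well corrected (or self-reported)
values track measured ones:

* weighted Pearson correlations between BMI series,
* binary threshold diagnostics (sensitivity, specificity, PPV, NPV) with
  95% confidence intervals, and
* 4x4 weighted misclassification contingency tables over the ordered weight
  statuses, decomposed into underestimation (above the diagonal, with rows =
  assigned status and columns = reference status), overestimation (below)
  and agreement (the diagonal).

Confidence intervals default to the Wilson score interval on a Kish
effective sample size; exact Clopper-Pearson intervals are available by
flag.  Survey design-based variance (strata/PSUs) is out of scope: weights
enter all point estimates, and CIs are model-agnostic approximations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import DataError, DomainError, UndefinedMetricError
from .growth_reference import STATUS_ORDER, WeightStatus

__all__ = [
    "ClassificationTable",
    "DiagnosticResult",
    "DiagnosticsDelta",
    "weighted_pearson",
    "contingency",
    "underestimation_rate",
    "overestimation_rate",
    "overall_misclassification",
    "binary_diagnostics",
    "compare_diagnostics",
]

_STATUS_LABELS = [s.name for s in STATUS_ORDER]

_CI_METHODS = {"wilson": "wilson", "exact": "beta"}


@dataclass
class ClassificationTable:
    """4x4 weighted cross-classification of weight statuses, in percent.

    Rows are the assigned status (self-reported or corrected), columns the
    reference status (measured, or self-reported when no measurement
    exists); both run UW, HW, OW, OB.  Cells sum to 100 up to ``total_atol``
    (published tables carry rounding, freshly computed ones are exact).
    """

    cells: np.ndarray
    n: float
    row_axis: str = "assigned"
    col_axis: str = "reference"
    counts: Optional[np.ndarray] = None
    total_atol: float = 1e-9

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.shape != (4, 4):
            raise DataError(f"classification table must be 4x4, got {self.cells.shape}")
        if np.any(self.cells < 0):
            raise DataError("classification table cells must be nonnegative")
        total = float(self.cells.sum())
        if abs(total - 100.0) > self.total_atol:
            raise DataError(
                f"classification table cells sum to {total}, expected 100"
            )

    @classmethod
    def from_percentages(cls, cells, n: float, total_atol: float = 0.5,
                         **kwargs) -> "ClassificationTable":
        """Build from externally printed percentages (rounded, so the total
        is only required to be within ``total_atol`` of 100)."""
        return cls(cells=np.asarray(cells, dtype=float), n=n,
                   total_atol=total_atol, **kwargs)

    @classmethod
    def from_counts(cls, counts, **kwargs) -> "ClassificationTable":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise DataError("counts must sum to a positive total")
        return cls(cells=100.0 * counts / total, n=float(total),
                   counts=counts, **kwargs)

    def to_dict(self) -> dict:
        d = {
            "rows": self.row_axis,
            "columns": self.col_axis,
            "labels": _STATUS_LABELS,
            "cells_percent": self.cells.tolist(),
            "n": self.n,
        }
        if self.counts is not None:
            d["counts"] = np.asarray(self.counts).tolist()
        return d

    def to_text(self) -> str:
        head = f"{self.row_axis} \\ {self.col_axis}"
        lines = [
            f"{head:<22}" + "".join(f"{lbl:>8}" for lbl in _STATUS_LABELS) + f"{'Total':>9}"
        ]
        for i, lbl in enumerate(_STATUS_LABELS):
            row = self.cells[i]
            lines.append(
                f"{lbl:<22}" + "".join(f"{v:8.1f}" for v in row) + f"{row.sum():9.1f}"
            )
        col_tot = self.cells.sum(axis=0)
        lines.append(
            f"{'Total':<22}" + "".join(f"{v:8.1f}" for v in col_tot)
            + f"{self.cells.sum():9.1f}"
        )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.cells, index=_STATUS_LABELS, columns=_STATUS_LABELS).to_csv(
            path, index_label=f"{self.row_axis}\\{self.col_axis}"
        )


def _as_status_indices(values) -> np.ndarray:
    out = []
    for v in values:
        if isinstance(v, WeightStatus):
            out.append(int(v))
        elif isinstance(v, str):
            out.append(int(WeightStatus.from_label(v)))
        else:
            iv = int(v)
            if iv not in (0, 1, 2, 3):
                raise DomainError(f"invalid weight status code: {v!r}")
            out.append(iv)
    return np.asarray(out, dtype=int)


def contingency(assigned, reference, w=None) -> ClassificationTable:
    """Weighted 4x4 cross-classification (rows = assigned, cols = reference).

    Raw integer counts are kept alongside the percentages whenever the
    weights are uniform.
    """
    a = _as_status_indices(assigned)
    r = _as_status_indices(reference)
    if len(a) != len(r) or len(a) == 0:
        raise DataError("assigned and reference must be equal-length and nonempty")
    if w is None:
        w = np.ones(len(a))
    w = np.asarray(w, dtype=float)
    if len(w) != len(a) or np.any(w <= 0):
        raise DataError("weights must be positive and match the data length")
    table = np.zeros((4, 4))
    np.add.at(table, (a, r), w)
    cells = 100.0 * table / table.sum()
    counts = None
    if np.allclose(w, w[0]):
        counts = np.zeros((4, 4), dtype=int)
        np.add.at(counts, (a, r), 1)
    n_eff = float(w.sum() ** 2 / (w**2).sum())  # Kish effective count
    return ClassificationTable(cells=cells, n=n_eff, counts=counts)


def underestimation_rate(table: ClassificationTable) -> float:
    """Sum of cells above the diagonal: reference status exceeds assigned
    status, i.e. the assigned value underestimates."""
    i, j = np.triu_indices(4, k=1)
    return float(table.cells[i, j].sum())


def overestimation_rate(table: ClassificationTable) -> float:
    """Sum of cells below the diagonal (assigned overestimates reference)."""
    i, j = np.tril_indices(4, k=-1)
    return float(table.cells[i, j].sum())


def overall_misclassification(table: ClassificationTable) -> float:
    """100 minus the diagonal (any disagreement between the two methods)."""
    return float(100.0 - np.trace(table.cells))


def weighted_pearson(x, y, w=None) -> float:
    """Weighted product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("x and y must be equal-length with at least 3 points")
    if w is None:
        w = np.ones(len(x))
    w = np.asarray(w, dtype=float)
    if len(w) != len(x) or np.any(w <= 0):
        raise DataError("weights must be positive and match the data length")
    mx = np.average(x, weights=w)
    my = np.average(y, weights=w)
    cov = np.average((x - mx) * (y - my), weights=w)
    vx = np.average((x - mx) ** 2, weights=w)
    vy = np.average((y - my) ** 2, weights=w)
    if vx <= 0 or vy <= 0:
        raise DomainError("weighted variance is zero; correlation undefined")
    r = cov / np.sqrt(vx * vy)
    return float(min(max(r, -1.0), 1.0))


@dataclass
class DiagnosticResult:
    """Threshold diagnostics with 95% confidence intervals.

    All point estimates and CI bounds are proportions in [0, 1];
    ``ci`` maps each metric name to its (low, high) pair.
    """

    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    ci: dict = field(default_factory=dict)
    method: str = "wilson"

    _METRICS = ("sensitivity", "specificity", "ppv", "npv")

    def __post_init__(self):
        for m in self._METRICS:
            v = getattr(self, m)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{m} must be in [0, 1], got {v}")
            if m in self.ci:
                lo, hi = self.ci[m]
                if not (lo - 1e-12 <= v <= hi + 1e-12):
                    raise DomainError(
                        f"{m} CI [{lo}, {hi}] does not contain the estimate {v}"
                    )

    def to_dict(self) -> dict:
        d = {"threshold": self.threshold, "ci_method": self.method}
        for m in self._METRICS:
            d[m] = getattr(self, m)
            if m in self.ci:
                d[f"{m}_ci"] = list(self.ci[m])
        return d


def _kish_neff(w: np.ndarray) -> float:
    return float(w.sum() ** 2 / (w**2).sum())


def _proportion_ci(p: float, w_denom: np.ndarray, method: str):
    n_eff = _kish_neff(w_denom)
    count = p * n_eff
    lo, hi = proportion_confint(count, n_eff, alpha=0.05, method=_CI_METHODS[method])
    # guard against numerical jitter at the extremes
    return (min(float(lo), p), max(float(hi), p))


def binary_diagnostics(bmi_pred, bmi_ref, threshold: float, w=None,
                       ci_method: str = "wilson") -> DiagnosticResult:
    """Sensitivity/specificity/PPV/NPV of ``bmi_pred >= threshold`` against
    the reference classification ``bmi_ref >= threshold``.

    Cell masses are sampling-weighted; CIs use the Kish effective sample
    size of each metric's denominator group.
    """
    if not (threshold > 0):
        raise DomainError(f"threshold must be positive, got {threshold}")
    if ci_method not in _CI_METHODS:
        raise DomainError(f"ci_method must be one of {sorted(_CI_METHODS)}")
    pred = np.asarray(bmi_pred, dtype=float) >= threshold
    ref = np.asarray(bmi_ref, dtype=float) >= threshold
    if len(pred) != len(ref) or len(pred) == 0:
        raise DataError("bmi_pred and bmi_ref must be equal-length and nonempty")
    if w is None:
        w = np.ones(len(pred))
    w = np.asarray(w, dtype=float)
    if len(w) != len(pred) or np.any(w <= 0):
        raise DataError("weights must be positive and match the data length")

    tp = float(w[pred & ref].sum())
    fn = float(w[~pred & ref].sum())
    tn = float(w[~pred & ~ref].sum())
    fp = float(w[pred & ~ref].sum())

    if tp + fn == 0:
        raise UndefinedMetricError(
            "sensitivity undefined: no positive cases in the reference"
        )
    if tn + fp == 0:
        raise UndefinedMetricError(
            "specificity undefined: no negative cases in the reference"
        )
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    if tp + fp == 0:
        raise UndefinedMetricError("PPV undefined: no predicted positives")
    if tn + fn == 0:
        raise UndefinedMetricError("NPV undefined: no predicted negatives")
    ppv = tp / (tp + fp)
    npv = tn / (tn + fn)

    ci = {
        "sensitivity": _proportion_ci(sens, w[ref], ci_method),
        "specificity": _proportion_ci(spec, w[~ref], ci_method),
        "ppv": _proportion_ci(ppv, w[pred], ci_method),
        "npv": _proportion_ci(npv, w[~pred], ci_method),
    }
    return DiagnosticResult(
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        ci=ci,
        method=ci_method,
    )


@dataclass
class DiagnosticsDelta:
    """Percentage-point changes from a baseline (self-report) diagnostic to
    a comparison (corrected) diagnostic, plus CI-overlap flags (non-overlap
    of the two 95% CIs is the conventional bolding rule)."""

    deltas_pp: dict
    ci_overlap: dict

    def to_dict(self) -> dict:
        return {"deltas_pp": dict(self.deltas_pp), "ci_overlap": dict(self.ci_overlap)}


def compare_diagnostics(sr: DiagnosticResult,
                        corrected: DiagnosticResult) -> DiagnosticsDelta:
    deltas, overlap = {}, {}
    for m in DiagnosticResult._METRICS:
        deltas[m] = (getattr(corrected, m) - getattr(sr, m)) * 100.0
        if m in sr.ci and m in corrected.ci:
            (lo1, hi1), (lo2, hi2) = sr.ci[m], corrected.ci[m]
            overlap[m] = max(lo1, lo2) <= min(hi1, hi2)
    return DiagnosticsDelta(deltas_pp=deltas, ci_overlap=overlap)
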