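"""ROC curves, AUC, Youden-optimal cutoffs, and diagnostic metrics.

Cutoff selection follows the empirical-ROC convention: candidate thresholds
are the midpoints between consecutive distinct observed values (plus
sentinels outside the observed range), and the optimal cutoff maximizes the
Youden index J = sensitivity + specificity - 1.  The abnormal side of a
cutoff is closed (a value equal to the cutoff counts as abnormal); with
midpoint cutoffs no observed value lands on the boundary, so this choice is
observationally neutral.

AUC is the trapezoidal area of the empirical curve, which equals the
Mann-Whitney U statistic divided by n_pos * n_neg with ties counted one
half; its p-value (against AUC = 0.5) comes from the tie-corrected normal
approximation of U.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .inference import ContingencyTable

__all__ = [
    "RocCurve",
    "CutoffSpec",
    "DiagnosticMetrics",
    "RocError",
    "DegenerateRocWarning",
    "UndefinedMetricWarning",
    "build_roc",
    "auc",
    "youden_cutoff",
    "diagnostic_metrics",
    "truncate2",
    "HIGH_ABNORMAL",
    "LOW_ABNORMAL",
]

HIGH_ABNORMAL = "high_abnormal"
LOW_ABNORMAL = "low_abnormal"


class RocError(ValueError):
    """Raised when a ROC curve is undefined (e.g. a single outcome class)."""


class DegenerateRocWarning(UserWarning):
    """All marker values identical: the curve is the chance diagonal."""


class UndefinedMetricWarning(UserWarning):
    """A predictive value has a zero denominator and is reported missing."""


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve for one marker against a binary event.

    ``thresholds`` are candidate cutoffs ordered from the most permissive
    (everything abnormal) to the most restrictive (nothing abnormal);
    ``tpr``/``fpr`` give sensitivity and 1 - specificity of the "abnormal"
    call at each threshold.  ``direction`` states which side of a threshold
    is abnormal.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    direction: str
    n_pos: int
    n_neg: int
    values: np.ndarray
    labels: np.ndarray

    def to_rows(self) -> list[dict[str, float]]:
        return [
            {"threshold": float(t), "tpr": float(s), "fpr": float(f)}
            for t, s, f in zip(self.thresholds, self.tpr, self.fpr)
        ]


@dataclass(frozen=True)
class CutoffSpec:
    """A marker's dichotomization rule plus the ROC statistics behind it.

    ``direction`` is ``high_abnormal`` (abnormal iff value >= cutoff) or
    ``low_abnormal`` (abnormal iff value <= cutoff).  ``youden_j`` is
    Se + Sp - 1 at the cutoff; ``auc``/``auc_p`` describe the whole curve.
    """

    marker: str
    timepoint: str
    cutoff: float
    direction: str
    youden_j: float
    auc: float
    auc_p: float

    def __post_init__(self) -> None:
        if self.direction not in (HIGH_ABNORMAL, LOW_ABNORMAL):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not -1.0 - 1e-12 <= self.youden_j <= 1.0 + 1e-12:
            raise ValueError(f"youden_j={self.youden_j} outside [-1, 1]")

    def is_abnormal(self, value: float | None) -> bool | None:
        """Apply the rule; ``None`` propagates missingness."""
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        if self.direction == HIGH_ABNORMAL:
            return value >= self.cutoff
        return value <= self.cutoff


@dataclass(frozen=True)
class DiagnosticMetrics:
    """2x2-derived test metrics: Se/Sp as proportions, PPV/NPV as percentages."""

    table: ContingencyTable
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None


def _as_clean_arrays(values, labels) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be 1-D and equal length")
    if not np.all(np.isfinite(v)):
        raise ValueError("marker values must be finite")
    return v, y


def build_roc(values, labels, direction: str = "auto") -> RocCurve:
    """Empirical ROC of ``values`` against boolean event ``labels``.

    With ``direction="auto"`` the orientation whose AUC is >= 0.5 is chosen.
    Raises :class:`RocError` unless both classes are present; identical
    values yield the chance diagonal with a :class:`DegenerateRocWarning`.
    """
    v, y = _as_clean_arrays(values, labels)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise RocError(
            f"ROC undefined with a single outcome class (events={n_pos}, non-events={n_neg})"
        )
    if direction == "auto":
        hi = build_roc(v, y, HIGH_ABNORMAL)
        return hi if auc(hi)[0] >= 0.5 else build_roc(v, y, LOW_ABNORMAL)
    if direction not in (HIGH_ABNORMAL, LOW_ABNORMAL):
        raise ValueError(f"unknown direction {direction!r}")

    distinct = np.unique(v)
    if distinct.size == 1:
        warnings.warn(
            "all marker values identical; ROC degenerates to the diagonal",
            DegenerateRocWarning,
            stacklevel=2,
        )
    gap = 1.0 if distinct.size == 1 else float(distinct[1] - distinct[0])
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    below = distinct[0] - max(gap, 1.0) / 2.0
    above = distinct[-1] + max(
        1.0 if distinct.size == 1 else float(distinct[-1] - distinct[-2]), 1.0
    ) / 2.0
    if direction == HIGH_ABNORMAL:
        # most permissive first: threshold below the minimum flags everyone
        thresholds = np.concatenate(([below], mids, [above]))
        abnormal = v[None, :] >= thresholds[:, None]
    else:
        thresholds = np.concatenate(([above], mids[::-1], [below]))
        abnormal = v[None, :] <= thresholds[:, None]
    tpr = (abnormal & y).sum(axis=1) / n_pos
    fpr = (abnormal & ~y).sum(axis=1) / n_neg
    return RocCurve(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        direction=direction,
        n_pos=n_pos,
        n_neg=n_neg,
        values=v,
        labels=y,
    )


def auc(roc: RocCurve) -> tuple[float, float]:
    """Area under the curve and its p-value against the chance diagonal.

    The trapezoidal area equals U / (n_pos * n_neg) where U is the
    Mann-Whitney statistic of events vs non-events (ties counted 1/2); the
    p-value uses the tie-corrected normal approximation without continuity
    correction.
    """
    # integrate in fpr order; curve runs (1,1) -> (0,0) or reverse
    area = float(abs(np.trapezoid(roc.tpr, roc.fpr)))
    pos = roc.values[roc.labels]
    neg = roc.values[~roc.labels]
    if np.unique(roc.values).size == 1:
        return 0.5, 1.0
    if roc.direction == HIGH_ABNORMAL:
        res = stats.mannwhitneyu(
            pos, neg, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    else:
        res = stats.mannwhitneyu(
            neg, pos, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return area, float(res.pvalue)


def youden_cutoff(
    roc: RocCurve, marker: str = "", timepoint: str = ""
) -> CutoffSpec:
    """Cutoff maximizing J = Se + Sp - 1 over all candidate thresholds.

    Ties on J are broken toward the threshold flagging fewer subjects
    abnormal (the more specific rule), which is deterministic because the
    abnormal count is strictly monotone along the threshold ordering.
    """
    j = roc.tpr - roc.fpr
    best = np.flatnonzero(j >= j.max() - 1e-12)
    # thresholds are ordered most-permissive first, so the last tied index
    # flags the fewest subjects
    idx = int(best[-1])
    area, p = auc(roc)
    return CutoffSpec(
        marker=marker,
        timepoint=timepoint,
        cutoff=float(roc.thresholds[idx]),
        direction=roc.direction,
        youden_j=float(j[idx]),
        auc=area,
        auc_p=p,
    )


def diagnostic_metrics(values, labels, spec: CutoffSpec) -> DiagnosticMetrics:
    """Se/Sp/PPV/NPV of ``spec`` applied to ``values`` against ``labels``.

    The abnormal side is inclusive of the cutoff.  A zero denominator makes
    the corresponding predictive value ``None`` with a warning.
    """
    v, y = _as_clean_arrays(values, labels)
    if y.all() or not y.any():
        raise RocError("both outcome classes required")
    abnormal = v >= spec.cutoff if spec.direction == HIGH_ABNORMAL else v <= spec.cutoff
    table = ContingencyTable(
        tp=int((abnormal & y).sum()),
        fp=int((abnormal & ~y).sum()),
        fn=int((~abnormal & y).sum()),
        tn=int((~abnormal & ~y).sum()),
    )
    se = table.tp / (table.tp + table.fn)
    sp = table.tn / (table.tn + table.fp)
    if table.tp + table.fp == 0:
        warnings.warn("no subject called abnormal; PPV undefined", UndefinedMetricWarning, stacklevel=2)
        ppv = None
    else:
        ppv = 100.0 * table.tp / (table.tp + table.fp)
    if table.tn + table.fn == 0:
        warnings.warn("no subject called normal; NPV undefined", UndefinedMetricWarning, stacklevel=2)
        npv = None
    else:
        npv = 100.0 * table.tn / (table.tn + table.fn)
    return DiagnosticMetrics(table=table, sensitivity=se, specificity=sp, ppv=ppv, npv=npv)


def truncate2(x: float) -> float:
    """Truncate toward zero at two decimals — display layer only.

    Published percentages and ratios here are truncated, not rounded
    (e.g. 81.8181... prints as 81.81), so comparisons against printed
    values must truncate too.  Never used inside computations.
    """
    if not math.isfinite(x):
        raise ValueError(f"cannot truncate {x!r}")
    scaled = round(x * 100.0, 6)  # shave float representation error first
    return math.trunc(scaled) / 100.0
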