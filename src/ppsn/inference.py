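"""Association statistics: 2x2 tables, odds ratios, logistic fits, group tests.

The 2x2 layout is exposure (abnormal marker / high score) by outcome
(event): ``tp`` exposed events, ``fp`` exposed non-events, ``fn`` unexposed
events, ``tn`` unexposed non-events.  Odds ratios use the cross-product
with Wald (log-scale normal) confidence intervals; the Haldane-Anscombe 0.5
correction is applied only when a cell is zero.  Logistic regression is
Newton-Raphson maximum likelihood (via statsmodels) with Wald z-tests, so
for a single binary predictor exp(slope) reproduces the cross-product odds
ratio exactly.

Two-group comparisons follow the branching rule common in clinical reports:
Shapiro-Wilk normality on each group, Student t when both pass, otherwise
Mann-Whitney U with the tie-corrected normal approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "ContingencyTable",
    "OddsRatioResult",
    "LogisticFit",
    "GroupComparison",
    "SeparationError",
    "SmallGroupWarning",
    "contingency_2x2",
    "odds_ratio_wald",
    "logistic_fit",
    "compare_groups",
    "rank_correlation",
]

_Z975 = 1.959963984540054  # standard normal 97.5th percentile


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a logistic fit."""


class SmallGroupWarning(UserWarning):
    """A comparison group is too small for a normality assessment."""


@dataclass(frozen=True)
class ContingencyTable:
    """Exposure x outcome cross-tabulation.

    tp = exposed events, fp = exposed non-events, fn = unexposed events,
    tn = unexposed non-events.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        cells = (self.tp, self.fp, self.fn, self.tn)
        if any(c < 0 for c in cells):
            raise ValueError("contingency cells must be non-negative")
        if sum(cells) == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class OddsRatioResult:
    """Cross-product odds ratio with a 95% Wald interval.

    ``corrected`` records whether the 0.5 zero-cell correction was used.
    """

    or_point: float
    ci_low: float
    ci_high: float
    p: float
    corrected: bool

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("Wald CI must contain the point estimate")


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic regression result.

    ``coefficients`` are log-odds per design column; ``se``, ``z`` and
    ``p`` are the Wald statistics; ``covariance`` is the inverse observed
    information at the optimum.
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    converged: bool
    n_iter: int
    n_obs: int

    def odds_ratios(self) -> list[OddsRatioResult]:
        """exp(beta) with 95% Wald bounds, one entry per design column."""
        out = []
        for b, s, p in zip(self.coefficients, self.se, self.p):
            out.append(
                OddsRatioResult(
                    or_point=math.exp(b),
                    ci_low=math.exp(b - _Z975 * s),
                    ci_high=math.exp(b + _Z975 * s),
                    p=float(p),
                    corrected=False,
                )
            )
        return out


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison with the routing decision recorded."""

    statistic: float
    p: float
    test_used: str  # "t" or "mann-whitney"


def _paired_mask(a, b) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(
        [math.nan if v is None else float(v) for v in a], dtype=float
    )
    y = np.asarray(
        [math.nan if v is None else float(v) for v in b], dtype=float
    )
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def contingency_2x2(exposure, outcome) -> ContingencyTable:
    """Cross-tabulate booleans; pairs with a missing member are dropped."""
    e, o = _paired_mask(
        [None if v is None else bool(v) for v in exposure],
        [None if v is None else bool(v) for v in outcome],
    )
    if e.size == 0:
        raise ValueError("no complete exposure/outcome pairs")
    eb = e.astype(bool)
    ob = o.astype(bool)
    return ContingencyTable(
        tp=int((eb & ob).sum()),
        fp=int((eb & ~ob).sum()),
        fn=int((~eb & ob).sum()),
        tn=int((~eb & ~ob).sum()),
    )


def odds_ratio_wald(table: ContingencyTable) -> OddsRatioResult:
    """OR = (tp*tn)/(fp*fn) with 95% Wald CI and Wald p-value.

    A zero cell triggers the Haldane-Anscombe correction (0.5 added to
    every cell, flagged in the result).  Two zero cells on the same
    diagonal leave the OR undefined and raise.
    """
    if (table.tp == 0 and table.tn == 0) or (table.fp == 0 and table.fn == 0):
        raise ValueError("odds ratio undefined: both cells of a diagonal are zero")
    a, b, c, d = (float(x) for x in (table.tp, table.fp, table.fn, table.tn))
    corrected = False
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    return OddsRatioResult(
        or_point=math.exp(log_or),
        ci_low=math.exp(log_or - _Z975 * se),
        ci_high=math.exp(log_or + _Z975 * se),
        p=2.0 * stats.norm.sf(abs(z)),
        corrected=corrected,
    )


def logistic_fit(
    design,
    outcome,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Newton-Raphson logistic regression of a boolean outcome on ``design``.

    The caller supplies the design matrix including any intercept column.
    Raises :class:`SeparationError` when a coefficient diverges
    (|beta| > 15, the fingerprint of complete separation) and
    ``RuntimeError`` on non-convergence.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.min() == y.max():
        raise ValueError("outcome is constant; logistic model undefined")
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns en route to separation
        try:
            res = model.fit(method="newton", maxiter=max_iter, tol=tol, disp=False)
        except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
            raise SeparationError(str(exc)) from exc
    params = np.asarray(res.params, dtype=float)
    if np.any(np.abs(params) > 15.0):
        raise SeparationError(
            f"coefficient diverged (max |beta| = {np.abs(params).max():.2f}); "
            "data are (quasi-)completely separated"
        )
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        raise RuntimeError(
            f"logistic fit did not converge in {max_iter} iterations; "
            f"trace: {res.mle_retvals}"
        )
    cov = np.asarray(res.cov_params(), dtype=float)
    se = np.sqrt(np.diag(cov))
    z = params / se
    return LogisticFit(
        coefficients=params,
        covariance=cov,
        se=se,
        z=z,
        p=2.0 * stats.norm.sf(np.abs(z)),
        converged=converged,
        n_iter=int(res.mle_retvals.get("iterations", max_iter)),
        n_obs=int(y.size),
    )


def compare_groups(x, y, alpha: float = 0.05) -> GroupComparison:
    """Two-group comparison with a normality gate.

    Shapiro-Wilk is run on each group at ``alpha``; if both look normal a
    two-sided Student t-test (equal-variance) is used, otherwise the
    Mann-Whitney U with tie-corrected normal approximation.  Groups smaller
    than 3 force the rank test with a warning.
    """
    a = np.asarray([v for v in x if v is not None], dtype=float)
    b = np.asarray([v for v in y if v is not None], dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size < 3 or b.size < 3:
        warnings.warn(
            "group smaller than 3: normality not assessable, using Mann-Whitney",
            SmallGroupWarning,
            stacklevel=2,
        )
        normal = False
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # shapiro warns on ties/small range
            normal = (
                stats.shapiro(a).pvalue > alpha and stats.shapiro(b).pvalue > alpha
            )
    if normal:
        res = stats.ttest_ind(a, b)
        return GroupComparison(statistic=float(res.statistic), p=float(res.pvalue), test_used="t")
    if np.unique(np.concatenate([a, b])).size == 1:
        return GroupComparison(statistic=float(a.size * b.size / 2), p=1.0, test_used="mann-whitney")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return GroupComparison(statistic=float(res.statistic), p=float(res.pvalue), test_used="mann-whitney")


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with tie handling; two-sided t-approx p."""
    a, b = _paired_mask(x, y)
    if a.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.unique(a).size == 1 or np.unique(b).size == 1:
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
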