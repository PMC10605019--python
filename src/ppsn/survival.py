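"""Kaplan-Meier estimation, the log-rank test, and horizon restriction.

Overall survival (OS) is time from the start of first treatment to death;
progression-free survival (PFS) to recurrence or death, whichever first.
Horizon-restricted analyses (3-year = 1095 days, 5-year = 1825 days)
administratively censor follow-up at the horizon; the companion binary
endpoint (used by the horizon logistic models) counts events within the
horizon as positive, subjects followed event-free beyond it as negative,
and excludes subjects censored alive before the horizon, reporting how
many were excluded.

Ties between events and censorings at the same time follow the standard
product-limit convention: events first, censored subjects leave the risk
set afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalData",
    "KMCurve",
    "LogRankResult",
    "HorizonOutcome",
    "km_estimate",
    "log_rank",
    "restrict_horizon",
    "horizon_binary_outcome",
    "YEARS_3",
    "YEARS_5",
]

YEARS_3 = 1095.0
YEARS_5 = 1825.0


@dataclass(frozen=True)
class SurvivalData:
    """Follow-up times (days > 0), event indicators, optional group labels."""

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=bool)
        if t.ndim != 1 or t.shape != e.shape:
            raise ValueError("time and event must be 1-D and equal length")
        if t.size == 0:
            raise ValueError("empty survival data")
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("times must be finite and positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)
        if self.group is not None:
            g = np.asarray(self.group)
            if g.shape != t.shape:
                raise ValueError("group labels must match time length")
            object.__setattr__(self, "group", g)

    def subset(self, mask: np.ndarray) -> "SurvivalData":
        return SurvivalData(
            time=self.time[mask],
            event=self.event[mask],
            group=None if self.group is None else self.group[mask],
        )


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate over the distinct event times of one group."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: int
    n_subjects: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_rows(self, group: str = "") -> list[dict[str, object]]:
        return [
            {
                "time": float(t),
                "survival": float(s),
                "at_risk": int(r),
                "events": int(d),
                "group": group,
            }
            for t, s, r, d in zip(
                self.event_times, self.survival, self.at_risk, self.n_events
            )
        ]


@dataclass(frozen=True)
class LogRankResult:
    """Unweighted two-group log-rank test (1 degree of freedom)."""

    chi2: float
    p: float
    observed: tuple[float, float]
    expected: tuple[float, float]
    groups: tuple[str, str]


def km_estimate(data: SurvivalData) -> KMCurve:
    """Kaplan-Meier product-limit estimator for a single group.

    S(t) multiplies (1 - d_j / n_j) over event times t_j <= t, with n_j the
    number at risk just before t_j (events precede censorings at ties).
    """
    order = np.argsort(data.time, kind="stable")
    t = data.time[order]
    e = data.event[order]
    n = t.size
    event_times: list[float] = []
    survival: list[float] = []
    at_risk: list[int] = []
    n_events: list[int] = []
    s = 1.0
    i = 0
    while i < n:
        tj = t[i]
        j = i
        d = 0
        while j < n and t[j] == tj:
            d += int(e[j])
            j += 1
        risk = n - i
        if d > 0:
            s *= 1.0 - d / risk
            event_times.append(float(tj))
            survival.append(s)
            at_risk.append(risk)
            n_events.append(d)
        i = j
    return KMCurve(
        event_times=np.asarray(event_times),
        survival=np.asarray(survival),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(n_events, dtype=int),
        n_censored=int((~data.event).sum()),
        n_subjects=n,
    )


def log_rank(data: SurvivalData, groups: tuple[object, object] | None = None) -> LogRankResult:
    """Unweighted log-rank comparison of two groups.

    At each distinct event time the expected events in group 1 follow the
    hypergeometric mean d * n1/n with variance
    d * (n1/n) * (1 - n1/n) * (n - d)/(n - 1); the statistic is
    (O1 - E1)^2 / V with a chi-square(1) p-value.
    """
    if data.group is None:
        raise ValueError("survival data carry no group labels")
    labels = groups if groups is not None else tuple(np.unique(data.group)[:2])
    if len(labels) != 2:
        raise ValueError("log-rank here compares exactly two groups")
    m1 = data.group == labels[0]
    m2 = data.group == labels[1]
    if not m1.any() or not m2.any():
        raise ValueError(f"empty group among {labels!r}")
    t = data.time
    e = data.event
    event_times = np.unique(t[e & (m1 | m2)])
    o1 = e1 = v = 0.0
    o2 = e2 = 0.0
    for tj in event_times:
        at_risk1 = ((t >= tj) & m1).sum()
        at_risk2 = ((t >= tj) & m2).sum()
        nj = at_risk1 + at_risk2
        d1 = int((e & m1 & (t == tj)).sum())
        d2 = int((e & m2 & (t == tj)).sum())
        dj = d1 + d2
        o1 += d1
        o2 += d2
        e1 += dj * at_risk1 / nj
        e2 += dj * at_risk2 / nj
        if nj > 1:
            v += dj * (at_risk1 / nj) * (1 - at_risk1 / nj) * (nj - dj) / (nj - 1)
    chi2 = 0.0 if v == 0.0 else (o1 - e1) ** 2 / v
    return LogRankResult(
        chi2=float(chi2),
        p=float(stats.chi2.sf(chi2, df=1)) if v > 0 else 1.0,
        observed=(o1, o2),
        expected=(e1, e2),
        groups=(str(labels[0]), str(labels[1])),
    )


def restrict_horizon(data: SurvivalData, horizon: float) -> SurvivalData:
    """Administrative censoring at ``horizon`` days.

    Follow-up beyond the horizon is cut to the horizon and the subject
    becomes a non-event there; ``horizon=inf`` is the identity.  Idempotent,
    and composing two restrictions equals restricting at the smaller
    horizon.
    """
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    if math.isinf(horizon):
        return data
    beyond = data.time > horizon
    return SurvivalData(
        time=np.where(beyond, horizon, data.time),
        event=np.where(beyond, False, data.event),
        group=data.group,
    )


@dataclass(frozen=True)
class HorizonOutcome:
    """Binary within-horizon endpoint with exclusion bookkeeping."""

    event: np.ndarray          # within-horizon event indicator, included subjects
    included: np.ndarray       # boolean mask into the original data
    n_excluded: int            # censored alive before the horizon


def horizon_binary_outcome(data: SurvivalData, horizon: float) -> HorizonOutcome:
    """Dichotomize survival at a horizon.

    Event within the horizon -> positive; event-free follow-up reaching the
    horizon -> negative; censored alive before the horizon -> excluded
    (cannot be classified either way).
    """
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    if math.isinf(horizon):
        return HorizonOutcome(
            event=data.event.copy(),
            included=np.ones_like(data.event, dtype=bool),
            n_excluded=0,
        )
    positive = data.event & (data.time <= horizon)
    negative = (data.time > horizon) | ((data.time == horizon) & ~data.event)
    included = positive | negative
    if not included.any():
        raise ValueError("every subject censored before the horizon; endpoint empty")
    return HorizonOutcome(
        event=positive[included],
        included=included,
        n_excluded=int((~included).sum()),
    )
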