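"""Endpoint construction and survival analysis.

Event-free survival (EFS) runs from diagnosis to the first major adverse
event — relapse after remission, failure to achieve remission, death from
any cause, treatment abandonment, a second malignancy, or transfer to
another hospital.  Overall survival (OS) runs from diagnosis to death;
patients who abandoned treatment are counted as OS events at their last
follow-up date (abandonment in this setting overwhelmingly follows
relapse or refractory disease), and patients lost to follow-up are
censored at last known contact.

Kaplan-Meier estimation (Greenwood variance, log-log 95% CI), the
log-rank test and Cox proportional-hazards regression (Efron ties) are
provided through lifelines behind a stable result surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test

#: Event types that qualify as an EFS event.
EFS_EVENT_TYPES = frozenset({
    "relapse", "induction_failure", "death", "abandonment",
    "second_malignancy", "transfer",
})


@dataclass
class FollowUpLog:
    """Raw per-patient event log: (event_type, years_from_diagnosis)."""

    sample_id: str
    events: tuple = ()                  # ordered or not; sorted internally
    last_contact: float = 0.0

    def __post_init__(self):
        for etype, t in self.events:
            if t < 0:
                raise ValueError(f"{self.sample_id}: event {etype} before diagnosis (t={t})")
            if etype not in EFS_EVENT_TYPES:
                raise ValueError(f"{self.sample_id}: unknown event type {etype!r}")
        if self.last_contact < 0:
            raise ValueError(f"{self.sample_id}: negative last_contact")


@dataclass
class Endpoints:
    sample_id: str
    efs_time: float
    efs_event: bool
    os_time: float
    os_event: bool
    abandonment: bool


def build_endpoints(log: FollowUpLog) -> Endpoints:
    """Derive EFS/OS endpoint fields from a raw follow-up log.

    EFS: event at the first qualifying adverse event, else censored at
    last contact.  OS: event at death; abandonment counts as an OS event
    dated at last follow-up; otherwise censored at last contact.
    """
    events = sorted(log.events, key=lambda e: e[1])
    abandonment = any(e == "abandonment" for e, _ in events)
    death_t = min((t for e, t in events if e == "death"), default=None)

    if events:
        efs_time, efs_event = events[0][1], True
    else:
        efs_time, efs_event = log.last_contact, False

    if death_t is not None:
        os_time, os_event = death_t, True
    elif abandonment:
        # abandonment: OS event at the last follow-up date
        os_time, os_event = log.last_contact, True
    else:
        os_time, os_event = log.last_contact, False

    if efs_time > os_time:
        efs_time = os_time  # first adverse event cannot postdate the OS endpoint
    return Endpoints(log.sample_id, efs_time, efs_event, os_time, os_event,
                     abandonment)


# --------------------------------------------------------------------------
# Kaplan-Meier
# --------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    times: np.ndarray                    # distinct event times (plus t=0)
    survival: np.ndarray                 # S(t) step values at `times`
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    variance: np.ndarray                 # Greenwood variance of S(t)
    degenerate: bool = False

    def at(self, t: float) -> float:
        """S(t) by the last step value at or before t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def rate_at(self, t: float) -> tuple[float, float, float]:
        """(S(t), ci_lower, ci_upper) at time t."""
        idx = max(np.searchsorted(self.times, t, side="right") - 1, 0)
        return (float(self.survival[idx]), float(self.ci_lower[idx]),
                float(self.ci_upper[idx]))


def km_estimate(times: Sequence[float], events: Sequence[bool],
                alpha: float = 0.05) -> SurvivalCurve:
    """Product-limit estimate with Greenwood variance and log-log CI."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty sample")
    if (times < 0).any():
        raise ValueError("negative survival times")
    degenerate = bool((times == 0).all() and (~events).all())

    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, events)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_survival_function_
    grid = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    lo = ci.iloc[:, 0].to_numpy(dtype=float)
    hi = ci.iloc[:, 1].to_numpy(dtype=float)

    # Greenwood variance of S(t): S^2 * sum d/(n(n-d)) over event times <= t
    order = np.argsort(grid)
    at_risk = np.array([int((times >= t).sum()) for t in grid])
    gw = np.zeros_like(s)
    acc = 0.0
    for i, t in enumerate(grid):
        d = int(((times == t) & events).sum())
        n = at_risk[i]
        if d > 0 and n > d:
            acc += d / (n * (n - d))
        elif d > 0 and n == d:
            acc = np.inf
        gw[i] = s[i] ** 2 * acc if np.isfinite(acc) else 0.0
    _ = order
    return SurvivalCurve(grid, s, np.clip(lo, 0, 1), np.clip(hi, 0, 1),
                         at_risk, gw, degenerate)


# --------------------------------------------------------------------------
# Log-rank
# --------------------------------------------------------------------------

@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    df: int


def logrank(times: Sequence[float], events: Sequence[bool],
            groups: Sequence) -> LogrankResult:
    """Standard (unweighted) log-rank test over >=2 groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("log-rank needs >=2 groups")
    if (counts == 0).any():
        raise ValueError("empty group")
    res = multivariate_logrank_test(times, groups, events)
    return LogrankResult(float(res.test_statistic), float(res.p_value),
                         int(labels.size - 1))


def logrank_two(times_a, events_a, times_b, events_b) -> LogrankResult:
    res = _ll_logrank(times_a, times_b, events_a, events_b)
    return LogrankResult(float(res.test_statistic), float(res.p_value), 1)


# --------------------------------------------------------------------------
# Cox proportional hazards
# --------------------------------------------------------------------------

@dataclass
class CoxResult:
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p_values: pd.Series
    coefs: pd.Series
    log_likelihood: float
    ties: str = "efron"

    def hr(self, covariate: str) -> float:
        return float(self.hazard_ratios[covariate])


def cox_fit(table: pd.DataFrame, duration_col: str = "time",
            event_col: str = "event", ties: str = "efron") -> CoxResult:
    """Cox PH fit (partial likelihood, Wald CIs) over the covariate table.

    All columns other than the duration/event columns enter as covariates.
    Constant covariates are rejected up front; lifelines raises (with its
    iteration trace) on non-convergence or complete separation.
    """
    covs = [c for c in table.columns if c not in (duration_col, event_col)]
    if not covs:
        raise ValueError("no covariates")
    for c in covs:
        if table[c].nunique() <= 1:
            raise ValueError(f"constant covariate: {c}")
    if int(table[event_col].sum()) < 1:
        raise ValueError("no events")
    cph = CoxPHFitter()
    cph.fit(table, duration_col=duration_col, event_col=event_col)
    summ = cph.summary
    return CoxResult(
        hazard_ratios=summ["exp(coef)"],
        ci_lower=summ["exp(coef) lower 95%"],
        ci_upper=summ["exp(coef) upper 95%"],
        p_values=summ["p"],
        coefs=summ["coef"],
        log_likelihood=float(cph.log_likelihood_),
        ties=ties,
    )
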