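"""Endpoint rules, Kaplan-Meier, log-rank and Cox regression."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from pedaml import (
    FollowUpLog,
    build_endpoints,
    cox_fit,
    km_estimate,
    logrank,
    logrank_two,
)


# --------------------------------------------------------------- endpoints

def test_relapse_then_death():
    ep = build_endpoints(FollowUpLog("P", (("relapse", 1.2), ("death", 2.0)), 2.0))
    assert (ep.efs_time, ep.efs_event) == (1.2, True)
    assert (ep.os_time, ep.os_event) == (2.0, True)


def test_abandonment_is_event_for_both_endpoints():
    ep = build_endpoints(FollowUpLog("P", (("abandonment", 0.8),), 0.8))
    assert (ep.efs_time, ep.efs_event) == (0.8, True)
    assert (ep.os_time, ep.os_event) == (0.8, True)
    assert ep.abandonment


def test_alive_in_remission_censored():
    ep = build_endpoints(FollowUpLog("P", (), 6.0))
    assert not ep.efs_event and not ep.os_event
    assert ep.efs_time == ep.os_time == 6.0


def test_event_before_diagnosis_rejected():
    with pytest.raises(ValueError, match="before diagnosis"):
        FollowUpLog("P", (("relapse", -0.1),), 1.0)


# ------------------------------------------------------------ Kaplan-Meier

def test_km_no_events_flat_one():
    c = km_estimate([1, 2, 3], [False, False, False])
    assert c.at(0) == 1.0 and c.at(10) == 1.0


def test_km_hand_worked_product_limit():
    # events at 1 and 2, censor at 3, event at 4, censor at 5:
    # S(4) = (4/5)(3/4)(1/2) = 0.3
    c = km_estimate([1, 2, 3, 4, 5], [True, True, False, True, False])
    assert c.at(4) == pytest.approx(0.3)
    assert c.at(1) == pytest.approx(0.8)
    assert c.at(3.9) == pytest.approx(0.6)


def test_km_without_censoring_is_empirical_survival(rng):
    times = rng.exponential(2.0, size=60)
    c = km_estimate(times, np.ones(60, bool))
    for t in (0.5, 1.0, 3.0):
        assert c.at(t) == pytest.approx((times > t).mean())


def test_km_monotone_and_ci_bounds(rng):
    times = rng.exponential(3.0, 100)
    events = rng.random(100) < 0.7
    c = km_estimate(times, events)
    assert (np.diff(c.survival) <= 1e-12).all()
    assert ((0 <= c.ci_lower) & (c.ci_lower <= c.ci_upper) & (c.ci_upper <= 1)).all()


def test_km_exponential_recovery(rng):
    # lambda calibrated to S(5)=0.849; KM at 5 within 3 Greenwood SE
    lam = -math.log(0.849) / 5
    n = 4000
    t = rng.exponential(1 / lam, n)
    cens = rng.uniform(2, 12, n)
    obs = np.minimum(t, cens)
    ev = t <= cens
    c = km_estimate(obs, ev)
    idx = max(np.searchsorted(c.times, 5.0, side="right") - 1, 0)
    se = math.sqrt(c.variance[idx])
    assert abs(c.at(5.0) - 0.849) < 3 * se


# ---------------------------------------------------------------- log-rank

def test_logrank_identical_groups():
    t = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
    e = [True] * 10
    g = ["a"] * 5 + ["b"] * 5
    r = logrank(t, e, g)
    assert r.statistic == pytest.approx(0.0, abs=1e-9)
    assert r.p_value == pytest.approx(1.0)


def test_logrank_requires_two_nonempty_groups():
    with pytest.raises(ValueError):
        logrank([1, 2], [True, True], ["a", "a"])


def _np_logrank_stat(times, events, mask):
    """Independent numpy log-rank statistic (group indicator `mask`)."""
    times = np.asarray(times, float); events = np.asarray(events, bool)
    stat_num = 0.0; var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum(); n1 = (at_risk & mask).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & mask).sum()
        stat_num += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return stat_num ** 2 / var if var > 0 else 0.0


def test_logrank_against_permutation_oracle(rng):
    n = 20
    times = np.concatenate([rng.exponential(1.0, 10), rng.exponential(3.0, 10)])
    events = rng.random(n) < 0.8
    mask = np.arange(n) < 10
    obs = _np_logrank_stat(times, events, mask)
    r = logrank_two(times[mask], events[mask], times[~mask], events[~mask])
    assert r.statistic == pytest.approx(obs, rel=1e-6)
    perm = np.empty(2000)
    for i in range(2000):
        m = np.zeros(n, bool)
        m[rng.choice(n, 10, replace=False)] = True
        perm[i] = _np_logrank_stat(times, events, m)
    p_perm = (1 + (perm >= obs - 1e-12).sum()) / (len(perm) + 1)
    ci = 3 * math.sqrt(p_perm * (1 - p_perm) / len(perm))
    assert abs(r.p_value - p_perm) < max(ci, 0.02)


def test_logrank_invariant_under_monotone_time_transform(rng):
    times = rng.exponential(1.0, 40)
    events = rng.random(40) < 0.7
    g = np.repeat(["a", "b"], 20)
    r1 = logrank(times, events, g)
    r2 = logrank(np.log1p(times), events, g)
    assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)


# --------------------------------------------------------------------- Cox

def test_cox_identical_groups_hr_near_one(rng):
    t = rng.exponential(1.0, 200)
    df = pd.DataFrame({"time": np.concatenate([t, t]),
                       "event": True,
                       "x": np.repeat([0, 1], 200)})
    res = cox_fit(df)
    assert res.hr("x") == pytest.approx(1.0, abs=0.02)
    assert res.ci_lower["x"] < 1.0 < res.ci_upper["x"]


def test_cox_rejects_constant_covariate_and_no_events():
    df = pd.DataFrame({"time": [1, 2], "event": [True, True], "x": [1, 1]})
    with pytest.raises(ValueError, match="constant"):
        cox_fit(df)
    df2 = pd.DataFrame({"time": [1, 2], "event": [False, False], "x": [0, 1]})
    with pytest.raises(ValueError, match="events"):
        cox_fit(df2)


def test_cox_matches_brute_force_partial_likelihood():
    """<=8-subject fixture, distinct event times: maximize the partial
    likelihood directly and compare the coefficient to 1e-6."""
    times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
    events = [1, 1, 0, 1, 1, 0, 1, 1]
    x = np.array([1, 0, 1, 1, 0, 0, 1, 0], float)

    def neg_pl(beta):
        ll = 0.0
        for i, (t, e) in enumerate(zip(times, events)):
            if not e:
                continue
            risk = [j for j, tj in enumerate(times) if tj >= t]
            ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
        return -ll

    brute = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                            options={"xatol": 1e-10})
    df = pd.DataFrame({"time": times, "event": events, "x": x})
    res = cox_fit(df)
    assert res.coefs["x"] == pytest.approx(brute.x, abs=1e-6)


def test_cox_consistent_under_covariate_rescaling(rng):
    n = 300
    x = rng.random(n)
    t = rng.exponential(np.exp(-0.7 * x))
    df = pd.DataFrame({"time": t, "event": True, "x": x})
    b1 = cox_fit(df).coefs["x"]
    df2 = df.assign(x=df.x * 10)
    b2 = cox_fit(df2).coefs["x"]
    assert b2 == pytest.approx(b1 / 10, rel=1e-4)


def test_cox_recovers_planted_hazard_ratio(rng):
    n = 1000
    grp = np.repeat([0, 1], n // 2)
    lam = 0.2 * np.where(grp == 1, 2.0, 1.0)
    t = rng.exponential(1 / lam)
    cens = rng.uniform(2, 15, n)
    df = pd.DataFrame({"time": np.minimum(t, cens), "event": t <= cens,
                       "x": grp})
    hr = cox_fit(df).hr("x")
    assert 1.7 < hr < 2.35
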