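"""Independent brute-force oracles used to validate the survival machinery.

Everything here is deliberately naive: explicit risk-set loops for the
product-limit estimator and the log-rank statistic, and a Cox partial
log-likelihood written directly from its definition and maximized with
scipy's bounded scalar minimizer (derivative-free), with a
finite-difference information for the Wald p. None of it shares code with
the package's implementations.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar


def km_brute_force(times, events):
    """Product-limit S(t) at distinct event times via explicit risk sets.

    Returns (event_times, surv, n_at_risk, median).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    ev_times = sorted(set(times[events == 1]))
    surv, risk = [], []
    s = 1.0
    for tau in ev_times:
        at_risk = int(np.sum(times >= tau))
        d = int(np.sum((times == tau) & (events == 1)))
        s *= 1.0 - d / at_risk
        surv.append(s)
        risk.append(at_risk)
    median = None
    for tau, sv in zip(ev_times, surv):
        if sv <= 0.5 + 1e-9:  # tolerance: curves hitting 0.5 exactly
            median = tau
            break
    return np.array(ev_times), np.array(surv), np.array(risk), median


def logrank_brute_force(times, events, group):
    """Two-group log-rank chi-square via observed-minus-expected loops."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group).astype(int)
    o_minus_e, var = 0.0, 0.0
    for tau in sorted(set(times[events == 1])):
        at_risk = times >= tau
        n = int(at_risk.sum())
        n1 = int((at_risk & (group == 1)).sum())
        dead = (times == tau) & (events == 1)
        d = int(dead.sum())
        d1 = int((dead & (group == 1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, float(stats.chi2.sf(chi2, df=1))


def efron_loglik_naive(beta, x, times, events):
    """Efron partial log-likelihood, written out term by term."""
    x = np.asarray(x, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    r = np.exp(beta * x)
    ll = 0.0
    for tau in sorted(set(times[events == 1])):
        dead = (times == tau) & (events == 1)
        at_risk = times >= tau
        d = int(dead.sum())
        sum_risk = r[at_risk].sum()
        sum_tied = r[dead].sum()
        ll += beta * x[dead].sum()
        for ell in range(d):
            ll -= np.log(sum_risk - (ell / d) * sum_tied)
    return ll


BETA_BOUND = 14.0  # |log HR| beyond which a split counts as non-identifiable


def cox_mle_is_finite(x, times, events, bound=BETA_BOUND, h=1e-6):
    """The concave partial log-likelihood has an interior maximum iff its
    slope points inward at both ends of the search interval."""
    slope_hi = (
        efron_loglik_naive(bound + h, x, times, events)
        - efron_loglik_naive(bound - h, x, times, events)
    ) / (2 * h)
    slope_lo = (
        efron_loglik_naive(-bound + h, x, times, events)
        - efron_loglik_naive(-bound - h, x, times, events)
    ) / (2 * h)
    return slope_hi < 0 and slope_lo > 0


def cox_binary_naive(x, times, events, lo=-BETA_BOUND, hi=BETA_BOUND):
    """Derivative-free fit of the binary-covariate Cox model.

    Returns (beta, se, wald_p, hr); se from a central finite difference of
    the log-likelihood.
    """
    res = minimize_scalar(
        lambda b: -efron_loglik_naive(b, x, times, events),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    beta = float(res.x)
    h = 1e-4
    info = -(
        efron_loglik_naive(beta + h, x, times, events)
        - 2.0 * efron_loglik_naive(beta, x, times, events)
        + efron_loglik_naive(beta - h, x, times, events)
    ) / h**2
    se = 1.0 / np.sqrt(info)
    p = float(stats.chi2.sf((beta / se) ** 2, df=1))
    return beta, se, p, float(np.exp(beta))


def scan_brute_force(scores, times, events):
    """Exhaustive enumeration of every quartile-bounded split.

    Returns (cutoffs, p, hr) for the candidates where both groups contain
    events (the identifiable splits), computed entirely through the naive
    Cox route above.
    """
    scores = np.asarray(scores, float)
    q1, q3 = np.quantile(scores, [0.25, 0.75])
    cutoffs, ps, hrs = [], [], []
    for t in np.unique(scores):
        if not q1 <= t <= q3:
            continue
        x = (scores > t).astype(float)
        if x.sum() in (0, len(x)):
            continue
        ev1 = int(((x == 1) & (np.asarray(events) == 1)).sum())
        ev0 = int(((x == 0) & (np.asarray(events) == 1)).sum())
        if ev1 == 0 or ev0 == 0:
            continue
        if not cox_mle_is_finite(x, times, events):
            continue
        beta, se, p, hr = cox_binary_naive(x, times, events)
        cutoffs.append(float(t))
        ps.append(p)
        hrs.append(hr)
    return np.array(cutoffs), np.array(ps), np.array(hrs)


def select_brute_force(cutoffs, p, hr):
    """Minimum-p selection with strongest-|log HR| / lower-cutoff tie-break,
    re-derived independently by full enumeration."""
    best = None
    for i in range(len(cutoffs)):
        key = (p[i], -abs(np.log(hr[i])), cutoffs[i])
        if best is None or key < best[0]:
            best = (key, i)
    return best[1]


def bh_brute_force(p):
    """Step-up BH from the definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
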