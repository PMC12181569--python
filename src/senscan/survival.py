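"""Survival statistics and the quartile-bounded minimum-p cutoff scan.

The scan is the analysis' core statistic: a continuous per-sample score is
dichotomized at every distinct observed value between its lower and upper
quartiles; each split is tested with a Cox proportional-hazards model on
the binary high/low indicator (hazard ratio oriented high vs low, so
HR < 1 means longer survival with high scores); the split with the
smallest p-value is selected, ties broken by the strongest effect
(largest |log HR|), residual ties by the smaller cutoff; and the family
of per-cutoff p-values is Benjamini–Hochberg adjusted. Minimum-p
selection is anti-conservative by construction — the unadjusted selected
p overstates significance — which is exactly what the BH step addresses.

Kaplan–Meier estimation, the log-rank test, and general multi-covariate
Cox fits are delegated to lifelines. The per-cutoff fits instead use a
dedicated Newton solver for the single-binary-covariate Cox partial
likelihood (Efron or Breslow tie handling) built on per-event-time
aggregate counts: a scan touches thousands of fits, and for a binary
covariate the partial likelihood depends on the data only through risk-set
and tied-event counts per group, making each fit O(number of events).
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CoxResult, KMCurve, PipelineError, ScanResult

logger = logging.getLogger(__name__)


class ConvergenceError(PipelineError):
    """A Cox fit failed to converge (possible separation)."""


class DegenerateSplitError(PipelineError):
    """A candidate cutoff yields a split the Cox model cannot identify."""


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

def km_estimate(times, events) -> KMCurve:
    """Product-limit estimate over the distinct event times.

    The median is the smallest time at which S(t) drops to <= 0.5 and is
    ``None`` when the curve never reaches 0.5.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValueError("km_estimate needs at least one subject")
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    event_times = ev.index.to_numpy(float)
    surv = (
        kmf.survival_function_["KM_estimate"]
        .reindex(ev.index)
        .to_numpy(float)
    )
    n_at_risk = ev["at_risk"].to_numpy(int)
    # median = smallest t with S(t) <= 0.5 (lifelines' accessor uses a
    # strict inequality, which disagrees when the curve hits 0.5 exactly)
    reached = np.nonzero(surv <= 0.5 + 1e-9)[0]
    median = float(event_times[reached[0]]) if len(reached) else None
    return KMCurve(
        event_times=event_times,
        surv=surv,
        n_at_risk=n_at_risk,
        median_months=median,
    )


def km_frame(curve: KMCurve, group: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": curve.event_times,
            "surv": curve.surv,
            "n_at_risk": curve.n_at_risk,
            "group": group,
        }
    )


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def logrank_test(times, events, group) -> Tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group).astype(bool)
    if group.all() or (~group).all():
        raise ValueError("log-rank test needs two non-empty groups")
    res = _ll_logrank(
        times[group], times[~group], events[group], events[~group]
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# binary-covariate Cox partial likelihood (Efron / Breslow)
# ---------------------------------------------------------------------------

#: |log HR| beyond which a split is treated as non-identifiable
_BETA_BOUND = 14.0


class SurvivalData:
    """Sorted survival data with the event-time group structure precomputed.

    Reused across the candidate cutoffs of one scan: only the binary
    covariate changes between fits, and all partial-likelihood quantities
    reduce to per-event-time counts of the high group.
    """

    def __init__(self, times, events):
        times = np.asarray(times, float)
        events = np.asarray(events, int)
        if times.ndim != 1 or times.shape != events.shape:
            raise ValueError("times and events must be 1-D and aligned")
        if (times < 0).any() or not np.isfinite(times).all():
            raise ValueError("times must be finite and non-negative")
        if not np.isin(events, (0, 1)).all():
            raise ValueError("events must be binary")
        self.n = len(times)
        self.order = np.argsort(times, kind="stable")
        self.t = times[self.order]
        self.d = events[self.order]
        ev_mask = self.d == 1
        self.n_events = int(ev_mask.sum())
        # distinct event times tau_k with multiplicities d_k
        self.tau, self.dk = np.unique(self.t[ev_mask], return_counts=True)
        # risk set R_k = {i : t_i >= tau_k}; suffix start index per k
        self.risk_start = np.searchsorted(self.t, self.tau, side="left")
        self.n_risk = self.n - self.risk_start
        # flattened Efron fractions l/d_k, l = 0..d_k-1, with group pointers
        self.frac = (
            np.concatenate([np.arange(d) / d for d in self.dk])
            if len(self.dk)
            else np.empty(0)
        )
        self.flat_k = np.repeat(np.arange(len(self.dk)), self.dk)
        self.event_pos = np.nonzero(ev_mask)[0]
        self.event_k = np.searchsorted(self.tau, self.t[self.event_pos])

    def group_counts(self, x_sorted: np.ndarray):
        """Per-event-time at-risk and tied-event counts of the x==1 group."""
        suffix = np.concatenate(
            [np.cumsum(x_sorted[::-1])[::-1], [0.0]]
        )
        n1 = suffix[self.risk_start]
        m1 = np.bincount(
            self.event_k,
            weights=x_sorted[self.event_pos],
            minlength=len(self.tau),
        )
        return n1, m1


def _binary_derivatives(data: SurvivalData, n1, m1, beta, ties):
    """(loglik, score U, information I) of the binary-covariate model."""
    r = np.exp(beta)
    a = (data.n_risk - n1) + n1 * r
    da = n1 * r
    if ties == "efron":
        b = (data.dk - m1) + m1 * r
        db = m1 * r
        phi = a[data.flat_k] - data.frac * b[data.flat_k]
        dphi = da[data.flat_k] - data.frac * db[data.flat_k]
    else:  # breslow: every tied event sees the full risk set
        phi = np.repeat(a, data.dk)
        dphi = np.repeat(da, data.dk)
    w = dphi / phi
    loglik = beta * m1.sum() - np.log(phi).sum()
    score = m1.sum() - w.sum()
    info = (w * (1.0 - w)).sum()
    return loglik, score, info


def _binary_cox(
    data: SurvivalData,
    x: np.ndarray,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
):
    """Newton fit of the single binary covariate; returns (beta, se)."""
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    x_sorted = np.asarray(x, float)[data.order]
    if data.n_events == 0:
        raise DegenerateSplitError("no events")
    n1, m1 = data.group_counts(x_sorted)
    events_high = m1.sum()
    if events_high == 0 or events_high == data.n_events:
        raise DegenerateSplitError(
            "all events fall in one group (monotone likelihood)"
        )
    # the partial log-likelihood is concave in beta, so the MLE is finite
    # and inside (-BOUND, BOUND) iff the score points inward at both ends
    _, score_hi, _ = _binary_derivatives(data, n1, m1, _BETA_BOUND, ties)
    _, score_lo, _ = _binary_derivatives(data, n1, m1, -_BETA_BOUND, ties)
    if score_hi > 0 or score_lo < 0:
        raise DegenerateSplitError(
            "hazard ratio diverges at this split (separation)"
        )
    beta = 0.0
    for _ in range(max_iter):
        _, score, info = _binary_derivatives(data, n1, m1, beta, ties)
        if info <= 0:
            raise ConvergenceError("non-positive information")
        step = float(np.clip(score / info, -2.0, 2.0))
        beta = float(np.clip(beta + step, -_BETA_BOUND, _BETA_BOUND))
        if abs(step) < tol:
            break
    else:
        raise ConvergenceError("Newton iteration did not converge")
    _, _, info = _binary_derivatives(data, n1, m1, beta, ties)
    return float(beta), float(1.0 / np.sqrt(info))


def _wald(beta: float, se: float) -> Tuple[float, Tuple[float, float]]:
    z = beta / se
    p = float(stats.chi2.sf(z * z, df=1))
    half = 1.959963984540054 * se
    return p, (float(np.exp(beta - half)), float(np.exp(beta + half)))


def binary_cox_fit(
    group, times, events, ties: str = "efron"
) -> CoxResult:
    """Cox PH fit of a single binary indicator (e.g. high vs low score).

    HR is oriented hazard(group==1) / hazard(group==0). Raises
    :class:`DegenerateSplitError` when the likelihood is monotone (all
    events in one group) and :class:`ConvergenceError` when Newton fails.
    """
    group = np.asarray(group).astype(float)
    if not np.isin(group, (0.0, 1.0)).all():
        raise ValueError("group must be binary")
    if group.all() or not group.any():
        raise DegenerateSplitError("both groups must be non-empty")
    data = SurvivalData(times, events)
    beta, se = _binary_cox(data, group, ties=ties)
    p, ci = _wald(beta, se)
    return CoxResult(
        names=["group_high"],
        beta=np.array([beta]),
        se=np.array([se]),
        hr=np.array([np.exp(beta)]),
        ci95=np.array([ci]),
        p=np.array([p]),
        n_used=data.n,
        n_events=data.n_events,
        ties_method=ties,
    )


def cox_score_statistic(group, times, events, ties: str = "breslow") -> float:
    """Score statistic U(0)^2 / I(0) of the binary-covariate Cox model.

    With Breslow (or, equivalently on tie-free data, Efron) handling and
    no tied event times this equals the log-rank chi-square exactly.
    """
    group = np.asarray(group).astype(float)
    data = SurvivalData(times, events)
    n1, m1 = data.group_counts(group[np.argsort(np.asarray(times, float), kind="stable")])
    _, score, info = _binary_derivatives(data, n1, m1, 0.0, ties)
    if info <= 0:
        raise ValueError("degenerate score test (no information)")
    return float(score * score / info)


# ---------------------------------------------------------------------------
# general Cox fit (lifelines)
# ---------------------------------------------------------------------------

def cox_fit(
    covariates: pd.DataFrame,
    times,
    events,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 500,
) -> CoxResult:
    """Multi-covariate Cox PH fit (Newton on the Efron partial likelihood).

    Delegates to lifelines' ``CoxPHFitter`` (which implements exactly
    this). Non-convergence and separation surface as
    :class:`ConvergenceError` rather than silent output. Breslow ties are
    only available on the dedicated binary-covariate path
    (:func:`binary_cox_fit`).
    """
    if ties != "efron":
        raise ValueError("general cox_fit supports Efron ties only")
    covariates = pd.DataFrame(covariates).astype(float).reset_index(drop=True)
    if covariates.isna().any().any() or not np.isfinite(
        covariates.to_numpy()
    ).all():
        raise ValueError("covariates must be finite and complete")
    nunique = covariates.nunique()
    if (nunique <= 1).any():
        raise ValueError(
            f"constant covariate(s): {list(nunique[nunique <= 1].index)}"
        )
    df = covariates.copy()
    df["_time"] = np.asarray(times, float)
    df["_event"] = np.asarray(events, int)
    if df["_event"].sum() == 0:
        raise ValueError("cox_fit needs at least one event")
    cph = CoxPHFitter()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(
                df,
                duration_col="_time",
                event_col="_event",
                fit_options={
                    "precision": tol,
                    "max_steps": max_iter,
                },
            )
        except _LLConvergenceError as exc:
            raise ConvergenceError(str(exc)) from exc
    for w in caught:
        msg = str(w.message).lower()
        if "convergence" in msg and ("complete" in msg or "separat" in msg):
            raise ConvergenceError(str(w.message))
    se = cph.standard_errors_.to_numpy()
    if (se > 1e3).any():
        raise ConvergenceError(
            "implausibly large standard error (possible separation)"
        )
    beta = cph.params_.to_numpy()
    summary = cph.summary
    return CoxResult(
        names=list(cph.params_.index),
        beta=beta,
        se=se,
        hr=np.exp(beta),
        ci95=np.column_stack(
            [
                np.exp(summary["coef lower 95%"].to_numpy()),
                np.exp(summary["coef upper 95%"].to_numpy()),
            ]
        ),
        p=summary["p"].to_numpy(),
        n_used=len(df),
        n_events=int(df["_event"].sum()),
        ties_method="efron",
    )


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (capped at 1)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the cutoff scan
# ---------------------------------------------------------------------------

def cutoff_scan(
    scores,
    times,
    events,
    p_source: str = "cox",
    ties: str = "efron",
    quartile_bounds: Tuple[float, float] = (0.25, 0.75),
) -> ScanResult:
    """Scan every candidate cutoff between the score quartiles.

    Candidates are the distinct observed score values t with
    Q1 <= t <= Q3; the split puts score > t in the high group. Per cutoff
    the hazard ratio (high vs low) and p-value come from one binary Cox
    model (``p_source='logrank'`` swaps in the log-rank p; the HR still
    comes from the Cox fit). Degenerate candidates are skipped and logged;
    a scan with no valid candidate raises :class:`PipelineError`.
    """
    if p_source not in ("cox", "logrank"):
        raise ValueError("p_source must be 'cox' or 'logrank'")
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if not (len(scores) == len(times) == len(events)):
        raise ValueError("scores, times, events must be aligned")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if events.sum() == 0:
        raise PipelineError("cutoff scan needs at least one event")
    q1, q3 = np.quantile(scores, quartile_bounds)
    candidates = np.unique(scores)
    candidates = candidates[(candidates >= q1) & (candidates <= q3)]
    data = SurvivalData(times, events)

    kept, fits, skipped = [], [], []
    for t in candidates:
        x = (scores > t).astype(float)
        n_high = int(x.sum())
        if n_high == 0 or n_high == len(scores):
            skipped.append((float(t), "empty group"))
            continue
        try:
            beta, se = _binary_cox(data, x, ties=ties)
        except (DegenerateSplitError, ConvergenceError) as exc:
            skipped.append((float(t), str(exc)))
            continue
        wald_p, ci = _wald(beta, se)
        if p_source == "logrank":
            _, p = logrank_test(times, events, x.astype(bool))
        else:
            p = wald_p
        kept.append(t)
        fits.append((beta, se, p, ci, n_high))
    if not kept:
        raise PipelineError(
            "all candidate cutoffs degenerate; scores may be constant"
        )
    for t, reason in skipped:
        logger.info("cutoff %.6g skipped: %s", t, reason)

    cutoffs = np.asarray(kept, float)
    beta_at = np.array([f[0] for f in fits])
    se_at = np.array([f[1] for f in fits])
    p_at = np.array([f[2] for f in fits])
    n_high_at = np.array([f[4] for f in fits], int)
    n_low_at = len(scores) - n_high_at
    q_at = bh_adjust(p_at)

    selected_index = select_cutoff_index(cutoffs, p_at, beta_at)
    sel_beta, sel_se = beta_at[selected_index], se_at[selected_index]
    sel_p, sel_ci = _wald(sel_beta, sel_se)
    high = scores > cutoffs[selected_index]
    selected = CoxResult(
        names=["signature_high"],
        beta=np.array([sel_beta]),
        se=np.array([sel_se]),
        hr=np.array([np.exp(sel_beta)]),
        ci95=np.array([sel_ci]),
        p=np.array([p_at[selected_index]]),
        n_used=len(scores),
        n_events=int(events.sum()),
        ties_method=ties,
    )
    return ScanResult(
        cutoffs=cutoffs,
        p_at=p_at,
        hr_at=np.exp(beta_at),
        q_at=q_at,
        n_low_at=n_low_at,
        n_high_at=n_high_at,
        selected_index=int(selected_index),
        selected=selected,
        km_low=km_estimate(times[~high], events[~high]),
        km_high=km_estimate(times[high], events[high]),
        quartile_bounds=(float(q1), float(q3)),
        skipped_cutoffs=skipped,
    )


def select_cutoff_index(
    cutoffs: np.ndarray, p_at: np.ndarray, beta_at: np.ndarray
) -> int:
    """Minimum-p selection with the strongest-|log HR| then lower-cutoff
    tie-breaks (p ties are exact float ties)."""
    pmin = p_at.min()
    tied = np.nonzero(p_at == pmin)[0]
    if len(tied) == 1:
        return int(tied[0])
    strength = np.abs(beta_at[tied])
    strongest = tied[strength == strength.max()]
    return int(strongest[np.argmin(cutoffs[strongest])])
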