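"""Time-to-recurrence evaluation.

Recurrence-free survival is administratively censored at 10 years.  Model
predictions (binary risk group or continuous score) are evaluated with
Harrell's concordance index; two predictors on the same subjects are
compared with a jackknife test on the paired C-index difference;
association with recurrence is tested with a univariable Cox proportional
hazards model (Wald test) and the log-rank test; group-wise cumulative
recurrence is 1 - Kaplan-Meier.

The C-index pair rule used throughout: a pair is comparable iff the
strictly earlier time carries an event; all equal-time pairs are excluded;
predictor ties receive half credit.  The Cox partial likelihood uses
Breslow handling of tied event times and is maximised by Newton-Raphson
from beta = 0 (tolerance 1e-8 on the score, at most 50 iterations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .metrics import TestResult
from .risk import MEDIUM_HIGH_CUT

__all__ = [
    "SurvivalData",
    "CoxFit",
    "censor_at",
    "concordance_index",
    "compare_correlated_cindex",
    "cox_univariable",
    "logrank_test",
    "cumulative_recurrence",
    "threshold_continuous_predictions",
]


@dataclass
class SurvivalData:
    """Aligned follow-up times (years), event indicators and a predictor."""

    time: np.ndarray
    event: np.ndarray
    predictor: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event).astype(bool)
        self.predictor = np.asarray(self.predictor, dtype=float)
        if not (len(self.time) == len(self.event) == len(self.predictor)):
            raise ValueError("time, event and predictor must be aligned")
        if not np.all(np.isfinite(self.time)) or (self.time < 0).any():
            raise ValueError("times must be finite and non-negative")
        if not np.all(np.isfinite(self.predictor)):
            raise ValueError("predictor must be finite")

    def __len__(self) -> int:
        return len(self.time)


def censor_at(data: SurvivalData, horizon: float = 10.0) -> SurvivalData:
    """Administrative censoring: time := min(time, horizon).

    Events after the horizon become censored; events exactly at the horizon
    are kept as events ("within" the horizon).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    late = data.time > horizon
    return replace(
        data,
        time=np.minimum(data.time, horizon),
        event=np.where(late, False, data.event),
    )


def _pair_matrices(data: SurvivalData) -> tuple[np.ndarray, np.ndarray]:
    """Ordered-pair comparability and credit matrices (i = earlier subject)."""
    t, e, x = data.time, data.event, data.predictor
    comp = (t[:, None] < t[None, :]) & e[:, None]
    credit = comp * ((x[:, None] > x[None, :]) + 0.5 * (x[:, None] == x[None, :]))
    return comp, credit


def concordance_index(data: SurvivalData) -> float:
    """Harrell's C over comparable pairs (1 concordant, 1/2 predictor tie)."""
    comp, credit = _pair_matrices(data)
    n_comp = comp.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    return float(credit.sum() / n_comp)


def compare_correlated_cindex(data_a: SurvivalData, data_b: SurvivalData) -> TestResult:
    """Jackknife test on the paired difference of two concordance indices.

    Both datasets must carry the same subjects and outcomes and differ only
    in the predictor.  The variance of ``C_a - C_b`` is the leave-one-
    subject-out jackknife estimate (each jackknife replicate is computed by
    an O(1) update of the pair sums); the statistic is referred to the
    standard normal, two-sided.
    """
    if len(data_a) != len(data_b) or not np.array_equal(data_a.time, data_b.time) or not np.array_equal(
        data_a.event, data_b.event
    ):
        raise ValueError("correlated C comparison needs identical subjects and outcomes")
    n = len(data_a)

    def loo_curve(data: SurvivalData) -> tuple[float, np.ndarray]:
        comp, credit = _pair_matrices(data)
        s_d, s_c = comp.sum(), credit.sum()
        if s_d == 0:
            raise ValueError("no comparable pairs")
        d_k = comp.sum(axis=0) + comp.sum(axis=1)
        c_k = credit.sum(axis=0) + credit.sum(axis=1)
        denom = s_d - d_k
        if (denom <= 0).any():
            raise ValueError("jackknife undefined: a subject carries all comparable pairs")
        return float(s_c / s_d), (s_c - c_k) / denom

    c_a, loo_a = loo_curve(data_a)
    c_b, loo_b = loo_curve(data_b)
    delta = c_a - c_b
    loo = loo_a - loo_b
    var = (n - 1) / n * np.sum((loo - loo.mean()) ** 2)
    if var <= 0:
        if np.isclose(delta, 0.0):
            return TestResult(statistic=0.0, p_value=1.0, effect=float(delta))
        warnings.warn("zero jackknife variance with a nonzero C difference")
        return TestResult(statistic=np.inf, p_value=0.0, effect=float(delta), note="degenerate variance")
    z = delta / np.sqrt(var)
    return TestResult(statistic=float(z), p_value=float(2 * stats.norm.sf(abs(z))), effect=float(delta))


@dataclass
class CoxFit:
    """Univariable Cox proportional-hazards fit (Breslow ties, Wald test)."""

    coef: float
    se: float
    z: float
    p_value: float
    n: int
    n_events: int
    converged: bool = True
    note: str = ""

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.coef))

    def summary(self) -> str:
        return (
            "Univariable Cox PH (Breslow ties)\n"
            + "=" * 40
            + f"\nn = {self.n}, events = {self.n_events}"
            + f"\ncoef      {self.coef: .4f}"
            + f"\nHR        {self.hazard_ratio: .4f}"
            + f"\nse        {self.se: .4f}"
            + f"\nWald z    {self.z: .4f}"
            + f"\np         {self.p_value: .3g}"
            + ("" if self.converged else f"\nWARNING: did not converge ({self.note})")
        )


def _cox_derivatives(beta: float, t: np.ndarray, e: np.ndarray, x: np.ndarray):
    """Breslow partial log-likelihood derivatives at beta (single covariate)."""
    order = np.argsort(-t, kind="stable")
    ts, es, xs = t[order], e[order], x[order]
    w = np.exp(beta * xs)
    cum0 = np.cumsum(w)
    cum1 = np.cumsum(w * xs)
    cum2 = np.cumsum(w * xs**2)
    # risk set for an event at time u = all subjects with time >= u; with
    # descending sort that is the prefix up to the last index with time == u
    last_at_time = np.searchsorted(-ts, -ts, side="right") - 1
    ev = np.flatnonzero(es)
    s0 = cum0[last_at_time[ev]]
    s1 = cum1[last_at_time[ev]]
    s2 = cum2[last_at_time[ev]]
    score = float(np.sum(xs[ev] - s1 / s0))
    info = float(np.sum(s2 / s0 - (s1 / s0) ** 2))
    return score, info


def cox_univariable(data: SurvivalData) -> CoxFit:
    """Maximise the Breslow partial likelihood by Newton-Raphson.

    Monotone likelihood (perfect separation of events by the predictor) is
    reported as a flagged non-converged fit rather than an error.
    """
    t, e, x = data.time, data.event, data.predictor
    n_events = int(e.sum())
    if n_events < 1:
        raise ValueError("need at least one event")
    if np.std(x) == 0:
        raise ValueError("predictor is constant")

    beta = 0.0
    for _ in range(50):
        score, info = _cox_derivatives(beta, t, e, x)
        if info <= 0 or not np.isfinite(score):
            return CoxFit(beta, np.nan, np.nan, np.nan, len(t), n_events, False, "singular information")
        step = score / info
        beta += step
        if abs(beta) > 100:
            return CoxFit(beta, np.nan, np.nan, np.nan, len(t), n_events, False, "monotone likelihood")
        if abs(score) < 1e-8:
            break
    else:
        score, info = _cox_derivatives(beta, t, e, x)
        if abs(score) >= 1e-6:
            return CoxFit(beta, np.nan, np.nan, np.nan, len(t), n_events, False, "no convergence in 50 iterations")

    _, info = _cox_derivatives(beta, t, e, x)
    se = float(1.0 / np.sqrt(info))
    # monotone likelihood flattens the score at an arbitrarily large beta;
    # a huge coefficient or standard error marks the fit as unreliable
    if abs(beta) * np.std(x) > 15 or se * np.std(x) > 50:
        return CoxFit(float(beta), se, np.nan, np.nan, len(t), n_events, False, "monotone likelihood")
    z = beta / se
    return CoxFit(float(beta), se, float(z), float(2 * stats.norm.sf(abs(z))), len(t), n_events)


def logrank_test(data: SurvivalData, groups) -> TestResult:
    """Two-group log-rank test (chi-square on 1 df, two-sided)."""
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"log-rank needs exactly two non-empty groups, got {levels}")
    a = groups == levels[0]
    res = _ll_logrank(
        data.time[a], data.time[~a], event_observed_A=data.event[a], event_observed_B=data.event[~a]
    )
    return TestResult(statistic=float(res.test_statistic), p_value=float(res.p_value), effect=float(res.test_statistic))


def cumulative_recurrence(data: SurvivalData, groups) -> dict:
    """Cumulative recurrence (1 - Kaplan-Meier) step curves per group.

    Returns ``{group: (times, cumulative_incidence)}`` with the step value
    at each distinct time, starting at (0, 0).
    """
    groups = np.asarray(groups)
    curves = {}
    for g in np.unique(groups):
        sel = groups == g
        km = KaplanMeierFitter()
        km.fit(data.time[sel], data.event[sel])
        times = km.survival_function_.index.to_numpy(dtype=float)
        surv = km.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        curves[g] = (times, 1.0 - surv)
    return curves


def threshold_continuous_predictions(scores, threshold: float = MEDIUM_HIGH_CUT) -> np.ndarray:
    """Binarize continuous predictions at the assay's high-risk cutoff.

    A predicted score >= threshold is called high risk (1), else
    low/medium (0) — the basis of the categorical-vs-thresholded-continuous
    comparison.
    """
    scores = np.asarray(scores, dtype=float)
    binary = (scores >= threshold).astype(int)
    if len(np.unique(binary)) < 2:
        warnings.warn("thresholded predictions form a single group; downstream log-rank will be degenerate")
    return binary
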