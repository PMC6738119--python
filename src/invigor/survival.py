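"""Survival-analysis primitives: Kaplan-Meier, log-rank, Cox/AIC.

The Kaplan-Meier product-limit estimator and the two-group log-rank test
are implemented natively (the log-rank statistic is scanned over hundreds
of candidate cutpoints by the stratification stage, so a vectorised scan
is provided); Cox proportional-hazards fitting delegates to lifelines
with Efron tie handling, and AIC is reported as 2k - 2 log partial
likelihood. Death from breast cancer is the event; everything else is
censored. A fixed analysis horizon (10-year BCSS, 120 months) is applied
as administrative censoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, DataError


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group.

    Defined at the observed event times; conceptually starts at S(0) = 1.
    """

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk_counts: np.ndarray
    events: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """S(t): survival probability at time ``t`` (right-continuous step)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probs[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival_probs,
                "at_risk": self.at_risk_counts,
                "events": self.events,
            }
        )


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    observed_events: tuple[float, float]
    expected_events: tuple[float, float]


@dataclass
class CoxFit:
    coefficients: pd.Series
    hazard_ratios: pd.Series
    p_values: pd.Series
    log_partial_likelihood: float
    aic: float
    n_params: int
    n: int
    n_events: int
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "hazard_ratio": self.hazard_ratios,
                "p": self.p_values,
            }
        )


def _as_arrays(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if time.shape != event.shape:
        raise DataError("time and event must have the same length")
    if np.any(time < 0):
        raise DataError("survival times must be non-negative")
    if not np.isin(event, (0.0, 1.0)).all():
        raise DataError("event indicator must be 0 or 1")
    return time, event.astype(int)


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimate for a single group."""
    time, event = _as_arrays(time, event)
    if time.size == 0:
        raise DataError("empty group: no subjects")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    event_times = np.unique(time[event == 1])
    n = time.size
    at_risk = np.empty(event_times.size, dtype=int)
    deaths = np.empty(event_times.size, dtype=int)
    for i, t in enumerate(event_times):
        at_risk[i] = int(np.sum(time >= t))
        deaths[i] = int(np.sum((time == t) & (event == 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - deaths / at_risk
    surv = np.cumprod(factors)
    return KMCurve(event_times, surv, at_risk, deaths, n)


def administrative_censor(time, event, horizon: float):
    """Truncate follow-up at ``horizon``: later times become censored there.

    A subject with time exactly at the horizon keeps their status.
    """
    if horizon <= 0:
        raise DataError("horizon must be positive")
    time, event = _as_arrays(time, event)
    over = time > horizon
    time = np.where(over, horizon, time)
    event = np.where(over, 0, event)
    return time, event


def _logrank_components(time, event, group):
    """O, E and V for group 1 summed over distinct event times."""
    event_times = np.unique(time[event == 1])
    O = E = V = 0.0
    for t in event_times:
        at_risk = time >= t
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & group).sum())
        dying = (time == t) & (event == 1)
        d_tot = int(dying.sum())
        d1 = int((dying & group).sum())
        O += d1
        E += d_tot * n1 / n_tot
        if n_tot > 1:
            V += d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
    return O, E, V, float(event.sum())


def logrank_test(time, event, group) -> LogRankResult:
    """Two-group log-rank test.

    ``group`` is a boolean/binary label per subject. Per event time the
    observed deaths in group 1 are compared with their hypergeometric
    expectation given the risk sets; the variance-standardised sum is a
    chi-square statistic with 1 df (two-sided p). Symmetric in the group
    labelling.
    """
    time, event = _as_arrays(time, event)
    group = np.asarray(group).astype(bool)
    if group.shape != time.shape:
        raise DataError("group labels must align with times")
    if group.all() or (~group).all():
        raise DataError("both groups must be non-empty")
    if event.sum() == 0:
        raise DataError("log-rank statistic undefined with zero events")
    O1, E1, V, d_total = _logrank_components(time, event, group)
    chi2 = 0.0 if V == 0 else (O1 - E1) ** 2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(
        chi_square=float(chi2),
        p_value=p,
        observed_events=(d_total - O1, O1),
        expected_events=(d_total - E1, E1),
    )


def logrank_scan(time, event, values, thresholds) -> np.ndarray:
    """Log-rank chi-square for every dichotomisation ``values > threshold``.

    Vectorised over thresholds: risk-set counts for all thresholds are
    accumulated in one pass over the distinct event times, so scanning
    hundreds of candidate cutpoints costs little more than one test.
    Thresholds yielding an empty group get chi-square 0.
    """
    time, event = _as_arrays(time, event)
    values = np.asarray(values, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if event.sum() == 0:
        raise DataError("log-rank statistic undefined with zero events")
    if thresholds.size == 0:
        return np.empty(0)

    fast = values[:, None] > thresholds[None, :]  # n x C
    event_times = np.unique(time[event == 1])
    O1 = np.zeros(thresholds.size)
    E1 = np.zeros(thresholds.size)
    V = np.zeros(thresholds.size)
    for t in event_times:
        at_risk = time >= t
        n_tot = int(at_risk.sum())
        dying = (time == t) & (event == 1)
        d_tot = int(dying.sum())
        n1 = fast[at_risk].sum(axis=0).astype(float)
        d1 = fast[dying].sum(axis=0).astype(float)
        frac = n1 / n_tot
        O1 += d1
        E1 += d_tot * frac
        if n_tot > 1:
            V += d_tot * frac * (1 - frac) * (n_tot - d_tot) / (n_tot - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 0, (O1 - E1) ** 2 / V, 0.0)
    return chi2


def fit_cox(
    df: pd.DataFrame,
    covariates,
    duration_col: str = "time",
    event_col: str = "event",
    horizon_months: float | None = None,
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties) with AIC = 2k - 2 lnL.

    ``df`` must contain the duration, event and covariate columns; if
    ``horizon_months`` is given the data are administratively censored
    there before fitting. Constant covariates raise :class:`DataError`;
    non-convergence raises :class:`ConvergenceError`; monotone-likelihood
    (complete separation) warnings from the fitter are captured on the
    result.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError as LLConvergenceError
    from lifelines.exceptions import ConvergenceWarning

    covariates = list(covariates)
    if not covariates:
        raise DataError("at least one covariate is required")
    data = df[[duration_col, event_col, *covariates]].dropna().copy()
    if data.empty:
        raise DataError("no complete-case rows for the Cox fit")
    if data[event_col].sum() == 0:
        raise DataError("Cox fit requires at least one event")
    for cov in covariates:
        if data[cov].nunique() <= 1:
            raise DataError(f"covariate '{cov}' is constant across subjects")
    if horizon_months is not None:
        t, e = administrative_censor(data[duration_col], data[event_col], horizon_months)
        data[duration_col] = t
        data[event_col] = e
        if data[event_col].sum() == 0:
            raise DataError("no events remain inside the analysis horizon")

    cph = CoxPHFitter()
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            cph.fit(data, duration_col=duration_col, event_col=event_col)
        except LLConvergenceError as exc:
            raise ConvergenceError(str(exc)) from exc
        for w in wlist:
            if issubclass(w.category, ConvergenceWarning):
                captured.append(str(w.message))
    k = len(covariates)
    llf = float(cph.log_likelihood_)
    return CoxFit(
        coefficients=cph.params_.copy(),
        hazard_ratios=np.exp(cph.params_).copy(),
        p_values=cph.summary["p"].copy(),
        log_partial_likelihood=llf,
        aic=2 * k - 2 * llf,
        n_params=k,
        n=int(len(data)),
        n_events=int(data[event_col].sum()),
        warnings=captured,
    )
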