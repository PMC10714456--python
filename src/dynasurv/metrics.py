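"""Out-of-sample performance assessment for survival predictions.

All metrics are evaluated at a fixed prediction horizon *v* (months from
each subject's own entry) and handle right censoring by inverse
probability of censoring weighting (IPCW): observed outcomes are
reweighted by the Kaplan–Meier estimate of the censoring distribution
``G_hat`` so that the censored sample represents the uncensored one.

* ``ipcw_cindex`` — Uno-style concordance restricted to event times up to
  the horizon, pair weights ``1 / G_hat(T_i-)^2``.
* ``ipcw_brier`` — Graf's weighted Brier score of predicted survival at
  the horizon.
* ``weak_calibration`` — calibration intercept and slope from log-link
  event-count regressions with the predicted cumulative hazard as offset
  (targets 0 and 1 for a perfectly calibrated model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter

from .estimators import StepFunction
from .survdata import CohortTable

__all__ = [
    "MetricsReport",
    "censoring_survival",
    "ipcw_cindex",
    "ipcw_brier",
    "weak_calibration",
]

logger = logging.getLogger(__name__)

#: Subjects/pairs whose censoring-survival weight denominator falls below
#: this value are excluded (with a logged count) for numerical stability.
MIN_G = 0.01


@dataclass
class MetricsReport:
    """Per-period, per-method out-of-sample performance."""

    period: int
    method: str
    horizon: float
    cindex: float
    brier: float
    calib_intercept: float
    calib_slope: float
    n_eval: int
    n_events: int

    def __post_init__(self):
        if self.n_events > self.n_eval:
            raise ValueError("n_events cannot exceed n_eval")

    def as_rows(self, **extra) -> list[dict]:
        """Tidy rows: one (metric, value) pair per row."""
        base = dict(period=self.period, method=self.method, horizon=self.horizon,
                    n_eval=self.n_eval, n_events=self.n_events, **extra)
        return [
            {**base, "metric": m, "value": getattr(self, m)}
            for m in ("cindex", "brier", "calib_intercept", "calib_slope")
        ]


def _durations(cohort: CohortTable) -> tuple[np.ndarray, np.ndarray]:
    df = cohort.df
    t = (df["exit_time"] - df["entry_time"]).to_numpy(float)
    d = df["event"].to_numpy(int)
    return t, d


def censoring_survival(cohort: CohortTable) -> StepFunction:
    """Kaplan–Meier estimate of the censoring survival function G(t).

    The roles of event and censoring are swapped: a censoring is the
    "event" and events censor the censoring time. ``G(0) = 1``.
    """
    t, d = _durations(cohort)
    if len(t) == 0:
        raise ValueError("empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=1 - d)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(float)
    vals = sf.iloc[:, 0].to_numpy(float)
    # anchor G(0) = 1 so the step function is 1 anywhere before the first drop
    if len(times) == 0 or times[0] > 0:
        times = np.concatenate(([0.0], times))
        vals = np.concatenate(([1.0], vals))
    return StepFunction(times, vals)


def ipcw_cindex(predictions, cohort: CohortTable, horizon: float) -> float:
    """IPCW concordance index at the horizon.

    ``predictions`` are risk scores (higher = higher risk). Usable pairs
    (i, j) have ``T_i < T_j``, ``T_i <= horizon`` and an event for i; a
    pair is concordant when i's risk score exceeds j's (ties count 1/2),
    and is weighted by ``1 / G_hat(T_i-)^2``.
    """
    score = np.asarray(predictions, dtype=float)
    t, d = _durations(cohort)
    if len(score) != len(t):
        raise ValueError("one risk score per subject required")
    G = censoring_survival(cohort)
    num = den = 0.0
    n_dropped = 0
    idx_i = np.where((d == 1) & (t <= horizon))[0]
    for i in idx_i:
        g = float(G.left_limit(t[i]))
        if g < MIN_G:
            n_dropped += 1
            continue
        w = 1.0 / g**2
        later = t > t[i]
        n_pairs = int(later.sum())
        if n_pairs == 0:
            continue
        conc = (score[i] > score[later]).sum() + 0.5 * (score[i] == score[later]).sum()
        num += w * conc
        den += w * n_pairs
    if den == 0:
        raise ValueError("no usable pairs for the concordance index")
    if n_dropped:
        logger.info("ipcw_cindex: dropped %d events with G < %g", n_dropped, MIN_G)
    return float(num / den)


def ipcw_brier(predicted_survival, cohort: CohortTable, horizon: float) -> float:
    """IPCW (Graf) Brier score of predicted survival at the horizon.

    ``(1/n) * sum_i [ S_i^2 * 1(T_i <= v, event) / G(T_i-)
    + (1 - S_i)^2 * 1(T_i > v) / G(v) ]``; subjects censored before the
    horizon contribute only through the weights.
    """
    S = np.asarray(predicted_survival, dtype=float)
    if np.any((S < 0) | (S > 1)):
        raise ValueError("predicted survival must be in [0, 1]")
    t, d = _durations(cohort)
    if len(S) != len(t):
        raise ValueError("one prediction per subject required")
    G = censoring_survival(cohort)
    n = len(t)
    total = 0.0
    n_dropped = 0
    Gv = float(G(horizon))

    ev = (t <= horizon) & (d == 1)
    for i in np.where(ev)[0]:
        g = float(G.left_limit(t[i]))
        if g == 0:
            raise ValueError(f"zero censoring-survival weight for subject index {i}")
        if g < MIN_G:
            n_dropped += 1
            continue
        total += S[i] ** 2 / g
    surv = t > horizon
    if surv.any():
        if Gv == 0:
            raise ValueError("zero censoring-survival weight at the horizon")
        if Gv < MIN_G:
            n_dropped += int(surv.sum())
        else:
            total += np.sum((1.0 - S[surv]) ** 2) / Gv
    if n_dropped:
        logger.info("ipcw_brier: dropped %d subjects with G < %g", n_dropped, MIN_G)
    return float(total / n)


def weak_calibration(
    predicted_cumhaz, linear_predictor, cohort: CohortTable, horizon: float
) -> tuple[float, float]:
    """Calibration intercept and slope via log-link event-count regression.

    ``predicted_cumhaz`` is each subject's predicted cumulative hazard at
    ``min(T_i, v)`` and ``linear_predictor`` the model's ``eta_i``. The
    intercept *a* comes from a Poisson regression of the event indicator
    on a constant with ``log predicted_cumhaz`` as offset; the slope *b*
    from a regression on ``eta_i`` with the baseline cumulative hazard
    (``log predicted_cumhaz - eta_i``) as offset. Perfect calibration
    gives (0, 1) in expectation.
    """
    lam = np.asarray(predicted_cumhaz, dtype=float)
    eta = np.asarray(linear_predictor, dtype=float)
    t, d = _durations(cohort)
    if np.any(lam <= 0):
        raise ValueError("predicted cumulative hazards must be positive")
    if d.sum() == 0:
        raise ValueError("no observed events; calibration undefined")
    # events beyond the horizon are administratively ignored
    y = ((d == 1) & (t <= horizon)).astype(float)
    if y.sum() == 0:
        raise ValueError("no observed events before the horizon")

    m_int = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Poisson(), offset=np.log(lam))
    a = float(m_int.fit().params[0])
    exog = sm.add_constant(eta)
    m_slope = sm.GLM(y, exog, family=sm.families.Poisson(), offset=np.log(lam) - eta)
    b = float(m_slope.fit().params[1])
    return a, b
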