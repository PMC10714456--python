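"""Proportional-hazards machinery for model updating.

The model is ``h_i(t | x_i) = h_0(t) exp(beta' x_i)`` with survival
predictions ``S_i(t) = exp(-H0_hat(t) exp(beta_hat' x_i))`` where
``H0_hat`` is Breslow's estimate of the cumulative baseline hazard. Three
update operations act on a fitted model:

* intercept recalibration — re-estimate the baseline hazard on new data
  holding the linear predictor fixed (a Cox model with the linear predictor
  as the only covariate and its coefficient fixed at 1, which reduces to
  Breslow's estimator with a fixed offset);
* refitting — a fresh fit on the new data only, with a feasibility rule
  that falls back to the previous model when the new data cannot support a
  fit;
* (Bayesian updating lives in :mod:`dynasurv.bayes`.)

Analysis time throughout is time since the subject's own entry
(``exit_time - entry_time``); periods are self-contained after the time
origin reset so each subject contributes a single duration per period.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.duration.hazard_regression import PHReg

from .survdata import CohortTable

__all__ = [
    "StepFunction",
    "PHModel",
    "PHResults",
    "DegenerateCovariateError",
    "fit_ph",
    "breslow_cumhaz",
    "predict_survival",
    "recalibrate_intercept",
    "refit",
]


class DegenerateCovariateError(ValueError):
    """A covariate cannot be estimated (no variation, or an empty level)."""


class StepFunction:
    """Right-continuous non-decreasing step function, zero before the first jump.

    Beyond the last jump the final value is carried forward.
    """

    def __init__(self, jump_times: np.ndarray, values: np.ndarray):
        t = np.asarray(jump_times, dtype=float)
        v = np.asarray(values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("jump_times and values must be 1-D of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("jump times must be strictly increasing")
        self.jump_times = t
        self.values = v

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="right")
        out = np.where(idx > 0, self.values[np.maximum(idx - 1, 0)], 0.0)
        return float(out) if out.ndim == 0 else out

    def left_limit(self, t) -> np.ndarray | float:
        """Value just before ``t`` (jumps at ``t`` excluded)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="left")
        out = np.where(idx > 0, self.values[np.maximum(idx - 1, 0)], 0.0)
        return float(out) if out.ndim == 0 else out


def _durations(cohort: CohortTable) -> tuple[np.ndarray, np.ndarray]:
    df = cohort.df
    dur = (df["exit_time"] - df["entry_time"]).to_numpy(float)
    ev = df["event"].to_numpy(int)
    return dur, ev


def _check_design(df: pd.DataFrame, covariates: Sequence[str], events: np.ndarray):
    for c in covariates:
        col = df[c].to_numpy(float)
        if np.isnan(col).any():
            raise ValueError(f"missing values in covariate '{c}'")
        if np.all(col == col[0]):
            raise DegenerateCovariateError(f"covariate '{c}' has no variation")
        levels = np.unique(col)
        if len(levels) == 2 and set(levels) <= {0.0, 1.0}:
            for lev in levels:
                if events[col == lev].sum() == 0:
                    raise DegenerateCovariateError(
                        f"binary covariate '{c}' has zero events at level {int(lev)}"
                    )


@dataclass
class PHResults:
    """Fitted proportional-hazards model state.

    Attributes
    ----------
    coefficients : pandas.Series
        Log hazard ratios, indexed by covariate name.
    covariance : pandas.DataFrame
        Estimated covariance of the coefficients (inverse observed
        information).
    baseline_cumhaz : StepFunction
        Breslow estimate of the cumulative baseline hazard on the period's
        analysis time scale.
    fit_period : int
        Update period whose data produced this state.
    method_tag : str
        One of ``original``, ``recalibrated``, ``refit``.
    retained : bool
        True when a refit was infeasible and the previous state was kept.
    """

    coefficients: pd.Series
    covariance: pd.DataFrame
    baseline_cumhaz: StepFunction
    fit_period: int = 0
    method_tag: str = "original"
    retained: bool = False

    def __post_init__(self):
        cov = self.covariance.to_numpy(float)
        if cov.shape != (len(self.coefficients),) * 2:
            raise ValueError("covariance dimension mismatch")
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    @property
    def covariate_names(self) -> list[str]:
        return list(self.coefficients.index)

    # -- predictions ---------------------------------------------------
    def linear_predictor(self, X) -> np.ndarray:
        X = _as_matrix(X, self.covariate_names)
        return X @ self.coefficients.to_numpy(float)

    def predict_survival(self, X, t) -> np.ndarray | float:
        """``S(t | x) = exp(-H0(t) exp(beta'x))`` at horizon ``t`` (months)."""
        if np.any(np.asarray(t) < 0):
            raise ValueError("t must be >= 0")
        eta = self.linear_predictor(X)
        out = np.exp(-np.asarray(self.baseline_cumhaz(t)) * np.exp(eta))
        return float(out) if np.ndim(out) == 0 else out

    def predict_cumhaz(self, X, t) -> np.ndarray:
        """Predicted cumulative hazard ``H0(t) exp(beta'x)``; t may be a vector."""
        eta = self.linear_predictor(X)
        return np.asarray(self.baseline_cumhaz(t)) * np.exp(eta)

    def recalibrate(self, new_cohort: CohortTable, period: Optional[int] = None) -> "PHResults":
        return recalibrate_intercept(self, new_cohort, period=period)

    # -- reporting -----------------------------------------------------
    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.covariance.to_numpy(float)))
        return pd.DataFrame(
            {
                "log HR": self.coefficients,
                "HR": np.exp(self.coefficients),
                "se": se,
                "ci95_low": self.coefficients - 1.96 * se,
                "ci95_high": self.coefficients + 1.96 * se,
            }
        )

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": self.coefficients.to_dict(),
                "covariate_names": self.covariate_names,
                "covariance": self.covariance.to_numpy(float).tolist(),
                "baseline_jump_times": self.baseline_cumhaz.jump_times.tolist(),
                "baseline_values": self.baseline_cumhaz.values.tolist(),
                "fit_period": self.fit_period,
                "method_tag": self.method_tag,
                "retained": self.retained,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "PHResults":
        d = json.loads(payload)
        names = d["covariate_names"]
        return cls(
            coefficients=pd.Series({k: d["coefficients"][k] for k in names}),
            covariance=pd.DataFrame(d["covariance"], index=names, columns=names),
            baseline_cumhaz=StepFunction(
                np.array(d["baseline_jump_times"]), np.array(d["baseline_values"])
            ),
            fit_period=d["fit_period"],
            method_tag=d["method_tag"],
            retained=d["retained"],
        )


def _as_matrix(X, names: Sequence[str]) -> np.ndarray:
    if isinstance(X, CohortTable):
        X = X.df
    if isinstance(X, pd.DataFrame):
        missing = [c for c in names if c not in X.columns]
        if missing:
            raise KeyError(f"unknown covariate name(s) {missing}")
        return X[list(names)].to_numpy(float)
    if isinstance(X, (pd.Series, dict)):
        return np.array([[float(X[c]) for c in names]])
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(names):
        raise ValueError(f"expected {len(names)} covariates, got {X.shape[1]}")
    return X


class PHModel:
    """Cox proportional-hazards model on a period's cohort data.

    ``fit`` maximises the partial likelihood (Breslow tie handling by
    default, Efron available) and attaches the Breslow baseline cumulative
    hazard; the result is deterministic given the input.
    """

    def __init__(
        self,
        cohort: CohortTable,
        covariates: Optional[Sequence[str]] = None,
        ties: str = "breslow",
    ):
        if ties not in ("breslow", "efron"):
            raise ValueError("ties must be 'breslow' or 'efron'")
        self.cohort = cohort
        self.covariates = list(covariates) if covariates is not None else cohort.covariates
        self.ties = ties

    def fit(self, fit_period: int = 0, method_tag: str = "original") -> PHResults:
        dur, ev = _durations(self.cohort)
        if ev.sum() < 1:
            raise ValueError("cohort has no events")
        df = self.cohort.df
        _check_design(df, self.covariates, ev)
        X = df[self.covariates].to_numpy(float)
        model = PHReg(dur, X, status=ev, ties=self.ties)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=200, disp=False)
        se = np.sqrt(np.diag(res.cov_params()))
        if not (
            np.all(np.isfinite(res.params))
            and np.all(np.isfinite(se))
            and np.max(np.abs(res.params)) < 20
            and np.max(se) < 20
        ):
            # log hazard ratios this size signal separation / too few events
            raise ValueError("partial-likelihood fit unstable or non-convergent")
        coef = pd.Series(res.params, index=self.covariates)
        cov = pd.DataFrame(
            res.cov_params(), index=self.covariates, columns=self.covariates
        )
        eta = X @ res.params
        base = _breslow(dur, ev, eta)
        return PHResults(
            coefficients=coef,
            covariance=cov,
            baseline_cumhaz=base,
            fit_period=fit_period,
            method_tag=method_tag,
        )


def _breslow(dur: np.ndarray, ev: np.ndarray, eta: np.ndarray) -> StepFunction:
    """Breslow cumulative baseline hazard for given durations and offsets.

    ``H0(t) = sum_{event times t_k <= t} d_k / sum_{j at risk at t_k} exp(eta_j)``
    with the risk set ``{j : dur_j >= t_k}``.
    """
    order = np.argsort(dur, kind="mergesort")
    dur_s, ev_s, w_s = dur[order], ev[order], np.exp(eta[order])
    # reverse cumulative sum of risk weights: denom at time dur_s[i] over all j >= i
    rev_cum = np.cumsum(w_s[::-1])[::-1]
    ev_times = dur_s[ev_s == 1]
    uniq, first_idx = np.unique(ev_times, return_index=True)
    jumps = np.empty(len(uniq))
    for k, t in enumerate(uniq):
        d_k = np.sum(ev_times == t)
        at_risk_start = np.searchsorted(dur_s, t, side="left")
        denom = rev_cum[at_risk_start]
        if denom <= 0:
            raise ValueError(f"empty risk set at event time {t}")
        jumps[k] = d_k / denom
    return StepFunction(uniq, np.cumsum(jumps))


# ----------------------------------------------------------------------
# module-level operation surface
# ----------------------------------------------------------------------

def fit_ph(
    cohort: CohortTable,
    covariates: Optional[Sequence[str]] = None,
    ties: str = "breslow",
    fit_period: int = 0,
    method_tag: str = "original",
) -> PHResults:
    """Fit a Cox proportional-hazards model; see :class:`PHModel`."""
    return PHModel(cohort, covariates, ties).fit(fit_period, method_tag)


def breslow_cumhaz(state: PHResults, cohort: CohortTable) -> StepFunction:
    """Breslow baseline cumulative hazard of ``cohort`` at ``state``'s coefficients."""
    dur, ev = _durations(cohort)
    eta = state.linear_predictor(cohort.df)
    return _breslow(dur, ev, eta)


def predict_survival(state: PHResults, X, t) -> np.ndarray | float:
    return state.predict_survival(X, t)


def recalibrate_intercept(
    state: PHResults, new_cohort: CohortTable, period: Optional[int] = None
) -> PHResults:
    """Re-estimate the baseline hazard on new data, log hazard ratios fixed.

    Equivalent to a Cox fit with the frozen linear predictor as the only
    covariate and its coefficient fixed at 1: the Breslow estimator with
    offsets ``eta_i``. Discrimination is unchanged because the subject
    ranking by linear predictor is preserved.
    """
    if new_cohort.n_events < 1:
        raise ValueError("new cohort has no events; cannot recalibrate")
    base = breslow_cumhaz(state, new_cohort)
    return replace(
        state,
        baseline_cumhaz=base,
        method_tag="recalibrated",
        fit_period=state.fit_period if period is None else period,
        retained=False,
    )


def refit(
    new_cohort: CohortTable,
    covariate_names: Sequence[str],
    previous: PHResults,
    ties: str = "breslow",
    period: Optional[int] = None,
) -> PHResults:
    """Fully refit on new data, retaining the previous model when infeasible.

    Infeasible means: no events; a covariate without variation; a binary
    covariate level with zero events; or non-convergence. In those cases
    the previous state is returned with ``retained=True`` rather than
    raising, mirroring an analyst who must wait for more data.
    """
    try:
        out = fit_ph(
            new_cohort,
            covariate_names,
            ties=ties,
            fit_period=previous.fit_period if period is None else period,
            method_tag="refit",
        )
        return out
    except (DegenerateCovariateError, ValueError, np.linalg.LinAlgError):
        return replace(previous, retained=True)
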