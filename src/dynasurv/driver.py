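"""Orchestration of the dynamic update/evaluate cycle.

Each replicate generates a development dataset D0 and quarterly updating
datasets D1..D5, fits the original Cox model M0 on D0, and then, for every
requested updating strategy, repeatedly (a) evaluates the current model
out-of-sample on the next quarter's data at the prediction horizon and
(b) updates it with the quarter's data once that quarter has arrived:
M_{u-1} updated with D_u is evaluated on D_{u+1}. Strategies:

``none``              keep M0 throughout;
``recal_quarterly``   re-estimate the baseline hazard each quarter;
``refit_quarterly``   refit on each quarter's data (falling back to the
                      previous model when a refit is infeasible);
``bayes_quarterly``   Bayesian exponential-model update each quarter with
                      forgetting-factor priors;
``recal_once@q`` / ``refit_once@q``  one-time update with quarter q's data.

Ad-hoc one-time updating with analysts choosing arbitrary calendar times
(quarter starts use the quarter ahead of them; mid-month analysts the
trailing three months of accrued data) is handled by
:func:`run_adhoc_experiment`. Results are tidy tables with one row per
(replicate, method, period, metric); :func:`summarize` aggregates them
into means with Monte-Carlo standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .survdata import CohortTable
from .simulate import ScenarioConfig, gen_series
from .estimators import PHResults, fit_ph, recalibrate_intercept, refit
from .bayes import (
    ExpPHPosterior,
    SamplerConfig,
    check_convergence,
    fit_exponential_ph_posterior,
    priors_from_state,
)
from .metrics import MetricsReport, ipcw_brier, ipcw_cindex, weak_calibration

__all__ = [
    "ExperimentConfig",
    "UpdateSchedule",
    "run_quarterly_experiment",
    "run_adhoc_experiment",
    "summarize",
]

QUARTERLY_METHODS = ("none", "recal_quarterly", "refit_quarterly", "bayes_quarterly")

#: Floor applied to predicted cumulative hazards in the calibration
#: regressions (a Cox baseline is zero before its first jump).
_CUMHAZ_FLOOR = 1e-8


@dataclass
class ExperimentConfig:
    """Configuration of one simulation experiment.

    ``methods`` mixes dynamic strategies with one-time strategies written
    ``recal_once@q`` / ``refit_once@q`` (update with quarter q's data).
    """

    scenario: ScenarioConfig
    methods: Sequence[str] = QUARTERLY_METHODS
    n_sim: int = 600
    xi: float = 0.9
    master_seed: int = 0
    sampler: SamplerConfig = field(default_factory=SamplerConfig)

    def __post_init__(self):
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        for m in self.methods:
            kind, when = _parse_method(m)
            if kind not in QUARTERLY_METHODS + ("recal_once", "refit_once"):
                raise ValueError(f"unknown method {m!r}")
            # one-time methods need a quarter tag for the quarterly runner;
            # the ad-hoc runner supplies analyst times instead
            if kind.endswith("_once") and when is not None and not (
                1 <= when <= self.scenario.schedule.n_periods - 1
            ):
                raise ValueError(f"one-time method {m!r} has an invalid update quarter")


@dataclass(frozen=True)
class UpdateSchedule:
    """Ad-hoc one-time analyst schedule.

    ``analyst_times`` are fractions of year 1 at which each analyst starts
    their single update; quarter starts (multiples of 0.25) update with the
    quarter of data ahead of them, all others with the trailing
    ``data_window`` months of accrued data ending at the last complete
    month.
    """

    kind: str = "one_time"
    analyst_times: tuple = (0.0, 0.1, 0.25, 0.46, 0.5, 0.69, 0.75)
    data_window: float = 3.0

    def __post_init__(self):
        if self.kind != "one_time":
            raise ValueError("only one_time schedules are supported")
        if any(t < 0 or t >= 1 for t in self.analyst_times):
            raise ValueError("analyst times must lie within year 1")
        if self.data_window <= 0:
            raise ValueError("data window must be positive")


def _parse_method(method: str) -> tuple[str, Optional[int]]:
    if "@" in method:
        kind, when = method.split("@", 1)
        return kind, int(when)
    return method, None


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


# ----------------------------------------------------------------------
# evaluation
# ----------------------------------------------------------------------

def _evaluate(state, cohort: CohortTable, horizon: float) -> MetricsReport:
    """All four performance measures of one model state on one dataset.

    A metric that is undefined on a given dataset (e.g. no events before
    the horizon in a sparse quarter) is recorded as NaN rather than
    aborting the replicate.
    """
    df = cohort.df
    dur = (df["exit_time"] - df["entry_time"]).to_numpy(float)
    S = np.asarray(state.predict_survival(df, horizon), dtype=float).reshape(-1)
    risk = 1.0 - S
    try:
        cindex = ipcw_cindex(risk, cohort, horizon)
    except ValueError:
        cindex = float("nan")
    brier = ipcw_brier(S, cohort, horizon)
    t_trunc = np.minimum(dur, horizon)
    lam = np.clip(state.predict_cumhaz(df, t_trunc), _CUMHAZ_FLOOR, 1e8)
    eta = np.asarray(state.linear_predictor(df), dtype=float)
    try:
        a, b = weak_calibration(lam, eta, cohort, horizon)
    except ValueError:
        a, b = float("nan"), float("nan")
    n_events = int(((dur <= horizon) & (df["event"] == 1)).sum())
    return MetricsReport(
        period=int(df["period_u"].iloc[0]) if len(df) else -1,
        method=getattr(state, "method_tag", "?"),
        horizon=horizon,
        cindex=cindex,
        brier=brier,
        calib_intercept=a,
        calib_slope=b,
        n_eval=len(df),
        n_events=n_events,
    )


def _varying_covariates(cohort: CohortTable, names: Sequence[str]) -> list[str]:
    df = cohort.df
    return [c for c in names if c in df.columns and df[c].nunique() > 1]


def _coef_rows(state, method: str, period: int) -> list[dict]:
    if isinstance(state, ExpPHPosterior):
        coefs = state.beta_hat
    elif isinstance(state, PHResults):
        coefs = state.coefficients
    else:
        return []
    return [
        {"method": method, "period": period, "metric": f"loghr_{k}", "value": float(v)}
        for k, v in coefs.items()
    ]


# ----------------------------------------------------------------------
# quarterly experiment
# ----------------------------------------------------------------------

def _update_state(state, kind, u, cohort, config, bayes_seed):
    """One update step; returns (new_state, flag_rows)."""
    flags: list[dict] = []
    scen = config.scenario
    if kind == "none":
        return state, flags
    if kind == "recal_quarterly" or kind == "recal_once":
        new = recalibrate_intercept(state, cohort, period=u)
        return new, flags
    if kind == "refit_quarterly" or kind == "refit_once":
        covs = _varying_covariates(cohort, scen.covariate_names)
        new = refit(cohort, covs, state, period=u)
        flags.append(
            {"method": kind, "period": u, "metric": "refit_feasible",
             "value": 0.0 if new.retained else 1.0}
        )
        return new, flags
    if kind == "bayes_quarterly":
        covs = _varying_covariates(cohort, scen.covariate_names)
        prior_source = state if isinstance(state, (ExpPHPosterior, PHResults)) else None
        if prior_source is None:
            raise TypeError("bayes update requires a previous model state")
        prev_names = (
            state.covariate_names
            if isinstance(state, (ExpPHPosterior, PHResults))
            else []
        )
        new_covs = [c for c in covs if c not in prev_names]
        prior = priors_from_state(state, config.xi, new_covariates=new_covs)
        sampler = dc_replace(config.sampler, seed=bayes_seed)
        post = fit_exponential_ph_posterior(
            cohort, prior, sampler=sampler, fit_period=u
        )
        rep = check_convergence(post)
        flags.append(
            {"method": kind, "period": u, "metric": "bayes_converged",
             "value": 1.0 if rep.passed else 0.0}
        )
        if not rep.passed:
            # unusable result: retain the previous period's model
            return dc_replace(state, retained=True), flags
        return post, flags
    raise ValueError(f"unknown update kind {kind!r}")


def run_quarterly_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run the quarterly update/evaluate cycle over all replicates.

    Returns a tidy results table: columns scenario, framework, sim_id,
    method, period, metric, value (plus n_eval/n_events on performance
    rows). Performance rows at period p evaluate, on D_p, the model last
    updated with D_{p-1}; coefficient and feasibility rows are tagged with
    their update period.
    """
    scen = config.scenario
    n_periods = scen.schedule.n_periods
    horizon = scen.schedule.horizon_v
    records: list[dict] = []

    for sim_id in range(config.n_sim):
        ss = np.random.SeedSequence(entropy=config.master_seed, spawn_key=(sim_id,))
        children = ss.spawn(2 + len(config.methods) * n_periods)
        gen_rng = np.random.default_rng(children[0])
        series = gen_series(scen, gen_rng, sim_id=sim_id)
        d0 = series[0]
        m0 = fit_ph(d0, _varying_covariates(d0, scen.covariate_names))
        records += [
            {**r, "sim_id": sim_id} for r in _coef_rows(m0, "original", 0)
        ]

        states = {m: m0 for m in config.methods}
        for u in range(0, n_periods):
            if u >= 1:
                for mi, method in enumerate(config.methods):
                    kind, when = _parse_method(method)
                    if kind.endswith("_once") and when != u:
                        continue
                    seed = _seed_int(children[2 + mi * n_periods + u])
                    new_state, flags = _update_state(
                        states[method], kind, u, series[u], config, seed
                    )
                    states[method] = new_state
                    records += [
                        {**f, "sim_id": sim_id, "method": method} for f in flags
                    ]
                    if kind in ("refit_quarterly", "refit_once", "bayes_quarterly"):
                        if not getattr(new_state, "retained", False):
                            records += [
                                {**r, "sim_id": sim_id, "method": method}
                                for r in _coef_rows(new_state, method, u)
                            ]
            eval_period = u + 1
            for method in config.methods:
                state = states[method]
                assert getattr(state, "fit_period", 0) < eval_period, "evaluation must be out-of-sample"
                perf = _evaluate(state, series[eval_period], horizon)
                for metric in ("cindex", "brier", "calib_intercept", "calib_slope"):
                    records.append(
                        {
                            "sim_id": sim_id,
                            "method": method,
                            "period": eval_period,
                            "metric": metric,
                            "value": getattr(perf, metric),
                            "n_eval": perf.n_eval,
                            "n_events": perf.n_events,
                        }
                    )
    out = pd.DataFrame.from_records(records)
    out.insert(0, "scenario", scen.name)
    out.insert(1, "framework", scen.framework)
    return out


# ----------------------------------------------------------------------
# ad-hoc one-time updating
# ----------------------------------------------------------------------

def assemble_window(
    series: Sequence[CohortTable], start_month: float, end_month: float
) -> CohortTable:
    """Assemble the follow-up accrued in calendar window [start, end) months.

    Calendar time 0 is the start of year 1 (first updating quarter); the
    development dataset covers [-12, 0). Each quarter's records are
    clipped to the window (events falling outside become censorings at the
    clip boundary) and shifted onto the window's own time origin. Under
    the exponential event-time model, clipped intervals remain valid
    follow-up.
    """
    if end_month <= start_month:
        raise ValueError("empty calendar window")
    pieces = []
    offsets = [-12.0] + [3.0 * (u - 1) for u in range(1, len(series))]
    for tab, off in zip(series, offsets):
        df = tab.df
        g_entry = df["entry_time"].to_numpy(float) + off
        g_exit = df["exit_time"].to_numpy(float) + off
        new_entry = np.maximum(g_entry, start_month)
        new_exit = np.minimum(g_exit, end_month)
        keep = new_exit > new_entry
        if not keep.any():
            continue
        sub = df.loc[keep].copy()
        sub["entry_time"] = new_entry[keep] - start_month
        sub["exit_time"] = new_exit[keep] - start_month
        sub["event"] = (df["event"].to_numpy(int)[keep] & (g_exit[keep] <= end_month)).astype(int)
        pieces.append(sub)
    if not pieces:
        raise ValueError(f"no data available in window [{start_month}, {end_month})")
    out = pd.concat(pieces, ignore_index=True)
    return CohortTable(out, validate=False)


def _analyst_window(tau: float, data_window: float) -> tuple[float, float]:
    """Calendar window (months from year-1 start) for an analyst at ``tau``."""
    m12 = tau * 12.0
    if abs(m12 / 3.0 - round(m12 / 3.0)) < 1e-9:
        return m12, m12 + data_window  # quarter start: the quarter ahead
    m = float(np.floor(m12))  # data collected at month ends
    return m - data_window, m


def run_adhoc_experiment(
    config: ExperimentConfig, schedule: UpdateSchedule
) -> pd.DataFrame:
    """One-time updating at each analyst's chosen time.

    Every analyst applies each one-time strategy in ``config.methods``
    (``recal_once`` / ``refit_once``, no ``@`` suffix needed here) to the
    three months of data their calendar position allows, deploys the
    updated model at the window end, and is evaluated on every subsequent
    quarter; quarters before deployment are predicted with M0. Result
    rows are tagged ``method@tau``.
    """
    scen = config.scenario
    n_periods = scen.schedule.n_periods
    horizon = scen.schedule.horizon_v
    kinds = []
    for m in config.methods:
        kind, _ = _parse_method(m)
        if kind in ("recal_once", "refit_once"):
            kinds.append(kind)
    if not kinds:
        raise ValueError("run_adhoc_experiment needs recal_once and/or refit_once methods")

    records: list[dict] = []
    for sim_id in range(config.n_sim):
        ss = np.random.SeedSequence(entropy=config.master_seed, spawn_key=(sim_id,))
        children = ss.spawn(2 + len(config.methods) * n_periods)
        gen_rng = np.random.default_rng(children[0])
        series = gen_series(scen, gen_rng, sim_id=sim_id)
        d0 = series[0]
        m0 = fit_ph(d0, _varying_covariates(d0, scen.covariate_names))

        for tau in schedule.analyst_times:
            w_start, w_end = _analyst_window(tau, schedule.data_window)
            window = assemble_window(series, w_start, w_end)
            for kind in kinds:
                label = f"{kind}@{tau}"
                if kind == "recal_once":
                    try:
                        updated = recalibrate_intercept(m0, window)
                    except ValueError:
                        updated = dc_replace(m0, retained=True)
                else:
                    covs = _varying_covariates(window, scen.covariate_names)
                    updated = refit(window, covs, m0)
                for eval_period in range(1, n_periods + 1):
                    q_start = 3.0 * (eval_period - 1)
                    state = updated if q_start >= w_end else m0
                    perf = _evaluate(state, series[eval_period], horizon)
                    for metric in ("cindex", "brier", "calib_intercept", "calib_slope"):
                        records.append(
                            {
                                "sim_id": sim_id,
                                "method": label,
                                "period": eval_period,
                                "metric": metric,
                                "value": getattr(perf, metric),
                                "n_eval": perf.n_eval,
                                "n_events": perf.n_events,
                            }
                        )
    out = pd.DataFrame.from_records(records)
    out.insert(0, "scenario", scen.name)
    out.insert(1, "framework", scen.framework)
    return out


# ----------------------------------------------------------------------
# aggregation
# ----------------------------------------------------------------------

def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Replicate means with Monte-Carlo standard errors.

    Groups by (scenario, framework, method, period, metric) and reports
    mean, MCSE = sd / sqrt(n) and n. At least two replicates per cell are
    required for the MCSE to exist.
    """
    keys = [c for c in ("scenario", "framework", "method", "period", "metric")
            if c in results.columns]
    grouped = results.groupby(keys, dropna=False)["value"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    if (out["n"] < 2).any():
        bad = out.loc[out["n"] < 2, keys].to_dict("records")
        raise ValueError(f"MCSE undefined for cells with a single replicate: {bad[:5]}")
    out["mcse"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns=["sd"])
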