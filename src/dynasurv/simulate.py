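"""Synthetic survival-cohort generator for dynamic model-updating studies.

Two data-arrival frameworks are emulated:

``replacement``
    A standing cohort of ``n_dev`` individuals followed through consecutive
    quarters. Individuals who have an event are replaced by a new person at
    the start of the following month; additional non-informative churn
    (random exits replaced by new entrants) tops the inflow up to roughly
    ``n_replacements`` new individuals per quarter, mimicking patient
    turnover in an electronic health-records cohort.

``new_cohorts``
    A disjoint group of ``n_per_month`` individuals enters each month (as if
    identified by a positive test that month); follow-up is truncated at the
    quarter end, so the three monthly waves have at most 3, 2 and 1 months
    of follow-up.

Event times are exponential under proportional hazards: the hazard for
individual *i* is ``exp(lambda_u) * exp(beta' x_i)`` where ``lambda_u`` is
the log baseline hazard of period *u*, numerically calibrated so that the
marginal 1-year event probability matches the scenario's target path
(e.g. a drift from 5% down to 2% per year). Covariates are age in decades
``x1 ~ U(1.8, 9.5)``, a biomarker ``x2 ~ N(1, 1)``, a binary comorbidity
``x3`` (optionally with age-dependent prevalence) and, in the treatment
scenarios, a staged treatment rollout ``x4`` opened to the oldest age
groups first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .survdata import CohortTable, PeriodSchedule

__all__ = [
    "RolloutSchedule",
    "ScenarioConfig",
    "SCENARIO_NAMES",
    "draw_covariates",
    "assign_treatment",
    "draw_event_times",
    "calibrate_baseline",
    "gen_replacement_series",
    "gen_newcohort_series",
    "gen_series",
]

SCENARIO_NAMES = (
    "constant_events",
    "decreasing_events",
    "increasing_events",
    "rare_1pct",
    "new_treatment",
    "new_treatment_comorbidity",
)

_AGE_LO, _AGE_HI = 1.8, 9.5  # age in decades, uniform support
_DEV_FOLLOWUP = 12.0  # months of follow-up in the development cohort
_CALIBRATION_N = 200_000  # covariate-law sample for marginal-rate calibration


@dataclass(frozen=True)
class RolloutSchedule:
    """Staged introduction of a treatment, oldest age groups first.

    From ``introduction_period`` onward, individuals at or above the
    period's age threshold (dropping by ``threshold_step`` decades each
    period) — or, when ``comorbidity_override`` is set, anyone with the
    comorbidity ``x3 = 1`` — are eligible; each period, untreated eligible
    individuals take the treatment up with probability ``uptake``.
    Treatment, once received, is permanent.
    """

    introduction_period: int = 2
    initial_age_threshold: float = 7.5
    threshold_step: float = 1.0
    uptake: float = 0.8
    comorbidity_override: bool = False

    def age_threshold(self, period: int) -> float:
        return self.initial_age_threshold - self.threshold_step * (
            period - self.introduction_period
        )

    def eligible(self, covariates: pd.DataFrame, period: int) -> np.ndarray:
        if period < self.introduction_period:
            return np.zeros(len(covariates), dtype=bool)
        elig = covariates["x1"].to_numpy() >= self.age_threshold(period)
        if self.comorbidity_override:
            elig = elig | (covariates["x3"].to_numpy() == 1)
        return elig


@dataclass
class ScenarioConfig:
    """Full data-generating specification for one simulation scenario.

    ``annual_event_rate_path`` holds the target marginal 1-year event
    probability for each period 0..n_periods (period 0 is development);
    the log baseline hazard of each period is calibrated against it.
    """

    name: str
    framework: str = "replacement"
    n_dev: int = 10_000
    n_replacements: int = 1_000
    n_per_month: int = 1_000
    annual_event_rate_path: tuple = (0.05,) * 6
    log_hazard_ratios: dict = field(
        default_factory=lambda: {"x1": 0.35, "x2": 0.3, "x3": 0.8}
    )
    p_x3: float = 0.05
    p_x3_age_slope: float = 0.0  # logistic slope of comorbidity prevalence in age
    p_x3_marginal_scope: str = "total"  # calibrate marginal prevalence over all ages
    rollout: Optional[RolloutSchedule] = None
    schedule: PeriodSchedule = field(default_factory=PeriodSchedule)
    seed: int = 0

    def __post_init__(self):
        if self.framework not in ("replacement", "new_cohorts"):
            raise ValueError(f"unknown framework {self.framework!r}")
        path = np.asarray(self.annual_event_rate_path, dtype=float)
        if len(path) != self.schedule.n_periods + 1:
            raise ValueError(
                "annual_event_rate_path must cover periods 0..n_periods "
                f"({self.schedule.n_periods + 1} values, got {len(path)})"
            )
        if np.any((path <= 0) | (path >= 1)):
            raise ValueError("event-rate targets must lie in (0, 1)")
        if self.rollout is not None and not (0 <= self.rollout.uptake <= 1):
            raise ValueError("rollout uptake must be a probability")
        self._lambda_cache: dict[int, float] = {}
        self._x3_intercept: Optional[float] = None

    # ------------------------------------------------------------------
    @classmethod
    def preset(cls, name: str, framework: str = "replacement", seed: int = 0, **overrides):
        """Construct one of the six named study scenarios."""
        if name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
        kw: dict = {"name": name, "framework": framework, "seed": seed}
        n_up = overrides.get("schedule", PeriodSchedule()).n_periods
        if name == "decreasing_events":
            kw["annual_event_rate_path"] = (0.05, *np.linspace(0.05, 0.02, n_up))
        elif name == "increasing_events":
            kw["annual_event_rate_path"] = (0.05, *np.linspace(0.05, 0.08, n_up))
        elif name == "rare_1pct":
            # comorbidity in 1% of people over age 55, prevalence rising with age
            kw["p_x3"] = 0.01
            kw["p_x3_age_slope"] = 1.0
            kw["p_x3_marginal_scope"] = "over55"
        elif name in ("new_treatment", "new_treatment_comorbidity"):
            kw["rollout"] = RolloutSchedule(
                comorbidity_override=(name == "new_treatment_comorbidity")
            )
            kw["log_hazard_ratios"] = {"x1": 0.35, "x2": 0.3, "x3": 0.8, "x4": -1.0}
        kw.update(overrides)
        return cls(**kw)

    # ------------------------------------------------------------------
    @property
    def covariate_names(self) -> list[str]:
        names = ["x1", "x2", "x3"]
        if self.rollout is not None:
            names.append("x4")
        return names

    def betas(self) -> np.ndarray:
        return np.array([self.log_hazard_ratios.get(c, 0.0) for c in self.covariate_names])

    def x3_probability(self, x1: np.ndarray) -> np.ndarray:
        """Comorbidity prevalence, possibly age-dependent.

        With a nonzero ``p_x3_age_slope`` the prevalence follows a logistic
        model in age whose intercept is calibrated so the stated marginal
        prevalence holds over the configured scope (all ages, or over-55s).
        """
        if self.p_x3_age_slope == 0.0:
            return np.full(np.shape(x1), self.p_x3, dtype=float)
        if self._x3_intercept is None:
            grid = np.linspace(_AGE_LO, _AGE_HI, 4001)
            if self.p_x3_marginal_scope == "over55":
                grid = grid[grid > 5.5]
            slope = self.p_x3_age_slope

            def marginal(a):
                return expit(a + slope * grid).mean() - self.p_x3

            self._x3_intercept = brentq(marginal, -40.0, 10.0, xtol=1e-12)
        return expit(self._x3_intercept + self.p_x3_age_slope * np.asarray(x1))

    def log_baseline(self, period: int) -> float:
        """Calibrated log baseline hazard for a period (cached)."""
        if period not in self._lambda_cache:
            self._lambda_cache[period] = calibrate_baseline(self, period)
        return self._lambda_cache[period]


# ----------------------------------------------------------------------
# covariates and event times
# ----------------------------------------------------------------------

def draw_covariates(
    n: int,
    scenario: ScenarioConfig,
    period: int,
    rng: np.random.Generator,
    with_treatment: bool = True,
) -> pd.DataFrame:
    """Draw covariates for ``n`` fresh individuals entering in ``period``.

    In treatment scenarios the rollout history up to ``period`` is replayed
    so that the cross-sectional treated fraction of new entrants matches the
    standing population's.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    x1 = rng.uniform(_AGE_LO, _AGE_HI, size=n)
    x2 = rng.normal(1.0, 1.0, size=n)
    p3 = scenario.x3_probability(x1)
    if np.any((p3 < 0) | (p3 > 1)):
        raise ValueError("invalid comorbidity probability")
    x3 = (rng.random(n) < p3).astype(int)
    df = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
    if scenario.rollout is not None:
        x4 = np.zeros(n, dtype=int)
        if with_treatment:
            for p in range(scenario.rollout.introduction_period, period + 1):
                x4 = assign_treatment(df, scenario, p, rng, current=x4)
        df["x4"] = x4
    return df


def assign_treatment(
    covariates: pd.DataFrame,
    scenario: ScenarioConfig,
    period: int,
    rng: np.random.Generator,
    current: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One period of treatment uptake among currently eligible untreated.

    Returns the updated treatment indicator; treatment is absorbing, so the
    treated fraction is non-decreasing across repeated calls.
    """
    n = len(covariates)
    if current is None:
        current = np.zeros(n, dtype=int)
    rollout = scenario.rollout
    if rollout is None or period < rollout.introduction_period:
        return np.asarray(current, dtype=int)
    elig = rollout.eligible(covariates, period)
    take = elig & (np.asarray(current) == 0) & (rng.random(n) < rollout.uptake)
    return (np.asarray(current) | take).astype(int)


def draw_event_times(
    covariates: pd.DataFrame | np.ndarray,
    log_baseline: float,
    betas: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exponential event times with hazard ``exp(log_baseline + beta' x)``."""
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    rate = np.exp(log_baseline + X @ np.asarray(betas, dtype=float))
    if not np.all(np.isfinite(rate)):
        raise ValueError("non-finite hazard")
    out = np.full(len(rate), np.inf)
    pos = rate > 0
    out[pos] = rng.exponential(1.0 / rate[pos])
    return out


def calibrate_baseline(
    scenario: ScenarioConfig, period: int, rng: Optional[np.random.Generator] = None
) -> float:
    """Solve for the log baseline hazard hitting the period's marginal rate.

    Finds ``lambda`` such that ``E_X[1 - exp(-12 * exp(lambda + beta'X))]``
    equals the period's target 1-year event probability, integrating over
    the pre-treatment covariate law with a large fixed Monte-Carlo sample
    (deterministic given the scenario seed).
    """
    target = scenario.annual_event_rate_path[period]
    if not 0 < target < 1:
        raise ValueError("target event probability must be in (0, 1)")
    betas = scenario.betas()
    if np.allclose(betas, 0.0):
        return float(np.log(-np.log1p(-target) / _DEV_FOLLOWUP))
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=scenario.seed, spawn_key=(9001,))
        )
    X = draw_covariates(
        _CALIBRATION_N, scenario, period=0, rng=rng, with_treatment=False
    )[scenario.covariate_names].to_numpy(float)
    eta = X @ betas

    def gap(lam):
        return np.mean(-np.expm1(-_DEV_FOLLOWUP * np.exp(lam + eta))) - target

    return float(brentq(gap, -30.0, 5.0, xtol=1e-10))


# ----------------------------------------------------------------------
# series generators
# ----------------------------------------------------------------------

def _dev_cohort(scenario: ScenarioConfig, rng, sim_id: int):
    """Development dataset D0: n_dev subjects censored at 12 months."""
    X = draw_covariates(scenario.n_dev, scenario, period=0, rng=rng)
    lam = scenario.log_baseline(0)
    T = draw_event_times(X[scenario.covariate_names], lam, scenario.betas(), rng)
    df = X.copy()
    df.insert(0, "sim_id", sim_id)
    df.insert(1, "subject_id", np.arange(1, scenario.n_dev + 1))
    df.insert(2, "period_u", 0)
    df.insert(3, "entry_time", 0.0)
    df.insert(4, "exit_time", np.minimum(T, _DEV_FOLLOWUP))
    df.insert(5, "event", (T <= _DEV_FOLLOWUP).astype(int))
    return CohortTable(df, validate=False), X, T


def gen_replacement_series(
    scenario: ScenarioConfig,
    rng: Optional[np.random.Generator] = None,
    sim_id: int = 0,
) -> list[CohortTable]:
    """Generate D0..D_n under the *cohort with replacement* framework.

    The standing pool stays at exactly ``n_dev`` members: every exit (event
    or churn) is matched by a new entrant at the start of the following
    month, with churn sized so that roughly ``n_replacements`` new
    individuals join per quarter. Each quarter's table is on its own time
    origin (entry 0 for the standing cohort, 1 or 2 for mid-quarter
    entrants) and is administratively censored at the quarter end.
    """
    if scenario.framework != "replacement":
        raise ValueError("scenario framework is not 'replacement'")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=scenario.seed))
    sched = scenario.schedule
    Q = sched.period_length
    cov_names = scenario.covariate_names
    betas = scenario.betas()

    d0, X0, T0 = _dev_cohort(scenario, rng, sim_id)
    tables = [d0]
    next_id = scenario.n_dev + 1

    # pool entering year 1: development survivors, events replaced 1:1
    dead = T0 <= _DEV_FOLLOWUP
    pool = X0.loc[~dead].copy()
    pool["subject_id"] = np.arange(1, scenario.n_dev + 1)[~dead]
    n_new = int(dead.sum())
    entrants_at_start = n_new

    target_month = int(round(scenario.n_replacements / 3.0))

    for u in range(1, sched.n_periods + 1):
        lam = scenario.log_baseline(u)
        if entrants_at_start > 0:
            fresh = draw_covariates(entrants_at_start, scenario, u, rng)
            fresh["subject_id"] = np.arange(next_id, next_id + entrants_at_start)
            next_id += entrants_at_start
            pool = pd.concat([pool, fresh], ignore_index=True)
        # one uptake round per period for the standing pool
        if scenario.rollout is not None:
            pool["x4"] = assign_treatment(pool, scenario, u, rng, current=pool["x4"].to_numpy())

        finalized: list[pd.DataFrame] = []

        def _finalize(chunk: pd.DataFrame, exit_time, event: int) -> None:
            out = chunk[["subject_id"] + cov_names].copy()
            out["entry_time"] = chunk["entry"].to_numpy()
            out["exit_time"] = exit_time
            out["event"] = event
            finalized.append(out)

        act = pool.reset_index(drop=True).copy()
        act["entry"] = 0.0
        act["tdeath"] = act["entry"] + draw_event_times(
            act[cov_names], lam, betas, rng
        )

        for m in range(int(Q)):
            month_end = float(m + 1)
            ev = act["tdeath"] <= month_end
            n_events = int(ev.sum())
            _finalize(act.loc[ev], act.loc[ev, "tdeath"].to_numpy(), 1)
            act = act.loc[~ev].reset_index(drop=True)

            n_churn = max(0, target_month - n_events)
            if n_churn > 0:
                eligible_idx = act.index[act["entry"] < month_end].to_numpy()
                n_churn = min(n_churn, len(eligible_idx))
                churn_idx = rng.choice(eligible_idx, size=n_churn, replace=False)
            else:
                churn_idx = np.array([], dtype=int)
            if month_end < Q:
                # churned members exit (censored) at the month boundary
                _finalize(act.loc[churn_idx], month_end, 0)
                act = act.drop(index=churn_idx).reset_index(drop=True)
                n_enter = n_events + len(churn_idx)
                if n_enter > 0:
                    fresh = draw_covariates(n_enter, scenario, u, rng)
                    fresh["subject_id"] = np.arange(next_id, next_id + n_enter)
                    next_id += n_enter
                    fresh["entry"] = month_end
                    fresh["tdeath"] = month_end + draw_event_times(
                        fresh[cov_names], lam, betas, rng
                    )
                    act = pd.concat([act, fresh], ignore_index=True)
            else:
                # quarter end: survivors are administratively censored;
                # churned members leave the pool, their record is identical
                _finalize(act, Q, 0)
                entrants_at_start = n_events + len(churn_idx)
                pool = (
                    act.drop(index=churn_idx)
                    .reset_index(drop=True)[cov_names + ["subject_id"]]
                    .copy()
                )
        df = pd.concat(finalized, ignore_index=True)
        df.insert(0, "sim_id", sim_id)
        df.insert(2, "period_u", u)
        df = df[
            ["sim_id", "subject_id", "period_u", "entry_time", "exit_time", "event"]
            + cov_names
        ]
        tables.append(CohortTable(df, validate=False))
    return tables


def gen_newcohort_series(
    scenario: ScenarioConfig,
    rng: Optional[np.random.Generator] = None,
    sim_id: int = 0,
) -> list[CohortTable]:
    """Generate D0..D_n under the *new cohorts* framework.

    After the development cohort, each quarter consists of three disjoint
    monthly entry waves of ``n_per_month`` fresh individuals entering at
    months 0, 1 and 2 of the quarter, followed until the quarter end (3, 2
    and 1 months of maximum follow-up respectively) or until an event.
    """
    if scenario.framework != "new_cohorts":
        raise ValueError("scenario framework is not 'new_cohorts'")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=scenario.seed))
    sched = scenario.schedule
    Q = sched.period_length
    cov_names = scenario.covariate_names
    betas = scenario.betas()

    d0, _, _ = _dev_cohort(scenario, rng, sim_id)
    tables = [d0]
    next_id = scenario.n_dev + 1

    for u in range(1, sched.n_periods + 1):
        lam = scenario.log_baseline(u)
        frames = []
        for wave in range(int(Q)):
            X = draw_covariates(scenario.n_per_month, scenario, u, rng)
            T = draw_event_times(X[cov_names], lam, betas, rng)
            max_f = Q - wave
            df = X.copy()
            df.insert(0, "sim_id", sim_id)
            df.insert(1, "subject_id", np.arange(next_id, next_id + len(X)))
            next_id += len(X)
            df.insert(2, "period_u", u)
            df.insert(3, "entry_time", float(wave))
            df.insert(4, "exit_time", wave + np.minimum(T, max_f))
            df.insert(5, "event", (T <= max_f).astype(int))
            frames.append(df)
        tables.append(CohortTable(pd.concat(frames, ignore_index=True), validate=False))
    return tables


def gen_series(
    scenario: ScenarioConfig,
    rng: Optional[np.random.Generator] = None,
    sim_id: int = 0,
) -> list[CohortTable]:
    """Dispatch to the scenario's framework generator."""
    if scenario.framework == "replacement":
        return gen_replacement_series(scenario, rng, sim_id)
    return gen_newcohort_series(scenario, rng, sim_id)
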