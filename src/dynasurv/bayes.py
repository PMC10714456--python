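"""Bayesian dynamic updating of an exponential proportional-hazards model.

In update period *u* survival times are modelled as exponential with log
rate ``omega_i = lambda_u + beta_u' x_i`` (``lambda_u`` is the log baseline
hazard). The prior carries last period's knowledge forward:

* ``beta_u ~ N(beta_hat_{u-1}, Sigma_hat_{u-1} / xi)`` where ``xi`` in
  (0, 1] is the forgetting factor — dividing the covariance by ``xi``
  inflates prior uncertainty so older information is down-weighted;
* coefficients absent from the previous model (e.g. a newly introduced
  treatment) get independent ``N(0, 2.5)`` priors;
* ``lambda_u ~ N(0, sigma_lambda)``, vague.

The censored-data exponential log likelihood is
``sum_i [ d_i * omega_i - t_i * exp(omega_i) ]`` with ``t_i`` the observed
follow-up duration and ``d_i`` the event indicator. The posterior is
log-concave, which the sampler exploits: each chain is an independence
Metropolis–Hastings sampler whose proposal is a multivariate Student-t
built from the Laplace approximation (posterior mode and curvature), run
as multiple independent seeded chains so split-Rhat applies. Point
estimates are posterior medians.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .survdata import CohortTable

__all__ = [
    "PriorSpec",
    "SamplerConfig",
    "ExpPHPosterior",
    "ConvergenceReport",
    "ExponentialPHModel",
    "priors_from_state",
    "fit_exponential_ph_posterior",
    "posterior_predict_survival",
    "check_convergence",
]


@dataclass
class PriorSpec:
    """Forgetting-factor prior for one Bayesian update.

    ``beta_cov`` is the previous covariance already divided by the
    forgetting factor; ``from_cox`` flags priors taken from a
    semi-parametric Cox fit, whose coefficients were estimated under a
    different (non-exponential) baseline and may therefore be imperfect
    priors for the exponential model.
    """

    beta_mean: pd.Series
    beta_cov: pd.DataFrame
    forgetting_xi: float = 0.9
    lambda_prior_sd: float = 2.5
    new_coef_sd: float = 2.5
    from_cox: bool = False

    def __post_init__(self):
        if not 0 < self.forgetting_xi <= 1:
            raise ValueError("forgetting factor must be in (0, 1]")
        if self.lambda_prior_sd <= 0 or self.new_coef_sd <= 0:
            raise ValueError("prior standard deviations must be positive")
        cov = self.beta_cov.to_numpy(float)
        if cov.shape != (len(self.beta_mean),) * 2:
            raise ValueError("beta_cov dimension mismatch")
        if cov.size:
            eigvals = np.linalg.eigvalsh((cov + cov.T) / 2)
            if eigvals.min() < -1e-8 * max(1.0, eigvals.max()):
                raise ValueError("beta_cov must be positive semi-definite")

    @property
    def covariate_names(self) -> list[str]:
        return list(self.beta_mean.index)


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings. Defaults mirror a 2-chain, 7500-iteration run with
    1000 burn-in; reduced settings are fine for the log-concave posterior."""

    chains: int = 2
    iterations: int = 7500
    burn_in: int = 1000
    seed: int = 0
    proposal_df: float = 7.0  # Student-t degrees of freedom of the proposal
    proposal_scale: float = 1.2  # inflation of the Laplace covariance

    def __post_init__(self):
        if self.chains < 1 or self.iterations <= self.burn_in:
            raise ValueError("need >=1 chain and iterations > burn_in")


@dataclass
class ConvergenceReport:
    rhat: pd.Series
    ess: pd.Series
    mcse: pd.Series
    posterior_sd: pd.Series
    passed: bool
    rhat_threshold: float
    mcse_fraction: Optional[float]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rhat": self.rhat, "ess": self.ess, "mcse": self.mcse, "sd": self.posterior_sd}
        )


@dataclass
class ExpPHPosterior:
    """Posterior of the exponential PH model for one update period.

    ``draws`` has shape (chains, kept iterations, 1 + p) with the log
    baseline hazard first, then the coefficients in ``covariate_names``
    order. Point estimates are componentwise posterior medians over all
    chains.
    """

    draws: np.ndarray
    covariate_names: list[str]
    sampler_config: SamplerConfig
    fit_period: int = 0
    method_tag: str = "bayes"
    acceptance_rate: float = float("nan")
    retained: bool = False

    @property
    def param_names(self) -> list[str]:
        return ["lambda"] + list(self.covariate_names)

    @property
    def flat_draws(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    @property
    def point_estimates(self) -> pd.Series:
        return pd.Series(np.median(self.flat_draws, axis=0), index=self.param_names)

    @property
    def lambda_hat(self) -> float:
        return float(self.point_estimates["lambda"])

    @property
    def beta_hat(self) -> pd.Series:
        return self.point_estimates[self.covariate_names]

    def beta_covariance(self) -> pd.DataFrame:
        cov = np.cov(self.flat_draws[:, 1:], rowvar=False)
        cov = np.atleast_2d(cov)
        return pd.DataFrame(cov, index=self.covariate_names, columns=self.covariate_names)

    # -- predictions ---------------------------------------------------
    def linear_predictor(self, X) -> np.ndarray:
        from .estimators import _as_matrix

        return _as_matrix(X, self.covariate_names) @ self.beta_hat.to_numpy(float)

    def predict_survival(self, X, t) -> np.ndarray | float:
        return posterior_predict_survival(self, X, t)

    def predict_cumhaz(self, X, t) -> np.ndarray:
        """Cumulative hazard at posterior-median parameters; t may be a vector."""
        return np.asarray(t) * np.exp(self.lambda_hat + self.linear_predictor(X))

    def convergence(self, **kwargs) -> ConvergenceReport:
        return check_convergence(self, **kwargs)

    def summary(self) -> pd.DataFrame:
        flat = self.flat_draws
        rep = self.convergence() if self.draws.shape[0] >= 2 else None
        out = pd.DataFrame(
            {
                "median": np.median(flat, axis=0),
                "sd": flat.std(axis=0, ddof=1),
                "q2.5": np.quantile(flat, 0.025, axis=0),
                "q97.5": np.quantile(flat, 0.975, axis=0),
            },
            index=self.param_names,
        )
        if rep is not None:
            out["rhat"] = rep.rhat
            out["ess"] = rep.ess
        return out

    def draws_to_csv(self, path) -> None:
        """Write the draw matrix (one row per draw, chain column first)."""
        flat = self.flat_draws
        chains = np.repeat(np.arange(self.draws.shape[0]), self.draws.shape[1])
        out = pd.DataFrame(flat, columns=self.param_names)
        out.insert(0, "chain", chains)
        out.to_csv(path, index=False)

    def to_summary_json(self) -> str:
        import json

        rep = self.convergence() if self.draws.shape[0] >= 2 else None
        return json.dumps(
            {
                "medians": self.point_estimates.to_dict(),
                "sds": dict(
                    zip(self.param_names, self.flat_draws.std(axis=0, ddof=1))
                ),
                "rhat": rep.rhat.to_dict() if rep else None,
                "ess": rep.ess.to_dict() if rep else None,
                "acceptance_rate": self.acceptance_rate,
                "fit_period": self.fit_period,
            }
        )


def priors_from_state(
    previous, xi: float, new_covariates: Sequence[str] = (), **kwargs
) -> PriorSpec:
    """Build the forgetting-factor prior from last period's fitted state.

    ``previous`` may be a frequentist :class:`~dynasurv.estimators.PHResults`
    (its coefficients and covariance are used, flagged as Cox-derived) or a
    previous :class:`ExpPHPosterior` (posterior medians and covariance of
    the coefficient draws). The covariance is scaled by ``1/xi`` and any
    ``new_covariates`` receive independent N(0, ``new_coef_sd``) priors.
    """
    if not 0 < xi <= 1:
        raise ValueError("forgetting factor must be in (0, 1]")
    from .estimators import PHResults

    if isinstance(previous, ExpPHPosterior):
        mean = previous.beta_hat.copy()
        cov = previous.beta_covariance().to_numpy(float)
        from_cox = False
    elif isinstance(previous, PHResults):
        mean = previous.coefficients.copy()
        cov = previous.covariance.to_numpy(float)
        from_cox = previous.method_tag != "bayes"
    else:
        raise TypeError("previous must be PHResults or ExpPHPosterior")

    new_sd = kwargs.get("new_coef_sd", 2.5)
    names = list(mean.index)
    cov = cov / xi
    for c in new_covariates:
        if c in names:
            continue
        names.append(c)
        mean[c] = 0.0
        k = len(names)
        padded = np.zeros((k, k))
        padded[: k - 1, : k - 1] = cov
        padded[k - 1, k - 1] = new_sd**2
        cov = padded
    return PriorSpec(
        beta_mean=mean[names],
        beta_cov=pd.DataFrame(cov, index=names, columns=names),
        forgetting_xi=xi,
        from_cox=from_cox,
        **kwargs,
    )


# ----------------------------------------------------------------------
# model and sampler
# ----------------------------------------------------------------------

class ExponentialPHModel:
    """Bayesian exponential proportional-hazards model for one period."""

    def __init__(
        self,
        cohort: CohortTable,
        prior: PriorSpec,
        covariates: Optional[Sequence[str]] = None,
    ):
        self.cohort = cohort
        self.prior = prior
        self.covariates = (
            list(covariates) if covariates is not None else prior.covariate_names
        )
        if self.covariates != prior.covariate_names:
            raise ValueError("covariates must match the prior's covariate names")
        df = cohort.df
        self._X = df[self.covariates].to_numpy(float)
        self._dur = (df["exit_time"] - df["entry_time"]).to_numpy(float)
        self._ev = df["event"].to_numpy(float)
        # prior precision pieces
        self._pm = np.concatenate(([0.0], prior.beta_mean.to_numpy(float)))
        prec_beta = np.linalg.inv(prior.beta_cov.to_numpy(float))
        p = len(self.covariates)
        self._prec = np.zeros((p + 1, p + 1))
        self._prec[0, 0] = 1.0 / prior.lambda_prior_sd**2
        self._prec[1:, 1:] = (prec_beta + prec_beta.T) / 2

    # log posterior and derivatives ------------------------------------
    def _omega(self, theta: np.ndarray) -> np.ndarray:
        return theta[0] + self._X @ theta[1:]

    def log_posterior(self, theta: np.ndarray) -> float:
        om = self._omega(theta)
        ll = np.sum(self._ev * om - self._dur * np.exp(om))
        dd = theta - self._pm
        return float(ll - 0.5 * dd @ self._prec @ dd)

    def _log_posterior_many(self, thetas: np.ndarray) -> np.ndarray:
        # chunked so that (proposals x subjects) intermediates stay small
        n = len(self._dur)
        chunk = max(1, int(4_000_000 / max(n, 1)))
        out = np.empty(len(thetas))
        for s in range(0, len(thetas), chunk):
            block = thetas[s : s + chunk]
            om = block[:, 0][:, None] + block[:, 1:] @ self._X.T
            out[s : s + chunk] = om @ self._ev - np.exp(om) @ self._dur
        dd = thetas - self._pm
        return out - 0.5 * np.einsum("ij,jk,ik->i", dd, self._prec, dd)

    def _neg_log_post_grad(self, theta: np.ndarray):
        om = self._omega(theta)
        mu = self._dur * np.exp(om)
        resid = self._ev - mu
        grad = np.concatenate(([resid.sum()], self._X.T @ resid))
        grad -= self._prec @ (theta - self._pm)
        return -self.log_posterior(theta), -grad

    def _hessian(self, theta: np.ndarray) -> np.ndarray:
        om = self._omega(theta)
        w = self._dur * np.exp(om)
        p = self._X.shape[1]
        H = np.zeros((p + 1, p + 1))
        H[0, 0] = w.sum()
        xw = self._X.T @ w
        H[0, 1:] = xw
        H[1:, 0] = xw
        H[1:, 1:] = self._X.T @ (self._X * w[:, None])
        return H + self._prec

    def laplace(self) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mode and inverse-curvature covariance."""
        theta0 = self._pm.copy()
        # crude rate-based start for lambda
        total_t = max(self._dur.sum(), 1e-12)
        d = max(self._ev.sum(), 0.5)
        theta0[0] = np.log(d / total_t) - float(np.mean(self._X @ theta0[1:]))
        res = minimize(
            self._neg_log_post_grad, theta0, jac=True, method="BFGS",
            options={"maxiter": 500, "gtol": 1e-8},
        )
        mode = res.x
        cov = np.linalg.inv(self._hessian(mode))
        return mode, (cov + cov.T) / 2

    # sampling ----------------------------------------------------------
    def fit(self, sampler: Optional[SamplerConfig] = None, fit_period: int = 0) -> ExpPHPosterior:
        cfg = sampler or SamplerConfig()
        mode, cov = self.laplace()
        scale = cov * cfg.proposal_scale
        chol = np.linalg.cholesky(scale)
        dim = len(mode)
        nu = cfg.proposal_df
        keep = cfg.iterations - cfg.burn_in
        ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(271828,))
        chain_seeds = ss.spawn(cfg.chains)
        all_draws = np.empty((cfg.chains, keep, dim))
        accepts = 0

        # log density of the multivariate-t proposal (constant terms dropped)
        prec_chol = np.linalg.inv(chol)

        def log_q(thetas: np.ndarray) -> np.ndarray:
            z = (thetas - mode) @ prec_chol.T
            return -0.5 * (nu + dim) * np.log1p((z * z).sum(axis=1) / nu)

        for c, cs in enumerate(chain_seeds):
            rng = np.random.default_rng(cs)
            # draw all proposals up front; vectorised density evaluation
            z = rng.standard_normal((cfg.iterations, dim))
            g = rng.chisquare(nu, size=cfg.iterations) / nu
            props = mode + (z / np.sqrt(g)[:, None]) @ chol.T
            lp = self._log_posterior_many(props)
            lq = log_q(props)
            logu = np.log(rng.random(cfg.iterations))

            cur = mode.copy()
            cur_lp = self.log_posterior(cur)
            cur_lq = float(log_q(cur[None, :])[0])
            chain = np.empty((cfg.iterations, dim))
            for i in range(cfg.iterations):
                if logu[i] < (lp[i] - cur_lp) - (lq[i] - cur_lq):
                    cur, cur_lp, cur_lq = props[i], lp[i], lq[i]
                    accepts += 1
                chain[i] = cur
            all_draws[c] = chain[cfg.burn_in:]

        return ExpPHPosterior(
            draws=all_draws,
            covariate_names=list(self.covariates),
            sampler_config=cfg,
            fit_period=fit_period,
            acceptance_rate=accepts / (cfg.chains * cfg.iterations),
        )


def fit_exponential_ph_posterior(
    cohort: CohortTable,
    prior: PriorSpec,
    sampler: Optional[SamplerConfig] = None,
    covariates: Optional[Sequence[str]] = None,
    fit_period: int = 0,
) -> ExpPHPosterior:
    """Fit the Bayesian exponential PH model; see :class:`ExponentialPHModel`."""
    return ExponentialPHModel(cohort, prior, covariates).fit(sampler, fit_period)


def posterior_predict_survival(posterior: ExpPHPosterior, X, t) -> np.ndarray | float:
    """Posterior-predictive survival: mean over draws of ``exp(-t e^omega)``.

    Vectorised over subjects; scalar input gives a scalar output.
    """
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be >= 0")
    flat = posterior.flat_draws
    if flat.shape[0] == 0:
        raise ValueError("posterior has no draws")
    from .estimators import _as_matrix

    Xm = _as_matrix(X, posterior.covariate_names)
    scalar = Xm.shape[0] == 1
    # omega: draws x subjects, averaged over draws in chunks to bound memory
    out = np.zeros(Xm.shape[0])
    chunk = max(1, int(2_000_000 / max(Xm.shape[0], 1)))
    for start in range(0, flat.shape[0], chunk):
        block = flat[start : start + chunk]
        om = block[:, 0][:, None] + block[:, 1:] @ Xm.T
        out += np.exp(-np.asarray(t) * np.exp(om)).sum(axis=0)
    out /= flat.shape[0]
    return float(out[0]) if (scalar and out.size == 1) else out


def check_convergence(
    posterior: ExpPHPosterior,
    rhat_threshold: float = 1.1,
    mcse_fraction: Optional[float] = None,
) -> ConvergenceReport:
    """Split-Rhat / ESS / MCSE diagnostics.

    Passes when every parameter's split-Rhat is below ``rhat_threshold``
    and, if ``mcse_fraction`` is given (e.g. 0.01), every parameter's
    Monte-Carlo standard error is at most that fraction of its posterior
    standard deviation. Requires at least two chains.
    """
    if posterior.draws.shape[0] < 2:
        raise ValueError("convergence diagnostics require at least 2 chains")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        idata = az.convert_to_dataset(
            {"theta": posterior.draws}, coords={"param": posterior.param_names},
            dims={"theta": ["param"]},
        )
        rhat = az.rhat(idata)["theta"].to_numpy()
        ess = az.ess(idata)["theta"].to_numpy()
        mcse = az.mcse(idata)["theta"].to_numpy()
    names = posterior.param_names
    sd = posterior.flat_draws.std(axis=0, ddof=1)
    passed = bool(np.all(rhat < rhat_threshold))
    if mcse_fraction is not None:
        passed = passed and bool(np.all(mcse <= mcse_fraction * sd))
    return ConvergenceReport(
        rhat=pd.Series(rhat, index=names),
        ess=pd.Series(ess, index=names),
        mcse=pd.Series(mcse, index=names),
        posterior_sd=pd.Series(sd, index=names),
        passed=passed,
        rhat_threshold=rhat_threshold,
        mcse_fraction=mcse_fraction,
    )
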