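import numpy as np
import pandas as pd
import pytest

from dynasurv.survdata import CohortTable


def make_cohort(durations, events, sim_id=0, period=0, **covariates) -> CohortTable:
    """Build a one-row-per-subject cohort from durations and covariates."""
    durations = np.asarray(durations, dtype=float)
    n = len(durations)
    df = pd.DataFrame(
        {
            "sim_id": sim_id,
            "subject_id": np.arange(1, n + 1),
            "period_u": period,
            "entry_time": 0.0,
            "exit_time": durations,
            "event": np.asarray(events, dtype=int),
        }
    )
    for name, vals in covariates.items():
        df[name] = np.asarray(vals, dtype=float)
    return CohortTable(df)


def simulate_exponential_cohort(
    n, betas, log_baseline, rng, censor_at=12.0, binary=("x3",), p_binary=0.3
):
    """Plain exponential PH cohort: standard normal covariates except the
    named binary ones; censoring only administrative at ``censor_at``."""
    covs = {}
    names = list(betas.keys())
    for name in names:
        if name in binary:
            covs[name] = (rng.random(n) < p_binary).astype(float)
        else:
            covs[name] = rng.normal(size=n)
    X = np.column_stack([covs[c] for c in names])
    b = np.array([betas[c] for c in names])
    rate = np.exp(log_baseline + X @ b)
    T = rng.exponential(1.0 / rate)
    dur = np.minimum(T, censor_at)
    ev = (T <= censor_at).astype(int)
    return make_cohort(dur, ev, **covs)


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)
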