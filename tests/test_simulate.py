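import numpy as np
import pytest

from dynasurv.simulate import (
    ScenarioConfig,
    assign_treatment,
    calibrate_baseline,
    draw_covariates,
    draw_event_times,
    gen_newcohort_series,
    gen_replacement_series,
)


@pytest.fixture(scope="module")
def reference():
    return ScenarioConfig.preset("constant_events", seed=11)


class TestCovariates:
    def test_reference_covariate_law(self, reference, rng):
        X = draw_covariates(100_000, reference, 0, rng)
        assert X["x1"].mean() == pytest.approx((1.8 + 9.5) / 2, abs=0.05)
        assert X["x1"].between(1.8, 9.5).all()
        assert X["x2"].mean() == pytest.approx(1.0, abs=0.02)
        assert X["x2"].std() == pytest.approx(1.0, abs=0.02)
        assert X["x3"].mean() == pytest.approx(reference.p_x3, abs=0.005)

    def test_rare_risk_factor_prevalence_over_55(self, rng):
        scen = ScenarioConfig.preset("rare_1pct", seed=11)
        X = draw_covariates(200_000, scen, 0, rng)
        over55 = X[X["x1"] > 5.5]
        assert over55["x3"].mean() == pytest.approx(0.01, abs=0.002)
        # prevalence increases with age
        young = X[X["x1"] <= 5.5]["x3"].mean()
        old = X[X["x1"] > 8.0]["x3"].mean()
        assert young < old

    def test_same_seed_reproduces_draws(self, reference):
        a = draw_covariates(500, reference, 0, np.random.default_rng(3))
        b = draw_covariates(500, reference, 0, np.random.default_rng(3))
        assert a.equals(b)


class TestTreatment:
    def test_no_treatment_before_introduction(self, rng):
        scen = ScenarioConfig.preset("new_treatment", seed=11)
        X = draw_covariates(5000, scen, period=1, rng=rng)
        assert (X["x4"] == 0).all()

    def test_full_uptake_equals_age_threshold_set(self, rng):
        from dynasurv.simulate import RolloutSchedule

        scen = ScenarioConfig.preset(
            "new_treatment", seed=11,
            rollout=RolloutSchedule(introduction_period=2, initial_age_threshold=7.5, uptake=1.0),
        )
        X = draw_covariates(5000, scen, period=1, rng=rng)
        x4 = assign_treatment(X, scen, period=2, rng=rng)
        assert set(np.where(x4 == 1)[0]) == set(np.where(X["x1"] >= 7.5)[0])

    def test_comorbidity_override_makes_young_sick_eligible(self, rng):
        from dynasurv.simulate import RolloutSchedule

        scen = ScenarioConfig.preset(
            "new_treatment_comorbidity", seed=11,
            rollout=RolloutSchedule(comorbidity_override=True, uptake=1.0),
        )
        X = draw_covariates(5000, scen, period=1, rng=rng)
        x4 = assign_treatment(X, scen, period=2, rng=rng)
        young_sick = (X["x1"] < 7.5) & (X["x3"] == 1)
        assert x4[young_sick.to_numpy()].all()

    def test_treated_fraction_nondecreasing(self, rng):
        scen = ScenarioConfig.preset("new_treatment", seed=11)
        X = draw_covariates(20_000, scen, period=1, rng=rng)
        frac = []
        x4 = np.zeros(len(X), dtype=int)
        for u in range(2, 6):
            x4 = assign_treatment(X, scen, u, rng, current=x4)
            frac.append(x4.mean())
        assert all(a <= b for a, b in zip(frac, frac[1:]))


class TestEventTimes:
    def test_exponential_median_no_covariates(self, rng):
        lam = -3.0
        X = np.zeros((100_000, 1))
        T = draw_event_times(X, lam, np.array([0.0]), rng)
        assert np.median(T) == pytest.approx(np.log(2) / np.exp(lam), rel=0.02)

    def test_hazard_ratio_recovered_at_large_n(self, rng):
        # doubling exposure to a unit-beta covariate scales the fitted HR as exp(beta)
        from dynasurv.estimators import fit_ph
        from conftest import simulate_exponential_cohort

        beta = 0.7
        tab = simulate_exponential_cohort(
            20_000, {"x": beta}, log_baseline=-4.0, rng=rng, censor_at=12.0, binary=()
        )
        fit = fit_ph(tab)
        assert fit.coefficients["x"] == pytest.approx(beta, abs=0.05)


class TestCalibration:
    def test_closed_form_without_covariates(self):
        scen = ScenarioConfig.preset(
            "constant_events", seed=0, log_hazard_ratios={"x1": 0.0, "x2": 0.0, "x3": 0.0}
        )
        lam = calibrate_baseline(scen, 0)
        assert lam == pytest.approx(np.log(-np.log(0.95) / 12.0), abs=1e-8)

    def test_marginal_event_rate_hits_target(self, reference, rng):
        lam = reference.log_baseline(0)
        X = draw_covariates(100_000, reference, 0, rng)
        T = draw_event_times(
            X[reference.covariate_names], lam, reference.betas(), rng
        )
        assert 0.045 <= (T <= 12.0).mean() <= 0.055

    def test_decreasing_rate_path_gives_decreasing_baseline(self):
        scen = ScenarioConfig.preset("decreasing_events", seed=5)
        lams = [scen.log_baseline(u) for u in range(6)]
        assert all(a >= b for a, b in zip(lams[1:], lams[2:]))
        assert lams[1] > lams[5]


def small(name, framework="replacement", **kw):
    kw = {"n_dev": 300, "n_replacements": 60, "n_per_month": 50, **kw}
    return ScenarioConfig.preset(name, framework=framework, **kw)


class TestReplacementFramework:
    def test_degenerate_no_events_means_static_membership(self):
        scen = small("constant_events", seed=3, n_replacements=0,
                     annual_event_rate_path=(1e-9,) * 6)
        series = gen_replacement_series(scen)
        ids0 = set(series[1].df["subject_id"])
        for tab in series[1:]:
            df = tab.df
            assert tab.n_events == 0
            assert set(df["subject_id"]) == ids0
            assert (df["entry_time"] == 0).all()
            assert (df["exit_time"] == 3.0).all()

    def test_event_followed_by_entrant_next_month(self):
        scen = small("constant_events", seed=4,
                     annual_event_rate_path=(0.4,) * 6)  # high rate: many replacements
        series = gen_replacement_series(scen)
        for tab in series[1:]:
            df = tab.df
            for m in (0.0, 1.0):
                exits = (
                    ((df["event"] == 1) & (df["exit_time"] > m) & (df["exit_time"] <= m + 1))
                    | ((df["event"] == 0) & (df["exit_time"] == m + 1))
                ).sum()
                entrants = (df["entry_time"] == m + 1).sum()
                # replacement rule replayed from the output table itself
                assert entrants == exits

    def test_pool_size_is_conserved(self):
        scen = small("constant_events", seed=5)
        series = gen_replacement_series(scen)
        for tab in series[1:]:
            df = tab.df
            # subjects under observation just after each month start
            for t in (0.001, 1.001, 2.001):
                active = ((df["entry_time"] <= t) & (df["exit_time"] > t)).sum()
                assert active == scen.n_dev

    def test_development_cohort_censored_at_one_year(self):
        scen = small("constant_events", seed=6)
        d0 = gen_replacement_series(scen)[0]
        assert len(d0) == scen.n_dev
        assert d0.df["exit_time"].max() <= 12.0
        assert ((d0.df["event"] == 1) | (d0.df["exit_time"] == 12.0)).all()


class TestNewCohortsFramework:
    def test_wave_structure_and_disjoint_quarters(self):
        scen = small("constant_events", framework="new_cohorts", seed=7)
        series = gen_newcohort_series(scen)
        seen: set = set()
        for tab in series[1:]:
            df = tab.df
            ids = set(df["subject_id"])
            assert not ids & seen
            seen |= ids
            for wave, max_f in ((0.0, 3.0), (1.0, 2.0), (2.0, 1.0)):
                sub = df[df["entry_time"] == wave]
                assert len(sub) == scen.n_per_month
                durations = sub["exit_time"] - sub["entry_time"]
                assert durations.max() <= max_f + 1e-12
                # censoring only at the quarter boundary: a non-event implies
                # full follow-up to the quarter end (recount oracle)
                censored = sub[sub["event"] == 0]
                assert np.allclose(censored["exit_time"], 3.0)

    def test_generation_reproducible_from_seed(self):
        scen = small("constant_events", framework="new_cohorts", seed=8)
        a = gen_newcohort_series(scen, np.random.default_rng(1))
        b = gen_newcohort_series(scen, np.random.default_rng(1))
        assert all(x == y for x, y in zip(a, b))


def test_event_rate_monotone_under_drift():
    """Per-quarter event rates follow the configured drift direction in
    expectation (averaged over replicates)."""
    rates = {}
    for name in ("decreasing_events", "increasing_events"):
        scen = ScenarioConfig.preset(name, n_dev=400, n_replacements=80, seed=9)
        per_quarter = np.zeros(5)
        reps = 50
        for k in range(reps):
            rng = np.random.default_rng(np.random.SeedSequence(entropy=9, spawn_key=(k,)))
            series = gen_replacement_series(scen, rng, sim_id=k)
            for u, tab in enumerate(series[1:], start=1):
                per_quarter[u - 1] += tab.n_events / tab.total_followup / reps
        rates[name] = per_quarter
    assert rates["decreasing_events"][0] > rates["decreasing_events"][-1]
    assert rates["increasing_events"][0] < rates["increasing_events"][-1]
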