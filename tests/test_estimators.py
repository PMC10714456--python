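import numpy as np
import pandas as pd
import pytest

from dynasurv.estimators import (
    DegenerateCovariateError,
    PHResults,
    StepFunction,
    breslow_cumhaz,
    fit_ph,
    recalibrate_intercept,
    refit,
)
from dynasurv.metrics import ipcw_cindex
from conftest import make_cohort, simulate_exponential_cohort


def breslow_log_partial_likelihood(beta, dur, ev, x):
    """Independent oracle: Breslow-ties log partial likelihood for a single
    covariate, by direct summation over event times."""
    lp = 0.0
    for t in np.unique(dur[ev == 1]):
        dead = (dur == t) & (ev == 1)
        at_risk = dur >= t
        lp += beta * x[dead].sum() - dead.sum() * np.log(np.sum(np.exp(beta * x[at_risk])))
    return lp


class TestFitPH:
    def test_matches_grid_search_on_toy(self):
        """Fitted log HR equals the argmax of the Breslow partial likelihood
        located by brute-force grid search."""
        dur = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        ev = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        tab = make_cohort(dur, ev, x=x)
        fit = fit_ph(tab)
        grid = np.arange(-5.0, 5.0, 1e-4)
        lps = [breslow_log_partial_likelihood(b, dur, ev, x) for b in grid]
        beta_star = grid[int(np.argmax(lps))]
        assert fit.coefficients["x"] == pytest.approx(beta_star, abs=1e-3)

    def test_constant_covariate_refused_by_name(self):
        tab = make_cohort([1.0, 2.0, 3.0], [1, 1, 0], x=[2.0, 2.0, 2.0])
        with pytest.raises(DegenerateCovariateError, match="'x'"):
            fit_ph(tab)

    def test_null_covariate_estimate_small(self, rng):
        tab = simulate_exponential_cohort(
            10_000, {"x": 0.0}, log_baseline=-3.5, rng=rng, binary=()
        )
        fit = fit_ph(tab)
        se = np.sqrt(fit.covariance.loc["x", "x"])
        assert abs(fit.coefficients["x"]) < 3 * se

    def test_fit_is_deterministic(self, rng):
        tab = simulate_exponential_cohort(
            2_000, {"x": 0.5}, log_baseline=-3.5, rng=rng, binary=()
        )
        a, b = fit_ph(tab), fit_ph(tab)
        assert (a.coefficients == b.coefficients).all()
        assert np.array_equal(a.baseline_cumhaz.values, b.baseline_cumhaz.values)


class TestBreslowBaseline:
    def test_null_model_equals_nelson_aalen(self):
        from lifelines import NelsonAalenFitter

        dur = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 7.0])
        ev = np.array([1, 1, 1, 0, 1, 0, 1])
        tab = make_cohort(dur, ev, x=np.zeros(7))
        state = PHResults(
            coefficients=pd.Series({"x": 0.0}),
            covariance=pd.DataFrame([[1.0]], index=["x"], columns=["x"]),
            baseline_cumhaz=StepFunction(np.array([1.0]), np.array([0.0])),
        )
        H = breslow_cumhaz(state, tab)
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(dur, event_observed=ev)
        for t in (0.5, 1.0, 2.5, 4.0, 7.0):
            assert H(t) == pytest.approx(
                float(naf.cumulative_hazard_.loc[:t].iloc[-1, 0]), abs=1e-10
            )

    def test_hand_computed_jumps(self):
        # 4 subjects, eta = log([2, 1, 1, 0.5]); events at t=1 (s1) and t=3 (s3)
        dur = np.array([1.0, 2.0, 3.0, 4.0])
        ev = np.array([1, 0, 1, 0])
        x = np.array([1.0, 0.0, 0.0, -1.0])
        beta = np.log(2.0)
        state = PHResults(
            coefficients=pd.Series({"x": beta}),
            covariance=pd.DataFrame([[1.0]], index=["x"], columns=["x"]),
            baseline_cumhaz=StepFunction(np.array([1.0]), np.array([0.0])),
        )
        H = breslow_cumhaz(state, make_cohort(dur, ev, x=x))
        jump1 = 1.0 / (2.0 + 1.0 + 1.0 + 0.5)
        jump2 = 1.0 / (1.0 + 0.5)
        assert H(0.5) == 0.0
        assert H(1.0) == pytest.approx(jump1, abs=1e-12)
        assert H(3.5) == pytest.approx(jump1 + jump2, abs=1e-12)

    def test_zero_before_first_event(self):
        tab = make_cohort([2.0, 3.0], [1, 0], x=[1.0, 0.0])
        state = PHResults(
            coefficients=pd.Series({"x": 0.3}),
            covariance=pd.DataFrame([[1.0]], index=["x"], columns=["x"]),
            baseline_cumhaz=StepFunction(np.array([1.0]), np.array([0.0])),
        )
        assert breslow_cumhaz(state, tab)(1.99) == 0.0


class TestPredictSurvival:
    @pytest.fixture
    def state(self):
        return PHResults(
            coefficients=pd.Series({"x": np.log(2.0)}),
            covariance=pd.DataFrame([[0.1]], index=["x"], columns=["x"]),
            baseline_cumhaz=StepFunction(np.array([1.0, 3.0]), np.array([0.1, 0.2])),
        )

    def test_direct_substitution(self, state):
        # eta = 0 -> S = exp(-H0(t))
        assert state.predict_survival({"x": 0.0}, 3.0) == pytest.approx(np.exp(-0.2))
        # eta = log 2 -> S = exp(-0.4)
        assert state.predict_survival({"x": 1.0}, 3.0) == pytest.approx(np.exp(-0.4))

    def test_boundary_t_zero(self, state):
        assert state.predict_survival({"x": 1.3}, 0.0) == 1.0

    def test_monotone_in_linear_predictor(self, state):
        s = [state.predict_survival({"x": v}, 3.0) for v in (-1.0, 0.0, 1.0, 2.0)]
        assert all(a > b for a, b in zip(s, s[1:]))

    def test_unknown_covariate_name(self, state):
        with pytest.raises(KeyError):
            state.predict_survival(pd.DataFrame({"z": [1.0]}), 3.0)

    def test_json_roundtrip(self, state):
        back = PHResults.from_json(state.to_json())
        assert (back.coefficients == state.coefficients).all()
        assert back.predict_survival({"x": 1.0}, 2.0) == state.predict_survival({"x": 1.0}, 2.0)


class TestRecalibration:
    def test_self_recalibration_reproduces_baseline(self, rng):
        tab = simulate_exponential_cohort(
            500, {"x": 0.8}, log_baseline=-3.0, rng=rng, binary=()
        )
        fit = fit_ph(tab)
        rec = recalibrate_intercept(fit, tab)
        assert np.allclose(rec.baseline_cumhaz.jump_times, fit.baseline_cumhaz.jump_times)
        assert np.allclose(rec.baseline_cumhaz.values, fit.baseline_cumhaz.values)
        assert rec.method_tag == "recalibrated"

    def test_doubled_hazard_doubles_baseline(self, rng):
        base = simulate_exponential_cohort(
            50_000, {"x": 0.5}, log_baseline=-3.5, rng=rng, binary=()
        )
        fit = fit_ph(base)
        doubled = simulate_exponential_cohort(
            100_000, {"x": 0.5}, log_baseline=-3.5 + np.log(2.0), rng=rng, binary=()
        )
        rec = recalibrate_intercept(fit, doubled)
        ratio = rec.baseline_cumhaz(6.0) / fit.baseline_cumhaz(6.0)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_discrimination_unchanged(self, rng):
        train = simulate_exponential_cohort(
            1_000, {"x": 0.7, "z": -0.4}, log_baseline=-3.0, rng=rng, binary=()
        )
        test = simulate_exponential_cohort(
            1_000, {"x": 0.7, "z": -0.4}, log_baseline=-2.5, rng=rng, binary=()
        )
        fit = fit_ph(train)
        rec = recalibrate_intercept(fit, test)
        horizon = 3.0
        c_before = ipcw_cindex(1 - np.asarray(fit.predict_survival(test.df, horizon)), test, horizon)
        c_after = ipcw_cindex(1 - np.asarray(rec.predict_survival(test.df, horizon)), test, horizon)
        assert c_before == c_after

    def test_prediction_order_preserved(self, rng):
        train = simulate_exponential_cohort(
            300, {"x": 0.7}, log_baseline=-3.0, rng=rng, binary=()
        )
        fit = fit_ph(train)
        rec = recalibrate_intercept(fit, train)
        xs = np.linspace(-2, 2, 41)
        s0 = np.array([fit.predict_survival({"x": v}, 3.0) for v in xs])
        s1 = np.array([rec.predict_survival({"x": v}, 3.0) for v in xs])
        assert (np.argsort(s0) == np.argsort(s1)).all()

    def test_requires_events(self):
        tab = make_cohort([1.0, 2.0], [0, 0], x=[0.5, -0.5])
        state = PHResults(
            coefficients=pd.Series({"x": 0.1}),
            covariance=pd.DataFrame([[1.0]], index=["x"], columns=["x"]),
            baseline_cumhaz=StepFunction(np.array([1.0]), np.array([0.1])),
        )
        with pytest.raises(ValueError, match="no events"):
            recalibrate_intercept(state, tab)


class TestRefit:
    def test_stationary_refit_close_to_previous(self, rng):
        a = simulate_exponential_cohort(10_000, {"x3": 0.8}, log_baseline=-4.0, rng=rng)
        b = simulate_exponential_cohort(10_000, {"x3": 0.8}, log_baseline=-4.0, rng=rng)
        prev = fit_ph(a)
        new = refit(b, ["x3"], prev)
        se = np.sqrt(new.covariance.loc["x3", "x3"])
        assert not new.retained
        assert abs(new.coefficients["x3"] - prev.coefficients["x3"]) < 3 * se

    def test_zero_event_level_falls_back_to_previous(self, rng):
        prev_tab = simulate_exponential_cohort(500, {"x3": 0.8}, log_baseline=-3.0, rng=rng)
        prev = fit_ph(prev_tab)
        # new binary predictor whose positive level has no events
        n = 200
        dur = rng.exponential(4.0, size=n)
        ev = (dur < 3.0).astype(int)
        new_bin = np.zeros(n)
        new_bin[ev == 0] = (rng.random((ev == 0).sum()) < 0.3).astype(float)[: (ev == 0).sum()]
        tab = make_cohort(np.minimum(dur, 3.0), ev, x3=(rng.random(n) < 0.3).astype(float), x4=new_bin)
        out = refit(tab, ["x3", "x4"], prev)
        assert out.retained
        assert (out.coefficients == prev.coefficients).all()

    def test_tracks_shifted_coefficient(self, rng):
        prev = fit_ph(simulate_exponential_cohort(10_000, {"x3": 0.8}, log_baseline=-4.0, rng=rng))
        shifted = simulate_exponential_cohort(10_000, {"x3": 0.4}, log_baseline=-4.0, rng=rng)
        new = refit(shifted, ["x3"], prev)
        se = np.sqrt(new.covariance.loc["x3", "x3"])
        assert abs(new.coefficients["x3"] - 0.4) < 3 * se


def test_coefficient_recovery_improves_with_n(rng):
    """Large-sample consistency: bias shrinks from n=1e3 to n=1e4."""
    errs = {}
    for n in (1_000, 10_000):
        reps = []
        for k in range(5):
            tab = simulate_exponential_cohort(
                n, {"x": 0.5}, log_baseline=-3.5,
                rng=np.random.default_rng(100 * n + k), binary=()
            )
            reps.append(fit_ph(tab).coefficients["x"] - 0.5)
        errs[n] = np.abs(np.mean(reps))
    assert errs[10_000] < 0.05
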