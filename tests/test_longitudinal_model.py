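"""Mixed sub-models: splines, REML fit (with independent oracles), BLUPs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from fbctrend import (
    LongitudinalParams,
    RandomEffects,
    SplineSpec,
    estimate_random_effects,
    fit_mixed_model,
    linear_spline_basis,
    trend_deviation,
)
from fbctrend.longitudinal_model import estimate_random_effects_batch
from tests.conftest import make_prepared


class TestSplineBasis:
    @pytest.mark.parametrize(
        "x, knots, expected",
        [
            (60.0, (60.0, 70.0, 80.0), [60.0, 0.0, 0.0, 0.0]),
            (75.0, (60.0, 70.0, 80.0), [75.0, 15.0, 5.0, 0.0]),
            (2.0, (3.0,), [2.0, 0.0]),
        ],
    )
    def test_direct_evaluation(self, x, knots, expected):
        out = linear_spline_basis(x, SplineSpec(knots))
        assert np.allclose(out, expected)

    def test_non_increasing_knots_rejected(self):
        with pytest.raises(ValueError):
            SplineSpec((70.0, 60.0))

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=4, unique=True),
        st.floats(0.01, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_continuity_at_every_knot(self, knots, coef_scale):
        spec = SplineSpec(tuple(sorted(knots)))
        coefs = coef_scale * np.arange(1, spec.n_terms + 1)
        for k in spec.knots:
            below = linear_spline_basis(k - 1e-9, spec) @ coefs
            above = linear_spline_basis(k + 1e-9, spec) @ coefs
            assert abs(above - below) < 1e-6


def _simulate_simple(rng, n_pat=400, beta=(2.0, -0.5, 0.3, -0.2),
                     G=((0.8, -0.05), (-0.05, 0.05)), s2=0.25, mean_visits=4.0):
    """Well-conditioned mixed-model data: centred age, simple knots."""
    nvis = 1 + rng.poisson(mean_visits - 1, n_pat)
    g = np.repeat(np.arange(n_pat), nvis)
    t = rng.uniform(0, 5, g.size)
    age = np.repeat(rng.normal(0, 1, n_pat), nvis)
    b = rng.multivariate_normal([0, 0], G, size=n_pat)
    y = (
        beta[0] + beta[1] * age + beta[2] * t + beta[3] * np.maximum(t - 3, 0)
        + b[g, 0] + b[g, 1] * t + rng.normal(0, np.sqrt(s2), g.size)
    )
    pid = np.array([f"p{i}" for i in range(n_pat)])
    patients = pd.DataFrame({"patient_id": pid, "age_at_baseline": age[np.cumsum(nvis) - 1]})
    meas = pd.DataFrame(
        {"patient_id": pid[g], "analyte": "HB", "value": y, "window_time": t}
    )
    return make_prepared(patients, meas), b


def _dense_reml_criterion(y, X, t, g, G, s2):
    """Independent dense-matrix REML criterion (no cross-product tricks)."""
    n, p = X.shape
    Z = np.column_stack([np.ones_like(t), t])
    V = s2 * np.eye(n)
    for i in np.unique(g):
        idx = np.flatnonzero(g == i)
        V[np.ix_(idx, idx)] += Z[idx] @ G @ Z[idx].T
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    _, ldV = np.linalg.slogdet(V)
    _, ldA = np.linalg.slogdet(A)
    return float(ldV + ldA + r @ Vi @ r)


class TestFitMixedModel:
    def test_noise_free_data_recovers_fixed_effects(self):
        rng = np.random.default_rng(0)
        prep, _ = _simulate_simple(rng, n_pat=150, G=((0, 0), (0, 0)), s2=1e-6)
        params = fit_mixed_model(prep, "HB", age_spec=SplineSpec(()),
                                 interaction=False)
        est = [params.intercept, params.age_coefs[0], *params.time_coefs]
        assert np.allclose(est, [2.0, -0.5, 0.3, -0.2], atol=1e-3)

    def test_matches_brute_force_dense_reml_on_toy(self):
        """3 patients x 4 visits: generic optimiser on a hand-written
        dense REML criterion finds the same optimum."""
        rng = np.random.default_rng(1)
        g = np.repeat(np.arange(3), 4)
        t = np.tile([0.5, 2.0, 3.5, 5.0], 3)
        age = np.repeat([-0.5, 0.3, 1.1], 4)
        b = rng.multivariate_normal([0, 0], [[0.5, 0.0], [0.0, 0.02]], size=3)
        y = 1.0 + 0.4 * age - 0.1 * t + b[g, 0] + b[g, 1] * t + rng.normal(0, 0.3, 12)
        pid = np.array(["a", "b", "c"])
        prep = make_prepared(
            pd.DataFrame({"patient_id": pid, "age_at_baseline": [-0.5, 0.3, 1.1]}),
            pd.DataFrame({"patient_id": pid[g], "analyte": "HB", "value": y,
                          "window_time": t}),
        )
        params = fit_mixed_model(prep, "HB", age_spec=SplineSpec(()),
                                 time_spec=SplineSpec((3.0,)), interaction=False)

        X = np.column_stack([np.ones(12), age, t, np.maximum(t - 3, 0)])

        # direct minimisation over (chol G, log s2)
        def crit4(th):
            L = np.array([[np.exp(th[0]), 0], [th[2], np.exp(th[1])]])
            return _dense_reml_criterion(y, X, t, g, L @ L.T, np.exp(th[3]))

        best = None
        for start in ([-1.0, -2.0, 0.0, -1.0], [0.0, -1.0, 0.0, -2.0]):
            res = minimize(crit4, start, method="Nelder-Mead",
                           options={"xatol": 1e-9, "fatol": 1e-11, "maxfev": 8000})
            if best is None or res.fun < best.fun:
                best = res
        L = np.array([[np.exp(best.x[0]), 0], [best.x[2], np.exp(best.x[1])]])
        G_oracle = L @ L.T
        s2_oracle = np.exp(best.x[3])
        # same optimum (criterion value is the robust comparison)
        c_mine = _dense_reml_criterion(y, X, t, g, params.re_cov, params.resid_var)
        assert c_mine == pytest.approx(best.fun, abs=1e-4)
        assert params.resid_var == pytest.approx(s2_oracle, rel=0.05)
        assert np.allclose(params.re_cov, G_oracle, atol=0.05 * max(1, G_oracle.max()))

    def test_matches_statsmodels_mixedlm(self):
        statsmodels = pytest.importorskip("statsmodels")
        from statsmodels.regression.mixed_linear_model import MixedLM

        rng = np.random.default_rng(2)
        prep, _ = _simulate_simple(rng, n_pat=500)
        params = fit_mixed_model(prep, "HB", age_spec=SplineSpec(()),
                                 interaction=False)
        sub = prep.measurements
        g, uniq = pd.factorize(sub["patient_id"])
        t = sub["window_time"].to_numpy()
        age = prep.patients.set_index("patient_id")["age_at_baseline"].loc[uniq].to_numpy()[g]
        X = np.column_stack([np.ones_like(t), age, t, np.maximum(t - 3, 0)])
        Z = np.column_stack([np.ones_like(t), t])
        fit = MixedLM(sub["value"].to_numpy(), X, groups=g, exog_re=Z).fit(reml=True)
        mine = np.r_[params.intercept, params.age_coefs, params.time_coefs]
        assert np.allclose(mine, fit.params[:4], atol=2e-3)
        assert np.allclose(params.re_cov, np.asarray(fit.cov_re), atol=2e-2)
        assert params.resid_var == pytest.approx(fit.scale, rel=0.02)

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(3)
        prep, _ = _simulate_simple(rng, n_pat=120)
        p1 = fit_mixed_model(prep, "HB", age_spec=SplineSpec(()), interaction=False)
        p2 = fit_mixed_model(prep, "HB", age_spec=SplineSpec(()), interaction=False)
        assert p1.intercept == p2.intercept
        assert np.array_equal(p1.re_cov, p2.re_cov)
        assert p1.resid_var == p2.resid_var

    def test_singular_design_rejected_with_column_names(self):
        pid = np.array(["a", "b", "c", "d"])
        g = np.repeat(np.arange(4), 3)
        prep = make_prepared(
            pd.DataFrame({"patient_id": pid, "age_at_baseline": [60.0] * 4}),
            pd.DataFrame({"patient_id": pid[g], "analyte": "HB",
                          "value": np.random.default_rng(0).normal(14, 1, 12),
                          "window_time": np.tile([1.0, 3.0, 5.0], 4)}),
        )
        # constant age makes intercept and age columns collinear
        with pytest.raises(ValueError, match="collinear"):
            fit_mixed_model(prep, "HB", interaction=False)

    def test_fixed_effect_ci_coverage_over_replicates(self):
        hits = total = 0
        beta_true = np.array([2.0, -0.5, 0.3, -0.2])
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            prep, _ = _simulate_simple(rng, n_pat=400)
            p = fit_mixed_model(prep, "HB", age_spec=SplineSpec(()), interaction=False)
            est = np.r_[p.intercept, p.age_coefs, p.time_coefs]
            se = np.sqrt(np.diag(p.fixed_cov))
            hits += int(np.sum(np.abs(est - beta_true) <= 1.96 * se))
            total += 4
        assert hits / total >= 0.75  # nominal 95%, small-replicate slack


class TestBlups:
    def test_hand_computed_two_by_two_solve(self):
        params = LongitudinalParams(
            analyte="HB", intercept=0.0, age_coefs=[0.0], time_coefs=[0.0, 0.0],
            re_cov=np.array([[1.0, 0.2], [0.2, 0.5]]), resid_var=0.4,
            age_knots=(), time_knots=(3.0,),
        )
        t = np.array([1.0, 4.0])
        r = np.array([0.7, -0.3])  # residuals (population mean is 0 here)
        Z = np.column_stack([np.ones(2), t])
        G = params.re_cov
        expected = G @ np.linalg.solve(Z.T @ Z @ G + 0.4 * np.eye(2), Z.T @ r)
        re = estimate_random_effects(params, t, r, age=60.0)
        assert np.allclose([re.b0, re.b1], expected, atol=1e-12)

    def test_patient_on_population_mean_gets_zero(self):
        params = LongitudinalParams(
            analyte="HB", intercept=14.0, age_coefs=[0.0], time_coefs=[0.1, 0.0],
            re_cov=np.eye(2), resid_var=0.3, age_knots=(), time_knots=(3.0,),
        )
        t = np.array([1.0, 2.0, 4.5])
        y = params.population_mean(55.0, t)
        re = estimate_random_effects(params, t, y, age=55.0)
        assert re.b0 == pytest.approx(0.0, abs=1e-12)
        assert re.b1 == pytest.approx(0.0, abs=1e-12)

    def test_full_shrinkage_limits(self):
        base = dict(analyte="HB", intercept=0.0, age_coefs=[0.0],
                    time_coefs=[0.0, 0.0], age_knots=(), time_knots=(3.0,))
        t = np.array([1.0, 4.0])
        y = np.array([2.0, -1.0])
        zero_g = LongitudinalParams(re_cov=np.zeros((2, 2)), resid_var=0.4, **base)
        re = estimate_random_effects(zero_g, t, y, age=60.0)
        assert (re.b0, re.b1) == (0.0, 0.0)
        huge_noise = LongitudinalParams(re_cov=np.eye(2), resid_var=1e12, **base)
        re = estimate_random_effects(huge_noise, t, y, age=60.0)
        assert abs(re.b0) < 1e-9 and abs(re.b1) < 1e-9

    def test_no_measurements_falls_back_to_population_mean(self):
        params = LongitudinalParams(
            analyte="HB", intercept=0.0, age_coefs=[0.0], time_coefs=[0.0, 0.0],
            re_cov=np.eye(2), resid_var=0.3, age_knots=(), time_knots=(3.0,),
        )
        re = estimate_random_effects(params, [], [], age=60.0)
        assert (re.b0, re.b1) == (0.0, 0.0)

    def test_batch_matches_per_patient(self, male_cohort, fitted_bundle):
        _, prep = male_cohort
        params = fitted_bundle.longitudinal["HB"]
        batch = estimate_random_effects_batch(params, prep).set_index("patient_id")
        ages = prep.patients.set_index("patient_id")["age_at_baseline"]
        sub = prep.measurements[prep.measurements["analyte"] == "HB"]
        for pid, grp in list(sub.groupby("patient_id"))[:20]:
            re = estimate_random_effects(
                params, grp["window_time"].to_numpy(), grp["value"].to_numpy(),
                ages.loc[pid],
            )
            assert batch.loc[pid, "b0"] == pytest.approx(re.b0, abs=1e-10)
            assert batch.loc[pid, "b1"] == pytest.approx(re.b1, abs=1e-10)


class TestTrendDeviation:
    def test_arithmetic(self):
        assert trend_deviation(RandomEffects(0.0, 0.0)) == 0.0
        assert trend_deviation(RandomEffects(-0.5, -0.1), 5.0) == pytest.approx(-1.0)

    def test_linearity(self):
        d1 = trend_deviation(RandomEffects(0.3, -0.05))
        d2 = trend_deviation(RandomEffects(0.6, -0.1))
        assert d2 == pytest.approx(2 * d1)
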