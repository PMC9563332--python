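"""Cox sub-model: FP age, partial likelihood (with oracles), Breslow, risks."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from fbctrend import (
    CoxParams,
    ModelBundle,
    breslow_baseline_survival,
    fit_cox,
    fp_age_terms,
    predict_patient,
    two_year_risk,
)
from fbctrend.risk_model import _cox_newton, cox_partial_loglik


class TestFpAgeTerms:
    def test_unit_age_gives_one_zero(self):
        a2, a2l = fp_age_terms(10.0, age_scale=10.0)
        assert (a2, a2l) == (1.0, 0.0)

    def test_direct_evaluation(self):
        a2, a2l = fp_age_terms(70.0, age_scale=10.0)
        assert a2 == pytest.approx(49.0)
        assert a2l == pytest.approx(49.0 * np.log(7.0))

    def test_ratio_is_log_age_hence_increasing(self):
        ages = np.array([45.0, 60.0, 75.0, 90.0])
        a2, a2l = fp_age_terms(ages)
        assert np.allclose(a2l / a2, np.log(ages))
        assert np.all(np.diff(a2l / a2) > 0)

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError):
            fp_age_terms(0.0)


def _toy_survival(rng, n=500, beta=(0.5, -0.3)):
    X = rng.normal(0, 1, (n, len(beta)))
    t = rng.exponential(1.0 / (0.2 * np.exp(X @ np.array(beta))))
    c = rng.exponential(5.0, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return time, event, X


class TestCoxNewton:
    def test_matches_brute_force_partial_likelihood_on_toy(self):
        """<= 10 distinct-time observations: generic optimiser agreement."""
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        X = np.array([[0.5], [-1.0], [0.2], [1.5], [-0.3], [0.8]])
        beta, cov, ll, conv = _cox_newton(time, event, X)
        res = minimize(lambda b: -cox_partial_loglik(time, event, X, b), [0.0],
                       method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        assert conv
        assert beta[0] == pytest.approx(res.x[0], abs=1e-5)
        assert ll == pytest.approx(-res.fun, abs=1e-6)

    def test_matches_scikit_survival_breslow(self, rng):
        sksurv = pytest.importorskip("sksurv.linear_model")
        time, event, X = _toy_survival(rng)
        # introduce ties so the Breslow handling actually matters
        time = np.round(time, 1) + 0.01
        beta, *_ = _cox_newton(time, event, X - X.mean(0))
        y = np.array([(bool(e), t) for e, t in zip(event, time)],
                     dtype=[("e", bool), ("t", float)])
        ref = sksurv.CoxPHSurvivalAnalysis(ties="breslow").fit(X, y)
        assert np.allclose(beta, ref.coef_, atol=1e-4)

    def test_constant_covariates_give_zero_coefficients(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 0, 1])
        params = fit_cox(time, event, np.full(4, 60.0),
                         np.zeros(4), np.zeros(4), np.zeros(4))
        assert np.allclose(params.coefs, 0.0)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            fit_cox([1.0, 2.0], [0, 0], [60.0, 65.0], [0.1, -0.1], [0, 0], [0, 0])

    def test_hazard_ratios_invariant_to_time_rescaling(self, rng):
        time, event, X = _toy_survival(rng, n=300)
        b1, *_ = _cox_newton(time, event, X)
        b2, *_ = _cox_newton(time * 7.3, event, X)
        assert np.allclose(b1, b2, atol=1e-8)


class TestBreslowBaseline:
    def test_reduces_to_nelson_aalen_with_null_covariates(self):
        from lifelines import NelsonAalenFitter

        time = np.array([0.5, 1.0, 1.2, 1.8, 2.5])
        event = np.array([1, 0, 1, 1, 0])
        s0 = breslow_baseline_survival(time, event, np.zeros(5), horizon=2.0)
        naf = NelsonAalenFitter()
        naf.fit(time, event)
        assert s0 == pytest.approx(np.exp(-naf.cumulative_hazard_at_times(2.0).iloc[0]))

    def test_no_events_before_horizon_gives_one(self):
        s0 = breslow_baseline_survival(
            np.array([3.0, 4.0]), np.array([1, 1]), np.zeros(2), horizon=2.0
        )
        assert s0 == 1.0

    def test_horizon_beyond_followup_warns_and_clamps(self, caplog):
        time = np.array([0.5, 1.0])
        event = np.array([1, 1])
        with caplog.at_level("WARNING"):
            s0 = breslow_baseline_survival(time, event, np.zeros(2), horizon=5.0)
        assert s0 == pytest.approx(
            breslow_baseline_survival(time, event, np.zeros(2), horizon=1.0)
        )

    def test_non_increasing_in_horizon(self):
        time = np.array([0.5, 0.9, 1.4, 1.9, 2.2, 2.4])
        event = np.array([1, 1, 0, 1, 1, 0])
        lp = np.array([0.2, -0.1, 0.0, 0.4, -0.3, 0.1])
        s = [breslow_baseline_survival(time, event, lp, horizon=h)
             for h in (0.6, 1.0, 1.5, 2.0)]
        assert all(a >= b for a, b in zip(s, s[1:]))


class TestTwoYearRisk:
    def _params(self, s0=0.999941):
        return CoxParams(
            gamma_age2=np.log(1.015), gamma_age2log=np.log(0.997),
            alpha_hb=np.log(0.868), alpha_mcv=np.log(0.996),
            alpha_plt=np.log(1.001),
            covariate_means=np.array([3600.0, 3600.0 * np.log(60.0), 0, 0, 0]),
            s0_2y=s0, age_scale=1.0,
        )

    def test_baseline_patient_risk_is_survival_complement(self):
        lp, risk = two_year_risk(self._params(), 60.0, 0.0, 0.0, 0.0)
        assert lp == pytest.approx(0.0, abs=1e-12)
        assert risk == pytest.approx(5.9e-5, rel=1e-3)

    def test_one_unit_haemoglobin_drop_scales_hazard(self):
        # dev -1 g/dL multiplies the hazard by 1/0.868
        _, r0 = two_year_risk(self._params(), 60.0, 0.0, 0.0, 0.0)
        _, r1 = two_year_risk(self._params(), 60.0, -1.0, 0.0, 0.0)
        assert r1 == pytest.approx(r0 / 0.868, rel=1e-3)
        assert r1 == pytest.approx(6.8e-5, rel=2e-2)

    def test_strictly_increasing_in_linear_predictor_and_bounded(self):
        devs = np.linspace(-5, 5, 41)
        lp, risk = two_year_risk(self._params(0.99), 60.0, -devs, devs * 0, devs * 0)
        assert np.all(np.diff(risk[np.argsort(lp)]) > 0)
        assert np.all((risk > 0) & (risk < 1))

    def test_printed_survival_roundtrips_through_json(self, tmp_path):
        p = self._params(0.999941)
        path = tmp_path / "cox.json"
        path.write_text(json.dumps(p.to_dict()))
        back = CoxParams.from_dict(json.loads(path.read_text()))
        assert back.s0_2y == 0.999941


class TestPipelineAndBundle:
    def test_bundle_roundtrip_predictions_bitwise(self, male_cohort, fitted_bundle, tmp_path):
        _, prep = male_cohort
        path = tmp_path / "model.json"
        fitted_bundle.save(path)
        back = ModelBundle.load(path)
        a = fitted_bundle.predict(prep)
        b = back.predict(prep)
        pd.testing.assert_frame_equal(a, b)

    def test_single_sex_cohort_fits_without_error(self, fitted_bundle):
        assert fitted_bundle.meta["sex"] == ["male"]
        assert 0 < fitted_bundle.cox.s0_2y < 1

    def test_score_identity_slope_one_on_development_data(self, male_cohort, fitted_bundle):
        _, prep = male_cohort
        preds = fitted_bundle.predict(prep)
        pi = preds["linear_predictor"].to_numpy()
        beta, *_ = _cox_newton(
            prep.patients["followup_years"].to_numpy(),
            prep.patients["event"].to_numpy(int),
            (pi - pi.mean())[:, None],
        )
        assert beta[0] == pytest.approx(1.0, abs=1e-6)


class TestPredictPatient:
    def _history_on_population_curve(self, bundle, age, dates):
        rows = []
        anchor = max(dates)
        for d in dates:
            t = 5.0 - (anchor - d).days / 365.25
            for analyte in ("HB", "MCV", "PLT"):
                p = bundle.longitudinal[analyte]
                rows.append({"analyte": analyte, "value": float(p.population_mean(age, t)),
                             "date": d})
        return pd.DataFrame(rows)

    def test_population_curve_history_gives_age_only_risk(self, fitted_bundle):
        dates = [pd.Timestamp("2010-06-01") - pd.Timedelta(days=k) for k in (0, 400, 900)]
        hist = self._history_on_population_curve(fitted_bundle, 65.0, dates)
        out = predict_patient(fitted_bundle, hist, age_at_baseline=65.0)
        assert all(abs(v) < 1e-9 for v in out["deviations"].values())
        _, risk = two_year_risk(fitted_bundle.cox, 65.0, 0.0, 0.0, 0.0)
        assert out["risk_2y"] == pytest.approx(float(risk))

    def test_appending_low_haemoglobin_increases_risk(self, fitted_bundle):
        assert fitted_bundle.cox.alpha_hb < 0
        dates = [pd.Timestamp("2010-06-01") - pd.Timedelta(days=k) for k in (0, 400, 900)]
        hist = self._history_on_population_curve(fitted_bundle, 65.0, dates)
        before = predict_patient(fitted_bundle, hist, 65.0)
        new = pd.DataFrame(
            [{"analyte": "HB", "value": 9.0, "date": pd.Timestamp("2010-12-01")}]
        )
        after = predict_patient(fitted_bundle, pd.concat([hist, new]), 65.5)
        assert after["baseline_date"] == pd.Timestamp("2010-12-01")
        assert after["risk_2y"] > before["risk_2y"]

    def test_measurements_outside_window_ignored(self, fitted_bundle):
        anchor = pd.Timestamp("2010-06-01")
        hist = pd.DataFrame(
            [
                {"analyte": "HB", "value": 5.0, "date": anchor - pd.Timedelta(days=3000)},
                {"analyte": "HB", "value": 14.0, "date": anchor},
                {"analyte": "MCV", "value": 90.0, "date": anchor},
                {"analyte": "PLT", "value": 250.0, "date": anchor},
            ]
        )
        out = predict_patient(fitted_bundle, hist, 65.0)
        hist2 = hist.iloc[1:]
        out2 = predict_patient(fitted_bundle, hist2, 65.0)
        assert out["risk_2y"] == pytest.approx(out2["risk_2y"])

    def test_empty_history_rejected(self, fitted_bundle):
        with pytest.raises(ValueError):
            predict_patient(fitted_bundle, pd.DataFrame(columns=["analyte", "value", "date"]), 60.0)
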