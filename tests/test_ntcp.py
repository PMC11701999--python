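"""Logistic fitting, AIC backward elimination, shrinkage, and prediction."""

import numpy as np
import pandas as pd
import pytest

from bedntcp import (
    ModelSpec,
    TruthSpec,
    apply_shrinkage,
    backward_eliminate,
    deserialize_model,
    develop_model,
    estimate_shrinkage,
    extract_features,
    fit_logistic,
    generate_cohort,
    hypotreat_retained,
    load_model,
    predict_ntcp,
    save_model,
    serialize_model,
    standard_model_specs,
)
from bedntcp.ntcp import _intercept_only_fit

SPEC_B = standard_model_specs(3.0)["B"]


def sim_features(n, rng, beta_dose=0.7, beta_abd=0.6, beta_hf=0.0, beta0=-2.0):
    """Direct logistic simulation on a standardized 'dose' column."""
    X = pd.DataFrame(
        {
            SPEC_B.dose_metric.label: rng.standard_normal(n),
            "ABD_SURG": (rng.random(n) < 0.2).astype(float),
            "HYPOTREAT": (rng.random(n) < 0.5).astype(float),
        }
    )
    eta = beta0 + beta_dose * X.iloc[:, 0] + beta_abd * X["ABD_SURG"] + beta_hf * X["HYPOTREAT"]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, pd.Series(y)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 5 + [0] * 5, dtype=float)
        fit = _intercept_only_fit(y)
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-12)
        assert fit.aic == pytest.approx(2 + 20 * np.log(2))

    def test_two_by_two_table_odds_ratio(self):
        # events 10/20 exposed, 5/20 unexposed -> log OR = ln((10*15)/(5*10)) = ln 3
        x = np.repeat([1.0, 0.0], 20)
        y = np.concatenate([np.ones(10), np.zeros(10), np.ones(5), np.zeros(15)])
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.converged
        assert fit.params["x"] == pytest.approx(np.log(3), abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(pd.DataFrame({"x": [0.0, 1.0]}), np.array([1.0, 1.0]))

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(pd.DataFrame({"x": [2.0, 2.0, 2.0, 2.0]}), np.array([0, 1, 0, 1.0]))

    def test_complete_separation_flagged_not_raised(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        y = x.copy()
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert not fit.converged


class TestBackwardElimination:
    def test_null_hypotreat_is_eliminated_in_majority_of_seeds(self):
        # a truly null schedule indicator survives AIC elimination only by
        # chance (P ~ chi2_1 > 2, about 16%), so it is dropped in the majority
        eliminated = 0
        for seed in range(20):
            X, y = sim_features(2000, np.random.default_rng(1000 + seed), beta_hf=0.0)
            model = backward_eliminate(X, y, SPEC_B)
            assert SPEC_B.dose_metric.label in model.retained
            eliminated += not hypotreat_retained(model)
        assert eliminated > 10

    def test_all_null_can_reduce_to_intercept_only(self):
        hits = 0
        for seed in range(10):
            X, y = sim_features(
                2000, np.random.default_rng(2000 + seed),
                beta_dose=0.0, beta_abd=0.0, beta_hf=0.0,
            )
            model = backward_eliminate(X, y, SPEC_B)
            hits += model.intercept_only
        assert hits >= 1  # the null model is reachable and flagged as such

    def test_strong_single_candidate_retained(self, rng):
        X, y = sim_features(2000, rng, beta_dose=1.0)
        spec = ModelSpec(SPEC_B.dose_metric, (), alpha_beta=3.0)
        model = backward_eliminate(X[[SPEC_B.dose_metric.label]], y, spec)
        assert model.retained == (SPEC_B.dose_metric.label,)

    def test_aic_never_increases_along_trace(self, rng):
        for _ in range(5):
            X, y = sim_features(300, rng, beta_dose=0.2, beta_abd=0.0, beta_hf=0.0)
            model = backward_eliminate(X, y, SPEC_B)
            aics = [a for _, a in model.elimination_trace]
            assert all(b <= a + 1e-12 for a, b in zip(aics, aics[1:]))

    def test_recovers_generating_coefficients_within_3_mc_se(self, hypro5000):
        X, y, truth = hypro5000
        model = backward_eliminate(X, y, standard_model_specs(3.0)["B"])
        import statsmodels.api as sm

        res = sm.Logit(y, sm.add_constant(X[list(model.retained)])).fit(disp=0)
        label = SPEC_B.dose_metric.label
        assert abs(res.params[label] - truth.beta_dose) < 3 * res.bse[label]
        if "ABD_SURG" in model.retained:
            assert abs(res.params["ABD_SURG"] - truth.beta_abd) < 3 * res.bse["ABD_SURG"]


@pytest.fixture(scope="module")
def hypro5000():
    truth = TruthSpec()
    cohort = generate_cohort(5000, truth, rng=np.random.default_rng(314159))
    X, y = extract_features(cohort, standard_model_specs(3.0)["B"])
    return X, y, truth


class TestShrinkage:
    def test_self_calibration_slope_is_one_without_resampling(self, rng):
        # a model refit on data identical to the original calibrates to slope 1
        X, y = sim_features(500, rng)
        model = backward_eliminate(X, y, SPEC_B)
        lp = model.linear_predictor(X)
        cal = fit_logistic(pd.DataFrame({"lp": lp}), y)
        assert cal.params["lp"] == pytest.approx(1.0, abs=1e-6)
        assert cal.params["const"] == pytest.approx(0.0, abs=1e-6)

    def test_large_sample_strong_effects_give_factor_near_one(self, rng):
        X, y = sim_features(40000, rng, beta_dose=1.0, beta_abd=0.8, beta_hf=0.5)
        est = estimate_shrinkage(X, y, SPEC_B, B=40, rng=rng)
        assert est.factor == pytest.approx(1.0, abs=0.02)

    def test_small_weak_sample_shrinks_below_one(self, rng):
        X, y = sim_features(200, rng, beta_dose=0.25, beta_abd=0.2, beta_hf=0.1)
        est = estimate_shrinkage(X, y, SPEC_B, B=100, rng=rng)
        assert est.factor < 1.0
        assert est.n_degenerate + len(est.slopes) == 100

    def test_apply_shrinkage_or_arithmetic_and_score_equation(self, rng):
        X, y = sim_features(800, rng)
        model = backward_eliminate(X, y, SPEC_B)
        s = 0.9
        final = apply_shrinkage(model, s, X, y)
        for name in model.retained:
            assert final.coefficients[name] == pytest.approx(s * model.coefficients[name])
            assert np.exp(final.coefficients[name]) == pytest.approx(
                np.exp(model.coefficients[name]) ** s
            )
        # intercept re-estimation restores mean predicted = observed prevalence
        assert final.predict(X).sum() == pytest.approx(float(np.sum(y)), abs=1e-6)

    def test_identity_shrinkage_changes_nothing(self, rng):
        X, y = sim_features(800, rng)
        model = backward_eliminate(X, y, SPEC_B)
        final = apply_shrinkage(model, 1.0, X, y)
        for k, v in model.coefficients.items():
            assert final.coefficients[k] == pytest.approx(v, abs=1e-7)

    def test_published_or_shrinkage_arithmetic(self):
        # uniform shrinkage acts on the log-odds scale: OR_final = OR^s
        assert round(1.88**0.93, 2) == 1.80
        assert round(1.83**0.88, 2) == 1.70

    def test_invalid_factor_rejected(self, rng):
        X, y = sim_features(200, rng)
        model = backward_eliminate(X, y, SPEC_B)
        with pytest.raises(ValueError):
            apply_shrinkage(model, 0.0, X, y)


class TestPrediction:
    def test_logistic_inverse_link_values(self, rng):
        X, y = sim_features(500, rng)
        model = develop_model(X, y, SPEC_B, rng=rng, shrinkage_bootstraps=0)
        # hand-constructed coefficients
        model.coefficients = {"intercept": -3.0, SPEC_B.dose_metric.label: 0.07}
        model.retained = (SPEC_B.dose_metric.label,)
        assert predict_ntcp(model, 0.0, {}) == pytest.approx(1 / (1 + np.exp(3)))
        p_mid = predict_ntcp(model, 3.0 / 0.07, {})
        assert p_mid == pytest.approx(0.5)

    def test_monotone_in_dose_for_positive_coefficient(self, rng):
        X, y = sim_features(2000, rng, beta_dose=0.8)
        model = develop_model(X, y, SPEC_B, rng=rng, shrinkage_bootstraps=0)
        cov = {"ABD_SURG": 0.0, "HYPOTREAT": 0.0}
        cov = {k: v for k, v in cov.items() if k in model.retained}
        grid = np.linspace(-3, 3, 21)
        probs = [predict_ntcp(model, g, cov) for g in grid]
        assert np.all(np.diff(probs) > 0)
        assert all(0 < p < 1 for p in probs)

    def test_missing_covariate_raises(self, rng):
        X, y = sim_features(3000, rng, beta_abd=1.5)
        model = develop_model(X, y, SPEC_B, rng=rng, shrinkage_bootstraps=0)
        if "ABD_SURG" in model.retained:
            with pytest.raises(KeyError, match="ABD_SURG"):
                predict_ntcp(model, 0.0, {})


class TestSerialization:
    def test_round_trip_identity(self, rng, tmp_path):
        X, y = sim_features(600, rng)
        model = develop_model(X, y, SPEC_B, rng=rng, shrinkage_bootstraps=20)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back.retained == model.retained
        assert back.coefficients == model.coefficients
        assert back.shrinkage_factor == model.shrinkage_factor
        assert back.spec.dose_metric == model.spec.dose_metric
        assert back.spec.alpha_beta == model.spec.alpha_beta

    def test_missing_field_reports_path(self, rng):
        X, y = sim_features(600, rng)
        model = develop_model(X, y, SPEC_B, rng=rng, shrinkage_bootstraps=0)
        doc = serialize_model(model)
        del doc["coefficients"]["intercept"]
        with pytest.raises(ValueError, match=r"coefficients\.intercept"):
            deserialize_model(doc)

    def test_schema_version_enforced(self, rng):
        X, y = sim_features(600, rng)
        doc = serialize_model(develop_model(X, y, SPEC_B, rng=rng, shrinkage_bootstraps=0))
        doc["schema_version"] = "0"
        with pytest.raises(ValueError, match="schema_version"):
            deserialize_model(doc)
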