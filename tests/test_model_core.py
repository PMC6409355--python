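import math

import numpy as np
import pytest
from scipy import optimize

from oct4expr.genomic_io import TimeCourseRecord
from oct4expr.model_core import (CANDIDATE_TERMS, MODEL_D_FUNCTIONS, ModelSpec,
                                 RankDeficientDesign, build_candidate_set,
                                 design_matrix, fit_lsm, fit_model, predict,
                                 stepwise_select, terms_matrix)
from oct4expr.synthetic_data import GenerativeConfig, generate_timecourse

from conftest import random_records


def _rec(h, d, w, t, exp=0.0):
    return TimeCourseRecord("g", t, h, d, w, exp)


class TestCandidateSet:
    def test_eighteen_terms_deterministic_order(self):
        v = build_candidate_set(_rec(1, 1, 1, 0))
        assert tuple(v) == CANDIDATE_TERMS and len(v) == 18

    def test_t_zero_identities(self):
        v = build_candidate_set(_rec(2, 3, 5, 0))
        assert v["H*exp(t)"] == 2 and v["H*0.5^t"] == 2
        assert v["H*log10(t+1)"] == 0 and v["W*log10(t+1)"] == 0
        assert v["D*t"] == 0

    def test_direct_arithmetic(self):
        v = build_candidate_set(_rec(2, 3, 5, 1))
        assert v["D*0.5^t"] == pytest.approx(1.5)
        assert v["D*t"] == 3 and v["D*t^3"] == 3
        v3 = build_candidate_set(_rec(2, 3, 5, 3))
        assert v3["W*log10(t+1)"] == pytest.approx(5 * math.log10(4))


class TestDesignMatrix:
    def test_model4_t0_row(self):
        X, y = design_matrix([_rec(1, 1, 1, 0, exp=2.0)], ModelSpec(4))
        np.testing.assert_allclose(X, [[1.0, 1.0, 0.0]])
        assert y == [2.0]

    def test_models_differ_only_in_distance_column(self):
        recs = random_records(np.random.default_rng(1))
        X1, _ = design_matrix(recs, ModelSpec(1))
        X4, _ = design_matrix(recs, ModelSpec(4))
        np.testing.assert_array_equal(X1[:, [0, 2]], X4[:, [0, 2]])
        assert not np.allclose(X1[:, 1], X4[:, 1])

    def test_shape(self):
        recs = random_records(np.random.default_rng(2))
        X, y = design_matrix(recs, ModelSpec(4))
        assert X.shape == (8, 3) and y.shape == (8,)

    @pytest.mark.parametrize("model_id,f_t", sorted(MODEL_D_FUNCTIONS.items()))
    def test_named_models_fix_distance_function(self, model_id, f_t):
        assert ModelSpec(model_id).terms[1] == f"D*{f_t}"

    def test_non_finite_fatal(self):
        rec = TimeCourseRecord("g", 3, 1.0, 1.0, 1.0, 0.0)
        object.__setattr__(rec, "expression", math.nan)
        with pytest.raises(ValueError):
            terms_matrix([rec], ModelSpec(4).terms)


class TestFitLSM:
    def test_exact_interpolation(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        y = 0.5 * X[:, 0] - 0.3 * X[:, 1] + 1.2 * X[:, 2] + 0.1
        fit = fit_lsm(X, y)
        np.testing.assert_allclose(fit.beta, [0.5, -0.3, 1.2], atol=1e-12)
        assert fit.intercept == pytest.approx(0.1, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_constant_response_projects_onto_intercept(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        y = np.full(10, 3.5)
        fit = fit_lsm(X, y)
        np.testing.assert_allclose(fit.beta, 0.0, atol=1e-12)
        assert fit.intercept == pytest.approx(3.5)

    def test_matches_numeric_rss_minimizer(self):
        """BFGS minimisation of the RSS surface lands on the same solution."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            recs = random_records(rng)
            X, _ = terms_matrix(recs, ModelSpec(4).terms)
            y = rng.normal(size=8)
            fit = fit_lsm(X, y)
            A = np.column_stack([np.ones(8), X])
            scale = np.linalg.norm(A, axis=0)

            def rss(g):
                r = y - A @ (g / scale)
                return r @ r

            def grad(g):
                r = y - A @ (g / scale)
                return -2.0 * (A.T @ r) / scale

            res = optimize.minimize(rss, np.zeros(4), jac=grad, method="BFGS",
                                    options={"gtol": 1e-14, "maxiter": 2000})
            oracle = res.x / scale
            np.testing.assert_allclose(
                np.concatenate([[fit.intercept], fit.beta]), oracle, atol=1e-8)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        recs = random_records(rng, n_genes=3)
        X, _ = terms_matrix(recs, ModelSpec(4).terms)
        y = rng.normal(size=len(recs))
        fit = fit_lsm(X, y)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.beta, ref.params[1:], rtol=1e-9)
        np.testing.assert_allclose(fit.intercept, ref.params[0], rtol=1e-9)
        np.testing.assert_allclose(fit.se_beta, ref.bse[1:], rtol=1e-8)
        assert fit.residual_sd == pytest.approx(np.sqrt(ref.mse_resid))

    def test_rank_deficiency_names_column(self):
        rng = np.random.default_rng(11)
        X = np.empty((8, 2))
        X[:, 0] = rng.normal(size=8)
        X[:, 1] = 2.0 * X[:, 0]  # exactly collinear with column 1
        with pytest.raises(RankDeficientDesign, match="x2"):
            fit_lsm(X, y=np.arange(8.0), term_names=["x1", "x2"])

    def test_fitted_invariant_under_column_rescaling(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        base = fit_lsm(X, y)
        X2 = X.copy()
        X2[:, 1] *= 1e6
        scaled = fit_lsm(X2, y)
        np.testing.assert_allclose(scaled.fitted, base.fitted, rtol=1e-8)
        assert scaled.beta[1] == pytest.approx(base.beta[1] / 1e6)


class TestPredict:
    def test_training_predictions_equal_fitted(self, noisy_dataset):
        spec = ModelSpec(4)
        fit = fit_model(noisy_dataset.records, spec)
        np.testing.assert_allclose(
            predict(fit, noisy_dataset.records, spec), fit.fitted)

    def test_zero_coefficient_fit_constant(self):
        rng = np.random.default_rng(8)
        recs = random_records(rng)
        fit = fit_model(recs, ModelSpec(4))
        fit.beta = np.zeros(3)
        fit.intercept = 2.0
        np.testing.assert_allclose(predict(fit, recs, ModelSpec(4)), 2.0)

    def test_noiseless_generative_roundtrip(self, noiseless_dataset):
        spec = ModelSpec(4)
        fit = fit_model(noiseless_dataset.records, spec)
        truth = np.array([r.expression for r in noiseless_dataset.records])
        pred = predict(fit, noiseless_dataset.records, spec)
        np.testing.assert_allclose(pred, truth, rtol=1e-9)


class TestStepwise:
    def test_recovers_active_pair(self):
        cfg = GenerativeConfig(n_genes=30, noise_sd=0.01,
                               true_beta=(0.5, 0.0, 1.2), seed=11)
        sel = stepwise_select(generate_timecourse(cfg).records,
                              criterion="pvalue")
        assert sorted(sel) == ["H*exp(t)", "W*log10(t+1)"]

    def test_pure_noise_mostly_empty(self):
        empty = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            recs = random_records(rng, n_genes=4)
            sel = stepwise_select(recs, criterion="pvalue")
            empty += not sel
        assert empty >= 45

    def test_single_perfect_candidate(self):
        rng = np.random.default_rng(9)
        recs = []
        for g in range(4):
            for d in (0, 1, 3, 5, 7, 11, 15, 18):
                w = float(rng.uniform(50, 500))
                recs.append(TimeCourseRecord(
                    f"g{g}", d, 1.0, 1.0, w,
                    expression=2.0 * w * math.log10(d + 1)))
        assert stepwise_select(recs, candidates=["W*log10(t+1)"],
                               criterion="pvalue") == ["W*log10(t+1)"]

    def test_deterministic_given_input(self):
        cfg = GenerativeConfig(n_genes=10, noise_sd=0.5, seed=3)
        recs = generate_timecourse(cfg).records
        assert stepwise_select(recs) == stepwise_select(recs)
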