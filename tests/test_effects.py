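"""Post-fit inference: inclusion probabilities, effect estimates,
counterfactual prediction and the averaged-prediction evaluation."""

import numpy as np
import pytest

from perturbgp import (
    PerturbDataset,
    averaged_prediction_eval,
    call_effects,
    inclusion_probability,
    perturbation_effect,
    predict_expression,
)
from perturbgp.likelihoods import sigmoid, softplus

RNG = np.random.default_rng(0)


def _e(L, j=0, scale=1.0):
    c = np.zeros(L)
    c[j] = scale
    return c


class TestInclusionProbability:
    def test_control_is_exactly_zero_under_constrained_model(self, make_synthetic_model):
        model = make_synthetic_model(eta_mean=5.0)
        np.testing.assert_array_equal(
            inclusion_probability(model, np.zeros(model.L)), 0.0
        )

    def test_point_mass_eta_plugin_limit(self, make_synthetic_model):
        model = make_synthetic_model(eta_mean=-3.0, eta_logvar=-40.0)
        probs = inclusion_probability(model, _e(model.L), n_mc=64)
        np.testing.assert_allclose(probs, 1.0 / (1.0 + np.e**3), rtol=1e-6)

    def test_range_for_random_inputs(self, small_gaussian_fit):
        model, *_ = small_gaussian_fit
        c = np.abs(RNG.standard_normal(model.L))
        probs = inclusion_probability(model, c, n_mc=128)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_dimension_mismatch(self, make_synthetic_model):
        model = make_synthetic_model()
        with pytest.raises(ValueError, match="length"):
            inclusion_probability(model, np.zeros(model.L + 1))


class TestPerturbationEffect:
    def test_control_effect_zero_with_degenerate_interval(self, make_synthetic_model):
        model = make_synthetic_model(mu_mean=3.0, eta_mean=5.0)
        tab = perturbation_effect(model, np.zeros(model.L))
        assert (tab["effect_mean"] == 0).all()
        assert (tab["effect_ci_low"] == 0).all()
        assert (tab["effect_ci_high"] == 0).all()

    def test_degenerate_limit_inclusion_one_point_mass_mu(self, make_synthetic_model):
        model = make_synthetic_model(mu_mean=2.0, eta_mean=40.0)
        tab = perturbation_effect(model, _e(model.L), n_mc=256)
        np.testing.assert_allclose(tab["effect_mean"], 2.0, atol=1e-6)
        np.testing.assert_allclose(tab["inclusion_prob"], 1.0)

    def test_factorisation_oracle(self, make_synthetic_model):
        """E[z mu] = sigma_bar * mu_bar for independent point-mass factors."""
        logit = float(np.log(0.3 / 0.7))
        model = make_synthetic_model(mu_mean=1.5, eta_mean=logit, eta_logvar=-40.0)
        n_mc = 20_000
        tab = perturbation_effect(model, _e(model.L), n_mc=n_mc, seed=1)
        se = 1.5 * np.sqrt(0.3 * 0.7 / n_mc)
        np.testing.assert_allclose(tab["effect_mean"], 0.3 * 1.5, atol=3 * se)

    def test_interval_orders_and_level(self, small_gaussian_fit):
        model, truth, *_ = small_gaussian_fit
        tab = perturbation_effect(model, truth.unique_perturbations[0], n_mc=256)
        assert (tab["effect_ci_low"] <= tab["effect_ci_high"]).all()
        # the conditional posterior is Gaussian, hence symmetric: its mean
        # sits inside its own credible interval
        assert (tab["cond_ci_low"] <= tab["effect_given_on"] + 1e-9).all()
        assert (tab["effect_given_on"] <= tab["cond_ci_high"] + 1e-9).all()

    def test_invalid_level(self, make_synthetic_model):
        with pytest.raises(ValueError):
            perturbation_effect(make_synthetic_model(), _e(2), level=1.5)


class TestPredictExpression:
    def test_gaussian_control_returns_basal(self, make_synthetic_model):
        model = make_synthetic_model(basal=1.3)
        k = RNG.standard_normal(2)
        mean, var = predict_expression(model, np.zeros(model.L), k)
        np.testing.assert_allclose(mean, 1.3)
        np.testing.assert_allclose(var, float(softplus(model.params["lam"][0])))

    def test_gaussian_degenerate_limit(self, make_synthetic_model):
        model = make_synthetic_model(mu_mean=2.0, eta_mean=40.0, basal=1.0)
        mean, _ = predict_expression(model, _e(model.L), np.zeros(2), n_mc=128)
        np.testing.assert_allclose(mean, 3.0, atol=1e-8)

    def test_zip_control_returns_deflated_basal_rate(self, make_synthetic_model):
        model = make_synthetic_model(modality="zip", basal=0.7, pi_value=0.2)
        mean = predict_expression(model, np.zeros(model.L), np.zeros(2))
        np.testing.assert_allclose(mean, 0.8 * float(softplus(0.7)), rtol=1e-9)

    def test_zip_forward_sampling_oracle(self, make_synthetic_model):
        """Predicted ZIP mean matches the mean of 10^5 generative draws."""
        logit = float(np.log(0.6 / 0.4))
        model = make_synthetic_model(
            modality="zip", P=1, mu_mean=1.2, eta_mean=logit, eta_logvar=-40.0,
            basal=0.5, pi_value=0.25,
        )
        pred = predict_expression(model, _e(model.L), np.zeros(2), n_mc=4096, seed=2)
        rng = np.random.default_rng(3)
        n = 100_000
        z = rng.uniform(size=n) < 0.6
        rate = np.asarray(softplus(0.5 + z * 1.2))
        drop = rng.uniform(size=n) < 0.25
        draws = np.where(drop, 0, rng.poisson(rate))
        se = draws.std(ddof=1) / np.sqrt(n)
        assert pred[0] == pytest.approx(draws.mean(), abs=3 * se)


class TestAveragedPredictionEval:
    def test_good_fit_gives_high_pooled_pearson(self, small_gaussian_fit):
        model, _, _, test = small_gaussian_fit
        table, r = averaged_prediction_eval(model, test, seed=0)
        assert r > 0.9
        assert {"perturbation", "gene", "predicted", "observed"} <= set(table.columns)

    def test_constant_predictions_yield_nan_with_warning(self, make_synthetic_model):
        model = make_synthetic_model(mu_mean=0.0, eta_mean=-40.0, basal=2.0)
        test = PerturbDataset(
            X=RNG.standard_normal((20, model.P)),
            C=np.zeros((20, model.L)),
            K=RNG.standard_normal((20, 2)),
        )
        with pytest.warns(UserWarning, match="constant"):
            _, r = averaged_prediction_eval(model, test)
        assert np.isnan(r)

    def test_invariant_to_cell_ordering(self, small_gaussian_fit):
        model, _, _, test = small_gaussian_fit
        perm = np.random.default_rng(4).permutation(test.n_cells)
        _, r1 = averaged_prediction_eval(model, test, seed=0)
        _, r2 = averaged_prediction_eval(model, test.subset(perm), seed=0)
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_gene_set_mismatch_rejected(self, small_gaussian_fit, toy_dataset):
        model, *_ = small_gaussian_fit
        with pytest.raises(ValueError, match="gene set"):
            averaged_prediction_eval(model, toy_dataset)


class TestCallEffects:
    def _table(self, probs):
        import pandas as pd

        return pd.DataFrame({"gene": range(len(probs)), "inclusion_prob": probs})

    def test_filter_semantics(self):
        out = call_effects(self._table([0.99, 0.50, 0.96]), 0.95)
        assert len(out) == 2

    def test_zero_threshold_keeps_positive_probabilities(self):
        out = call_effects(self._table([0.0, 0.1, 0.5]), 0.0)
        assert len(out) == 2

    def test_monotone_in_threshold(self):
        probs = list(RNG.uniform(size=50))
        counts = [len(call_effects(self._table(probs), t))
                  for t in (0.1, 0.5, 0.9, 0.99)]
        assert counts == sorted(counts, reverse=True)
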