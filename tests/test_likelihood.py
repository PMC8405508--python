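"""Individual- and aggregate-data log-likelihoods, MAP estimation, diagnostics."""

import numpy as np
import pytest

from aggpk import (
    AggregateData,
    Design,
    IndividualDataset,
    PopulationParams,
    PredictedMoments,
    aggregate_loglik,
    aggregate_observed,
    expected_moments_fo,
    get_model,
    individual_loglik,
    loo_mc_se,
    map_random_effects,
    ofv,
    sample_random_effects,
    simulate_individuals,
)

WANG_TIMES = np.array([0.25, 0.5, 1.0, 2.0, 4.0])


def wang_dataset(n=6, seed=0, residual="additive"):
    model = get_model("wang", residual_kind=residual)
    params = PopulationParams(
        beta=[0.5], omega=[[0.04]],
        sigma_add2=0.1 if residual == "additive" else 0.0,
        sigma_prop2=0.1 if residual == "proportional" else 0.0,
    )
    d = Design(times=WANG_TIMES, n_subjects=n)
    return model, params, simulate_individuals(model, params, d, seed=seed)


class TestMapRandomEffects:
    def test_exact_typical_data_maps_to_zero(self, wang_model, wang_params):
        d = Design(times=WANG_TIMES)
        y = wang_model.predict([0.5], d)
        b, ok = map_random_effects(y, wang_model, wang_params, d)
        assert ok
        assert abs(b[0]) < 1e-6

    def test_vanishing_prior_variance_pins_b_at_zero(self, wang_model):
        p = PopulationParams(beta=[0.5], omega=[[1e-10]], sigma_add2=0.1)
        d = Design(times=WANG_TIMES)
        y = wang_model.predict([0.5], d) + 0.5  # strongly shifted data
        b, _ = map_random_effects(y, wang_model, p, d)
        assert abs(b[0]) < 1e-4

    def test_matches_grid_search_oracle(self, wang_model, wang_params):
        d = Design(times=WANG_TIMES)
        y = wang_model.predict([0.5], d) + np.array([0.3, -0.2, 0.4, 0.1, -0.3])
        b, _ = map_random_effects(y, wang_model, wang_params, d)
        omega_inv = 1.0 / 0.04
        grid = np.linspace(-3 * 0.2, 3 * 0.2, 10000)
        vals = []
        for g in grid:
            f = wang_model.predict([0.5 * np.exp(g)], d)
            res = y - f
            vals.append(0.5 * (np.sum(res**2 / 0.1) + 5 * np.log(0.1) + g**2 * omega_inv))
        assert abs(b[0] - grid[int(np.argmin(vals))]) < 1e-4


class TestIndividualLoglik:
    def test_single_obs_zero_residual_unit_variance(self):
        # contribution -(residual^2/V + log V)/2 vanishes at res=0, V=1
        from aggpk import StructuralModel
        m = StructuralModel(
            name="const", n_theta=1, v=1,
            predict_batch=lambda th, des: th[:, :1].repeat(des.n_obs, axis=1),
            param_map_kind="identity",
        )
        p = PopulationParams(beta=[3.0], omega=[[0.0]], sigma_add2=1.0)
        d = Design(times=[1.0], n_subjects=1)
        data = IndividualDataset(Y=np.array([[3.0]]), design=d)
        ll, ws = individual_loglik(data, m, p, "FO")
        assert ll == pytest.approx(0.0, abs=1e-12)
        assert ws[0].V_i[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["FO", "FOCE", "FOCEI"])
    def test_quadratic_form_equals_trace_identity(self, method):
        model, params, data = wang_dataset(n=5, seed=3)
        _, ws = individual_loglik(data, model, params, method)
        for w in ws:
            quad = float(w.y_res_i @ np.linalg.inv(w.V_i) @ w.y_res_i)
            tr = float(np.trace(w.R_i @ np.linalg.inv(w.V_i)))
            assert quad == pytest.approx(tr, rel=1e-12)

    def test_foce_differs_from_fo_on_nonlinear_model(self):
        model, params, data = wang_dataset(n=6, seed=1)
        ll_fo, _ = individual_loglik(data, model, params, "FO")
        ll_foce, _ = individual_loglik(data, model, params, "FOCE")
        assert ll_fo != pytest.approx(ll_foce, abs=1e-6)

    def test_focei_interaction_matters_for_proportional_error(self):
        model, params, data = wang_dataset(n=6, seed=2, residual="proportional")
        ll_foce, _ = individual_loglik(data, model, params, "FOCE")
        ll_focei, _ = individual_loglik(data, model, params, "FOCEI")
        assert ll_foce != pytest.approx(ll_focei, abs=1e-8)


class TestAggregateLoglik:
    def test_identity_moments_value(self):
        K, N = 4, 7
        agg = AggregateData(ybar=np.ones(K), V=np.eye(K), n_subjects=N)
        mom = PredictedMoments(np.ones(K), np.eye(K), "FO")
        assert aggregate_loglik(agg, mom) == pytest.approx(-N * K / 2)

    def test_single_subject_collapse_to_individual(self, wang_model, wang_params):
        d = Design(times=WANG_TIMES, n_subjects=1)
        data = simulate_individuals(wang_model, wang_params, d, seed=8)
        agg = aggregate_observed(data)
        mom = expected_moments_fo(wang_model, wang_params, d)
        ll_agg = aggregate_loglik(agg, mom)
        ll_ind, _ = individual_loglik(data, wang_model, wang_params, "FO")
        assert ll_agg == pytest.approx(ll_ind, abs=1e-12)

    @pytest.mark.parametrize("model_name,n", [("wang", 9), ("twocomp_oral", 40)])
    def test_fo_aggregate_equals_summed_individual(self, model_name, n):
        """The aggregate-data FO log-likelihood is identical to individual-data FO."""
        model = get_model(model_name)
        if model_name == "wang":
            params = PopulationParams(beta=[0.5], omega=[[0.04]], sigma_add2=0.1)
            d = Design(times=WANG_TIMES, n_subjects=n)
        else:
            params = PopulationParams(beta=[5, 10, 30, 10, 1.0],
                                      omega=np.eye(5) * 0.09, sigma_add2=0.04)
            d = Design(times=[0.1, 0.5, 1, 3, 8.0], dose_amount=100.0, n_subjects=n)
        data = simulate_individuals(model, params, d, seed=13)
        ll_ind, _ = individual_loglik(data, model, params, "FO")
        agg = aggregate_observed(data)
        ll_agg = aggregate_loglik(agg, expected_moments_fo(model, params, d))
        assert ll_agg == pytest.approx(ll_ind, abs=1e-8)

    def test_scales_linearly_in_n(self):
        K = 3
        rng = np.random.default_rng(4)
        A = rng.normal(size=(K, K))
        V = A @ A.T + np.eye(K)
        mom = PredictedMoments(np.zeros(K), np.eye(K) * 2.0, "FO")
        ybar = rng.normal(size=K)
        la = aggregate_loglik(AggregateData(ybar, V, 50), mom)
        lb = aggregate_loglik(AggregateData(ybar, V, 100), mom)
        assert lb == pytest.approx(2 * la, rel=1e-12)

    def test_maximized_at_observed_moments(self):
        """MVN/Wishart stationarity: perturbing (yt, Vt) away from (ybar, V) lowers it."""
        K = 3
        rng = np.random.default_rng(7)
        A = rng.normal(size=(K, K))
        V = A @ A.T + np.eye(K)
        ybar = rng.normal(size=K)
        agg = AggregateData(ybar, V, 30)
        base = aggregate_loglik(agg, PredictedMoments(ybar, V, "FO"))
        for _ in range(20):
            dy = rng.normal(scale=0.05, size=K)
            S = rng.normal(scale=0.05, size=(K, K))
            Vp = V + (S + S.T) / 2
            if np.min(np.linalg.eigvalsh(Vp)) <= 0:
                continue
            val = aggregate_loglik(agg, PredictedMoments(ybar + dy, Vp, "FO"))
            assert val < base

    def test_non_pd_moments_penalized(self):
        agg = AggregateData(np.zeros(2), np.eye(2), 5)
        bad = PredictedMoments(np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]), "FO")
        assert aggregate_loglik(agg, bad) < -1e9


class TestOfv:
    def test_definition(self):
        assert ofv(-0.0129) == pytest.approx(0.0258)
        assert ofv(0.0) == 0.0
        with pytest.raises(ValueError):
            ofv(np.inf)


class TestLooMcSe:
    def test_zero_omega_gives_zero_se(self, case2_model):
        p = PopulationParams(beta=[5, 10, 30, 10, 1.0], omega=np.zeros((5, 5)),
                             sigma_add2=0.04)
        d = Design(times=[0.5, 1.0, 3.0], dose_amount=100.0, n_subjects=20)
        data = simulate_individuals(case2_model, p, d, seed=2)
        agg = aggregate_observed(data)
        se = loo_mc_se(agg, case2_model, p, sample_random_effects(p.omega, 50))
        assert se == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("approx", ["MC", "FOCE"])
    def test_se_decreases_with_sample_size(self, approx, case2_model, case2_params):
        d = Design(times=[0.1, 0.5, 1, 3, 8.0], dose_amount=100.0, n_subjects=200)
        data = simulate_individuals(case2_model, case2_params, d, seed=21)
        agg = aggregate_observed(data)
        se_small = loo_mc_se(agg, case2_model, case2_params,
                             sample_random_effects(case2_params.omega, 300), approx)
        se_large = loo_mc_se(agg, case2_model, case2_params,
                             sample_random_effects(case2_params.omega, 3000), approx)
        assert 0 < se_large < se_small

    def test_requires_at_least_two_vectors(self, case2_model, case2_params):
        d = Design(times=[1.0], dose_amount=100.0, n_subjects=2)
        data = simulate_individuals(case2_model, case2_params, d, seed=0)
        agg = aggregate_observed(data)
        with pytest.raises(ValueError):
            loo_mc_se(agg, case2_model, case2_params,
                      sample_random_effects(case2_params.omega, 1))
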