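"""FO / FOCE / MC expected aggregate moments."""

import numpy as np
import pytest

import aggpk.moments as moments_mod
from aggpk import (
    Design,
    PopulationParams,
    StructuralModel,
    expected_moments_fo,
    expected_moments_foce,
    expected_moments_mc,
    jacobian_f_wrt_b,
    sample_random_effects,
)


def linear_model():
    """f = theta * t with an identity parameter map: exactly linear in b."""
    return StructuralModel(
        name="linear",
        n_theta=1,
        v=1,
        predict_batch=lambda th, des: th[:, :1] * des.times[None, :],
        residual_kind="additive",
        param_map_kind="identity",
    )


def scalar_model():
    """A single observation slot equal to theta itself (lognormal map)."""
    return StructuralModel(
        name="scalar",
        n_theta=1,
        v=1,
        predict_batch=lambda th, des: th[:, :1].repeat(des.n_obs, axis=1),
        residual_kind="additive",
    )


class TestJacobian:
    def test_linear_model_is_exact(self):
        m = linear_model()
        p = PopulationParams(beta=[2.0], omega=[[0.25]], sigma_add2=0.1)
        d = Design(times=[0.5, 1.0, 3.0])
        J = jacobian_f_wrt_b(m, p, [0.7], d)
        np.testing.assert_allclose(J[:, 0], d.times, rtol=1e-9)

    def test_wang_analytic_value(self, wang_model, wang_params):
        # theta = beta*exp(b); df/db at b=0, t=1 is -10*beta*t*exp(-beta*t)
        d = Design(times=[1.0])
        J = jacobian_f_wrt_b(wang_model, wang_params, [0.0], d)
        assert J[0, 0] == pytest.approx(-10 * 0.5 * np.exp(-0.5), rel=1e-8)

    def test_halving_step_quarters_the_error(self, wang_model, wang_params, monkeypatch):
        d = Design(times=[1.0])
        exact = -10 * 0.5 * np.exp(-0.5)
        errs = []
        for h in (1e-2, 5e-3):
            monkeypatch.setattr(moments_mod, "JAC_REL_STEP", h)
            J = jacobian_f_wrt_b(wang_model, wang_params, [0.0], d)
            errs.append(abs(J[0, 0] - exact))
        ratio = errs[0] / errs[1]
        assert 3.0 < ratio < 5.0  # central differences: O(h^2)


class TestFoMoments:
    def test_wang_hand_computed(self, wang_model, wang_params):
        d = Design(times=[1.0])
        mom = expected_moments_fo(wang_model, wang_params, d)
        assert mom.ytilde[0] == pytest.approx(10 * np.exp(-0.5), abs=1e-9)
        J = -10 * 0.5 * np.exp(-0.5)
        assert mom.Vtilde[0, 0] == pytest.approx(J**2 * 0.04 + 0.1, rel=1e-6)

    def test_no_iiv_gives_diagonal_residual(self, case2_model):
        p = PopulationParams(beta=[5, 10, 30, 10, 1.0], omega=np.zeros((5, 5)),
                             sigma_add2=0.04)
        d = Design(times=[0.5, 1.0, 2.0], dose_amount=100.0)
        mom = expected_moments_fo(case2_model, p, d)
        np.testing.assert_allclose(mom.Vtilde, np.eye(3) * 0.04, atol=1e-12)

    def test_off_diagonal_is_pure_random_effect_term(self, wang_model, wang_params):
        d = Design(times=[0.5, 1.0])
        mom = expected_moments_fo(wang_model, wang_params, d)
        J = jacobian_f_wrt_b(wang_model, wang_params, [0.0], d)
        assert mom.Vtilde[0, 1] == pytest.approx(J[0, 0] * 0.04 * J[1, 0], rel=1e-8)


class TestFoceMoments:
    def test_zero_omega_collapses_to_fo(self, case2_model):
        p = PopulationParams(beta=[5, 10, 30, 10, 1.0], omega=np.zeros((5, 5)),
                             sigma_add2=0.04)
        d = Design(times=[0.5, 1.0, 2.0], dose_amount=100.0)
        sample = sample_random_effects(p.omega, 32)
        foce = expected_moments_foce(case2_model, p, d, sample)
        fo = expected_moments_fo(case2_model, p, d)
        np.testing.assert_allclose(foce.ytilde, fo.ytilde, rtol=1e-12)
        np.testing.assert_allclose(foce.Vtilde, fo.Vtilde, rtol=1e-12, atol=1e-15)

    def test_linear_model_mean_is_exact(self):
        m = linear_model()
        p = PopulationParams(beta=[2.0], omega=[[0.25]], sigma_add2=0.1)
        d = Design(times=[0.5, 1.0, 3.0])
        sample = sample_random_effects(p.omega, 64)
        foce = expected_moments_foce(m, p, d, sample)
        fo = expected_moments_fo(m, p, d)
        np.testing.assert_allclose(foce.ytilde, fo.ytilde, rtol=1e-8)
        np.testing.assert_allclose(foce.Vtilde, fo.Vtilde, rtol=1e-7)

    def test_qmc_sample_size_stability(self, case2_model, case2_params):
        d = Design(times=[0.1, 0.5, 1.0, 3.0, 8.0], dose_amount=100.0)
        a = expected_moments_foce(case2_model, case2_params, d,
                                  sample_random_effects(case2_params.omega, 300))
        b = expected_moments_foce(case2_model, case2_params, d,
                                  sample_random_effects(case2_params.omega, 3000))
        assert np.max(np.abs(a.ytilde / b.ytilde - 1)) < 0.02
        assert np.max(np.abs(np.diag(a.Vtilde) / np.diag(b.Vtilde) - 1)) < 0.02

    def test_interaction_flag_changes_proportional_residual(self, case2_params):
        from aggpk import get_model

        m = get_model("twocomp_oral", residual_kind="proportional")
        p = PopulationParams(beta=case2_params.beta, omega=case2_params.omega,
                             sigma_prop2=0.01)
        d = Design(times=[0.5, 1.0, 3.0], dose_amount=100.0)
        sample = sample_random_effects(p.omega, 128)
        off = expected_moments_foce(m, p, d, sample, interaction=False)
        on = expected_moments_foce(m, p, d, sample, interaction=True)
        assert not np.allclose(np.diag(off.Vtilde), np.diag(on.Vtilde))


class TestMcMoments:
    def test_zero_omega_degenerate(self, case2_model):
        p = PopulationParams(beta=[5, 10, 30, 10, 1.0], omega=np.zeros((5, 5)),
                             sigma_add2=0.04)
        d = Design(times=[0.5, 1.0], dose_amount=100.0)
        mom = expected_moments_mc(case2_model, p, d, sample_random_effects(p.omega, 16))
        np.testing.assert_allclose(mom.ytilde, case2_model.predict(p.beta, d), rtol=1e-12)
        np.testing.assert_allclose(mom.Vtilde, np.eye(2) * 0.04, atol=1e-14)

    def test_lognormal_closed_form(self):
        m = scalar_model()
        p = PopulationParams(beta=[5.0], omega=[[0.09]], sigma_add2=0.04)
        d = Design(times=[1.0])
        mom = expected_moments_mc(m, p, d, sample_random_effects(p.omega, 8192))
        mean = 5 * np.exp(0.045)
        var = 25 * np.exp(0.09) * (np.exp(0.09) - 1) + 0.04
        assert abs(mom.ytilde[0] - mean) / mean < 0.01
        assert abs(mom.Vtilde[0, 0] - var) / var < 0.01

    def test_error_shrinks_with_tenfold_sample(self):
        m = scalar_model()
        p = PopulationParams(beta=[5.0], omega=[[0.09]], sigma_add2=0.04)
        d = Design(times=[1.0])
        var = 25 * np.exp(0.09) * (np.exp(0.09) - 1) + 0.04
        errs = []
        for n in (800, 8000):
            mom = expected_moments_mc(m, p, d, sample_random_effects(p.omega, n))
            errs.append(abs(mom.Vtilde[0, 0] - var))
        assert errs[1] < errs[0]

    def test_matches_pseudo_random_empirical_moments(self, case2_model, case2_params):
        """Sobol MC moments agree with a plain pseudo-random moment estimate."""
        d = Design(times=[0.5, 2.0, 8.0], dose_amount=100.0)
        qmc_mom = expected_moments_mc(
            case2_model, case2_params, d,
            sample_random_effects(case2_params.omega, 4096),
        )
        mc_mom = expected_moments_mc(
            case2_model, case2_params, d,
            sample_random_effects(case2_params.omega, 200000, generator="pseudo", seed=9),
        )
        np.testing.assert_allclose(qmc_mom.ytilde, mc_mom.ytilde, rtol=0.01)
        np.testing.assert_allclose(np.diag(qmc_mom.Vtilde), np.diag(mc_mom.Vtilde), rtol=0.03)


@pytest.mark.parametrize("approx", ["FO", "FOCE", "MC"])
def test_vtilde_symmetric_with_additive_floor(approx, case2_model, case2_params):
    """Predicted covariances are symmetric; additive error bounds the spectrum below."""
    d = Design(times=[0.1, 0.5, 1.0, 3.0, 8.0], dose_amount=100.0)
    sample = sample_random_effects(case2_params.omega, 256)
    if approx == "FO":
        mom = expected_moments_fo(case2_model, case2_params, d)
    elif approx == "FOCE":
        mom = expected_moments_foce(case2_model, case2_params, d, sample)
    else:
        mom = expected_moments_mc(case2_model, case2_params, d, sample)
    np.testing.assert_array_equal(mom.Vtilde, mom.Vtilde.T)
    assert np.min(np.linalg.eigvalsh(mom.Vtilde)) >= 0.04 - 1e-10
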