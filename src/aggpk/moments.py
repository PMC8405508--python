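"""Model-expected aggregate moments under FO, FOCE and Monte-Carlo approximations.

All three approximations produce a :class:`PredictedMoments` pair
``(ytilde, Vtilde)`` — the model's expected mean vector and covariance matrix
of observations for one subject's design:

* FO linearizes the model in the random effects at b = 0:
  ``ytilde = f(g(beta, 0))``, ``Vtilde = J Omega J^T + diag(residual)``.
* FOCE averages the same first-order expressions over a quasi-random sample
  of random-effect vectors, re-centering the mean by the Jacobian correction
  ``f(theta_i) - J_i b_i``.
* MC averages raw (residual-free) simulated predictions and adds the mean
  residual-variance diagonal; with a symmetric residual distribution this is
  exact in the limit of infinitely many samples.

The residual contribution is always a diagonal matrix (independent residuals
across observations). The FOCE "interaction" flag controls whether the
residual magnitude is evaluated at each sampled individual prediction
(FOCEI) or at the typical-value prediction (FOCE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import Design, PopulationParams, StructuralModel, residual_variances
from .simulate import RandomEffectSample

__all__ = [
    "PredictedMoments",
    "jacobian_f_wrt_b",
    "batch_jacobians",
    "expected_moments_fo",
    "expected_moments_foce",
    "expected_moments_mc",
    "expected_moments",
    "default_n_sim",
]

JAC_REL_STEP = 1e-5


@dataclass
class PredictedMoments:
    """Expected aggregate mean and covariance under one approximation."""

    ytilde: np.ndarray
    Vtilde: np.ndarray
    approximation: str
    n_sim: int = 1
    interaction: bool = False

    def __post_init__(self) -> None:
        self.ytilde = np.atleast_1d(np.asarray(self.ytilde, dtype=float))
        self.Vtilde = np.atleast_2d(np.asarray(self.Vtilde, dtype=float))
        K = self.ytilde.size
        if self.Vtilde.shape != (K, K):
            raise ValueError("moment dimensions do not match")


def _predict_for_b(
    model: StructuralModel, params: PopulationParams, B: np.ndarray, design: Design
) -> np.ndarray:
    theta = model.individual_params(params.beta, B)
    return model.predict_batch(theta, design)


def batch_jacobians(
    model: StructuralModel,
    params: PopulationParams,
    B: np.ndarray,
    design: Design,
) -> tuple[np.ndarray, np.ndarray]:
    """Predictions and central-difference Jacobians d f / d b at each row of B.

    Returns ``(F, J)`` with ``F`` of shape (n, K) and ``J`` of shape
    (n, K, v). Step size per coordinate: ``1e-5 * max(1, |b_j|)``. All
    perturbed points are evaluated in one batched model call.
    """
    B = np.atleast_2d(np.asarray(B, dtype=float))
    n, v = B.shape
    K = design.n_obs
    F = _predict_for_b(model, params, B, design)
    H = JAC_REL_STEP * np.maximum(1.0, np.abs(B))  # (n, v)
    Bp = np.repeat(B[:, None, :], v, axis=1)
    Bm = Bp.copy()
    idx = np.arange(v)
    Bp[:, idx, idx] += H
    Bm[:, idx, idx] -= H
    Fp = _predict_for_b(model, params, Bp.reshape(n * v, v), design).reshape(n, v, K)
    Fm = _predict_for_b(model, params, Bm.reshape(n * v, v), design).reshape(n, v, K)
    if not (np.all(np.isfinite(Fp)) and np.all(np.isfinite(Fm))):
        raise FloatingPointError("non-finite prediction at a finite-difference point")
    J = (Fp - Fm) / (2.0 * H[:, :, None])  # (n, v, K)
    return F, np.swapaxes(J, 1, 2)  # J -> (n, K, v)


def jacobian_f_wrt_b(
    model: StructuralModel,
    params: PopulationParams,
    b: np.ndarray,
    design: Design,
) -> np.ndarray:
    """K x v Jacobian of predictions with respect to the random effects at ``b``."""
    b = np.atleast_1d(np.asarray(b, dtype=float))
    _, J = batch_jacobians(model, params, b.reshape(1, -1), design)
    return J[0]


def default_n_sim(n_subjects: int, floor: int = 300) -> int:
    """QMC sample size: the dataset's subject count, but at least ``floor``."""
    return max(floor, int(n_subjects))


def expected_moments_fo(
    model: StructuralModel, params: PopulationParams, design: Design
) -> PredictedMoments:
    """First-order expected moments (linearization at b = 0)."""
    model.validate_params(params)
    zero = np.zeros(params.v)
    F, J = batch_jacobians(model, params, zero.reshape(1, -1), design)
    f0, J0 = F[0], J[0]
    Vt = J0 @ params.omega @ J0.T
    Vt[np.diag_indices_from(Vt)] += residual_variances(f0, params, model.residual_kind)
    return PredictedMoments(ytilde=f0, Vtilde=0.5 * (Vt + Vt.T), approximation="FO", n_sim=1)


def expected_moments_foce(
    model: StructuralModel,
    params: PopulationParams,
    design: Design,
    sample: RandomEffectSample,
    interaction: bool = False,
) -> PredictedMoments:
    """FOCE expected moments: first-order expressions averaged over ``sample``."""
    model.validate_params(params)
    F, J = batch_jacobians(model, params, sample.B, design)
    n = sample.n_sim
    ytilde = (F - np.einsum("nkv,nv->nk", J, sample.B)).mean(axis=0)
    JO = np.einsum("nkv,vw->nkw", J, params.omega)
    Vt = np.einsum("nkw,nlw->kl", JO, J) / n
    if interaction:
        res = residual_variances(F, params, model.residual_kind).mean(axis=0)
    else:
        f0 = model.predict(model.individual_params(params.beta, np.zeros(params.v)), design)
        res = residual_variances(f0, params, model.residual_kind)
    Vt[np.diag_indices_from(Vt)] += res
    return PredictedMoments(
        ytilde=ytilde,
        Vtilde=0.5 * (Vt + Vt.T),
        approximation="FOCEI" if interaction else "FOCE",
        n_sim=n,
        interaction=interaction,
    )


def expected_moments_mc(
    model: StructuralModel,
    params: PopulationParams,
    design: Design,
    sample: RandomEffectSample,
) -> PredictedMoments:
    """Monte-Carlo expected moments from residual-free simulated predictions.

    Both the empirical covariance of the simulated predictions and the
    averaged residual diagonal use the 1/N_sim denominator.
    """
    model.validate_params(params)
    F = _predict_for_b(model, params, sample.B, design)
    n = sample.n_sim
    ytilde = F.mean(axis=0)
    dev = F - ytilde
    Vt = (dev.T @ dev) / n
    res = residual_variances(F, params, model.residual_kind).mean(axis=0)
    Vt[np.diag_indices_from(Vt)] += res
    return PredictedMoments(
        ytilde=ytilde, Vtilde=0.5 * (Vt + Vt.T), approximation="MC", n_sim=n
    )


def expected_moments(
    model: StructuralModel,
    params: PopulationParams,
    design: Design,
    approximation: str,
    sample: RandomEffectSample = None,
) -> PredictedMoments:
    """Dispatch on approximation name: FO, FOCE, FOCEI or MC."""
    key = approximation.upper()
    if key == "FO":
        return expected_moments_fo(model, params, design)
    if sample is None:
        raise ValueError(f"{key} moments require a RandomEffectSample")
    if key == "FOCE":
        return expected_moments_foce(model, params, design, sample, interaction=False)
    if key == "FOCEI":
        return expected_moments_foce(model, params, design, sample, interaction=True)
    if key == "MC":
        return expected_moments_mc(model, params, design, sample)
    raise ValueError(f"unknown approximation {approximation!r}")
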