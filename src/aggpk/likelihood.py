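"""FO/FOCE(I) individual-data and aggregate-data log-likelihoods.

Conventions
-----------
No 2*pi constants appear anywhere: the objective function value
``OFV = -2 * loglik`` then matches the extended-least-squares convention of
standard pharmacometric software, which is also how reference objective
values are printed. This differs from a textbook multivariate-normal density
by ``K * log(2*pi)`` per subject.

The aggregate-data log-likelihood for N subjects sharing a design is

    l(ybar, V | Psi) = -(N/2) [ tr(V Vt^-1) + (ybar-yt)' Vt^-1 (ybar-yt)
                                + log|Vt| ]

with (yt, Vt) the model-expected moments. For a single subject (V = 0) it
collapses to the individual-data expression, and with FO moments it is
identically equal to the summed individual-data FO log-likelihood.

Evaluations where the predicted covariance is not positive definite return a
large negative penalty (-1e10 minus the magnitude of the most negative
eigenvalue) so that outer optimizers see a finite, repulsive surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg, optimize

from .models import Design, PopulationParams, StructuralModel, residual_variances
from .moments import PredictedMoments, batch_jacobians, expected_moments_fo
from .simulate import AggregateData, IndividualDataset, RandomEffectSample

__all__ = [
    "LikelihoodWorkspace",
    "map_random_effects",
    "individual_loglik",
    "aggregate_loglik",
    "ofv",
    "loo_mc_se",
    "PENALTY_BASE",
]

PENALTY_BASE = -1e10


@dataclass
class LikelihoodWorkspace:
    """Per-subject diagnostics from one likelihood evaluation."""

    y_res_i: np.ndarray
    V_i: np.ndarray
    b_map: np.ndarray
    theta_map: np.ndarray
    loglik_i: float

    @property
    def R_i(self) -> np.ndarray:
        """Outer product of the residual vector (rank <= 1, PSD)."""
        return np.outer(self.y_res_i, self.y_res_i)


def _penalized(V: np.ndarray) -> float:
    eigmin = float(np.min(np.linalg.eigvalsh(0.5 * (V + V.T))))
    return PENALTY_BASE - abs(min(eigmin, 0.0))


def _chol_terms(V: np.ndarray):
    """(cho_factor, logdet) of a symmetric matrix, or None if not PD."""
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except (linalg.LinAlgError, ValueError):
        return None
    return (c, low), 2.0 * float(np.sum(np.log(np.diag(c))))


def map_random_effects(
    y_i: np.ndarray,
    model: StructuralModel,
    params: PopulationParams,
    design: Design,
    b0: Optional[np.ndarray] = None,
    gtol: float = 1e-8,
    maxiter: int = 200,
) -> tuple[np.ndarray, bool]:
    """MAP (empirical-Bayes) random-effect estimate for one subject.

    Minimizes the conditional negative log-posterior

        0.5 * [sum_k (y_k - f_k(g(beta, b)))^2 / v_k(b) + sum_k log v_k(b)]
        + 0.5 * b' Omega^-1 b

    with the residual variance ``v_k`` evaluated at the candidate prediction,
    by quasi-Newton iterations from ``b0`` (default 0). Returns the estimate
    and a convergence flag; on non-convergence the best iterate is returned.
    """
    y_i = np.asarray(y_i, dtype=float)
    v = params.v
    if np.allclose(params.omega, 0.0):
        return np.zeros(v), True
    omega_inv = np.linalg.inv(params.omega)

    def objective(b: np.ndarray) -> float:
        f = model.predict(model.individual_params(params.beta, b), design)
        var = residual_variances(f, params, model.residual_kind)
        if np.any(var <= 0) or np.any(~np.isfinite(f)):
            return 1e12
        res = y_i - f
        return 0.5 * (
            float(np.sum(res**2 / var))
            + float(np.sum(np.log(var)))
            + float(b @ omega_inv @ b)
        )

    x0 = np.zeros(v) if b0 is None else np.asarray(b0, dtype=float)
    out = optimize.minimize(
        objective, x0, method="BFGS", options={"gtol": gtol, "maxiter": maxiter}
    )
    # "precision loss" at a flat optimum is fine as long as the gradient is small
    ok = bool(out.success) or float(np.max(np.abs(out.jac))) < 1e-5
    return out.x, ok


def individual_loglik(
    data: IndividualDataset,
    model: StructuralModel,
    params: PopulationParams,
    method: str = "FO",
    b_warm: Optional[np.ndarray] = None,
    return_workspaces: bool = True,
):
    """Summed individual-data log-likelihood under FO, FOCE or FOCEI.

    Per subject the residual is linearized around ``b_tilde`` (zero for FO,
    the MAP estimate for FOCE/FOCEI) and the contribution is
    ``-0.5 * (y_res' V_i^-1 y_res + log|V_i|)``.

    Returns ``(total, workspaces)``; workspaces carry per-subject residuals,
    covariances, MAP estimates and contributions.
    """
    method = method.upper()
    if method not in ("FO", "FOCE", "FOCEI"):
        raise ValueError(f"unknown individual-data method {method!r}")
    model.validate_params(params)
    Y = data.Y
    N, K = Y.shape
    zero = np.zeros(params.v)
    theta0 = model.individual_params(params.beta, zero)
    f0 = model.predict(theta0, design=data.design)

    if method == "FO":
        F, J = batch_jacobians(model, params, zero.reshape(1, -1), data.design)
        V = J[0] @ params.omega @ J[0].T
        V[np.diag_indices_from(V)] += residual_variances(f0, params, model.residual_kind)
        V = 0.5 * (V + V.T)
        ct = _chol_terms(V)
        if ct is None:
            pen = _penalized(V)
            return pen * N, []
        (c, low), logdet = ct
        dev = Y - f0
        sol = linalg.cho_solve((c, low), dev.T, check_finite=False)
        quads = np.sum(dev.T * sol, axis=0)
        contribs = -0.5 * (quads + logdet)
        total = float(np.sum(contribs))
        workspaces = []
        if return_workspaces:
            workspaces = [
                LikelihoodWorkspace(
                    y_res_i=dev[i], V_i=V, b_map=zero.copy(), theta_map=theta0.copy(),
                    loglik_i=float(contribs[i]),
                )
                for i in range(N)
            ]
        return total, workspaces

    interaction = method == "FOCEI"
    total = 0.0
    workspaces = []
    B = np.zeros((N, params.v))
    for i in range(N):
        x0 = None if b_warm is None else b_warm[i]
        b_i, _ = map_random_effects(Y[i], model, params, data.design, b0=x0)
        B[i] = b_i
    F, J = batch_jacobians(model, params, B, data.design)
    res0 = residual_variances(f0, params, model.residual_kind)
    for i in range(N):
        y_res = Y[i] - (F[i] - J[i] @ B[i])
        V_i = J[i] @ params.omega @ J[i].T
        resvar = (
            residual_variances(F[i], params, model.residual_kind) if interaction else res0
        )
        V_i[np.diag_indices_from(V_i)] += resvar
        V_i = 0.5 * (V_i + V_i.T)
        ct = _chol_terms(V_i)
        if ct is None:
            contrib = _penalized(V_i)
        else:
            (c, low), logdet = ct
            sol = linalg.cho_solve((c, low), y_res, check_finite=False)
            contrib = -0.5 * (float(y_res @ sol) + logdet)
        total += contrib
        if return_workspaces:
            workspaces.append(
                LikelihoodWorkspace(
                    y_res_i=y_res,
                    V_i=V_i,
                    b_map=B[i],
                    theta_map=model.individual_params(params.beta, B[i]),
                    loglik_i=float(contrib),
                )
            )
    return total, workspaces


def aggregate_loglik(agg: AggregateData, moments: PredictedMoments) -> float:
    """Aggregate-data log-likelihood of (ybar, V) under predicted moments."""
    if agg.n_obs != moments.ytilde.size:
        raise ValueError("aggregate data and moments have mismatched dimensions")
    Vt = moments.Vtilde
    ct = _chol_terms(Vt)
    if ct is None:
        return _penalized(Vt)
    (c, low), logdet = ct
    r = agg.ybar - moments.ytilde
    quad = float(r @ linalg.cho_solve((c, low), r, check_finite=False))
    tr = float(np.trace(linalg.cho_solve((c, low), agg.V, check_finite=False)))
    return -0.5 * agg.n_subjects * (tr + quad + logdet)


def ofv(loglik: float) -> float:
    """Objective function value: -2 * log-likelihood (no 2*pi constants)."""
    if not np.isfinite(loglik):
        raise ValueError("log-likelihood must be finite")
    return -2.0 * float(loglik)


def loo_mc_se(
    agg: AggregateData,
    model: StructuralModel,
    params: PopulationParams,
    sample: RandomEffectSample,
    approximation: str = "MC",
    return_values: bool = False,
):
    """Leave-one-out Monte-Carlo standard error of the aggregate log-likelihood.

    Each of the ``n_sim`` sampled random-effect vectors is excluded in turn,
    the expected moments and the aggregate log-likelihood are recomputed, and
    the standard deviation of the ``n_sim`` leave-one-out log-likelihoods is
    divided by the number of subjects, giving the approximation standard
    error per one subject in the dataset.
    """
    approximation = approximation.upper()
    if sample.n_sim < 2:
        raise ValueError("leave-one-out requires at least two sampled vectors")
    model.validate_params(params)
    n = sample.n_sim
    K = agg.n_obs

    if approximation == "MC":
        design = agg.design(n_subjects=1)
        theta = model.individual_params(params.beta, sample.B)
        F = model.predict_batch(theta, design)
        res = residual_variances(F, params, model.residual_kind)
        S1 = F.sum(axis=0)
        S2 = F.T @ F
        SR = res.sum(axis=0)
        lls = np.empty(n)
        for i in range(n):
            m = (S1 - F[i]) / (n - 1)
            Vt = (S2 - np.outer(F[i], F[i])) / (n - 1) - np.outer(m, m)
            Vt[np.diag_indices_from(Vt)] += (SR - res[i]) / (n - 1)
            lls[i] = aggregate_loglik(
                agg, PredictedMoments(m, 0.5 * (Vt + Vt.T), "MC", n_sim=n - 1)
            )
    elif approximation in ("FOCE", "FOCEI"):
        interaction = approximation == "FOCEI"
        design = agg.design(n_subjects=1)
        F, J = batch_jacobians(model, params, sample.B, design)
        M = F - np.einsum("nkv,nv->nk", J, sample.B)
        C = np.einsum("nkv,vw,nlw->nkl", J, params.omega, J)
        if interaction:
            res = residual_variances(F, params, model.residual_kind)
        else:
            f0 = model.predict(model.individual_params(params.beta, np.zeros(params.v)), design)
            res = np.broadcast_to(
                residual_variances(f0, params, model.residual_kind), (n, K)
            )
        SM = M.sum(axis=0)
        SC = C.sum(axis=0)
        SR = res.sum(axis=0)
        lls = np.empty(n)
        for i in range(n):
            m = (SM - M[i]) / (n - 1)
            Vt = (SC - C[i]) / (n - 1)
            Vt[np.diag_indices_from(Vt)] += (SR - res[i]) / (n - 1)
            lls[i] = aggregate_loglik(
                agg, PredictedMoments(m, 0.5 * (Vt + Vt.T), approximation, n_sim=n - 1)
            )
    else:
        raise ValueError(f"unsupported approximation for LOO diagnostic: {approximation!r}")

    se = float(np.std(lls, ddof=1)) / agg.n_subjects
    return (se, lls) if return_values else se

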