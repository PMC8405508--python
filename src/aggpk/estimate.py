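"""Maximum-likelihood fitting of population parameters to individual or
aggregate data.

All positive quantities (fixed effects under the lognormal map, variance
terms) are optimized on the log scale; random-effect covariance
off-diagonals are fixed (zero unless supplied) and not estimated. For the
quasi-Monte-Carlo methods (``foce_aggregate``, ``focei_aggregate``,
``mc_aggregate``) the underlying Sobol standard-normal points are drawn once
per fit and held fixed across outer iterations (common random numbers), so
the objective surface is deterministic and smooth; only the Cholesky
re-correlation with the candidate Omega changes between iterations.

The optimizer is a derivative-free simplex stage followed by a quasi-Newton
polish with numerical gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from scipy import optimize

from .likelihood import aggregate_loglik, individual_loglik, PENALTY_BASE
from .models import PopulationParams, StructuralModel
from .moments import default_n_sim, expected_moments
from .numdiff import central_hessian
from .simulate import (
    AggregateData,
    IndividualDataset,
    RandomEffectSample,
    aggregate_observed,
    standard_normal_quasi,
)

__all__ = [
    "ParameterTransform",
    "FitResult",
    "fit",
    "standard_errors",
    "INDIVIDUAL_METHODS",
    "AGGREGATE_METHODS",
]

INDIVIDUAL_METHODS = ("fo_individual", "foce_individual", "focei_individual")
AGGREGATE_METHODS = ("fo_aggregate", "foce_aggregate", "focei_aggregate", "mc_aggregate")


@dataclass
class ParameterTransform:
    """Bijection between PopulationParams and an unconstrained real vector.

    Estimated entries: fixed effects (log scale under a lognormal map, linear
    otherwise), diagonal random-effect variances (log) and residual variances
    (log). Entries masked out keep the template's values. Zero-variance
    entries are never estimated.
    """

    template: PopulationParams
    model: Optional[StructuralModel] = None
    est_beta: np.ndarray = None
    est_omega: np.ndarray = None
    est_sigma_add: bool = None
    est_sigma_prop: bool = None

    def __post_init__(self) -> None:
        t = self.template
        if self.est_beta is None:
            self.est_beta = np.ones(t.beta.size, dtype=bool)
        if self.est_omega is None:
            self.est_omega = np.diag(t.omega) > 0
        if self.est_sigma_add is None:
            self.est_sigma_add = t.sigma_add2 > 0
        if self.est_sigma_prop is None:
            self.est_sigma_prop = t.sigma_prop2 > 0
        self.est_beta = np.asarray(self.est_beta, dtype=bool)
        self.est_omega = np.asarray(self.est_omega, dtype=bool)
        self._log_beta = (
            self.model is None or self.model.param_map_kind == "lognormal"
        )

    @property
    def n_params(self) -> int:
        return (
            int(self.est_beta.sum())
            + int(self.est_omega.sum())
            + int(self.est_sigma_add)
            + int(self.est_sigma_prop)
        )

    def names(self) -> list:
        beta_names = (
            list(self.model.param_names)
            if self.model is not None and self.model.param_names
            else [f"beta{j + 1}" for j in range(self.template.beta.size)]
        )
        out = [beta_names[j] for j in np.flatnonzero(self.est_beta)]
        out += [f"omega2_{beta_names[j]}" for j in np.flatnonzero(self.est_omega)]
        if self.est_sigma_add:
            out.append("sigma_add2")
        if self.est_sigma_prop:
            out.append("sigma_prop2")
        return out

    # -- natural scale -----------------------------------------------------
    def natural_vector(self, params: PopulationParams) -> np.ndarray:
        parts = [params.beta[self.est_beta], np.diag(params.omega)[self.est_omega]]
        if self.est_sigma_add:
            parts.append([params.sigma_add2])
        if self.est_sigma_prop:
            parts.append([params.sigma_prop2])
        return np.concatenate([np.atleast_1d(p) for p in parts])

    def from_natural(self, x: np.ndarray) -> PopulationParams:
        x = np.asarray(x, dtype=float)
        p = self.template.copy()
        nb = int(self.est_beta.sum())
        no = int(self.est_omega.sum())
        p.beta[self.est_beta] = x[:nb]
        d = np.diag(p.omega).copy()
        d[self.est_omega] = x[nb : nb + no]
        p.omega[np.diag_indices_from(p.omega)] = d
        i = nb + no
        if self.est_sigma_add:
            p.sigma_add2 = float(x[i])
            i += 1
        if self.est_sigma_prop:
            p.sigma_prop2 = float(x[i])
        return PopulationParams(p.beta, p.omega, p.sigma_add2, p.sigma_prop2)

    # -- unconstrained scale -----------------------------------------------
    def to_vector(self, params: PopulationParams) -> np.ndarray:
        x = self.natural_vector(params)
        nb = int(self.est_beta.sum())
        y = np.log(x) if self._log_beta else np.concatenate([x[:nb], np.log(x[nb:])])
        return y

    def from_vector(self, y: np.ndarray) -> PopulationParams:
        y = np.asarray(y, dtype=float)
        nb = int(self.est_beta.sum())
        if self._log_beta:
            x = np.exp(y)
        else:
            x = np.concatenate([y[:nb], np.exp(y[nb:])])
        return self.from_natural(x)


@dataclass
class FitResult:
    """Estimates, objective value and diagnostics from one fit."""

    method: str
    estimates: PopulationParams
    loglik: float
    ofv: float
    converged: bool
    n_evals: int
    transform: ParameterTransform
    n_sim: int = 0
    seed: int = 0
    se: Optional[np.ndarray] = None
    rse_percent: Optional[np.ndarray] = None
    se_flag: str = "not_computed"
    message: str = ""

    def to_dict(self) -> dict:
        est = self.estimates
        return {
            "method": self.method,
            "estimates": {
                "beta": est.beta.tolist(),
                "omega": est.omega.tolist(),
                "sigma_add2": est.sigma_add2,
                "sigma_prop2": est.sigma_prop2,
            },
            "parameter_names": self.transform.names(),
            "parameter_values": self.transform.natural_vector(est).tolist(),
            "loglik": self.loglik,
            "ofv": self.ofv,
            "converged": bool(self.converged),
            "n_evals": self.n_evals,
            "n_sim": self.n_sim,
            "seed": self.seed,
            "se": None if self.se is None else self.se.tolist(),
            "rse_percent": None if self.rse_percent is None else self.rse_percent.tolist(),
            "se_flag": self.se_flag,
            "message": self.message,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [f"method: {self.method}   OFV: {self.ofv:.4f}   converged: {self.converged}"]
        names = self.transform.names()
        vals = self.transform.natural_vector(self.estimates)
        se = self.se if self.se is not None else [None] * len(names)
        rse = self.rse_percent if self.rse_percent is not None else [None] * len(names)
        lines.append(f"{'parameter':<16}{'estimate':>12}{'SE':>12}{'RSE%':>10}")
        for n, v, s, r in zip(names, vals, se, rse):
            s_str = f"{s:>12.4g}" if s is not None else f"{'-':>12}"
            r_str = f"{r:>10.3g}" if r is not None else f"{'-':>10}"
            lines.append(f"{n:<16}{v:>12.6g}{s_str}{r_str}")
        return "\n".join(lines)


def _negloglik_factory(
    data: Union[IndividualDataset, AggregateData],
    model: StructuralModel,
    method: str,
    transform: ParameterTransform,
    n_sim: int,
    seed: int,
) -> Callable[[PopulationParams], float]:
    """Negative log-likelihood as a function of PopulationParams.

    For QMC aggregate methods, the standard-normal Sobol points are fixed
    here and re-correlated with each candidate's Omega.
    """
    method = method.lower()
    if method in INDIVIDUAL_METHODS:
        if not isinstance(data, IndividualDataset):
            raise TypeError(f"method {method!r} requires an IndividualDataset")
        approx = method.split("_")[0].upper()
        warm = {"B": None}

        def nll(params: PopulationParams) -> float:
            ll, ws = individual_loglik(
                data, model, params, method=approx, b_warm=warm["B"]
            )
            if approx != "FO" and ws:
                warm["B"] = np.array([w.b_map for w in ws])
            return -ll

        return nll

    if method not in AGGREGATE_METHODS:
        raise ValueError(f"unknown estimation method {method!r}")
    agg = data if isinstance(data, AggregateData) else aggregate_observed(data)
    design = agg.design(n_subjects=agg.n_subjects)
    approx = {"fo_aggregate": "FO", "foce_aggregate": "FOCE",
              "focei_aggregate": "FOCEI", "mc_aggregate": "MC"}[method]
    Z = None
    if approx != "FO":
        Z = standard_normal_quasi(transform.template.v, n_sim, generator="sobol", seed=seed)

    def nll(params: PopulationParams) -> float:
        sample = None
        if Z is not None:
            sample = RandomEffectSample(B=None, generator="sobol", Z=Z).with_omega(params.omega)
        mom = expected_moments(model, params, design, approx, sample=sample)
        return -aggregate_loglik(agg, mom)

    return nll


def fit(
    data: Union[IndividualDataset, AggregateData],
    model: StructuralModel,
    init: PopulationParams,
    method: str = "fo_aggregate",
    transform: Optional[ParameterTransform] = None,
    n_sim: Optional[int] = None,
    seed: int = 0,
    compute_se: bool = False,
    simplex_maxiter: Optional[int] = None,
    ftol: float = 1e-10,
    log_bound_width: Optional[float] = 3.0,
) -> FitResult:
    """Maximize the chosen approximate log-likelihood over the parameter space.

    A Nelder-Mead simplex stage is followed by an L-BFGS-B polish on the
    log-transformed parameters; the better of the two stage results is
    returned. ``n_sim`` defaults to max(300, N).

    ``log_bound_width`` confines the search to a box of +/- that many log
    units (default 3, a factor ~20) around the initial estimates. Approximate
    NLME likelihood surfaces, especially under model misspecification, can
    possess degenerate modes in which a fixed effect escapes toward zero
    while its variance inflates without bound; the box keeps the optimizer
    on the principal mode. Pass ``None`` for an unconstrained search.
    """
    method = method.lower()
    model.validate_params(init)
    if transform is None:
        transform = ParameterTransform(template=init.copy(), model=model)
    n_subjects = data.n_subjects
    if n_sim is None:
        n_sim = default_n_sim(n_subjects)
    nll_params = _negloglik_factory(data, model, method, transform, n_sim, seed)
    evals = {"n": 0}

    def objective(y: np.ndarray) -> float:
        evals["n"] += 1
        try:
            params = transform.from_vector(y)
        except (ValueError, FloatingPointError):
            return -PENALTY_BASE
        try:
            val = nll_params(params)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return -PENALTY_BASE
        return val if np.isfinite(val) else -PENALTY_BASE

    y0 = transform.to_vector(init)
    bounds = None
    if log_bound_width is not None:
        bounds = optimize.Bounds(y0 - log_bound_width, y0 + log_bound_width)
    if simplex_maxiter is None:
        simplex_maxiter = 100 * y0.size

    def simplex(start, maxiter):
        return optimize.minimize(
            objective,
            start,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-6,
                     "adaptive": True},
        )

    def quasi_newton(start):
        return optimize.minimize(
            objective,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": ftol, "gtol": 1e-8, "maxiter": 200},
        )

    # alternate coarse simplex and quasi-Newton rounds until the objective
    # stabilizes: the restarted simplex (fresh 5%-sized simplex at the
    # incumbent) hops the small ridges that trap single-stage runs, and the
    # polish does the precise local work
    best = simplex(y0, simplex_maxiter)
    success = False
    for _ in range(4):
        polish = quasi_newton(best.x)
        if polish.fun <= best.fun:
            best = polish
        restart = simplex(best.x, simplex_maxiter)
        improvement = best.fun - restart.fun
        if restart.fun <= best.fun:
            best = restart
        if improvement <= 1e-7 * max(1.0, abs(best.fun)):
            success = bool(polish.success or restart.success)
            break
    converged = success and best.fun < -PENALTY_BASE / 2
    estimates = transform.from_vector(best.x)
    loglik = -float(best.fun)
    result = FitResult(
        method=method,
        estimates=estimates,
        loglik=loglik,
        ofv=-2.0 * loglik,
        converged=converged,
        n_evals=evals["n"],
        transform=transform,
        n_sim=0 if method in ("fo_aggregate", "fo_individual") else n_sim,
        seed=seed,
        message=str(best.message),
    )
    if compute_se:
        standard_errors(result, data, model)
    return result


def standard_errors(
    fitres: FitResult,
    data: Union[IndividualDataset, AggregateData],
    model: StructuralModel,
    rel_step: float = 1e-4,
) -> FitResult:
    """Observed-information standard errors on the natural parameter scale.

    Central-difference Hessian of the negative log-likelihood at the
    estimates; SE = sqrt(diag(H^-1)), RSE% = 100 * SE / |estimate|. If the
    Hessian is not invertible or has non-positive diagonal of the inverse,
    SEs are left absent with a flag.
    """
    transform = fitres.transform
    n_sim = fitres.n_sim if fitres.n_sim else default_n_sim(data.n_subjects)
    nll_params = _negloglik_factory(data, model, fitres.method, transform, n_sim, fitres.seed)

    def nll_nat(x: np.ndarray) -> float:
        try:
            return nll_params(transform.from_natural(x))
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return -PENALTY_BASE

    x0 = transform.natural_vector(fitres.estimates)
    H = central_hessian(nll_nat, x0, rel_step=rel_step)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive variance estimate")
        fitres.se = np.sqrt(diag)
        fitres.rse_percent = 100.0 * fitres.se / np.abs(x0)
        fitres.se_flag = "ok"
    except np.linalg.LinAlgError as exc:
        fitres.se = None
        fitres.rse_percent = None
        fitres.se_flag = f"hessian_not_pd: {exc}"
    return fitres
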