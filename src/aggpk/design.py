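"""Expected Fisher information, the one-step "aggregate-data OD" procedure,
and stochastic simulation-and-estimation (SSE) replications.

The expected FIM is obtained without analytic information expressions: the
model-expected aggregate data (mean vector and covariance matrix) are
simulated from the data-generating model, and the negative numerical Hessian
of the aggregate-data log-likelihood with respect to the data-analytic
model's parameters is taken at the evaluation point. When the generating and
analytic models coincide this reproduces classical optimal-design FIMs; when
they differ it extends optimal design to the misspecified-model case.

``fo_fim_linearized_oracle`` is an independent implementation of the
standard FO population-FIM formula (gradients of the FO moments plugged into
the multivariate-normal information identity) used to cross-check the
Hessian route.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .estimate import (
    AGGREGATE_METHODS,
    FitResult,
    ParameterTransform,
    fit,
    standard_errors,
)
from .likelihood import aggregate_loglik, PENALTY_BASE
from .models import Design, PopulationParams, StructuralModel
from .moments import default_n_sim, expected_moments, expected_moments_fo
from .numdiff import central_hessian
from .simulate import (
    AggregateData,
    RandomEffectSample,
    aggregate_observed,
    sample_random_effects,
    simulate_individuals,
    standard_normal_quasi,
)

__all__ = [
    "FimResult",
    "SseResult",
    "expected_aggregate_data",
    "expected_fim",
    "fo_fim_linearized_oracle",
    "aggregate_od",
    "run_sse",
]


@dataclass
class FimResult:
    """Expected Fisher information with per-parameter RSE%."""

    fim: np.ndarray
    rse_percent: np.ndarray
    approximation: str
    design: Design
    params: PopulationParams
    parameter_names: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        se = _se_from_fim(self.fim)
        return pd.DataFrame(
            {
                "parameter": self.parameter_names,
                "se": se,
                "rse_percent": self.rse_percent,
            }
        )


@dataclass
class SseResult:
    """Replicate-level SSE estimates and their summaries."""

    replicates: pd.DataFrame
    parameter_names: list
    methods: list
    n_replicates: int
    mode: str
    seed: int

    def summary(self) -> pd.DataFrame:
        """Mean and SD per parameter per method over converged replicates."""
        conv = self.replicates[self.replicates["converged"]]
        rows = []
        for m in self.methods:
            sub = conv[conv["method"] == m]
            for p in self.parameter_names:
                rows.append(
                    {
                        "method": m,
                        "parameter": p,
                        "mean": sub[p].mean(),
                        "sd": sub[p].std(ddof=1),
                        "n_converged": len(sub),
                    }
                )
        return pd.DataFrame(rows)


def _se_from_fim(fim: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(fim)
        d = np.diag(cov)
        return np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
    except np.linalg.LinAlgError:
        return np.full(fim.shape[0], np.nan)


def expected_aggregate_data(
    model: StructuralModel,
    params: PopulationParams,
    design: Design,
    approximation: str = "MC",
    n_sim: Optional[int] = None,
    seed: int = 0,
) -> AggregateData:
    """Model-expected aggregate data: asymptotic (ybar, V) on a given design."""
    if n_sim is None:
        n_sim = default_n_sim(design.n_subjects)
    sample = None
    if approximation.upper() != "FO":
        sample = sample_random_effects(params.omega, n_sim, generator="sobol", seed=seed)
    mom = expected_moments(model, params, design, approximation, sample=sample)
    return AggregateData(
        ybar=mom.ytilde,
        V=mom.Vtilde,
        n_subjects=design.n_subjects,
        times=design.times.copy(),
        dose_amount=design.dose_amount,
        dose_time=design.dose_time,
    )


def expected_fim(
    gen_model: StructuralModel,
    gen_params: PopulationParams,
    ana_model: StructuralModel,
    ana_params: PopulationParams,
    design: Design,
    approximation: str = "FO",
    n_sim: Optional[int] = None,
    seed: int = 0,
    transform: Optional[ParameterTransform] = None,
    rel_step: float = 1e-3,
) -> FimResult:
    """Expected FIM as the negative Hessian of the aggregate log-likelihood.

    Expected aggregate data are simulated from ``gen_model`` at
    ``gen_params``; the Hessian is taken with respect to ``ana_model``'s
    estimated parameters at ``ana_params`` on the natural scale (central
    differences, relative step ``rel_step``, one Richardson refinement).
    RSE% = 100 * sqrt(diag(FIM^-1)) / |parameter|.
    """
    approx = approximation.upper()
    if n_sim is None:
        n_sim = default_n_sim(design.n_subjects)
    agg = expected_aggregate_data(gen_model, gen_params, design, approx, n_sim, seed)
    if transform is None:
        transform = ParameterTransform(template=ana_params.copy(), model=ana_model)
    Z = None
    if approx != "FO":
        Z = standard_normal_quasi(ana_params.v, n_sim, generator="sobol", seed=seed)
    ana_design = agg.design(n_subjects=design.n_subjects)

    def ll(x: np.ndarray) -> float:
        p = transform.from_natural(x)
        sample = None
        if Z is not None:
            sample = RandomEffectSample(B=None, generator="sobol", Z=Z).with_omega(p.omega)
        mom = expected_moments(ana_model, p, ana_design, approx, sample=sample)
        return aggregate_loglik(agg, mom)

    x0 = transform.natural_vector(ana_params)
    fim = -central_hessian(ll, x0, rel_step=rel_step, richardson=True)
    fim = 0.5 * (fim + fim.T)
    se = _se_from_fim(fim)
    rse = 100.0 * se / np.abs(x0)
    return FimResult(
        fim=fim,
        rse_percent=rse,
        approximation=approx,
        design=design,
        params=ana_params,
        parameter_names=transform.names(),
    )


def fo_fim_linearized_oracle(
    model: StructuralModel,
    params: PopulationParams,
    design: Design,
    transform: Optional[ParameterTransform] = None,
    rel_step: float = 1e-4,
) -> FimResult:
    """FO population FIM from the multivariate-normal information identity.

    I_jk = N * [ (dy_j)' Vt^-1 dy_k + 0.5 tr(Vt^-1 dV_j Vt^-1 dV_k) ], with
    dy_j, dV_j central-difference gradients of the FO expected moments with
    respect to the j-th natural-scale parameter.
    """
    if transform is None:
        transform = ParameterTransform(template=params.copy(), model=model)
    x0 = transform.natural_vector(params)
    p_dim = x0.size

    def mom(x):
        m = expected_moments_fo(model, transform.from_natural(x), design)
        return m.ytilde, m.Vtilde

    y0, V0 = mom(x0)
    c, low = linalg.cho_factor(V0, lower=True)
    dys, dVs = [], []
    for j in range(p_dim):
        h = rel_step * max(abs(x0[j]), 1e-8)
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        yp, Vp = mom(xp)
        ym, Vm = mom(xm)
        dys.append((yp - ym) / (2 * h))
        dVs.append((Vp - Vm) / (2 * h))
    # pre-whiten: Vt^-1 dV_j
    W = [linalg.cho_solve((c, low), dV) for dV in dVs]
    fim = np.empty((p_dim, p_dim))
    for j in range(p_dim):
        sj = linalg.cho_solve((c, low), dys[j])
        for k in range(j, p_dim):
            val = float(dys[k] @ sj) + 0.5 * float(np.sum(W[j].T * W[k]))
            fim[j, k] = fim[k, j] = design.n_subjects * val
    se = _se_from_fim(fim)
    return FimResult(
        fim=fim,
        rse_percent=100.0 * se / np.abs(x0),
        approximation="FO",
        design=design,
        params=params,
        parameter_names=transform.names(),
    )


def aggregate_od(
    gen_model: StructuralModel,
    gen_params: PopulationParams,
    ana_model: StructuralModel,
    init: PopulationParams,
    design: Design,
    method: str = "mc_aggregate",
    n_sim: Optional[int] = None,
    seed: int = 0,
    gen_approximation: str = "MC",
    compute_se: bool = True,
) -> FitResult:
    """One-step SSE replacement: fit the analytic model to expected aggregate data.

    Expected aggregate data are simulated once from the generating model
    (MC approximation by default); the data-analytic model is then fitted to
    them by the requested aggregate-data method, and Hessian-based expected
    standard errors are attached.
    """
    if method not in AGGREGATE_METHODS:
        raise ValueError(f"aggregate_od requires an aggregate method, got {method!r}")
    if n_sim is None:
        n_sim = default_n_sim(design.n_subjects)
    agg = expected_aggregate_data(gen_model, gen_params, design, gen_approximation, n_sim, seed)
    result = fit(agg, ana_model, init, method=method, n_sim=n_sim, seed=seed)
    if compute_se:
        standard_errors(result, agg, ana_model)
    return result


def run_sse(
    gen_model: StructuralModel,
    gen_params: PopulationParams,
    ana_model: StructuralModel,
    init: PopulationParams,
    design: Design,
    n_replicates: int,
    methods: Sequence[str],
    mode: str = "aggregate",
    seed: int = 0,
    n_sim: Optional[int] = None,
) -> SseResult:
    """Simulate-then-fit replications (SSE).

    Per replicate: simulate an individual-level dataset from the generating
    model with a counter-derived seed; in ``aggregate`` mode reduce it to
    (ybar, V) before fitting. Each requested method is fitted to each
    replicate; failures are recorded per replicate, not fatal. The replicate
    datasets depend only on (gen_model, gen_params, design, seed), so
    individual-mode and aggregate-mode runs with the same seed see the same
    underlying data.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be at least 2")
    if mode not in ("individual", "aggregate"):
        raise ValueError(f"unknown SSE mode {mode!r}")
    transform = ParameterTransform(template=init.copy(), model=ana_model)
    names = transform.names()
    rows = []
    for r in range(n_replicates):
        rep_seed = int(seed + r) % (2**31)
        data = simulate_individuals(gen_model, gen_params, design, seed=rep_seed)
        target = aggregate_observed(data) if mode == "aggregate" else data
        for m in methods:
            row = {"replicate": r, "seed": rep_seed, "method": m}
            try:
                res = fit(
                    target,
                    ana_model,
                    init,
                    method=m,
                    transform=ParameterTransform(template=init.copy(), model=ana_model),
                    n_sim=n_sim,
                    seed=rep_seed,
                )
                row["converged"] = res.converged
                row["ofv"] = res.ofv
                for nme, val in zip(names, transform.natural_vector(res.estimates)):
                    row[nme] = val
            except Exception as exc:  # replicate failure is data, not a crash
                row["converged"] = False
                row["ofv"] = np.nan
                row["error"] = str(exc)
            rows.append(row)
    return SseResult(
        replicates=pd.DataFrame(rows),
        parameter_names=names,
        methods=list(methods),
        n_replicates=n_replicates,
        mode=mode,
        seed=seed,
    )
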