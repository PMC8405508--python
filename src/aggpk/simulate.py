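"""Simulation of individual-level data and aggregation to (mean, covariance) form.

Aggregate data here means the observed mean vector ``ybar`` and the observed
variance-covariance matrix ``V`` of a balanced N x K response matrix, with the
population (1/N) covariance denominator. The 1/N convention is load-bearing:
it is what makes the aggregate-data FO log-likelihood identically equal to
the summed individual-data FO log-likelihood.

Random effects for quasi-Monte-Carlo integration are drawn from a Sobol
sequence mapped through the inverse standard-normal CDF; residual errors in
simulated datasets use an ordinary seeded pseudo-random generator.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from scipy.stats import qmc

from .models import Design, PopulationParams, StructuralModel, residual_variances

__all__ = [
    "IndividualDataset",
    "RandomEffectSample",
    "AggregateData",
    "standard_normal_quasi",
    "sample_random_effects",
    "simulate_individuals",
    "aggregate_observed",
]


@dataclass
class IndividualDataset:
    """Balanced N x K observation matrix with its shared design."""

    Y: np.ndarray
    design: Design
    subject_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.Y.shape != (self.design.n_subjects, self.design.n_obs):
            raise ValueError(
                f"Y has shape {self.Y.shape}, design implies "
                f"({self.design.n_subjects}, {self.design.n_obs})"
            )
        if np.any(~np.isfinite(self.Y)):
            raise ValueError("dataset contains missing or non-finite cells")
        if self.subject_ids is None:
            self.subject_ids = np.arange(1, self.Y.shape[0] + 1)
        self.subject_ids = np.asarray(self.subject_ids)

    @property
    def n_subjects(self) -> int:
        return self.Y.shape[0]


@dataclass
class RandomEffectSample:
    """A deterministic set of random-effect vectors used for QMC integration.

    ``Z`` holds the underlying standard-normal points so the correlated
    sample can be re-derived for a different Omega with common random
    numbers: ``B = Z @ chol(Omega).T``.
    """

    B: np.ndarray
    generator: str = "sobol"
    Z: Optional[np.ndarray] = None

    @property
    def n_sim(self) -> int:
        return self.B.shape[0]

    @property
    def v(self) -> int:
        return self.B.shape[1]

    def with_omega(self, omega: np.ndarray) -> "RandomEffectSample":
        """Re-correlate the stored standard-normal points with a new Omega."""
        if self.Z is None:
            raise ValueError("sample does not carry its standard-normal points")
        L = _psd_cholesky(np.atleast_2d(omega))
        return RandomEffectSample(B=self.Z @ L.T, generator=self.generator, Z=self.Z)


@dataclass
class AggregateData:
    """Observed mean vector and covariance matrix for N subjects on one design.

    ``times``, ``dose_amount`` and ``dose_time`` are provenance: they let the
    model-expected moments be recomputed from the aggregate file alone.
    """

    ybar: np.ndarray
    V: np.ndarray
    n_subjects: int
    times: Optional[np.ndarray] = None
    dose_amount: float = 100.0
    dose_time: float = 0.0

    def __post_init__(self) -> None:
        self.ybar = np.atleast_1d(np.asarray(self.ybar, dtype=float))
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        K = self.ybar.size
        if self.V.shape != (K, K):
            raise ValueError(f"cov shape {self.V.shape} does not match mean length {K}")
        if not np.allclose(self.V, self.V.T, atol=1e-8 * max(1.0, float(np.abs(self.V).max()))):
            raise ValueError("covariance matrix is not symmetric")
        self.V = 0.5 * (self.V + self.V.T)
        eigmin = float(np.min(np.linalg.eigvalsh(self.V)))
        if eigmin < -1e-10 * max(1.0, float(np.abs(self.V).max())):
            raise ValueError(f"covariance matrix is not PSD (min eigenvalue {eigmin:.3e})")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if self.n_subjects == 1 and np.any(self.V != 0.0):
            raise ValueError("a single subject implies a zero covariance matrix")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)

    @property
    def n_obs(self) -> int:
        return self.ybar.size

    def design(self, n_subjects: Optional[int] = None) -> Design:
        """Reconstruct the shared elementary design behind this aggregate."""
        if self.times is None:
            raise ValueError("aggregate data carries no sampling-time grid")
        return Design(
            times=self.times,
            dose_amount=self.dose_amount,
            dose_time=self.dose_time,
            n_subjects=self.n_subjects if n_subjects is None else n_subjects,
        )


def _psd_cholesky(omega: np.ndarray) -> np.ndarray:
    """Cholesky-like factor of a PSD matrix (eigenvalue fallback at the boundary)."""
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    w = np.linalg.eigvalsh(omega)
    if w[0] < -1e-10 * max(1.0, w[-1]):
        raise ValueError(f"omega is not positive semi-definite (min eigenvalue {w[0]:.3e})")
    try:
        return np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        w, U = np.linalg.eigh(omega)
        return U @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def standard_normal_quasi(v: int, n_sim: int, generator: str = "sobol", seed: int = 0) -> np.ndarray:
    """Standard-normal points for QMC integration over random effects.

    Sobol points are unscrambled, hence fully deterministic for fixed
    (v, n_sim); the all-zero first point is skipped because the inverse
    normal CDF is undefined there. ``generator='pseudo'`` gives ordinary
    seeded normal draws for comparison studies.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be at least 1")
    if generator == "sobol":
        eng = qmc.Sobol(d=v, scramble=False)
        with warnings.catch_warnings():
            # n_sim + 1 is deliberately not a power of two: the all-zero
            # first point is dropped (inverse normal CDF undefined there)
            warnings.simplefilter("ignore", UserWarning)
            u = eng.random(n_sim + 1)[1:]
        return stats.norm.ppf(u)
    if generator == "pseudo":
        rng = np.random.default_rng(seed)
        return rng.standard_normal((n_sim, v))
    raise ValueError(f"unknown generator kind: {generator!r}")


def sample_random_effects(
    omega: np.ndarray,
    n_sim: int,
    generator: str = "sobol",
    seed: int = 0,
) -> RandomEffectSample:
    """Draw ``n_sim`` random-effect vectors with covariance ``omega``."""
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    L = _psd_cholesky(omega)
    Z = standard_normal_quasi(omega.shape[0], n_sim, generator=generator, seed=seed)
    return RandomEffectSample(B=Z @ L.T, generator=generator, Z=Z)


def simulate_individuals(
    model: StructuralModel,
    params: PopulationParams,
    design: Design,
    seed: int = 0,
) -> IndividualDataset:
    """Simulate a balanced individual-level dataset from the population model.

    Per subject: draw b_i ~ N(0, Omega) (pseudo-random, seeded), map to
    theta_i = g(beta, b_i), and add a normal residual with variance given by
    the residual model at the subject's own prediction. Concentrations are
    not truncated at zero: the likelihood assumes symmetric normal residuals.
    """
    model.validate_params(params)
    rng = np.random.default_rng(seed)
    N = design.n_subjects
    L = _psd_cholesky(params.omega)
    B = rng.standard_normal((N, params.v)) @ L.T
    theta = model.individual_params(params.beta, B)
    F = model.predict_batch(theta, design)
    var = residual_variances(F, params, model.residual_kind)
    Y = F + rng.standard_normal(F.shape) * np.sqrt(var)
    return IndividualDataset(Y=Y, design=design)


def aggregate_observed(data: IndividualDataset) -> AggregateData:
    """Column means and the 1/N-denominator covariance of a balanced dataset."""
    Y = data.Y
    N = Y.shape[0]
    ybar = Y.mean(axis=0)
    dev = Y - ybar
    V = (dev.T @ dev) / N
    return AggregateData(
        ybar=ybar,
        V=V,
        n_subjects=N,
        times=data.design.times.copy(),
        dose_amount=data.design.dose_amount,
        dose_time=data.design.dose_time,
    )
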