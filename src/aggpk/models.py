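"""Structural PK models, population parameters and designs.

A nonlinear mixed-effects (population) PK model is specified by the triplet
(f, h, g): a structural prediction ``f(theta_i, design)``, a residual-error
model ``h`` (additive, proportional or combined), and an individual-parameter
map ``theta_i = g(beta, b_i)`` taking the fixed effects ``beta`` and a
subject-level random-effect vector ``b_i ~ N(0, Omega)``.

Built-in models:

``wang``
    One-compartment monoexponential decay ``f = 10 * exp(-theta * t)`` with a
    single lognormal random effect on the rate constant.
``twocomp_oral``
    Two-compartment mammillary disposition with first-order absorption from a
    depot; parameters (CL, Vc, Vp, Q, ka), concentrations in mg/L.
``transit2``
    Absorption through a chain of first-order transit steps (depot counted as
    the first of three steps, each of rate ``3 / MTT``) feeding the same
    two-compartment disposition; parameters (MTT, CL, Vc, Vp, Q).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "Design",
    "PopulationParams",
    "StructuralModel",
    "param_map_g",
    "residual_variances",
    "predict_wang",
    "predict_twocomp_oral",
    "predict_transit",
    "get_model",
    "register_model",
]


@dataclass
class Design:
    """An elementary design: sampling schedule plus a single dose event.

    Parameters
    ----------
    times : array-like
        Sampling times in hours, non-negative and non-decreasing.
    dose_amount : float
        Dose in mg (amplitude is hard-coded for the ``wang`` model).
    dose_time : float
        Time of dosing in hours.
    n_subjects : int
        Number of subjects sharing this elementary design.
    """

    times: np.ndarray
    dose_amount: float = 100.0
    dose_time: float = 0.0
    n_subjects: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be a 1-D vector")
        if np.any(self.times < 0):
            raise ValueError("sampling times must be non-negative")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("sampling times must be non-decreasing")
        if self.dose_amount < 0:
            raise ValueError("dose_amount must be non-negative")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")

    @property
    def n_obs(self) -> int:
        return self.times.size


@dataclass
class PopulationParams:
    """Full population parameter vector Psi = (beta, Omega, sigma terms).

    ``omega`` holds the v x v random-effect covariance (log-scale variances
    for the lognormal map). ``sigma_add2`` is the additive residual variance
    in (mg/L)^2; ``sigma_prop2`` the dimensionless proportional residual
    variance. Either residual variance may be zero, but not both.
    """

    beta: np.ndarray
    omega: np.ndarray
    sigma_add2: float = 0.0
    sigma_prop2: float = 0.0

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        if self.omega.shape[0] != self.omega.shape[1]:
            raise ValueError("omega must be square")
        if not np.allclose(self.omega, self.omega.T, atol=1e-12):
            raise ValueError("omega must be symmetric")
        eigmin = float(np.min(np.linalg.eigvalsh(self.omega))) if self.omega.size else 0.0
        if eigmin < -1e-10:
            raise ValueError(f"omega must be positive semi-definite (min eigenvalue {eigmin:.3e})")
        if self.sigma_add2 < 0 or self.sigma_prop2 < 0:
            raise ValueError("residual variances must be non-negative")
        if self.sigma_add2 == 0 and self.sigma_prop2 == 0:
            raise ValueError("at least one residual variance must be positive")

    @property
    def v(self) -> int:
        return self.omega.shape[0]

    def copy(self) -> "PopulationParams":
        return PopulationParams(
            beta=self.beta.copy(),
            omega=self.omega.copy(),
            sigma_add2=self.sigma_add2,
            sigma_prop2=self.sigma_prop2,
        )


def param_map_g(beta: np.ndarray, b: np.ndarray, kind: str = "lognormal") -> np.ndarray:
    """Individual-parameter map ``theta_i = g(beta, b_i)``.

    ``lognormal``: ``theta = beta * exp(b)`` elementwise (requires beta > 0);
    ``identity``: ``theta = beta + b``. When ``b`` is shorter than ``beta``
    the trailing fixed effects carry no random effect. Both maps satisfy
    ``g(beta, 0) = beta``.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if b.shape[-1] > beta.shape[-1]:
        raise ValueError(f"random-effect vector longer ({b.shape[-1]}) than beta ({beta.shape[-1]})")
    pad = beta.shape[-1] - b.shape[-1]
    if pad:
        b = np.concatenate([b, np.zeros(b.shape[:-1] + (pad,))], axis=-1)
    if kind == "lognormal":
        if np.any(beta[: beta.shape[-1]] <= 0):
            raise ValueError("lognormal map requires strictly positive beta")
        return beta * np.exp(b)
    if kind == "identity":
        return beta + b
    raise ValueError(f"unknown parameter map kind: {kind!r}")


def residual_variances(f_pred: np.ndarray, params: PopulationParams, kind: str) -> np.ndarray:
    """Per-observation residual variance: the diagonal of J_h Sigma J_h^T at eps=0.

    additive: sigma1^2; proportional: f^2 sigma2^2; combined: the sum.
    Broadcasts over any leading axes of ``f_pred``.
    """
    f_pred = np.asarray(f_pred, dtype=float)
    if not np.all(np.isfinite(f_pred)):
        raise ValueError("predictions must be finite")
    if kind == "additive":
        return np.full_like(f_pred, params.sigma_add2)
    if kind == "proportional":
        return f_pred**2 * params.sigma_prop2
    if kind == "combined":
        return f_pred**2 * params.sigma_prop2 + params.sigma_add2
    raise ValueError(f"unknown residual kind: {kind!r}")


# ---------------------------------------------------------------------------
# Built-in structural predictions (vectorized over a batch of theta vectors)
# ---------------------------------------------------------------------------


def predict_wang(theta: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Monoexponential decay ``f = 10 * exp(-theta * t)`` (amplitude fixed at 10)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    return 10.0 * np.exp(-theta[..., :1] * times)


def _disposition_rates(CL, Vc, Vp, Q):
    k10 = CL / Vc
    k12 = Q / Vc
    k21 = Q / Vp
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    # coincident disposition eigenvalues: tiny relative nudge keeps the
    # partial-fraction expansion well defined
    close = np.abs(lam1 - lam2) < 1e-9 * lam1
    lam1 = np.where(close, lam1 * (1.0 + 1e-8), lam1)
    return k21, lam1, lam2


def predict_twocomp_oral(theta: np.ndarray, design: Design) -> np.ndarray:
    """Two-compartment first-order-absorption concentration (mg/L).

    ``theta`` rows are (CL, Vc, Vp, Q, ka); closed-form tri-exponential
    solution of the depot -> central <-> peripheral linear system with
    elimination from the central compartment.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if np.any(theta <= 0):
        raise ValueError("all two-compartment parameters must be strictly positive")
    CL, Vc, Vp, Q, ka = (theta[:, j][:, None] for j in range(5))
    k21, lam1, lam2 = _disposition_rates(CL, Vc, Vp, Q)
    # ka coinciding with a disposition eigenvalue: relative perturbation
    for lam in (lam1, lam2):
        ka = np.where(np.abs(ka - lam) < 1e-9 * np.maximum(ka, lam), ka * (1.0 + 1e-10), ka)
    tau = design.times[None, :] - design.dose_time
    active = tau > 0  # exactly zero at (and before) the dose instant
    tau = np.where(active, tau, 0.0)
    A = (k21 - lam1) / ((ka - lam1) * (lam2 - lam1))
    B = (k21 - lam2) / ((ka - lam2) * (lam1 - lam2))
    C = (k21 - ka) / ((lam1 - ka) * (lam2 - ka))
    conc = (design.dose_amount * ka / Vc) * (
        A * np.exp(-lam1 * tau) + B * np.exp(-lam2 * tau) + C * np.exp(-ka * tau)
    )
    return np.where(active, conc, 0.0)


def predict_transit(theta: np.ndarray, design: Design, n_transit: int = 2) -> np.ndarray:
    """Transit-compartment absorption into two-compartment disposition (mg/L).

    ``theta`` rows are (MTT, CL, Vc, Vp, Q). Drug passes through
    ``n_transit + 1`` sequential first-order steps (the depot is the first)
    of common rate ``ktr = (n_transit + 1) / MTT`` before reaching the central
    compartment, so the input to the central compartment is an
    Erlang(n_transit + 1, ktr) flow. Only ``n_transit = 2`` is supported.
    """
    if n_transit != 2:
        raise NotImplementedError("only a 2-transit-compartment chain is provided")
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if np.any(theta <= 0):
        raise ValueError("all transit-model parameters must be strictly positive")
    MTT, CL, Vc, Vp, Q = (theta[:, j][:, None] for j in range(5))
    ktr = 3.0 / MTT
    k21, lam1, lam2 = _disposition_rates(CL, Vc, Vp, Q)
    for lam in (lam1, lam2):
        ktr = np.where(np.abs(ktr - lam) < 1e-6 * np.maximum(ktr, lam), ktr * (1.0 + 1e-8), ktr)
    tau = design.times[None, :] - design.dose_time
    active = tau > 0  # exactly zero at (and before) the dose instant
    tau = np.where(active, tau, 0.0)

    def _I(lam):
        # int_0^t s^2 exp(-ktr s) exp(-lam (t-s)) ds, closed form
        d = ktr - lam
        dt = d * tau
        return np.exp(-lam * tau) * (2.0 - np.exp(-dt) * (dt * dt + 2.0 * dt + 2.0)) / d**3

    pref = design.dose_amount * ktr**3 / (2.0 * Vc * (lam2 - lam1))
    conc = pref * ((k21 - lam1) * _I(lam1) - (k21 - lam2) * _I(lam2))
    return np.where(active, conc, 0.0)


# ---------------------------------------------------------------------------
# StructuralModel contract and registry
# ---------------------------------------------------------------------------


@dataclass
class StructuralModel:
    """The (f, h, g) triplet plus dimensions.

    ``predict_batch`` maps an (n, n_theta) array of individual parameter
    vectors and a :class:`Design` to an (n, K) prediction matrix; ``predict``
    is the single-subject convenience wrapper. ``residual_kind`` selects h
    and ``param_map_kind`` selects g.
    """

    name: str
    n_theta: int
    v: int
    predict_batch: Callable[[np.ndarray, Design], np.ndarray]
    residual_kind: str = "additive"
    param_map_kind: str = "lognormal"
    param_names: tuple = field(default_factory=tuple)

    def predict(self, theta: np.ndarray, design: Design) -> np.ndarray:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        return self.predict_batch(theta.reshape(1, -1), design)[0]

    def individual_params(self, beta: np.ndarray, b: np.ndarray) -> np.ndarray:
        return param_map_g(beta, b, self.param_map_kind)

    def validate_params(self, params: PopulationParams) -> None:
        if params.beta.size != self.n_theta:
            raise ValueError(
                f"model {self.name!r} expects {self.n_theta} fixed effects, got {params.beta.size}"
            )
        if params.v != self.v:
            raise ValueError(
                f"model {self.name!r} expects {self.v} random effects, got {params.v}"
            )
        if self.residual_kind == "additive" and params.sigma_add2 <= 0:
            raise ValueError("additive residual model requires sigma_add2 > 0")
        if self.residual_kind == "proportional" and params.sigma_prop2 <= 0:
            raise ValueError("proportional residual model requires sigma_prop2 > 0")


_REGISTRY: dict = {}


def register_model(factory: Callable[..., StructuralModel], name: Optional[str] = None) -> None:
    _REGISTRY[name or factory().name] = factory


def get_model(name: str, residual_kind: Optional[str] = None) -> StructuralModel:
    """Look up a built-in model by name, optionally overriding its error model."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {sorted(_REGISTRY)}") from None
    model = factory()
    if residual_kind is not None:
        if residual_kind not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown residual kind: {residual_kind!r}")
        model.residual_kind = residual_kind
    return model


def _wang_factory() -> StructuralModel:
    return StructuralModel(
        name="wang",
        n_theta=1,
        v=1,
        predict_batch=lambda theta, design: predict_wang(theta, design.times),
        residual_kind="additive",
        param_names=("k",),
    )


def _twocomp_factory() -> StructuralModel:
    return StructuralModel(
        name="twocomp_oral",
        n_theta=5,
        v=5,
        predict_batch=predict_twocomp_oral,
        residual_kind="additive",
        param_names=("CL", "Vc", "Vp", "Q", "ka"),
    )


def _transit_factory() -> StructuralModel:
    return StructuralModel(
        name="transit2",
        n_theta=5,
        v=5,
        predict_batch=predict_transit,
        residual_kind="additive",
        param_names=("MTT", "CL", "Vc", "Vp", "Q"),
    )


register_model(_wang_factory, "wang")
register_model(_twocomp_factory, "twocomp_oral")
register_model(_transit_factory, "transit2")
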