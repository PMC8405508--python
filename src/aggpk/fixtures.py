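"""Fixture generators for the built-in case studies.

``case2``
    Two-compartment oral PK: CL 5 L/h, Vc 10 L, Vp 30 L, Q 10 L/h, ka 1/h,
    lognormal IIV with log-SD 0.3 on every parameter, additive residual SD
    0.2 mg/L, 100 mg dose, sampling at 0.1, 0.25, 0.5, 1, 2, 3, 5, 8, 12 h.
    Emits the config plus a simulated dataset of the requested size.
``case4_generator``
    Transit-compartment generating model (MTT 1 h, 2 transit compartments,
    same disposition and residual error as case2, log-SD 0.3 IIV) paired
    with the case2 model as the data-analytic model.
``wang_model``
    Monoexponential decay evaluated at k = 0.5, omega^2 = 0.04,
    sigma^2 = 0.1. Emits model/parameter config only: the published
    10-subject dataset is not redistributed here and must be supplied by the
    user as a CSV (columns ID, TIME, DV).
"""

from __future__ import annotations

from pathlib import Path

from .io import RunConfig, write_config, write_observations_csv
from .simulate import simulate_individuals

__all__ = ["make_fixture", "CASE2_TIMES", "case2_config", "case4_generator_config", "wang_config"]

CASE2_TIMES = [0.1, 0.25, 0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 12.0]


def case2_config(n_subjects: int = 100, seed: int = 0) -> RunConfig:
    return RunConfig(
        model="twocomp_oral",
        residual_kind="additive",
        params={
            "beta": [5.0, 10.0, 30.0, 10.0, 1.0],
            "omega_diag": [0.09] * 5,
            "sigma_add2": 0.04,
        },
        design={
            "times": CASE2_TIMES,
            "dose_amount": 100.0,
            "dose_time": 0.0,
            "n_subjects": n_subjects,
        },
        method="mc_aggregate",
        seed=seed,
    )


def case4_generator_config(n_subjects: int = 100, seed: int = 0) -> RunConfig:
    return RunConfig(
        model="transit2",
        residual_kind="additive",
        params={
            "beta": [1.0, 5.0, 10.0, 30.0, 10.0],
            "omega_diag": [0.09] * 5,
            "sigma_add2": 0.04,
        },
        design={
            "times": CASE2_TIMES,
            "dose_amount": 100.0,
            "dose_time": 0.0,
            "n_subjects": n_subjects,
        },
        method="mc_aggregate",
        seed=seed,
    )


def wang_config(residual_kind: str = "additive", seed: int = 0) -> RunConfig:
    return RunConfig(
        model="wang",
        residual_kind=residual_kind,
        params={
            "beta": [0.5],
            "omega_diag": [0.04],
            "sigma_add2": 0.1 if residual_kind == "additive" else 0.0,
            "sigma_prop2": 0.1 if residual_kind == "proportional" else 0.0,
        },
        design={"times": [0.0], "dose_amount": 0.0, "dose_time": 0.0, "n_subjects": 1},
        method="fo_aggregate",
        seed=seed,
        meta={
            "note": "design times are a placeholder; the observation grid comes "
            "from the user-supplied dataset"
        },
    )


def make_fixture(case: str, seed: int = 0, outdir=".", n_subjects: int = 100) -> RunConfig:
    """Write the named case's config (and simulated data where applicable)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if case == "case2":
        cfg = case2_config(n_subjects=n_subjects, seed=seed)
        model, params, design = cfg.build()
        data = simulate_individuals(model, params, design, seed=seed)
        write_observations_csv(data, outdir / "case2_observations.csv")
        write_config(cfg, outdir / "case2_config.json")
        return cfg
    if case == "case4_generator":
        gen = case4_generator_config(n_subjects=n_subjects, seed=seed)
        ana = case2_config(n_subjects=n_subjects, seed=seed)
        write_config(gen, outdir / "case4_generator_config.json")
        write_config(ana, outdir / "case4_analytic_config.json")
        return gen
    if case == "wang_model":
        cfg = wang_config(seed=seed)
        write_config(cfg, outdir / "wang_config.json")
        return cfg
    raise ValueError(f"unknown fixture case {case!r} (expected wang_model, case2, case4_generator)")
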