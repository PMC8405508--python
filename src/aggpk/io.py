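"""File formats: long-format observation CSV, aggregate-data JSON, run configs.

Observation CSV is a minimal NONMEM-like long format with columns
``ID, TIME, DV`` for observation rows and ``ID, TIME, AMT, EVID=1`` for dose
rows; times in hours, concentrations in mg/L, doses in mg. The aggregate
methods assume a balanced design, so every subject must share the same
sampling grid.

Aggregate JSON:
``{"times": [...], "n_subjects": N, "mean": [...], "cov": [[...]],
"dose_amount": ..., "dose_time": ...}``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .models import Design, PopulationParams, StructuralModel, get_model
from .simulate import AggregateData, IndividualDataset

__all__ = [
    "read_observations_csv",
    "write_observations_csv",
    "read_aggregate_json",
    "write_aggregate_json",
    "RunConfig",
    "read_config",
    "write_config",
]

log = logging.getLogger("aggpk")


def read_observations_csv(path) -> IndividualDataset:
    """Read a balanced long-format observation table (with optional dose rows)."""
    df = pd.read_csv(path)
    df.columns = [c.upper() for c in df.columns]
    for col in ("ID", "TIME"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    if "DV" not in df.columns:
        raise ValueError("missing required column 'DV'")
    evid = df["EVID"] if "EVID" in df.columns else pd.Series(0, index=df.index)
    evid = pd.to_numeric(evid, errors="raise").fillna(0).astype(int)
    doses = df[evid == 1]
    obs = df[evid == 0]
    if obs[["TIME", "DV"]].isna().any().any():
        raise ValueError("non-numeric or missing TIME/DV cells in observation rows")
    obs = obs.astype({"TIME": float, "DV": float})

    ids = list(dict.fromkeys(obs["ID"]))  # first-appearance order
    grids = {i: obs.loc[obs["ID"] == i, "TIME"].to_numpy() for i in ids}
    ref_times = np.sort(grids[ids[0]])
    for i in ids:
        g = np.sort(grids[i])
        if g.size != ref_times.size or not np.allclose(g, ref_times):
            missing = sorted(set(np.round(ref_times, 10)) - set(np.round(g, 10)))
            raise ValueError(
                f"subject {i!r} breaks the balanced grid "
                f"(expected times {ref_times.tolist()}, missing/extra around {missing})"
            )

    dose_amount, dose_time = 0.0, 0.0
    if len(doses):
        if "AMT" not in doses.columns or doses["AMT"].isna().any():
            raise ValueError("dose rows (EVID=1) require a numeric AMT column")
        dose_amount = float(doses["AMT"].iloc[0])
        dose_time = float(doses["TIME"].iloc[0])
    design = Design(
        times=ref_times,
        dose_amount=dose_amount,
        dose_time=dose_time,
        n_subjects=len(ids),
    )
    Y = np.empty((len(ids), ref_times.size))
    for r, i in enumerate(ids):
        sub = obs[obs["ID"] == i].sort_values("TIME")
        Y[r] = sub["DV"].to_numpy()
    return IndividualDataset(Y=Y, design=design, subject_ids=np.asarray(ids))


def write_observations_csv(data: IndividualDataset, path) -> None:
    rows = []
    d = data.design
    for sid, y in zip(data.subject_ids, data.Y):
        if d.dose_amount > 0:
            rows.append({"ID": sid, "TIME": d.dose_time, "DV": np.nan,
                         "AMT": d.dose_amount, "EVID": 1})
        for t, v in zip(d.times, y):
            rows.append({"ID": sid, "TIME": t, "DV": v, "AMT": np.nan, "EVID": 0})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_aggregate_json(path) -> AggregateData:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("times", "n_subjects", "mean", "cov"):
        if key not in doc:
            raise ValueError(f"aggregate JSON missing key {key!r}")
    V = np.asarray(doc["cov"], dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError("cov must be a square matrix")
    scale = max(1.0, float(np.abs(V).max()))
    asym = float(np.abs(V - V.T).max())
    if asym > 1e-8 * scale:
        raise ValueError(f"cov asymmetry {asym:.3e} exceeds tolerance")
    if asym > 0:
        log.info("symmetrizing cov (asymmetry %.3e within tolerance)", asym)
        V = 0.5 * (V + V.T)
    return AggregateData(
        ybar=np.asarray(doc["mean"], dtype=float),
        V=V,
        n_subjects=int(doc["n_subjects"]),
        times=np.asarray(doc["times"], dtype=float),
        dose_amount=float(doc.get("dose_amount", 0.0)),
        dose_time=float(doc.get("dose_time", 0.0)),
    )


def write_aggregate_json(agg: AggregateData, path, approximation: Optional[str] = None) -> None:
    doc = {
        "times": agg.times.tolist() if agg.times is not None else None,
        "n_subjects": agg.n_subjects,
        "mean": agg.ybar.tolist(),
        "cov": agg.V.tolist(),
        "dose_amount": agg.dose_amount,
        "dose_time": agg.dose_time,
    }
    if approximation is not None:
        doc["approximation"] = approximation
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


@dataclass
class RunConfig:
    """Fully-resolved run configuration; serialized next to every result."""

    model: str
    params: dict
    design: dict
    residual_kind: str = "additive"
    method: str = "fo_aggregate"
    n_sim: Optional[int] = None
    seed: int = 0
    estimate_mask: Optional[dict] = None
    meta: dict = field(default_factory=dict)

    def build(self) -> tuple[StructuralModel, PopulationParams, Design]:
        """Validate against the model registry and materialize the objects."""
        model = get_model(self.model, residual_kind=self.residual_kind)
        p = self.params
        omega = np.diag(np.asarray(p["omega_diag"], dtype=float))
        params = PopulationParams(
            beta=np.asarray(p["beta"], dtype=float),
            omega=omega,
            sigma_add2=float(p.get("sigma_add2", 0.0)),
            sigma_prop2=float(p.get("sigma_prop2", 0.0)),
        )
        model.validate_params(params)
        d = self.design
        design = Design(
            times=np.asarray(d["times"], dtype=float),
            dose_amount=float(d.get("dose_amount", 0.0)),
            dose_time=float(d.get("dose_time", 0.0)),
            n_subjects=int(d.get("n_subjects", 1)),
        )
        return model, params, design

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "residual_kind": self.residual_kind,
            "params": self.params,
            "design": self.design,
            "method": self.method,
            "n_sim": self.n_sim,
            "seed": self.seed,
            "estimate_mask": self.estimate_mask,
            "meta": self.meta,
        }


def read_config(path) -> RunConfig:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        return RunConfig(
            model=doc["model"],
            params=doc["params"],
            design=doc["design"],
            residual_kind=doc.get("residual_kind", "additive"),
            method=doc.get("method", "fo_aggregate"),
            n_sim=doc.get("n_sim"),
            seed=int(doc.get("seed", 0)),
            estimate_mask=doc.get("estimate_mask"),
            meta=doc.get("meta", {}),
        )
    except KeyError as exc:
        raise ValueError(f"config {path} missing required key {exc}") from None


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2)
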