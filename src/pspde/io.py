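"""Serialisation: HDF5 snapshots, CSV macroscopic series, YAML model configs,
JSON run manifests."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .grids import GridSpec, PhenotypeDensityField, make_grid
from .models import (
    FitnessSpec,
    ModelSpec,
    MotilitySpec,
    PhenotypeTransitionSpec,
    PressureLaw,
    SignalSpec,
)
from .profiles import Profile

__all__ = [
    "save_field",
    "load_field",
    "macroscopic_to_frame",
    "save_macroscopic_csv",
    "model_to_dict",
    "model_from_dict",
    "save_model_yaml",
    "load_model_yaml",
    "write_manifest",
]


def save_field(path, fld: PhenotypeDensityField) -> None:
    """HDF5 container: datasets /n (nx, ny), /x, /y; attribute t."""
    with h5py.File(path, "w") as f:
        f.create_dataset("n", data=fld.values)
        f.create_dataset("x", data=fld.grid.x_centers)
        f.create_dataset("y", data=fld.grid.y_centers)
        f.attrs["t"] = fld.time
        for k, v in dataclasses.asdict(fld.grid).items():
            f.attrs[f"grid_{k}"] = v


def load_field(path) -> PhenotypeDensityField:
    with h5py.File(path, "r") as f:
        grid = make_grid(
            f.attrs["grid_x_min"], f.attrs["grid_x_max"], int(f.attrs["grid_nx"]),
            f.attrs["grid_y_min"], f.attrs["grid_y_max"], int(f.attrs["grid_ny"]),
        )
        return PhenotypeDensityField(grid, f["n"][...], float(f.attrs["t"]))


def macroscopic_to_frame(grid: GridSpec, macro) -> pd.DataFrame:
    def col(v):
        if v is None:
            return np.full(grid.nx, np.nan)
        return np.ma.filled(np.ma.asarray(v), np.nan)

    return pd.DataFrame(
        {
            "x": grid.x_centers,
            "rho": col(macro.rho),
            "ybar": col(macro.ybar),
            "mean_y": col(macro.mean_y),
            "var_y": col(macro.var_y),
            "S": col(macro.S),
            "P": col(macro.P),
        }
    )


def save_macroscopic_csv(path, grid: GridSpec, macros, times) -> None:
    frames = []
    for t, m in zip(times, macros):
        df = macroscopic_to_frame(grid, m)
        df.insert(0, "t", t)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model config round-trip


def _profile_or_none(v):
    if v is None or isinstance(v, (int, float)):
        return v
    if isinstance(v, Profile):
        return v.to_dict()
    raise TypeError(
        f"cannot serialise {v!r}: use a named Profile (constant/linear/quadratic/"
        "gaussian/tabulated) rather than arbitrary callables in configs"
    )


def model_to_dict(model: ModelSpec) -> dict:
    m = model.motility
    fit = model.fitness
    d = {
        "name": model.name,
        "reaction_scale": model.reaction_scale,
        "motility": {
            "kind": m.kind,
            "D_of_y": _profile_or_none(m.D_of_y),
            "mu_of_y": _profile_or_none(m.mu_of_y),
            "chi_of_y": _profile_or_none(m.chi_of_y),
            "D_const": m.D_const,
        },
        "fitness": {
            "form": fit.form,
            "gamma": fit.gamma,
            "phi": fit.phi,
            "kappa": fit.kappa,
            "r_of_y": _profile_or_none(fit.r_of_y),
            "rho_M": fit.rho_M,
            "P_M": fit.P_M,
            "g_of_S": _profile_or_none(fit.g_of_S),
            "f_of_S": _profile_or_none(fit.f_of_S),
        },
        "transitions": {"Dbar": model.transitions.Dbar, "Abar": model.transitions.Abar},
        "pressure": None
        if model.pressure is None
        else {"form": model.pressure.form, "K": model.pressure.K, "gamma_exp": model.pressure.gamma_exp},
        "signal": None
        if model.signal is None
        else {
            "mode": model.signal.mode,
            "Sigma_of_x": _profile_or_none(model.signal.Sigma_of_x),
            "D_S": model.signal.D_S,
            "production": model.signal.production,
            "uptake": model.signal.uptake,
            "decay": model.signal.decay,
            "S_init": model.signal.S_init,
        },
    }
    return d


def _profile_from(v):
    if v is None or isinstance(v, (int, float)):
        return v
    return Profile.from_dict(v)


def model_from_dict(d: dict) -> ModelSpec:
    m = d["motility"]
    fit = d["fitness"]
    motility = MotilitySpec(
        kind=m["kind"],
        D_of_y=_profile_from(m.get("D_of_y")),
        mu_of_y=_profile_from(m.get("mu_of_y")),
        chi_of_y=_profile_from(m.get("chi_of_y")),
        D_const=m.get("D_const", 0.0),
    )
    fitness = FitnessSpec(
        form=fit["form"],
        gamma=fit.get("gamma", 1.0),
        phi=fit.get("phi", 0.0),
        kappa=fit.get("kappa", 1.0),
        r_of_y=_profile_from(fit.get("r_of_y")),
        rho_M=fit.get("rho_M"),
        P_M=fit.get("P_M"),
        g_of_S=_profile_from(fit.get("g_of_S")),
        f_of_S=_profile_from(fit.get("f_of_S")),
    )
    trans = PhenotypeTransitionSpec(**d.get("transitions", {}))
    pressure = None if d.get("pressure") is None else PressureLaw(**d["pressure"])
    sig = d.get("signal")
    signal = None
    if sig is not None:
        sig = dict(sig)
        sig["Sigma_of_x"] = _profile_from(sig.get("Sigma_of_x"))
        signal = SignalSpec(**sig)
    return ModelSpec(
        motility=motility,
        fitness=fitness,
        transitions=trans,
        pressure=pressure,
        signal=signal,
        reaction_scale=d.get("reaction_scale", 1.0),
        name=d.get("name", ""),
    )


def save_model_yaml(path, model: ModelSpec) -> None:
    Path(path).write_text(yaml.safe_dump(model_to_dict(model), sort_keys=False))


def load_model_yaml(path) -> ModelSpec:
    return model_from_dict(yaml.safe_load(Path(path).read_text()))


def write_manifest(path, **entries) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    Path(path).write_text(json.dumps(entries, indent=2, default=default))
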