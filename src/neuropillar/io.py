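"""HDF5 / CSV serialization of the simulation products."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .hh import APWaveform, HHParams, MembraneSeries
from .pnp import EffectiveSpeciesPair, IonSpecies, MembraneBC, Mesh, PNPField

__all__ = [
    "series_to_csv",
    "waveform_to_csv",
    "save_membrane_series",
    "load_membrane_series",
    "save_waveform",
    "load_waveform",
    "save_pnp_field",
    "load_pnp_field",
    "save_field_maps",
    "membrane_line_csv",
]

_SERIES_KEYS = ("t", "V_m", "m", "h", "n", "j_Na", "j_K", "j_L", "j_stim", "dVdt")
_WAVE_KEYS = ("xi", "V_m", "j_Na", "j_K", "j_L", "dVdt", "I")


def series_to_csv(path, series: MembraneSeries):
    """Flat CSV of the membrane trajectory."""
    df = pd.DataFrame({k: getattr(series, k) for k in _SERIES_KEYS})
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df


def waveform_to_csv(path, wf: APWaveform):
    """Flat CSV of the co-moving waveform (xi in m, I in A)."""
    cols = {k: getattr(wf, k) for k in _WAVE_KEYS if getattr(wf, k) is not None}
    df = pd.DataFrame(cols)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df


def _write_params(grp, params: HHParams):
    for f in dataclasses.fields(params):
        grp.attrs[f.name] = getattr(params, f.name)


def _read_params(grp) -> HHParams:
    return HHParams(**{k: float(v) for k, v in grp.attrs.items()})


def save_membrane_series(path, series: MembraneSeries, mode="a", group="membrane"):
    with h5py.File(path, mode) as fh:
        if group in fh:
            del fh[group]
        grp = fh.create_group(group)
        for key in _SERIES_KEYS:
            grp.create_dataset(key, data=getattr(series, key))
        _write_params(grp.create_group("params"), series.params)


def load_membrane_series(path, group="membrane") -> MembraneSeries:
    with h5py.File(path, "r") as fh:
        grp = fh[group]
        data = {k: grp[k][...] for k in _SERIES_KEYS}
        params = _read_params(grp["params"])
    return MembraneSeries(params=params, **data)


def save_waveform(path, wf: APWaveform, mode="a", group="waveform"):
    with h5py.File(path, mode) as fh:
        if group in fh:
            del fh[group]
        grp = fh.create_group(group)
        for key in _WAVE_KEYS:
            val = getattr(wf, key)
            if val is not None:
                grp.create_dataset(key, data=val)
        grp.attrs["v"] = wf.v
        grp.attrs["a"] = wf.a
        grp.attrs["rho_i"] = wf.rho_i
        _write_params(grp.create_group("params"), wf.params)


def load_waveform(path, group="waveform") -> APWaveform:
    with h5py.File(path, "r") as fh:
        grp = fh[group]
        data = {k: grp[k][...] for k in _WAVE_KEYS if k in grp}
        attrs = dict(grp.attrs)
        params = _read_params(grp["params"])
    return APWaveform(
        v=float(attrs["v"]), a=float(attrs["a"]), rho_i=float(attrs["rho_i"]),
        params=params, **data,
    )


def save_pnp_field(path, field: PNPField, mode="a", group="pnp"):
    """Named datasets V/c_plus/c_minus/r/xi plus a JSON parameter sidecar
    in the group attributes."""
    with h5py.File(path, mode) as fh:
        if group in fh:
            del fh[group]
        grp = fh.create_group(group)
        grp.create_dataset("V", data=field.V)
        grp.create_dataset("c_plus", data=field.c_plus)
        grp.create_dataset("c_minus", data=field.c_minus)
        grp.create_dataset("r", data=field.mesh.r_centers)
        grp.create_dataset("r_faces", data=field.mesh.r_faces)
        grp.create_dataset("xi", data=field.mesh.xi_centers)
        grp.create_dataset("xi_faces", data=field.mesh.xi_faces)
        grp.create_dataset("sigma", data=field.bc.sigma)
        grp.create_dataset("F_plus", data=field.bc.F_plus)
        grp.create_dataset("F_minus", data=field.bc.F_minus)
        grp.attrs["params_json"] = json.dumps(
            {
                "v": field.v,
                "T": field.T,
                "eps": field.eps,
                "iterations": field.iterations,
                "converged": bool(field.converged),
                "residuals": list(map(float, field.residual_history)),
                "cation": dataclasses.asdict(field.ions.cation),
                "anion": dataclasses.asdict(field.ions.anion),
            }
        )


def load_pnp_field(path, group="pnp") -> PNPField:
    with h5py.File(path, "r") as fh:
        grp = fh[group]
        meta = json.loads(grp.attrs["params_json"])
        mesh = Mesh(r_faces=grp["r_faces"][...], xi_faces=grp["xi_faces"][...])
        bc = MembraneBC(
            xi=grp["xi"][...],
            sigma=grp["sigma"][...],
            F_plus=grp["F_plus"][...],
            F_minus=grp["F_minus"][...],
        )
        field = PNPField(
            mesh=mesh,
            V=grp["V"][...],
            c_plus=grp["c_plus"][...],
            c_minus=grp["c_minus"][...],
            ions=EffectiveSpeciesPair(
                cation=IonSpecies(**meta["cation"]),
                anion=IonSpecies(**meta["anion"]),
            ),
            bc=bc,
            v=meta["v"],
            T=meta["T"],
            eps=meta["eps"],
            converged=meta["converged"],
            iterations=meta["iterations"],
            residual_history=meta["residuals"],
        )
    return field


def save_field_maps(path, maps, mode="a", group="fields"):
    with h5py.File(path, mode) as fh:
        if group in fh:
            del fh[group]
        grp = fh.create_group(group)
        for key in ("E_r", "E_xi", "rho", "j_r", "j_xi"):
            grp.create_dataset(key, data=getattr(maps, key))
        if maps.B_phi is not None:
            grp.create_dataset("B_phi", data=maps.B_phi)
            grp.create_dataset("B_membrane", data=maps._B_membrane)
        grp.create_dataset("E_r_membrane", data=maps.E_r_membrane)


def membrane_line_csv(path, maps, I):
    """Summary CSV of membrane-line quantities vs xi."""
    mesh = maps.mesh
    from .fields import membrane_B

    df = pd.DataFrame(
        {
            "xi_m": mesh.xi_centers,
            "sigma_C_per_m2": maps.field.bc.sigma,
            "E_r_mV_per_m": maps.E_r_membrane * 1e3,
            "B_phi_nT": membrane_B(maps, I) * 1e9,
            "I_A": I,
            "V_surface_V": maps.field.V[0, :],
            "c_plus_mol_m3": maps.field.c_plus[0, :],
            "c_minus_mol_m3": maps.field.c_minus[0, :],
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df
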