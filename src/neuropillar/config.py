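"""Run configuration: one YAML file, strict keys, explicit units.

Every block maps onto the corresponding module's parameter dataclass; unknown
keys are rejected rather than ignored, so a typo cannot silently fall back to
a default.  All physical quantities are SI unless the field's docstring says
otherwise (the HH block uses mV/ms as is conventional).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hh import HHParams, StimulusPulse
from .nv import SensitivitySpec
from .pillar import GridSpec, PillarGeometry
from .pnp import (
    DEFAULT_SIGMA_CAPACITANCE,
    AxonGeometry,
    EffectiveSpeciesPair,
    IonSpecies,
    MeshSpec,
    SolverOptions,
)

__all__ = ["RunConfig", "HHBlock", "PNPBlock", "GrowthBlock", "OutputBlock",
           "load_config", "config_to_dict"]


@dataclass(frozen=True)
class HHBlock:
    params: HHParams = field(default_factory=HHParams)
    stimulus: StimulusPulse = field(default_factory=StimulusPulse)
    duration: float = 40.0  # ms
    dt: float = 0.005  # ms
    velocity: float = 0.17  # m/s, conduction velocity (calibrated)
    axon_radius: float = 500e-9  # m
    axoplasm_resistivity: float = 1.0  # Ohm m


@dataclass(frozen=True)
class PNPBlock:
    mesh: MeshSpec = field(default_factory=MeshSpec)
    solver: SolverOptions = field(default_factory=SolverOptions)
    sigma_capacitance: float = DEFAULT_SIGMA_CAPACITANCE  # F/m^2
    temperature: float = 310.0  # K


@dataclass(frozen=True)
class GrowthBlock:
    theta_tol: float = 10.0  # degrees
    chord: float = 8.0  # px
    min_object_px: int = 30
    min_path_px: float = 6.0
    threshold: str | float = "otsu"


@dataclass(frozen=True)
class OutputBlock:
    directory: str = "runs"
    save_plots: bool = True


@dataclass(frozen=True)
class RunConfig:
    hh: HHBlock = field(default_factory=HHBlock)
    ions: EffectiveSpeciesPair = field(default_factory=EffectiveSpeciesPair)
    geometry: AxonGeometry = field(default_factory=AxonGeometry)
    pnp: PNPBlock = field(default_factory=PNPBlock)
    pillar: PillarGeometry = field(default_factory=PillarGeometry)
    pillar_grid: GridSpec = field(default_factory=GridSpec)
    nv: SensitivitySpec = field(default_factory=SensitivitySpec)
    growth: GrowthBlock = field(default_factory=GrowthBlock)
    output: OutputBlock = field(default_factory=OutputBlock)
    seed: int = 0


_NESTED = {
    "params": HHParams,
    "stimulus": StimulusPulse,
    "mesh": MeshSpec,
    "solver": SolverOptions,
    "cation": IonSpecies,
    "anion": IonSpecies,
}


def _build(cls, data, where):
    if not isinstance(data, dict):
        raise TypeError(f"{where}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise KeyError(f"{where}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, val in data.items():
        if key in _NESTED and isinstance(val, dict):
            kwargs[key] = _build(_NESTED[key], val, f"{where}.{key}")
        else:
            kwargs[key] = val
    return cls(**kwargs)


_BLOCKS = {
    "hh": HHBlock,
    "ions": EffectiveSpeciesPair,
    "geometry": AxonGeometry,
    "pnp": PNPBlock,
    "pillar": PillarGeometry,
    "pillar_grid": GridSpec,
    "nv": SensitivitySpec,
    "growth": GrowthBlock,
    "output": OutputBlock,
}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration (all blocks optional; strict keys)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise TypeError("run config must be a mapping of blocks")
    unknown = set(raw) - set(_BLOCKS) - {"seed"}
    if unknown:
        raise KeyError(f"unknown config blocks {sorted(unknown)}")
    kwargs = {}
    for name, cls in _BLOCKS.items():
        if name in raw:
            kwargs[name] = _build(cls, raw[name], name)
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return RunConfig(**kwargs)


def config_to_dict(cfg) -> dict:
    """Recursive plain-dict view of a config (for the run manifest)."""
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        return {
            f.name: config_to_dict(getattr(cfg, f.name))
            for f in dataclasses.fields(cfg)
        }
    if isinstance(cfg, (list, tuple)):
        return [config_to_dict(x) for x in cfg]
    return cfg
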