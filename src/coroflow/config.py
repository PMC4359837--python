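"""Study configuration: one YAML file drives the whole pipeline.

Defaults reproduce the study conditions: blood density 1060 kg/m^3 and
viscosity 0.0035 Pa.s, 0.05 s time steps, the nine-parameter wall
coefficients, 15 brick layers of 0.03 mm at the wall interface.  The
default mesh ``face_size`` is desk-scale (0.3 mm); the final-resolution
range 0.09-0.12 mm is available as ``meshing.DEFAULT_FACE_SIZE``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import yaml

from .flow import BloodProperties
from .fsi import CouplingConfig
from .geometry import VesselSpec
from .wall import MooneyRivlinParams
from .waveforms import WaveformSpec


class ConfigError(ValueError):
    """Invalid configuration; the message lists every violation."""


@dataclass
class StudyConfig:
    vessels: Dict[str, VesselSpec] = field(
        default_factory=lambda: {"default": VesselSpec()})
    inlet_pressure: WaveformSpec = field(default_factory=lambda: WaveformSpec(
        kind="pressure", mean=100.0, pulse_amplitude=40.0))
    outlet_velocity: WaveformSpec = field(
        default_factory=lambda: WaveformSpec(
            kind="velocity", mean=0.2, pulse_amplitude=0.2))
    blood: BloodProperties = field(default_factory=BloodProperties)
    wall_params: MooneyRivlinParams = field(default_factory=MooneyRivlinParams)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    face_size: Union[float, Tuple[float, float]] = 0.3
    wall_face_size: float = 0.3
    n_layers: int = 4
    layer_thickness: float = 0.1
    axial_factor: float = 2.0
    velocity_ratio: float = 1.0
    dt: float = 0.05
    solver_tol: float = 1e-6
    output_dir: str = "out"
    seed: int = 0


_SECTION_TYPES = {
    "vessel": VesselSpec,
    "inlet_pressure": WaveformSpec,
    "outlet_velocity": WaveformSpec,
    "blood": BloodProperties,
    "wall": MooneyRivlinParams,
    "coupling": CouplingConfig,
}

_SCALAR_KEYS = {"face_size", "wall_face_size", "n_layers", "layer_thickness",
                "axial_factor", "velocity_ratio", "dt", "solver_tol",
                "output_dir", "seed"}


def _build_section(cls, data: dict, section: str, errors: list):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    for k in sorted(unknown):
        errors.append(f"{section}: unknown key {k!r}")
    kwargs = {k: v for k, v in data.items() if k in names}
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{section}: {exc}")
        return None


def load_config(path: Optional[str] = None) -> StudyConfig:
    """Load a YAML study config; missing keys take the defaults above.

    Every violation (unknown key, invalid value) is collected and
    reported in a single error.
    """
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    errors: list = []
    cfg = StudyConfig()
    for key in sorted(set(data) - set(_SECTION_TYPES) - _SCALAR_KEYS
                      - {"vessels"}):
        errors.append(f"unknown top-level key {key!r}")

    if "vessel" in data and "vessels" in data:
        errors.append("give either 'vessel' or 'vessels', not both")
    if "vessel" in data:
        v = _build_section(VesselSpec, data["vessel"] or {}, "vessel", errors)
        if v is not None:
            cfg.vessels = {"default": v}
    if "vessels" in data:
        vessels = {}
        for name, sub in (data["vessels"] or {}).items():
            v = _build_section(VesselSpec, sub or {}, f"vessels.{name}",
                               errors)
            if v is not None:
                vessels[name] = v
        cfg.vessels = vessels
    for key, attr in (("inlet_pressure", "inlet_pressure"),
                      ("outlet_velocity", "outlet_velocity"),
                      ("blood", "blood"), ("wall", "wall_params"),
                      ("coupling", "coupling")):
        if key in data:
            obj = _build_section(_SECTION_TYPES[key], data[key] or {}, key,
                                 errors)
            if obj is not None:
                setattr(cfg, attr, obj)
    for key in _SCALAR_KEYS & set(data):
        value = data[key]
        if key == "face_size" and isinstance(value, (list, tuple)):
            value = tuple(float(v) for v in value)
        setattr(cfg, key, value)
    if cfg.dt <= 0:
        errors.append(f"dt must be > 0, got {cfg.dt}")
    if cfg.solver_tol <= 0:
        errors.append(f"solver_tol must be > 0, got {cfg.solver_tol}")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    # waveform kinds are fixed by their role
    cfg.inlet_pressure.kind = "pressure"
    cfg.outlet_velocity.kind = "velocity"
    # derive distinct waveform seeds from the study seed
    cfg.inlet_pressure.seed = (cfg.seed * 2654435761 + 1) % (2**31)
    cfg.outlet_velocity.seed = (cfg.seed * 2654435761 + 2) % (2**31)
    return cfg
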