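"""TOML run configuration: validation, defaults, lossless round-tripping.

A run configuration has four sections — ``[geometry]``, ``[material]``,
``[cycle]``, ``[solver]`` — each key optional (documented defaults apply) and
unknown keys rejected with the offending dotted name.  Temperatures may be
given in kelvin (``*_K``) or Celsius (``*_C``, converted on load); dumped
files always use kelvin, SI units throughout.
"""

from __future__ import annotations

import hashlib
import io
import tomllib
from dataclasses import dataclass, field, fields

import numpy as np

from foamsim.constitutive import MaterialParams
from foamsim.foam_geometry import KelvinCell, build_kelvin_cell, tile_lattice
from foamsim.smp_cycle import CycleProtocol

__all__ = ["GeometryConfig", "SolverConfig", "RunConfig", "load_config",
           "dump_config", "config_hash"]

_CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class GeometryConfig:
    theta_deg: float = 65.92
    L_m: float = 0.58e-3
    r_m: float = 50.44e-6
    torsion_factor: float = 1.0
    nx: int = 1
    ny: int = 1
    nz: int = 1
    jitter_frac: float = 0.0
    seed: int = 0

    def build_cell(self) -> KelvinCell:
        return build_kelvin_cell(self.theta_deg, self.L_m, self.r_m,
                                 self.torsion_factor)

    def build_lattice(self, periodic: bool = False):
        cell = self.build_cell()
        rng = np.random.default_rng(self.seed) if self.jitter_frac else None
        return tile_lattice(cell, self.nx, self.ny, self.nz, periodic=periodic,
                            jitter_frac=self.jitter_frac, rng=rng)


@dataclass(frozen=True)
class SolverConfig:
    direction: str = "x"
    dt_s: float = 0.5
    applied_strain: float = 1e-3    # strain used by linear RVE probes

    def __post_init__(self):
        if self.direction not in ("x", "y", "z"):
            raise ValueError(f"solver.direction must be x, y or z, got {self.direction!r}")
        if self.dt_s <= 0.0:
            raise ValueError("solver.dt_s must be positive")


@dataclass(frozen=True)
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    material: MaterialParams = field(default_factory=MaterialParams)
    cycle: CycleProtocol = field(default_factory=CycleProtocol)
    solver: SolverConfig = field(default_factory=SolverConfig)


# mapping between TOML keys and dataclass field names, per section
_MATERIAL_KEYS = {
    "Tg_K": "Tg", "dThl_K": "dThl", "Eh_Pa": "Eh", "El_Pa": "El",
    "mu_h": "mu_h", "mu_l": "mu_l", "mu_units": "mu_units",
    "lam_h_s": "lam_h", "lam_l_s": "lam_l",
    "alpha_h": "alpha_h", "alpha_l": "alpha_l", "nu_s": "nu_s",
    "maxwell_floor": "maxwell_floor",
}
_CYCLE_KEYS = {
    "Th_K": "Th", "Tl_K": "Tl", "eps_max": "eps_max",
    "strain_rate": "strain_rate", "thermal_rate_K_s": "thermal_rate",
    "unload_time_s": "unload_time", "dwell_after_unload_s": "dwell_after_unload",
}
_POSITIVE_MATERIAL = {"Tg_K", "dThl_K", "Eh_Pa", "El_Pa", "mu_h", "mu_l",
                      "lam_h_s", "lam_l_s"}


def _build_section(section: str, raw: dict, key_map: dict, cls):
    kwargs = {}
    for key, val in raw.items():
        if key not in key_map:
            raise ValueError(f"unknown configuration key {section}.{key}")
        if key in _POSITIVE_MATERIAL and not (isinstance(val, (int, float)) and val > 0):
            raise ValueError(f"configuration key {section}.{key} must be a "
                             f"positive number, got {val!r}")
        kwargs[key_map[key]] = val
    try:
        return cls(**kwargs)
    except ValueError as exc:
        raise ValueError(f"invalid [{section}] configuration: {exc}") from exc


def load_config(path_or_text) -> RunConfig:
    """Load and validate a TOML run configuration (path or literal text)."""
    if hasattr(path_or_text, "read"):
        raw = tomllib.load(path_or_text)
    elif isinstance(path_or_text, str) and ("\n" in path_or_text
                                            or path_or_text.lstrip().startswith("[")):
        raw = tomllib.loads(path_or_text)
    else:
        with open(path_or_text, "rb") as fh:
            raw = tomllib.load(fh)
    known_sections = {"geometry", "material", "cycle", "solver"}
    for sec in raw:
        if sec not in known_sections:
            raise ValueError(f"unknown configuration section [{sec}]")

    cyc_raw = dict(raw.get("cycle", {}))
    for c_key, k_key in (("Th_C", "Th_K"), ("Tl_C", "Tl_K")):
        if c_key in cyc_raw:
            if k_key in cyc_raw:
                raise ValueError(f"configuration gives both cycle.{c_key} and cycle.{k_key}")
            cyc_raw[k_key] = cyc_raw.pop(c_key) + _CELSIUS_OFFSET

    geo_map = {f.name: f.name for f in fields(GeometryConfig)}
    sol_map = {f.name: f.name for f in fields(SolverConfig)}
    geometry = _build_section("geometry", raw.get("geometry", {}), geo_map, GeometryConfig)
    material = _build_section("material", raw.get("material", {}), _MATERIAL_KEYS, MaterialParams)
    cycle = _build_section("cycle", cyc_raw, _CYCLE_KEYS, CycleProtocol)
    solver = _build_section("solver", raw.get("solver", {}), sol_map, SolverConfig)
    return RunConfig(geometry=geometry, material=material, cycle=cycle, solver=solver)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    raise TypeError(f"cannot serialize {v!r} to TOML")


def dump_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig to TOML text (kelvin, SI; lossless round-trip)."""
    out = io.StringIO()
    sections = [
        ("geometry", {f.name: getattr(cfg.geometry, f.name) for f in fields(GeometryConfig)}),
        ("material", {k: getattr(cfg.material, a) for k, a in _MATERIAL_KEYS.items()}),
        ("cycle", {k: getattr(cfg.cycle, a) for k, a in _CYCLE_KEYS.items()}),
        ("solver", {f.name: getattr(cfg.solver, f.name) for f in fields(SolverConfig)}),
    ]
    for name, entries in sections:
        out.write(f"[{name}]\n")
        for key, val in entries.items():
            out.write(f"{key} = {_toml_value(val)}\n")
        out.write("\n")
    return out.getvalue()


def config_hash(cfg: RunConfig) -> str:
    """Stable SHA-256 over the canonical dump (reproducibility manifest)."""
    return hashlib.sha256(dump_config(cfg).encode()).hexdigest()
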