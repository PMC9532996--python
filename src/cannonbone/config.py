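"""Flat key-value configuration files and run configuration.

The config dialect is a flat YAML mapping (``key: value``); nested
structures appear only for morphotype profiles.  Units at the file
interface are mm, g, MPa, N and m/s, documented per key below; material
stresses/moduli are MPa in files and converted to Pa in memory.  Unknown
keys are rejected by name, and every override is type-checked against its
default.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .fea import Material, SimulationConfig
from .morphology import MorphotypeSpec, SectionProfile

__all__ = [
    "RunConfig",
    "load_config",
    "save_spec",
    "load_spec",
    "spec_to_dict",
    "spec_from_dict",
]

log = logging.getLogger(__name__)

#: SimulationConfig keys accepted in config files (units in comments)
_SIM_KEYS = {
    "plate_speed": float,  # m/s
    "plate_travel": float,  # mm
    "initial_gap": float,  # mm
    "inclination": float,  # degrees
    "travel_includes_gap": bool,
    "dwell_time": float,  # s
    "contact_penalty": float,  # N/m
    "mass_damping": float,  # 1/s
    "dt_safety": float,
    "n_circumferential_samples": int,
    "n_output_frames": int,
}

#: Material keys (MPa at the file interface)
_MAT_KEYS = {
    "youngs_modulus_mpa": float,
    "poisson_ratio": float,
    "density_kg_m3": float,
    "ultimate_stress_mpa": float,
}

_TOP_KEYS = {
    "condition": str,
    "fixture_dir": str,
    "output_dir": str,
    "n_elements": int,
    "verbosity": str,
}


@dataclass
class RunConfig:
    """Fully resolved run configuration: defaults merged with file overrides."""

    condition: str = "scaled"
    fixture_dir: str | None = None
    output_dir: str = "results"
    n_elements: int = 100
    verbosity: str = "info"
    material: Material = field(default_factory=Material)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def describe(self) -> str:
        return (
            f"condition={self.condition} n_elements={self.n_elements} "
            f"E={self.material.youngs_modulus/1e6:.0f} MPa "
            f"travel={self.simulation.plate_travel} mm "
            f"speed={self.simulation.plate_speed} m/s"
        )


def _coerce(key: str, value, typ):
    if typ is float and isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if typ is int and isinstance(value, int) and not isinstance(value, bool):
        return value
    if typ is bool and isinstance(value, bool):
        return value
    if typ is str and isinstance(value, str):
        return value
    raise ConfigError(f"config key {key!r}: expected {typ.__name__}, got {value!r}")


def load_config(path) -> RunConfig:
    """Load a run configuration file, merging overrides into the defaults.

    An empty file yields pure defaults.  Any key that is not a documented
    top-level, simulation or material key raises :class:`ConfigError`
    naming the offending key.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    top: dict = {}
    sim: dict = {}
    mat: dict = {}
    for key, value in raw.items():
        if key in _TOP_KEYS:
            top[key] = _coerce(key, value, _TOP_KEYS[key])
        elif key in _SIM_KEYS:
            sim[key] = _coerce(key, value, _SIM_KEYS[key])
        elif key in _MAT_KEYS:
            mat[key] = _coerce(key, value, _MAT_KEYS[key])
        else:
            raise ConfigError(f"unknown config key {key!r} in {path}")

    material = Material(
        youngs_modulus=mat.get("youngs_modulus_mpa", 20e3) * 1e6,
        poisson_ratio=mat.get("poisson_ratio", 0.3),
        density=mat.get("density_kg_m3", 2000.0),
        ultimate_stress=mat.get("ultimate_stress_mpa", 205.0) * 1e6,
    )
    simulation = SimulationConfig(**sim)
    cfg = RunConfig(material=material, simulation=simulation, **top)
    if cfg.condition not in ("unscaled", "scaled"):
        raise ConfigError(f"condition must be 'unscaled' or 'scaled', not {cfg.condition!r}")
    log.info("loaded config %s: %s", path, cfg.describe())
    return cfg


# ---------------------------------------------------------------------------
# morphotype serialization (mm / g units, documented field names)
# ---------------------------------------------------------------------------


def spec_to_dict(spec: MorphotypeSpec) -> dict:
    return {
        "name": spec.name,
        "fusion": spec.fusion,
        "length_mm": spec.length,
        "ray_spacing_mm": spec.ray_spacing,
        "column_stations": list(spec.column_stations),
        "column_radius_mm": spec.column_radius,
        "limb_measurements_mm": list(spec.limb_measurements),
        "body_mass_g": spec.body_mass,
        "segment_fractions": list(spec.segment_fractions),
        "profiles": [
            {
                "axial_stations": list(p.axial_stations),
                "outer_radius_mm": list(p.outer_radius),
                "cortical_thickness_mm": list(p.cortical_thickness),
            }
            for p in spec.profiles
        ],
    }


_SPEC_KEYS = {
    "name", "fusion", "length_mm", "ray_spacing_mm", "column_stations",
    "column_radius_mm", "limb_measurements_mm", "body_mass_g",
    "segment_fractions", "profiles",
}


def spec_from_dict(data: dict) -> MorphotypeSpec:
    unknown = set(data) - _SPEC_KEYS
    if unknown:
        raise ConfigError(f"unknown morphotype keys: {sorted(unknown)}")
    try:
        profiles = tuple(
            SectionProfile(
                axial_stations=tuple(p["axial_stations"]),
                outer_radius=tuple(p["outer_radius_mm"]),
                cortical_thickness=tuple(p["cortical_thickness_mm"]),
            )
            for p in data["profiles"]
        )
        return MorphotypeSpec(
            name=data["name"],
            fusion=data["fusion"],
            length=data["length_mm"],
            profiles=profiles,
            limb_measurements=tuple(data["limb_measurements_mm"]),
            body_mass=data["body_mass_g"],
            ray_spacing=data.get("ray_spacing_mm", 0.0),
            column_stations=tuple(data.get("column_stations") or ()),
            column_radius=data.get("column_radius_mm"),
            segment_fractions=tuple(
                data.get("segment_fractions", (0.10, 0.15, 0.60, 0.15))
            ),
        )
    except KeyError as exc:
        raise ConfigError(f"morphotype file missing key {exc.args[0]!r}") from exc


def save_spec(spec: MorphotypeSpec, path) -> None:
    """Write a morphotype to a flat YAML file (mm/g units)."""
    Path(path).write_text(
        yaml.safe_dump(spec_to_dict(spec), sort_keys=True, default_flow_style=None)
    )


def load_spec(path) -> MorphotypeSpec:
    """Load a morphotype written by :func:`save_spec` (round-trip exact)."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    return spec_from_dict(data)
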