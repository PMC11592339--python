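"""YAML run configuration: geometry, electrode, materials, gradients,
Greenwood constants and the stapes drive table.

A configuration file may override any subset of fields; unspecified values
fall back to the package defaults. ``default_config_yaml()`` emits a fully
commented template, flagging which defaults are literature stand-ins.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .geometry import ElectrodeSpec, GeometryParams
from .greenwood import GreenwoodParams
from .materials import BMGradient, MaterialTable
from .solver import StapesDriveTable

__all__ = ["RunConfig", "load_config", "save_gradient_fragment", "default_config_yaml"]


@dataclass(frozen=True)
class RunConfig:
    geometry: GeometryParams = field(default_factory=GeometryParams)
    electrode: ElectrodeSpec = field(default_factory=ElectrodeSpec)
    materials: MaterialTable = field(default_factory=MaterialTable)
    gradient: BMGradient = field(default_factory=BMGradient)
    greenwood: GreenwoodParams = field(default_factory=GreenwoodParams)
    drive: StapesDriveTable = field(default_factory=StapesDriveTable.default)


_SECTION_TYPES = {
    "geometry": GeometryParams,
    "electrode": ElectrodeSpec,
    "materials": MaterialTable,
    "gradient": BMGradient,
    "greenwood": GreenwoodParams,
}


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}"
        )
    return cls(**data)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; ``None`` returns the defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")
    unknown = set(raw) - set(_SECTION_TYPES) - {"drive"}
    if unknown:
        raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            kwargs[section] = _build_section(cls, raw[section] or {}, section)
    if "drive" in raw:
        rows = raw["drive"]
        try:
            kwargs["drive"] = StapesDriveTable.from_rows(np.asarray(rows, dtype=float))
        except (TypeError, ValueError, IndexError) as exc:
            raise ConfigurationError(
                "drive must be a list of [frequency_hz, amplitude_nm, phase_deg] rows"
            ) from exc
    return RunConfig(**kwargs)


def save_gradient_fragment(grad: BMGradient, path: str | Path) -> None:
    """Write a fitted gradient as a config fragment mergeable under the
    ``gradient:`` section."""
    data = {"gradient": {k: float(v) for k, v in dataclasses.asdict(grad).items()}}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def default_config_yaml() -> str:
    """Fully commented default configuration template."""
    return """\
# rhesusear run configuration (defaults shown; delete what you don't override)

geometry:
  bm_length: 27.0          # mm, rhesus basilar-membrane length
  n_sections: 82           # longitudinal sections
  bm_width_base: 0.1       # mm; width increases base->apex
  bm_width_apex: 0.3
  bm_thickness_base: 0.01  # mm
  bm_thickness_apex: 0.005
  area_sv_base: 1.0        # mm^2  (stand-in: no rhesus scala morphometry)
  area_sv_apex: 0.3        # stand-in
  area_st_base: 1.0        # stand-in
  area_st_apex: 0.3        # stand-in
  ow_area: 0.8             # mm^2, oval window (stand-in)
  rw_area: 0.6             # mm^2, round window (stand-in)
  helicotrema_area: 0.2    # mm^2 (stand-in)
  vestibular_branch: null  # optional lumped compliance, m^3/Pa (off)

electrode:
  insertion_depth: 12.0    # mm from the round window (assumed scaling)
  diameter_base: 0.5       # mm (assumed scaling of a human lateral-wall array)
  diameter_tip: 0.25       # mm
  material_ref: electrode

materials:
  bm_density: 1200.0         # kg/m^3
  wall_modulus: 1.0e+7        # Pa, membranous labyrinth (stand-in)
  wall_damping: 1.0e-04      # stiffness-proportional, bone-damped wall (stand-in)
  wall_thickness: 0.2        # mm, wall + elastic support (stand-in)
  rwm_modulus: 3.5e+5         # Pa, round-window membrane (stand-in)
  rwm_density: 1200.0
  rwm_thickness: 0.05        # mm, macaque membrane (stand-in)
  rwm_damping: 1.0e-04       # stiffness-proportional membrane damping (stand-in)
  ow_modulus: 3.5e+5          # assumed equal to the round window
  ligament_modulus: 2.0e+5    # Pa, annular ligament (stand-in)
  electrode_modulus: 3.0e+6   # Pa, medical-grade silicone (stand-in)
  fluid_density: 1000.0      # kg/m^3, perilymph ~ water
  fluid_bulk_modulus: 2.2e+9  # Pa
  rwm_stiffening_factor: 1.0 # set by the scenario, not here
  poisson_ratio: 0.49

gradient:                  # basilar-membrane property gradients
  E0_log10: 5.7            # E(x) = 10^E0_log10 * exp(-E_decay * x) Pa
  E_decay: 0.19            # 1/mm
  beta0_log10: -5.91       # beta(x) = 10^beta0_log10 * exp(beta_growth * x)
  beta_growth: 0.1         # 1/mm
  k_geom: 5.333333333333333  # clamped-strip plate constant (calibratable)

greenwood:
  A: 395.0                 # Hz-scale species constant
  a: 2.0
  k: 1.0
  bm_length: 27.0          # mm, must match geometry

drive:                     # stapes rows: [frequency Hz, amplitude nm, phase deg]
  - [1000.0, 8.00, -300.0]
  - [2000.0, 2.00, -380.0]
  - [4000.0, 0.35, -470.0]
  - [6000.0, 0.10, -510.0]
  - [8000.0, 0.09, -585.0]
  - [10000.0, 0.05, -650.0]
"""
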