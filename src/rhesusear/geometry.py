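"""Parametric uncoiled cochlear geometry.

The cochlea is represented as a straight two-chamber "box": scala vestibuli
above and scala tympani below a basilar membrane (BM) of length 27 mm,
discretized into 82 longitudinal sections. All per-section quantities are
evaluated at section midpoints, with x = 0 at the base (oval/round windows)
increasing toward the apex (helicotrema). Reissner's membrane is treated as
acoustically transparent, so the scala media is not resolved as a third
chamber — the standard passive-model simplification.

Cross-sectional area profiles, window areas and the helicotrema area are
literature stand-ins (no rhesus morphometry is available for them); they are
all exposed in the configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GeometryError

__all__ = [
    "GeometryParams",
    "CochlearGeometry",
    "ElectrodeSpec",
    "build_geometry",
    "apply_electrode",
]

#: Minimum number of longitudinal sections for a meaningful discretization.
MIN_SECTIONS = 8


@dataclass(frozen=True)
class GeometryParams:
    """Configuration of the parametric cochlear box model.

    Lengths in mm, areas in mm². Width/thickness/area profiles taper
    linearly between their base and apex values. BM width must increase
    base→apex; the duct areas and BM thickness decrease.
    """

    bm_length: float = 27.0          # mm, rhesus BM length
    n_sections: int = 82             # longitudinal sections
    bm_width_base: float = 0.1       # mm
    bm_width_apex: float = 0.3       # mm
    bm_thickness_base: float = 0.01  # mm
    bm_thickness_apex: float = 0.005 # mm
    area_sv_base: float = 1.0        # mm², scala vestibuli (stand-in)
    area_sv_apex: float = 0.3        # mm²
    area_st_base: float = 1.0        # mm², scala tympani (stand-in)
    area_st_apex: float = 0.3        # mm²
    ow_area: float = 0.8             # mm², oval window (stand-in)
    rw_area: float = 0.6             # mm², round window (stand-in)
    helicotrema_area: float = 0.2    # mm² (stand-in)
    #: optional lumped vestibular/semicircular-canal compliance, m³/Pa
    vestibular_branch: float | None = None


@dataclass(frozen=True)
class CochlearGeometry:
    """Discretized two-chamber cochlear domain.

    Per-section arrays are aligned on section midpoints ``x_base_mm``
    (mm from the base). Areas in mm², lengths in mm.
    """

    bm_length: float
    x_base_mm: np.ndarray
    bm_width: np.ndarray
    bm_thickness: np.ndarray
    area_sv: np.ndarray
    area_st: np.ndarray
    ow_area: float
    rw_area: float
    helicotrema_area: float
    vestibular_branch: float | None = None
    #: per-section scala-tympani area occupied by an electrode (mm²);
    #: zero when unimplanted. area_st excludes it; the anatomical duct
    #: bounded by the elastic wall is area_st + occlusion_st.
    occlusion_st: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.x_base_mm)
        if self.bm_length <= 0:
            raise GeometryError("bm_length must be positive")
        for name in ("bm_width", "bm_thickness", "area_sv", "area_st"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise GeometryError(f"{name} length {len(arr)} != n_sections {n}")
            if np.any(arr <= 0):
                raise GeometryError(f"{name} must be strictly positive everywhere")
        if np.any(np.diff(self.bm_width) <= 0):
            raise GeometryError("bm_width must strictly increase base→apex")
        if np.any(np.diff(self.x_base_mm) <= 0):
            raise GeometryError("x_base_mm must be strictly increasing")
        if self.x_base_mm[0] <= 0 or self.x_base_mm[-1] >= self.bm_length:
            raise GeometryError("section midpoints must lie strictly inside (0, bm_length)")
        for name in ("ow_area", "rw_area", "helicotrema_area"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.occlusion_st is not None:
            if len(self.occlusion_st) != n:
                raise GeometryError("occlusion_st misaligned with sections")
            if np.any(self.occlusion_st < 0):
                raise GeometryError("occlusion_st cannot be negative")

    @property
    def n_sections(self) -> int:
        return len(self.x_base_mm)

    @property
    def dx_mm(self) -> float:
        """Uniform section length, mm."""
        return self.bm_length / self.n_sections

    @property
    def duct_area_st(self) -> np.ndarray:
        """Anatomical scala-tympani area (mm²) bounded by the elastic
        wall, i.e. the flow area plus any electrode occlusion."""
        if self.occlusion_st is None:
            return self.area_st
        return self.area_st + self.occlusion_st

    def to_frame(self) -> pd.DataFrame:
        """Per-section table (the human-readable export of the domain)."""
        return pd.DataFrame(
            {
                "x_base_mm": self.x_base_mm,
                "bm_width_mm": self.bm_width,
                "bm_thickness_mm": self.bm_thickness,
                "area_sv_mm2": self.area_sv,
                "area_st_mm2": self.area_st,
            }
        )


@dataclass(frozen=True)
class ElectrodeSpec:
    """Cochlear-implant electrode inserted through the round window along
    the scala tympani.

    The carrier is a linearly tapered silicone cylinder occupying the
    scala tympani from the base (x = 0) to ``insertion_depth``. Dimensions
    are a scaled-down lateral-wall array (human FLEX24-like, reduced for the
    macaque cochlea); the scaling is an assumption, exposed in config.
    """

    insertion_depth: float = 12.0   # mm from the round window
    diameter_base: float = 0.5      # mm at x = 0
    diameter_tip: float = 0.25      # mm at the insertion depth
    material_ref: str = "electrode"

    def __post_init__(self) -> None:
        if self.insertion_depth < 0:
            raise ConfigurationError("insertion_depth must be non-negative")
        if self.diameter_base < 0 or self.diameter_tip < 0:
            raise ConfigurationError("electrode diameters must be non-negative")

    def diameter_at(self, x_mm: np.ndarray) -> np.ndarray:
        """Local carrier diameter (mm); zero beyond the tip."""
        x = np.asarray(x_mm, dtype=float)
        if self.insertion_depth == 0:
            return np.zeros_like(x)
        frac = np.clip(x / self.insertion_depth, 0.0, 1.0)
        d = self.diameter_base + (self.diameter_tip - self.diameter_base) * frac
        return np.where(x <= self.insertion_depth, d, 0.0)

    def volume_mm3(self) -> float:
        """Exact carrier volume (truncated cone)."""
        rb = self.diameter_base / 2.0
        rt = self.diameter_tip / 2.0
        return math.pi * self.insertion_depth / 3.0 * (rb * rb + rb * rt + rt * rt)


def _taper(base: float, apex: float, x_mm: np.ndarray, length: float) -> np.ndarray:
    return base + (apex - base) * (x_mm / length)


def build_geometry(params: GeometryParams | None = None) -> CochlearGeometry:
    """Construct the discretized two-chamber domain from its parameters.

    Section midpoints are ``(i + 1/2)·L/n`` so rescaling ``bm_length`` by a
    factor rescales every coordinate by exactly that factor while profile
    shapes (functions of x/L) are unchanged.
    """
    if params is None:
        params = GeometryParams()
    for name in (
        "bm_length", "bm_width_base", "bm_width_apex", "bm_thickness_base",
        "bm_thickness_apex", "area_sv_base", "area_sv_apex", "area_st_base",
        "area_st_apex", "ow_area", "rw_area", "helicotrema_area",
    ):
        if getattr(params, name) <= 0:
            raise ConfigurationError(f"geometry parameter {name!r} must be positive")
    if params.n_sections < MIN_SECTIONS:
        raise ConfigurationError(
            f"n_sections must be >= {MIN_SECTIONS}, got {params.n_sections}"
        )
    if params.bm_width_apex <= params.bm_width_base:
        raise ConfigurationError("bm_width_apex must exceed bm_width_base")
    if params.vestibular_branch is not None and params.vestibular_branch <= 0:
        raise ConfigurationError("vestibular_branch compliance must be positive")

    L, n = params.bm_length, params.n_sections
    x = (np.arange(n) + 0.5) * (L / n)
    return CochlearGeometry(
        bm_length=L,
        x_base_mm=x,
        bm_width=_taper(params.bm_width_base, params.bm_width_apex, x, L),
        bm_thickness=_taper(params.bm_thickness_base, params.bm_thickness_apex, x, L),
        area_sv=_taper(params.area_sv_base, params.area_sv_apex, x, L),
        area_st=_taper(params.area_st_base, params.area_st_apex, x, L),
        ow_area=params.ow_area,
        rw_area=params.rw_area,
        helicotrema_area=params.helicotrema_area,
        vestibular_branch=params.vestibular_branch,
    )


def electrode_occlusion_area(
    geom: CochlearGeometry, spec: ElectrodeSpec
) -> np.ndarray:
    """Per-section scala-tympani area (mm²) occupied by the electrode.

    The midpoint cross-section π(d/2)² is weighted by the fraction of the
    section that overlaps [0, insertion_depth], so the summed occluded
    volume matches the exact cone volume to midpoint-rule accuracy and the
    occlusion is exactly zero for sections entirely beyond the tip.
    """
    dx = geom.dx_mm
    lo = geom.x_base_mm - dx / 2.0
    hi = geom.x_base_mm + dx / 2.0
    overlap = np.clip(np.minimum(hi, spec.insertion_depth) - lo, 0.0, dx) / dx
    x_eval = np.minimum(geom.x_base_mm, spec.insertion_depth)
    d = spec.diameter_at(x_eval)
    return math.pi * (d / 2.0) ** 2 * overlap


def apply_electrode(geom: CochlearGeometry, spec: ElectrodeSpec) -> CochlearGeometry:
    """Return a geometry whose scala-tympani areas are reduced by the
    electrode's cross-section; the scala vestibuli is untouched."""
    if spec.insertion_depth > geom.bm_length:
        raise GeometryError(
            f"insertion_depth {spec.insertion_depth} mm exceeds BM length "
            f"{geom.bm_length} mm"
        )
    occ = electrode_occlusion_area(geom, spec)
    frac = occ / geom.area_st
    if np.any(frac >= 1.0):
        i = int(np.argmax(frac >= 1.0))
        raise GeometryError(
            f"electrode occludes the whole scala tympani at section {i} "
            f"(x = {geom.x_base_mm[i]:.2f} mm); reduce its diameter"
        )
    prior = geom.occlusion_st if geom.occlusion_st is not None else 0.0
    return replace(geom, area_st=geom.area_st - occ, occlusion_st=prior + occ)
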