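"""Material constants and basilar-membrane property gradients.

The basilar membrane's elastic modulus decays and its damping coefficient
grows exponentially with distance from the base::

    E(x)    = 10^5.7   · exp(-0.19 x)   [Pa]
    beta(x) = 10^-5.91 · exp( 0.1  x)   [unitless, stiffness-proportional]

with x in mm from the base. These gradients are what give the membrane its
tonotopy; their four coefficients (plus the plate-conversion constant
``k_geom``) are the quantities adjusted during phenomenological calibration.

Damping is stiffness-proportional (Rayleigh beta); mass-proportional
damping is zero. The remaining constants (fluids, windows, ligament,
electrode silicone, labyrinth wall) are literature stand-ins for soft
tissue and perilymph, each exposed in the configuration file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, DomainError, GeometryError
from .geometry import CochlearGeometry

__all__ = [
    "BMGradient",
    "MaterialTable",
    "SCENARIOS",
    "bm_elastic_modulus",
    "bm_damping_coefficient",
    "bm_point_impedance",
    "scenario_table",
]

#: Valid scenario labels: no implant; electrode in the scala tympani;
#: electrode plus a ten-fold stiffened round-window membrane (scarring).
SCENARIOS = ("healthy", "implanted", "implanted_stiffened")

#: Round-window stiffening multiplier applied in the scarred scenario.
RWM_STIFFENING = 10.0


@dataclass(frozen=True)
class BMGradient:
    """Coefficients of the longitudinal BM property gradients.

    ``E(x) = 10^E0_log10 · exp(-E_decay · x)`` (Pa) and
    ``beta(x) = 10^beta0_log10 · exp(beta_growth · x)`` with x in mm from
    the base. ``k_geom`` converts the modulus into an areal plate stiffness
    ``s(x) = k_geom · E(x) · t(x)³ / w(x)⁴`` (clamped-strip formula); only
    the product ``k_geom · 10^E0_log10`` is observable in the solution, so
    calibration treats k_geom as an absorbable scale.
    """

    E0_log10: float = 5.7
    E_decay: float = 0.19       # 1/mm
    beta0_log10: float = -5.91
    beta_growth: float = 0.1    # 1/mm
    k_geom: float = 16.0 / 3.0  # clamped-strip plate constant

    def __post_init__(self) -> None:
        if self.E_decay <= 0:
            raise ConfigurationError("E_decay must be positive (modulus decays base→apex)")
        if self.beta_growth <= 0:
            raise ConfigurationError("beta_growth must be positive (damping grows base→apex)")
        if self.k_geom <= 0:
            raise ConfigurationError("k_geom must be positive")


@dataclass(frozen=True)
class MaterialTable:
    """Every material constant of the model, SI units unless noted.

    Values marked "stand-in" are literature-typical soft-tissue / perilymph
    numbers, not species-specific measurements.
    """

    bm_density: float = 1200.0          # kg/m³
    wall_modulus: float = 10.0e6        # Pa, membranous labyrinth (stand-in)
    wall_damping: float = 1e-4          # unitless, stiffness-proportional;
                                        # the bony support damps the elastic wall
    wall_thickness: float = 0.2         # mm, membranous wall + support (stand-in)
    rwm_modulus: float = 0.35e6         # Pa, round window membrane (stand-in)
    rwm_density: float = 1200.0         # kg/m³
    rwm_thickness: float = 0.05         # mm (macaque membrane, thinner than
                                        # the ~0.07 mm human figure; stand-in)
    rwm_damping: float = 1e-4           # unitless, stiffness-proportional (stand-in)
    ow_modulus: float = 0.35e6          # Pa, assumed equal to the RWM
    ligament_modulus: float = 0.2e6     # Pa, stapedial annular ligament (stand-in)
    electrode_modulus: float = 3.0e6    # Pa, medical-grade silicone (stand-in)
    fluid_density: float = 1000.0       # kg/m³, perilymph ≈ water
    fluid_bulk_modulus: float = 2.2e9   # Pa, water-like
    rwm_stiffening_factor: float = 1.0  # ×10 models post-implantation scarring
    poisson_ratio: float = 0.49         # soft tissue, near-incompressible

    def __post_init__(self) -> None:
        positive = (
            "bm_density", "wall_modulus", "wall_thickness", "rwm_modulus",
            "rwm_density", "rwm_thickness", "ow_modulus", "ligament_modulus",
            "electrode_modulus", "fluid_density", "fluid_bulk_modulus",
        )
        if self.wall_damping < 0 or self.rwm_damping < 0:
            raise ConfigurationError("damping coefficients must be non-negative")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"material {name!r} must be positive")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise ConfigurationError("poisson_ratio must lie in (0, 0.5)")
        if self.rwm_stiffening_factor < 1.0:
            raise ConfigurationError("rwm_stiffening_factor must be >= 1")

    @property
    def effective_rwm_modulus(self) -> float:
        """Round-window modulus including the scenario stiffening factor."""
        return self.rwm_modulus * self.rwm_stiffening_factor


def _check_x(x, bm_length: float | None) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("x must be >= 0 (mm from the base)")
    if bm_length is not None and np.any(x > bm_length):
        raise DomainError(f"x exceeds the BM length {bm_length} mm")
    return x


def bm_elastic_modulus(x, g: BMGradient, bm_length: float | None = None):
    """BM elastic modulus E(x) in Pa at x mm from the base.

    Strictly decreasing in x. Accepts scalars or arrays.
    """
    x = _check_x(x, bm_length)
    return 10.0 ** g.E0_log10 * np.exp(-g.E_decay * x)


def bm_damping_coefficient(x, g: BMGradient, bm_length: float | None = None):
    """BM stiffness-proportional damping coefficient beta(x) (unitless).

    Strictly increasing in x.
    """
    x = _check_x(x, bm_length)
    return 10.0 ** g.beta0_log10 * np.exp(g.beta_growth * x)


def bm_areal_stiffness(x_mm, geom: CochlearGeometry, g: BMGradient):
    """Areal stiffness s(x) = k_geom·E(x)·t³/w⁴ in N/m³ at the section
    midpoints nearest ``x_mm`` (t, w interpolated from the geometry)."""
    x = np.asarray(x_mm, dtype=float)
    t = np.interp(x, geom.x_base_mm, geom.bm_thickness) * 1e-3  # m
    w = np.interp(x, geom.x_base_mm, geom.bm_width) * 1e-3      # m
    if np.any(t <= 0) or np.any(w <= 0):
        raise GeometryError("BM width/thickness must be positive")
    E = bm_elastic_modulus(x, g, geom.bm_length)
    return g.k_geom * E * t**3 / w**4


def bm_point_impedance(
    x_mm,
    omega: float,
    geom: CochlearGeometry,
    table: MaterialTable,
    g: BMGradient,
):
    """Locally reacting acoustic point impedance of the BM, Pa·s/m.

    Z(x, ω) = iω·m(x) + s(x)·(1 + iω·beta(x)) / (iω) with areal mass
    m(x) = bm_density·t(x) and areal stiffness from the clamped-strip
    conversion. The real part s·beta is the only dissipative term
    (stiffness-proportional damping).
    """
    if omega <= 0:
        raise DomainError("omega must be positive")
    x = np.asarray(x_mm, dtype=float)
    t = np.interp(x, geom.x_base_mm, geom.bm_thickness) * 1e-3
    m = table.bm_density * t
    s = bm_areal_stiffness(x, geom, g)
    beta = bm_damping_coefficient(x, g, geom.bm_length)
    return 1j * omega * m + s * (1.0 + 1j * omega * beta) / (1j * omega)


def bm_resonance_omega(x_mm, geom: CochlearGeometry, table: MaterialTable, g: BMGradient):
    """Undamped local resonance ω_r(x) = sqrt(s/m), rad/s."""
    x = np.asarray(x_mm, dtype=float)
    t = np.interp(x, geom.x_base_mm, geom.bm_thickness) * 1e-3
    m = table.bm_density * t
    s = bm_areal_stiffness(x, geom, g)
    return np.sqrt(s / m)


def _plate_compliance(area_mm2: float, modulus: float, thickness_mm: float,
                      poisson: float) -> float:
    """Volume compliance (m³/Pa) of a clamped circular plate of the given
    area: V/P = π a⁶ / (192 D), D = E t³ / (12 (1 − ν²))."""
    a = math.sqrt(area_mm2 * 1e-6 / math.pi)  # m
    t = thickness_mm * 1e-3                   # m
    D = modulus * t**3 / (12.0 * (1.0 - poisson**2))
    return math.pi * a**6 / (192.0 * D)


def rw_acoustic_compliance(geom: CochlearGeometry, table: MaterialTable) -> float:
    """Acoustic compliance of the round-window membrane, m³/Pa.

    Linear in 1/E, so the scenario stiffening factor divides the
    compliance exactly.
    """
    return _plate_compliance(
        geom.rw_area, table.effective_rwm_modulus,
        table.rwm_thickness, table.poisson_ratio,
    )


#: Width of the stapedial annular-ligament ring, mm. Literature values for
#: primates are of order 0.1 mm; fixed here (not a tuning dial).
LIGAMENT_RING_WIDTH_MM = 0.1


def ow_acoustic_compliance(geom: CochlearGeometry, table: MaterialTable) -> float:
    """Acoustic compliance of the oval-window input port, m³/Pa.

    The stapes footplate covers the oval window, so the compliant element
    at the input is the stapedial annular ligament: a ring of width b and
    thickness t around the footplate perimeter P, giving a piston stiffness
    k = E_lig·t·P/b (a few hundred N/m, consistent with measured annular
    ligament stiffnesses) and volume compliance C = A_ow²/k.

    The stapes is a displacement source acting *through* this compliance:
    intracochlear pressure bulges the ligament back, so the volume velocity
    entering the scala vestibuli is iω(u_stapes·A_ow − C_ow·p_v). A
    perfectly rigid input port would make every series termination
    (including the round window) invisible to the membrane.
    """
    A_ow = geom.ow_area * 1e-6                       # m²
    a = math.sqrt(A_ow / math.pi)                    # footplate radius, m
    perimeter = 2.0 * math.pi * a
    b = LIGAMENT_RING_WIDTH_MM * 1e-3
    t = table.rwm_thickness * 1e-3
    k = table.ligament_modulus * t * perimeter / b   # N/m
    return A_ow**2 / k


def wall_compliance_per_length(area_mm2, table: MaterialTable):
    """Volume compliance per unit length (m²/Pa) of a fluid duct bounded by
    the elastic membranous-labyrinth wall.

    Thin-walled tube distensibility dA/dp = 2π r³/(E h) with duct radius
    r = sqrt(A/π), wall modulus E and wall thickness h. This distributed
    shunt is what lets a boundary-impedance change (e.g. round-window
    stiffening) reshape, not merely rescale, the interior pressure field.
    """
    r = np.sqrt(np.asarray(area_mm2, dtype=float) * 1e-6 / math.pi)  # m
    h = table.wall_thickness * 1e-3
    return 2.0 * math.pi * r**3 / (table.wall_modulus * h)


def scenario_table(base: MaterialTable, scenario: str) -> MaterialTable:
    """Material table for a named scenario.

    ``healthy`` and ``implanted`` leave the table unchanged (the electrode
    is a geometric occupant, handled by the geometry module);
    ``implanted_stiffened`` multiplies the round-window modulus tenfold via
    the stiffening factor.
    """
    if scenario not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; expected one of {SCENARIOS}"
        )
    factor = RWM_STIFFENING if scenario == "implanted_stiffened" else 1.0
    return replace(base, rwm_stiffening_factor=factor)
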