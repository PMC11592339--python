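"""Harmonic two-duct transmission-line solver.

The cochlea is a pair of fluid ducts (scala vestibuli, scala tympani)
coupled section-by-section through the locally reacting basilar-membrane
impedance, shunted at the apex by the helicotrema and terminated basally by
the stapes-driven oval window (prescribed volume velocity) and the
compliant round window. The perilymph is treated as incompressible within
the ducts (long-wavelength limit); compressibility enters only through the
window and optional vestibular compliances.

Per drive frequency the model is a sparse complex linear system with three
unknowns per section — scala-vestibuli pressure p_v,i, scala-tympani
pressure p_t,i and BM displacement u_i — plus one unknown if the lumped
vestibular branch is enabled:

* duct continuity (finite volume): face flows q = A_f/(iωρΔx)·Δp balance
  the BM volume velocity ±iω·u_i·w_i·Δx in each cell;
* BM relation: p_v,i − p_t,i = Z(x_i, ω)·iω·u_i;
* base: oval-window volume velocity iω·u_stapes·A_ow into the scala
  vestibuli; round-window compliance C_rw draining the scala tympani;
* apex: helicotrema duct of area A_h shunting the pressure difference.

Everything is deterministic; the system is assembled in SI units from the
mm/nm/degree configuration values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigurationError, SolverError
from .geometry import CochlearGeometry
from .materials import (
    BMGradient,
    MaterialTable,
    bm_point_impedance,
    ow_acoustic_compliance,
    rw_acoustic_compliance,
    scenario_table,
    wall_compliance_per_length,
)

__all__ = [
    "StapesDriveTable",
    "DisplacementProfile",
    "HarmonicSystem",
    "assemble",
    "solve_harmonic",
    "run_sweep",
]

#: Supported drive-frequency range, Hz.
F_MIN, F_MAX = 100.0, 20_000.0

#: Stapes drive rows (frequency Hz, amplitude nm, phase degrees) adapted
#: from in-vivo human stapes-footplate vibration measurements.
DEFAULT_DRIVE_ROWS = (
    (1000.0, 8.00, -300.0),
    (2000.0, 2.00, -380.0),
    (4000.0, 0.35, -470.0),
    (6000.0, 0.10, -510.0),
    (8000.0, 0.09, -585.0),
    (10000.0, 0.05, -650.0),
)


@dataclass(frozen=True)
class StapesDriveTable:
    """Per-frequency stapes displacement drive.

    ``frequency_hz`` strictly positive and unique; ``amplitude_nm`` > 0;
    ``phase_deg`` applied as the complex factor exp(i·phase·π/180).
    """

    frequency_hz: np.ndarray
    amplitude_nm: np.ndarray
    phase_deg: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency_hz, dtype=float)
        a = np.asarray(self.amplitude_nm, dtype=float)
        ph = np.asarray(self.phase_deg, dtype=float)
        if not (len(f) == len(a) == len(ph)):
            raise ConfigurationError("drive table columns must share a length")
        if np.any(f <= 0):
            raise ConfigurationError("drive frequencies must be positive")
        if len(np.unique(f)) != len(f):
            raise ConfigurationError("drive frequencies must be unique")
        if np.any(a <= 0):
            raise ConfigurationError("drive amplitudes must be positive")
        object.__setattr__(self, "frequency_hz", f)
        object.__setattr__(self, "amplitude_nm", a)
        object.__setattr__(self, "phase_deg", ph)

    def __len__(self) -> int:
        return len(self.frequency_hz)

    def __iter__(self):
        return iter(zip(self.frequency_hz, self.amplitude_nm, self.phase_deg))

    @classmethod
    def default(cls) -> "StapesDriveTable":
        rows = np.array(DEFAULT_DRIVE_ROWS)
        return cls(rows[:, 0], rows[:, 1], rows[:, 2])

    @classmethod
    def from_rows(cls, rows) -> "StapesDriveTable":
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        return cls(rows[:, 0], rows[:, 1], rows[:, 2])

    def complex_amplitude_m(self) -> np.ndarray:
        """Complex stapes displacement per row, metres."""
        return (
            self.amplitude_nm * 1e-9 * np.exp(1j * np.deg2rad(self.phase_deg))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": self.frequency_hz,
                "amplitude_nm": self.amplitude_nm,
                "phase_deg": self.phase_deg,
            }
        )


@dataclass(frozen=True)
class DisplacementProfile:
    """Complex BM displacement along the cochlea at one drive frequency."""

    frequency: float          # Hz
    x_mm: np.ndarray          # section midpoints, mm from base
    u: np.ndarray             # complex displacement, m
    stapes_amplitude: float   # |u_stapes|, m
    scenario: str = "healthy"

    def __post_init__(self) -> None:
        if len(self.x_mm) != len(self.u):
            raise ConfigurationError("x_mm and u must share a length")
        if not np.all(np.isfinite(np.abs(self.u))):
            raise SolverError("non-finite displacement in profile")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.u)

    def to_frame(self) -> pd.DataFrame:
        mag = self.magnitude
        return pd.DataFrame(
            {
                "x_mm": self.x_mm,
                "re_u_m": self.u.real,
                "im_u_m": self.u.imag,
                "abs_u_m": mag,
                "normalized": mag / self.stapes_amplitude,
            }
        )


@dataclass
class HarmonicSystem:
    """Assembled sparse complex system A·z = b for one frequency.

    Unknown ordering: p_v (n), p_t (n), u (n), then the vestibular branch
    volume velocity if enabled. ``meta`` carries the SI quantities needed
    for power-balance diagnostics.
    """

    matrix: sp.csr_matrix
    rhs: np.ndarray
    frequency: float
    n_sections: int
    scenario: str
    meta: dict = field(default_factory=dict)
    solution: np.ndarray | None = None

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    def slice_pv(self, z: np.ndarray) -> np.ndarray:
        return z[: self.n_sections]

    def slice_pt(self, z: np.ndarray) -> np.ndarray:
        return z[self.n_sections : 2 * self.n_sections]

    def slice_u(self, z: np.ndarray) -> np.ndarray:
        return z[2 * self.n_sections : 3 * self.n_sections]


def assemble(
    geom: CochlearGeometry,
    mats: MaterialTable,
    grad: BMGradient,
    f: float,
    scenario: str = "healthy",
    stapes_displacement_m: complex = 1e-9,
) -> HarmonicSystem:
    """Assemble the harmonic system at drive frequency ``f`` (Hz).

    ``geom`` must already carry any electrode occlusion (the geometry
    module's job); the scenario label here selects the round-window
    stiffening via :func:`scenario_table` and tags the result.
    ``stapes_displacement_m`` is the complex stapes displacement (phase
    included), metres.
    """
    if not F_MIN <= f <= F_MAX:
        raise ConfigurationError(
            f"drive frequency {f} Hz outside supported range [{F_MIN}, {F_MAX}]"
        )
    mats_eff = scenario_table(mats, scenario)

    n = geom.n_sections
    omega = 2.0 * math.pi * f
    rho = mats_eff.fluid_density
    dx = geom.dx_mm * 1e-3                     # m
    w = geom.bm_width * 1e-3                   # m
    A_sv = geom.area_sv * 1e-6                 # m²
    A_st = geom.area_st * 1e-6
    A_h = geom.helicotrema_area * 1e-6
    A_ow = geom.ow_area * 1e-6

    Z = bm_point_impedance(geom.x_base_mm, omega, geom, mats_eff, grad)
    C_rw = rw_acoustic_compliance(geom, mats_eff)
    C_ow = ow_acoustic_compliance(geom, mats_eff)

    vest_on = geom.vestibular_branch is not None
    size = 3 * n + (1 if vest_on else 0)
    A = sp.lil_matrix((size, size), dtype=complex)
    b = np.zeros(size, dtype=complex)

    iv = lambda i: i          # p_v index
    it = lambda i: n + i      # p_t index
    iu = lambda i: 2 * n + i  # u index

    # face admittances q = Y (p_i - p_{i+1}); pure inertance (lossless)
    Y_sv = 0.5 * (A_sv[:-1] + A_sv[1:]) / (1j * omega * rho * dx)
    Y_st = 0.5 * (A_st[:-1] + A_st[1:]) / (1j * omega * rho * dx)
    Y_h = A_h / (1j * omega * rho * dx)

    # distributed membranous-wall shunt per cell (elastic outer support,
    # stiffness-proportional damping): Y = iωC_cell / (1 + iω·β_wall)
    damp = 1.0 + 1j * omega * mats_eff.wall_damping
    Yw_sv = 1j * omega * wall_compliance_per_length(geom.area_sv, mats_eff) * dx / damp
    # the wall bounds the anatomical duct; the electrode narrows the flow
    # area but does not remove wall
    Yw_st = 1j * omega * wall_compliance_per_length(geom.duct_area_st, mats_eff) * dx / damp

    bm_q = 1j * omega * w * dx  # BM volume-velocity coefficient on u_i

    for i in range(n):
        rv, rt = iv(i), it(i)
        if i > 0:
            A[rv, iv(i - 1)] += Y_sv[i - 1]
            A[rv, iv(i)] -= Y_sv[i - 1]
            A[rt, it(i - 1)] += Y_st[i - 1]
            A[rt, it(i)] -= Y_st[i - 1]
        if i < n - 1:
            A[rv, iv(i)] -= Y_sv[i]
            A[rv, iv(i + 1)] += Y_sv[i]
            A[rt, it(i)] -= Y_st[i]
            A[rt, it(i + 1)] += Y_st[i]
        # elastic-wall leak to the (rigid) bony boundary
        A[rv, iv(i)] -= Yw_sv[i]
        A[rt, it(i)] -= Yw_st[i]
        # BM pumping: positive u (toward scala tympani) drains SV, feeds ST
        A[rv, iu(i)] -= bm_q[i]
        A[rt, iu(i)] += bm_q[i]
        # BM dynamic relation
        A[iu(i), iv(i)] += 1.0
        A[iu(i), it(i)] -= 1.0
        A[iu(i), iu(i)] -= 1j * omega * Z[i]

    # apex: helicotrema shunt, flow q_h = Y_h (p_t - p_v) from ST into SV
    A[iv(n - 1), it(n - 1)] += Y_h
    A[iv(n - 1), iv(n - 1)] -= Y_h
    A[it(n - 1), it(n - 1)] -= Y_h
    A[it(n - 1), iv(n - 1)] += Y_h

    # base: round-window drain on the scala tympani — compliance with
    # stiffness-proportional membrane damping, Y = iωC/(1 + iωβ_rwm)
    win_damp = 1.0 + 1j * omega * mats_eff.rwm_damping
    Y_rw = 1j * omega * C_rw / win_damp
    A[it(0), it(0)] -= Y_rw

    # base: the stapes footplate displacement is prescribed, but the
    # oval-window rim / annular ligament still bulges under intracochlear
    # pressure: U_in = iω·u_st·A_ow − Y_ow·p_v,0
    Y_ow = 1j * omega * C_ow / win_damp
    A[iv(0), iv(0)] -= Y_ow
    U_ow = 1j * omega * stapes_displacement_m * A_ow
    b[iv(0)] = -U_ow

    if vest_on:
        ib = 3 * n
        C_vest = geom.vestibular_branch
        # branch volume velocity q_b leaves the basal SV cell
        A[iv(0), ib] -= 1.0
        A[ib, ib] += 1.0
        A[ib, iv(0)] -= 1j * omega * C_vest

    meta = {
        "omega": omega,
        "U_ow": U_ow,
        "C_rw": C_rw,
        "C_ow": C_ow,
        "Y_rw": Y_rw,
        "Y_ow": Y_ow,
        "Yw_sv": Yw_sv,
        "Yw_st": Yw_st,
        "Z": Z,
        "w_m": w,
        "dx_m": dx,
        "stapes_displacement_m": stapes_displacement_m,
        "x_mm": geom.x_base_mm,
    }
    return HarmonicSystem(
        matrix=A.tocsr(),
        rhs=b,
        frequency=f,
        n_sections=n,
        scenario=scenario,
        meta=meta,
    )


def solve_harmonic(system: HarmonicSystem) -> DisplacementProfile:
    """Solve the assembled sparse system; return the BM displacement profile.

    Deterministic direct sparse solve. Raises :class:`SolverError` on a
    singular or badly conditioned system (e.g. zero damping at an exact
    resonance), advising a nonzero beta.
    """
    Amat, b = system.matrix.tocsc(), system.rhs
    with warnings.catch_warnings():
        warnings.simplefilter("error", spla.MatrixRankWarning)
        try:
            z = spla.spsolve(Amat, b)
        except (spla.MatrixRankWarning, RuntimeError) as exc:
            raise SolverError(
                f"singular harmonic system at {system.frequency} Hz; "
                "ensure nonzero BM damping (beta) and positive areas"
            ) from exc
    if not np.all(np.isfinite(z)):
        raise SolverError(
            f"non-finite solution at {system.frequency} Hz; "
            "ensure nonzero BM damping (beta)"
        )
    # componentwise backward error |r| / (|A||z| + |b|): scale-invariant
    # across the mixed-unit rows (m³/s continuity vs Pa membrane relations)
    if np.linalg.norm(b) > 0:
        r = np.abs(Amat @ z - b)
        denom = np.abs(Amat) @ np.abs(z) + np.abs(b)
        mask = denom > 0
        backward = float(np.max(r[mask] / denom[mask])) if mask.any() else 0.0
        if backward > 1e-8:
            raise SolverError(
                f"ill-conditioned solve at {system.frequency} Hz: backward "
                f"error {backward:.2e}"
            )
    system.solution = z
    return DisplacementProfile(
        frequency=system.frequency,
        x_mm=system.meta["x_mm"],
        u=system.slice_u(z),
        stapes_amplitude=abs(system.meta["stapes_displacement_m"]),
        scenario=system.scenario,
    )


def power_balance(system: HarmonicSystem) -> dict:
    """Time-averaged power bookkeeping for a solved system (watts).

    Input power at the oval window vs. dissipation in BM damping and the
    round-window termination. The fluid network is purely reactive, so the
    two should balance to numerical precision.
    """
    if system.solution is None:
        raise SolverError("solve the system before querying power balance")
    z = system.solution
    m = system.meta
    omega = m["omega"]
    p_v = system.slice_pv(z)
    p_t = system.slice_pt(z)
    u = system.slice_u(z)
    p_v0, p_t0 = p_v[0], p_t[0]
    # the ideal source injects U_ow; the window branches are separate shunts
    P_in = 0.5 * np.real(p_v0 * np.conj(m["U_ow"]))
    v = 1j * omega * u
    P_bm = 0.5 * np.sum(np.real(m["Z"]) * np.abs(v) ** 2 * m["w_m"] * m["dx_m"])
    P_rw = 0.5 * np.abs(p_t0) ** 2 * np.real(m["Y_rw"])
    P_ow = 0.5 * np.abs(p_v0) ** 2 * np.real(m["Y_ow"])
    P_wall = 0.5 * float(
        np.sum(np.abs(p_v) ** 2 * np.real(m["Yw_sv"]))
        + np.sum(np.abs(p_t) ** 2 * np.real(m["Yw_st"]))
    )
    return {
        "input": float(P_in),
        "bm": float(P_bm),
        "rw": float(P_rw),
        "ow": float(P_ow),
        "wall": P_wall,
    }


def run_sweep(
    geom: CochlearGeometry,
    mats: MaterialTable,
    grad: BMGradient,
    drive: StapesDriveTable,
    scenario: str = "healthy",
) -> list[DisplacementProfile]:
    """Solve once per drive-table row; skip (with a warning) rows whose
    solve fails and continue with the rest."""
    if len(drive) == 0:
        warnings.warn("empty stapes drive table: no profiles computed")
        return []
    profiles: list[DisplacementProfile] = []
    failures: list[str] = []
    for f, amp_nm, phase_deg in drive:
        u_st = amp_nm * 1e-9 * np.exp(1j * np.deg2rad(phase_deg))
        try:
            system = assemble(geom, mats, grad, f, scenario, u_st)
            profiles.append(solve_harmonic(system))
        except SolverError as exc:  # pragma: no cover - defensive path
            failures.append(f"{f} Hz: {exc}")
    if failures:
        warnings.warn(
            "solver failed at "
            + "; ".join(failures)
            + f" ({len(profiles)}/{len(drive)} frequencies completed)"
        )
    return profiles
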