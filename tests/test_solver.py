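"""Harmonic transmission-line solver: assembly, solving and sweeps."""

from dataclasses import replace

import numpy as np
import pytest

from rhesusear import (
    BMGradient,
    ConfigurationError,
    GeometryParams,
    StapesDriveTable,
    assemble,
    build_geometry,
    run_sweep,
    solve_harmonic,
)
from rhesusear.calibration import ModelBundle, peak_positions
from rhesusear.materials import rw_acoustic_compliance
from rhesusear.solver import DEFAULT_DRIVE_ROWS, power_balance

# stapes vibration rows (frequency Hz, amplitude nm, phase deg)
TABLE1 = (
    (1000.0, 8.00, -300.0),
    (2000.0, 2.00, -380.0),
    (4000.0, 0.35, -470.0),
    (6000.0, 0.10, -510.0),
    (8000.0, 0.09, -585.0),
    (10000.0, 0.05, -650.0),
)


class TestDriveTable:
    def test_default_rows_match_published_stapes_data(self):
        assert DEFAULT_DRIVE_ROWS == TABLE1
        t = StapesDriveTable.default()
        np.testing.assert_array_equal(t.frequency_hz, [r[0] for r in TABLE1])
        np.testing.assert_array_equal(t.amplitude_nm, [r[1] for r in TABLE1])
        np.testing.assert_array_equal(t.phase_deg, [r[2] for r in TABLE1])

    def test_duplicate_frequencies_rejected(self):
        with pytest.raises(ConfigurationError):
            StapesDriveTable.from_rows([[1000, 1, 0], [1000, 2, 0]])

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(ConfigurationError):
            StapesDriveTable.from_rows([[1000, 0.0, 0]])


class TestAssemble:
    def test_system_size_is_three_per_section(self, geom, mats):
        s = assemble(geom, mats, BMGradient(), 1000.0)
        assert s.size == 3 * geom.n_sections

    def test_vestibular_branch_adds_one_unknown(self, mats):
        g = build_geometry(GeometryParams(vestibular_branch=1e-14))
        s = assemble(g, mats, BMGradient(), 1000.0)
        assert s.size == 3 * g.n_sections + 1
        solve_harmonic(s)  # and it still solves cleanly

    def test_frequency_range_enforced(self, geom, mats):
        with pytest.raises(ConfigurationError):
            assemble(geom, mats, BMGradient(), 50.0)

    def test_zero_drive_gives_zero_solution(self, geom, mats):
        s = assemble(geom, mats, BMGradient(), 1000.0, stapes_displacement_m=0.0)
        assert not np.any(s.rhs)
        p = solve_harmonic(s)
        assert np.all(p.u == 0)


class TestSolve:
    def test_linearity_in_drive_amplitude(self, geom, mats, calibrated_grad):
        p1 = solve_harmonic(
            assemble(geom, mats, calibrated_grad, 2000.0, stapes_displacement_m=1e-9)
        )
        p2 = solve_harmonic(
            assemble(geom, mats, calibrated_grad, 2000.0, stapes_displacement_m=2e-9)
        )
        np.testing.assert_allclose(p2.u, 2.0 * p1.u, rtol=1e-12)

    def test_drive_phase_rotates_solution(self, geom, mats, calibrated_grad):
        rot = np.exp(1j * np.deg2rad(-300.0))
        p1 = solve_harmonic(
            assemble(geom, mats, calibrated_grad, 2000.0, stapes_displacement_m=1e-9)
        )
        p2 = solve_harmonic(
            assemble(geom, mats, calibrated_grad, 2000.0, stapes_displacement_m=1e-9 * rot)
        )
        # normwise: elements deep in the apical cutoff are ~12 orders below
        # the peak and carry no relative precision through the LU solve
        err = np.max(np.abs(p2.u - rot * p1.u)) / np.max(np.abs(p1.u))
        assert err < 1e-10

    def test_sparse_solution_matches_dense_solve(self, mats, calibrated_grad):
        g8 = build_geometry(GeometryParams(n_sections=8))
        s = assemble(g8, mats, calibrated_grad, 2000.0, stapes_displacement_m=2e-9)
        solve_harmonic(s)
        dense = np.linalg.solve(s.matrix.toarray(), s.rhs)
        err = np.max(np.abs(s.solution - dense)) / np.max(np.abs(dense))
        assert err < 1e-12

    def test_rigid_membrane_reduces_to_series_duct_loop(self, geom, mats):
        """With a (near-)rigid membrane and lossless rigid-walled boundaries
        the flow runs base→apex→base as one series loop; the basal pressure
        must equal the closed-form sum of face impedances plus the
        round-window compliance."""
        rigid_mats = replace(
            mats,
            wall_modulus=1e18,       # rigid outer walls
            ligament_modulus=1e18,   # rigid input rim
            ow_modulus=1e18,
            rwm_damping=0.0,
            wall_damping=0.0,
        )
        rigid_grad = BMGradient(E0_log10=20.0)  # membrane ~10^14 × stiffer
        f, u_st = 500.0, 1e-9
        s = assemble(geom, rigid_mats, rigid_grad, f, stapes_displacement_m=u_st)
        prof = solve_harmonic(s)

        omega = 2 * np.pi * f
        rho = mats.fluid_density
        dx = geom.dx_mm * 1e-3
        A_sv = geom.area_sv * 1e-6
        A_st = geom.area_st * 1e-6
        Y_sv = 0.5 * (A_sv[:-1] + A_sv[1:]) / (1j * omega * rho * dx)
        Y_st = 0.5 * (A_st[:-1] + A_st[1:]) / (1j * omega * rho * dx)
        Y_h = geom.helicotrema_area * 1e-6 / (1j * omega * rho * dx)
        C_rw = rw_acoustic_compliance(geom, rigid_mats)
        U = 1j * omega * u_st * geom.ow_area * 1e-6
        p_pred = U * (
            np.sum(1 / Y_sv) + 1 / Y_h + np.sum(1 / Y_st) + 1 / (1j * omega * C_rw)
        )
        p_v0 = s.slice_pv(s.solution)[0]
        assert abs(p_v0 - p_pred) / abs(p_pred) < 1e-6
        assert prof.magnitude.max() < 1e-15  # membrane effectively rigid

    def test_power_identity(self, geom, mats, calibrated_grad):
        """Time-averaged source power equals the sum of all dissipation
        sites (membrane damping, window terminations, damped walls)."""
        for f, amp, ph in TABLE1:
            u = amp * 1e-9 * np.exp(1j * np.deg2rad(ph))
            s = assemble(geom, mats, calibrated_grad, f, stapes_displacement_m=u)
            solve_harmonic(s)
            pb = power_balance(s)
            total = pb["bm"] + pb["rw"] + pb["ow"] + pb["wall"]
            assert pb["input"] > 0
            assert all(v >= 0 for k, v in pb.items() if k != "input")
            assert abs(pb["input"] - total) / pb["input"] < 1e-6


class TestSweep:
    def test_default_sweep_returns_six_profiles(self, geom, mats, calibrated_grad, drive):
        profiles = run_sweep(geom, mats, calibrated_grad, drive)
        assert [p.frequency for p in profiles] == [r[0] for r in TABLE1]
        for p in profiles:
            assert len(p.u) == geom.n_sections
            assert np.all(np.isfinite(p.magnitude))

    def test_empty_drive_warns(self, geom, mats):
        empty = StapesDriveTable(np.array([]), np.array([]), np.array([]))
        with pytest.warns(UserWarning, match="empty"):
            assert run_sweep(geom, mats, BMGradient(), empty) == []

    def test_peaks_move_basally_with_frequency(self, geom, mats, calibrated_grad, drive):
        peaks = peak_positions(ModelBundle(geom, mats, calibrated_grad), drive)
        assert np.all(np.diff(peaks) < 0), "tonotopic ordering violated"

    def test_grid_refinement_keeps_peaks(self, mats, calibrated_grad, drive, geom):
        """Doubling the section count moves no peak by more than 0.25 mm
        (discretization-convergence check)."""
        fine = build_geometry(GeometryParams(n_sections=164))
        p82 = peak_positions(ModelBundle(geom, mats, calibrated_grad), drive)
        p164 = peak_positions(ModelBundle(fine, mats, calibrated_grad), drive)
        assert np.max(np.abs(p82 - p164)) < 0.25

    def test_displacements_span_nanometre_to_picometre(
        self, geom, mats, calibrated_grad, drive
    ):
        profiles = run_sweep(geom, mats, calibrated_grad, drive)
        peaks = np.array([p.magnitude.max() for p in profiles])
        assert 1e-9 <= peaks[0] <= 1e-7       # nanometres at 1 kHz
        assert 1e-13 <= peaks[-1] <= 1e-11    # picometres at 10 kHz
        assert np.all(np.diff(peaks) < 0)
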