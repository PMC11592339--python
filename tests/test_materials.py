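"""Basilar-membrane gradients, point impedance and scenario tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhesusear import (
    BMGradient,
    ConfigurationError,
    DomainError,
    MaterialTable,
    bm_damping_coefficient,
    bm_elastic_modulus,
    bm_point_impedance,
    scenario_table,
)
from rhesusear.materials import bm_areal_stiffness, bm_resonance_omega


class TestGradients:
    def test_basal_elastic_modulus(self):
        assert bm_elastic_modulus(0.0, BMGradient()) == pytest.approx(10**5.7)

    def test_apical_elastic_modulus(self):
        # direct evaluation of the exponential at the apex
        assert bm_elastic_modulus(27.0, BMGradient()) == pytest.approx(
            10**5.7 * np.exp(-0.19 * 27.0)
        )
        assert bm_elastic_modulus(27.0, BMGradient()) == pytest.approx(2.965e3, rel=1e-3)

    def test_basal_damping(self):
        assert bm_damping_coefficient(0.0, BMGradient()) == pytest.approx(10**-5.91)

    def test_apical_damping(self):
        assert bm_damping_coefficient(27.0, BMGradient()) == pytest.approx(
            1.831e-5, rel=1e-3
        )

    def test_modulus_decreases_damping_increases(self):
        g = BMGradient()
        assert bm_elastic_modulus(10.0, g) < bm_elastic_modulus(5.0, g)
        assert bm_damping_coefficient(20.0, g) > bm_damping_coefficient(10.0, g)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(x=st.floats(min_value=0.0, max_value=27.0),
           dx=st.floats(min_value=0.1, max_value=5.0))
    def test_log_modulus_is_affine_in_x(self, x, dx):
        # slope of log10 E is exactly -E_decay/ln(10) per mm
        g = BMGradient()
        if x + dx > 27.0:
            dx = 27.0 - x
            if dx <= 0:
                return
        lhs = np.log10(bm_elastic_modulus(x + dx, g)) - np.log10(bm_elastic_modulus(x, g))
        assert lhs == pytest.approx(-g.E_decay / np.log(10) * dx, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            bm_elastic_modulus(-1.0, BMGradient())
        with pytest.raises(DomainError):
            bm_damping_coefficient(30.0, BMGradient(), bm_length=27.0)

    def test_invalid_gradient_rejected(self):
        with pytest.raises(ConfigurationError):
            BMGradient(E_decay=-0.1)
        with pytest.raises(ConfigurationError):
            BMGradient(beta_growth=0.0)


class TestPointImpedance:
    def test_mass_dominates_at_high_frequency(self, geom, mats):
        g = BMGradient()
        x = 10.0
        omega = 1e9
        Z = bm_point_impedance(x, omega, geom, mats, g)
        t = np.interp(x, geom.x_base_mm, geom.bm_thickness) * 1e-3
        assert abs(Z) == pytest.approx(omega * mats.bm_density * t, rel=1e-3)

    def test_negligible_damping_gives_reactive_impedance(self, geom, mats):
        g = BMGradient(beta0_log10=-300.0)
        Z = bm_point_impedance(5.0, 2 * np.pi * 1000.0, geom, mats, g)
        assert Z.real == pytest.approx(0.0, abs=1e-12)

    def test_real_part_is_stiffness_times_beta(self, geom, mats):
        g = BMGradient()
        x, omega = 8.0, 2 * np.pi * 2000.0
        Z = bm_point_impedance(x, omega, geom, mats, g)
        s = bm_areal_stiffness(x, geom, g)
        beta = bm_damping_coefficient(x, g)
        assert Z.real == pytest.approx(s * beta, rel=1e-12)

    def test_resonance_matches_brute_force_scan(self, geom, mats):
        # scan Im Z over omega and find its zero crossing independently
        g = BMGradient(beta0_log10=-300.0)
        x = 12.0
        omegas = np.linspace(1e2, 1e6, 400_000)
        imag = np.array(
            [bm_point_impedance(x, w, geom, mats, g).imag for w in omegas[::1000]]
        )
        fine = omegas[::1000]
        k = int(np.argmax(imag > 0))
        # refine by bisection between the bracketing grid points
        lo, hi = fine[k - 1], fine[k]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if bm_point_impedance(x, mid, geom, mats, g).imag > 0:
                hi = mid
            else:
                lo = mid
        assert bm_resonance_omega(x, geom, mats, g) == pytest.approx(
            0.5 * (lo + hi), rel=1e-9
        )

    def test_invalid_omega(self, geom, mats):
        with pytest.raises(DomainError):
            bm_point_impedance(5.0, 0.0, geom, mats, BMGradient())


class TestScenarioTable:
    def test_healthy_is_identity(self, mats):
        assert scenario_table(mats, "healthy") == mats

    def test_implanted_leaves_moduli_alone(self, mats):
        out = scenario_table(mats, "implanted")
        assert out.rwm_modulus == mats.rwm_modulus
        assert out.rwm_stiffening_factor == 1.0

    def test_stiffened_multiplies_rwm_tenfold(self, mats):
        out = scenario_table(mats, "implanted_stiffened")
        assert out.effective_rwm_modulus == pytest.approx(10.0 * mats.rwm_modulus)
        assert out.bm_density == mats.bm_density

    def test_unknown_scenario_rejected(self, mats):
        with pytest.raises(ConfigurationError, match="unknown scenario"):
            scenario_table(mats, "bionic")

    def test_stiffening_factor_scales_boundary_stiffness_linearly(self, geom, mats):
        from dataclasses import replace

        from rhesusear.materials import rw_acoustic_compliance

        doubled = replace(mats, rwm_stiffening_factor=2.0)
        assert rw_acoustic_compliance(geom, mats) == pytest.approx(
            2.0 * rw_acoustic_compliance(geom, doubled), rel=1e-12
        )
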