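"""Constitutive conversions, degradation arithmetic, built-in models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonewave.materials import (
    DEGRADATION_LEVELS,
    DegradationLevel,
    ElasticIsotropic,
    FluidProps,
    InvalidMaterialError,
    Layer,
    LayeredCylinderSpec,
    apply_degradation,
    builtin_models,
    engineering_from_lame,
    equivalent_solid_from_fluid,
    lame_from_engineering,
    low_freq_bar_velocity,
    relative_velocity_change,
)


class TestLameConversion:
    @pytest.mark.parametrize(
        "E, nu, lam_expected, mu_expected",
        [
            (1.0, 0.0, 0.0, 0.5),                      # nu=0 forces lambda=0
            (16.46e9, 0.373, None, 5.994e9),           # validation-tube cortex
            (14.95e9, 0.31, 9.31e9, None),             # healthy phantom cortex
        ],
    )
    def test_known_values(self, E, nu, lam_expected, mu_expected):
        lam, mu = lame_from_engineering(E, nu)
        if lam_expected is not None:
            assert lam == pytest.approx(lam_expected, rel=1e-3)
        if mu_expected is not None:
            assert mu == pytest.approx(mu_expected, rel=1e-3)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(InvalidMaterialError):
            lame_from_engineering(1e9, 0.5)

    @settings(deadline=None, derandomize=True)
    @given(
        E=st.floats(1e8, 1e11),
        nu=st.floats(0.0, 0.49, exclude_max=True),
    )
    def test_round_trip(self, E, nu):
        lam, mu = lame_from_engineering(E, nu)
        E2, nu2 = engineering_from_lame(lam, mu)
        assert E2 == pytest.approx(E, rel=1e-12)
        assert nu2 == pytest.approx(nu, abs=1e-12)


class TestEquivalentSolid:
    MARROW = FluidProps(bulk_modulus=2.2e9, density=1000.0, viscosity=0.037)

    def test_ideal_fluid_longitudinal_speed(self):
        eq = equivalent_solid_from_fluid(
            FluidProps(2.2e9, 1000.0, 0.0), omega=2 * np.pi * 1e5,
            shear_floor=0.0, shear_damping=0.0,
        )
        assert eq.lame_mu == 0
        c = math.sqrt((eq.lame_lambda + 2 * eq.lame_mu).real / eq.density)
        assert c == pytest.approx(math.sqrt(2.2e9 / 1000.0), rel=1e-12)
        assert c == pytest.approx(1483.2, abs=0.5)

    def test_newtonian_shear_magnitude(self):
        omega = 2 * np.pi * 1e5
        eq = equivalent_solid_from_fluid(self.MARROW, omega, shear_floor=0.0)
        assert abs(eq.lame_mu) == pytest.approx(omega * 0.037, rel=1e-12)
        assert abs(eq.lame_mu) == pytest.approx(2.32e4, rel=3e-3)
        assert eq.lame_mu.real == 0.0
        assert eq.lame_mu.imag < 0  # dissipative under e^{-iωt}

    def test_bulk_modulus_honoured_with_floor(self):
        eq = equivalent_solid_from_fluid(self.MARROW, 2 * np.pi * 1e5)
        assert (eq.lame_lambda + 2 * eq.lame_mu / 3).real == pytest.approx(
            2.2e9, rel=1e-12
        )

    def test_floor_convergence_to_ideal_fluid(self):
        # viscosity→0, floor→0: longitudinal speed tends to sqrt(K/ρ)
        target = math.sqrt(2.2e9 / 1000.0)
        for floor in (100.0, 10.0, 1.0):
            eq = equivalent_solid_from_fluid(
                FluidProps(2.2e9, 1000.0, 0.0), 2 * np.pi * 1e5, shear_floor=floor
            )
            c = abs(
                np.sqrt((eq.lame_lambda + 2 * eq.lame_mu) / eq.density)
            )
            assert c == pytest.approx(target, rel=5 * (floor / target) ** 2 + 1e-9)


class TestDegradation:
    HEALTHY = ElasticIsotropic(14.95e9, 0.31, 2300.0)

    @pytest.mark.parametrize(
        "level, E_expected, rho_expected",
        [
            (DegradationLevel(0.20, 0.07), 11.96e9, 2139.0),
            (DegradationLevel(0.40, 0.13), 8.97e9, 2001.0),
            (DegradationLevel(0.0, 0.0), 14.95e9, 2300.0),
        ],
    )
    def test_fractional_arithmetic(self, level, E_expected, rho_expected):
        d = apply_degradation(self.HEALTHY, level)
        assert d.young_modulus == pytest.approx(E_expected, rel=1e-9)
        assert d.density == pytest.approx(rho_expected, rel=1e-9)
        assert d.poisson_ratio == self.HEALTHY.poisson_ratio

    @settings(deadline=None, derandomize=True)
    @given(
        de=st.floats(0.0, 0.9),
        drho=st.floats(0.0, 0.9),
    )
    def test_monotone_and_poisson_preserving(self, de, drho):
        d = apply_degradation(self.HEALTHY, DegradationLevel(de, drho))
        assert d.young_modulus <= self.HEALTHY.young_modulus
        assert d.density <= self.HEALTHY.density
        assert d.poisson_ratio == self.HEALTHY.poisson_ratio

    def test_level_ratio_approximately_three(self):
        for level in DEGRADATION_LEVELS:
            ratio = level.modulus_reduction / level.density_reduction
            assert ratio == pytest.approx(3.0, rel=0.05)


class TestAsymptoteFormulas:
    @pytest.mark.parametrize(
        "E, rho, expected",
        [
            (14.95e9, 2300.0, 2549.6),
            (8.97e9, 1993.0, 2121.5),
            (0.0, 1000.0, 0.0),
        ],
    )
    def test_bar_velocity(self, E, rho, expected):
        assert low_freq_bar_velocity(E, rho) == pytest.approx(expected, abs=0.1)

    @pytest.mark.parametrize(
        "de, drho, expected",
        [(0.0, 0.0, 0.0), (0.20, 0.07, 0.065), (0.40, 0.13, 0.135)],
    )
    def test_relative_velocity_change(self, de, drho, expected):
        assert relative_velocity_change(de, drho) == pytest.approx(expected, abs=1e-12)


class TestBuiltinModels:
    def test_trilayer_ring_radii(self):
        spec = builtin_models()["model3_healthy"]
        assert spec.interface_radii == pytest.approx((7e-3, 10e-3, 15e-3))

    def test_cortex_density(self):
        spec = builtin_models()["model2_healthy"]
        cortex = spec.material_by_region()["cortex"]
        assert cortex.density == 2300.0
        assert cortex.young_modulus == 14.95e9

    def test_degraded_cortices_use_printed_absolutes(self):
        models = builtin_models()
        printed = {"level1": (11.96e9, 2145.0), "level2": (10.465e9, 2070.0),
                   "level3": (8.97e9, 1993.0)}
        for label, (E, rho) in printed.items():
            cortex = models[f"model3_{label}"].material_by_region()["cortex"]
            assert cortex.young_modulus == E
            assert cortex.density == rho

    def test_free_tube_is_single_annulus(self):
        spec = builtin_models()["model1_free"]
        assert len(spec.layers) == 1
        assert spec.inner_radius > 0  # cavity, no core

    def test_fluid_coating_thickness_required(self):
        assert "model1_fluid" not in builtin_models()
        fluid = builtin_models(fluid_coating_thickness=2e-3)["model1_fluid"]
        assert fluid.outer_radius == pytest.approx(12e-3)
        with pytest.raises(ValueError):
            builtin_models(fluid_coating_thickness=-1.0)

    def test_layer_validation(self):
        mat = ElasticIsotropic(1e10, 0.3, 2000.0)
        with pytest.raises(ValueError):
            LayeredCylinderSpec(layers=(Layer(5e-3, mat, "a"), Layer(5e-3, mat, "b")))
        with pytest.raises(ValueError):
            LayeredCylinderSpec(layers=(Layer(5e-3, mat, "a"), Layer(7e-3, mat, "a")))
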