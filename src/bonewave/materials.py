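"""Constitutive models and built-in layered-cylinder configurations.

All quantities are SI internally (Pa, kg/m³, m, rad/s).  The sign
convention used throughout the package is the time-harmonic factor
``e^{i(k x3 - ω t)}``: lossy complex moduli carry a *negative* imaginary
part, and decaying forward-propagating modes have ``Re k > 0``,
``Im k >= 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Union

__all__ = [
    "ElasticIsotropic",
    "ViscoelasticEquivalent",
    "FluidProps",
    "DegradationLevel",
    "Layer",
    "LayeredCylinderSpec",
    "MaterialModel",
    "lame_from_engineering",
    "engineering_from_lame",
    "equivalent_solid_from_fluid",
    "apply_degradation",
    "low_freq_bar_velocity",
    "relative_velocity_change",
    "builtin_models",
]


class InvalidMaterialError(ValueError):
    """Raised for constitutive parameters outside the supported range."""


@dataclass(frozen=True)
class ElasticIsotropic:
    """Isotropic linear-elastic solid given by engineering constants.

    Parameters
    ----------
    young_modulus : float
        Young's modulus E in Pa.
    poisson_ratio : float
        Poisson's ratio ν, in (0, 0.5).
    density : float
        Mass density ρ in kg/m³.
    """

    young_modulus: float
    poisson_ratio: float
    density: float

    def __post_init__(self) -> None:
        if not self.young_modulus > 0:
            raise InvalidMaterialError("young_modulus must be > 0")
        if not 0 < self.poisson_ratio < 0.5:
            raise InvalidMaterialError("poisson_ratio must lie in (0, 0.5)")
        if not self.density > 0:
            raise InvalidMaterialError("density must be > 0")

    @property
    def lame(self) -> tuple[float, float]:
        return lame_from_engineering(self.young_modulus, self.poisson_ratio)

    def lame_at(self, omega: float) -> tuple[complex, complex]:
        """Frequency-independent Lamé constants (uniform interface)."""
        lam, mu = self.lame
        return complex(lam), complex(mu)

    @property
    def shear_speed(self) -> float:
        return math.sqrt(self.lame[1] / self.density)

    @property
    def longitudinal_speed(self) -> float:
        lam, mu = self.lame
        return math.sqrt((lam + 2 * mu) / self.density)


@dataclass(frozen=True)
class ViscoelasticEquivalent:
    """Equivalent viscoelastic isotropic solid with complex Lamé constants.

    Under the e^{i(kx3-ωt)} convention the imaginary parts of the moduli
    are non-positive for a dissipative material so that |Im k| grows with
    damping.
    """

    lame_lambda: complex
    lame_mu: complex
    density: float

    def __post_init__(self) -> None:
        if not (self.lame_lambda + 2 * self.lame_mu).real > 0:
            raise InvalidMaterialError("Re(lambda + 2 mu) must be > 0")
        if not self.density > 0:
            raise InvalidMaterialError("density must be > 0")

    def lame_at(self, omega: float) -> tuple[complex, complex]:
        return complex(self.lame_lambda), complex(self.lame_mu)


@dataclass(frozen=True)
class FluidProps:
    """A (possibly viscous) Newtonian fluid: bulk modulus, density, viscosity."""

    bulk_modulus: float
    density: float
    viscosity: float = 0.0

    def __post_init__(self) -> None:
        if not self.bulk_modulus > 0:
            raise InvalidMaterialError("bulk_modulus must be > 0")
        if not self.density > 0:
            raise InvalidMaterialError("density must be > 0")
        if self.viscosity < 0:
            raise InvalidMaterialError("viscosity must be >= 0")

    @property
    def sound_speed(self) -> float:
        return math.sqrt(self.bulk_modulus / self.density)


@dataclass(frozen=True)
class FluidLayerMaterial:
    """A fluid layer realised as an equivalent solid at each frequency.

    Wraps :class:`FluidProps` and produces frequency-dependent complex
    Lamé constants through :func:`equivalent_solid_from_fluid`, so the
    same assembly path handles solid and fluid regions.

    ``shear_floor`` (m/s) and ``shear_damping`` regularise the
    vanishing shear stiffness of the fluid; see
    :func:`equivalent_solid_from_fluid`.
    """

    fluid: FluidProps
    shear_floor: float = 100.0
    shear_damping: float = 0.5

    @property
    def density(self) -> float:
        return self.fluid.density

    def lame_at(self, omega: float) -> tuple[complex, complex]:
        eq = equivalent_solid_from_fluid(
            self.fluid, omega, shear_floor=self.shear_floor,
            shear_damping=self.shear_damping,
        )
        return eq.lame_lambda, eq.lame_mu


MaterialModel = Union[ElasticIsotropic, ViscoelasticEquivalent, FluidLayerMaterial]


@dataclass(frozen=True)
class DegradationLevel:
    """Proportional reduction of cortical stiffness and density.

    ``modulus_reduction`` is ΔE/E and ``density_reduction`` is Δρ/ρ,
    both as fractions in [0, 1).  Poisson's ratio is held fixed.
    """

    modulus_reduction: float
    density_reduction: float
    label: str = ""

    def __post_init__(self) -> None:
        for frac in (self.modulus_reduction, self.density_reduction):
            if not 0 <= frac < 1:
                raise ValueError("reduction fractions must lie in [0, 1)")


@dataclass(frozen=True)
class Layer:
    """One concentric layer: its outer radius, material and region tag."""

    outer_radius: float
    material: MaterialModel
    region_tag: str


@dataclass(frozen=True)
class LayeredCylinderSpec:
    """Concentric layered cylinder cross-section.

    ``inner_radius == 0`` means the innermost layer is a solid disc;
    a positive value leaves a traction-free inner cavity (hollow tube).
    Outer radii must be strictly increasing and region tags unique.
    """

    layers: tuple[Layer, ...]
    inner_radius: float = 0.0

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("at least one layer required")
        radii = [self.inner_radius] + [la.outer_radius for la in self.layers]
        for lo, hi in zip(radii, radii[1:]):
            if not hi > lo:
                raise ValueError("layer outer radii must be strictly increasing")
        tags = [la.region_tag for la in self.layers]
        if len(set(tags)) != len(tags):
            raise ValueError("region tags must be unique")

    @property
    def outer_radius(self) -> float:
        return self.layers[-1].outer_radius

    @property
    def region_tags(self) -> tuple[str, ...]:
        return tuple(la.region_tag for la in self.layers)

    @property
    def interface_radii(self) -> tuple[float, ...]:
        """Radii of material interfaces and boundaries (inner cavity included)."""
        inner = (self.inner_radius,) if self.inner_radius > 0 else ()
        return inner + tuple(la.outer_radius for la in self.layers)

    def material_by_region(self) -> dict[str, MaterialModel]:
        return {la.region_tag: la.material for la in self.layers}

    def thinnest_layer(self) -> float:
        radii = [self.inner_radius] + [la.outer_radius for la in self.layers]
        return min(hi - lo for lo, hi in zip(radii, radii[1:]))


# ---------------------------------------------------------------------------
# conversions and scalings


def lame_from_engineering(young_modulus: float, poisson_ratio: float) -> tuple[float, float]:
    """Convert (E, ν) to Lamé constants (λ, μ).

    μ = E / (2(1+ν)),  λ = Eν / ((1+ν)(1−2ν)).  The incompressible
    limit ν → 0.5 is rejected.
    """
    if not young_modulus > 0:
        raise InvalidMaterialError("young_modulus must be > 0")
    if not 0 <= poisson_ratio < 0.5:
        raise InvalidMaterialError(
            "poisson_ratio must lie in [0, 0.5); the incompressible limit is unsupported"
        )
    mu = young_modulus / (2.0 * (1.0 + poisson_ratio))
    lam = (
        young_modulus * poisson_ratio
        / ((1.0 + poisson_ratio) * (1.0 - 2.0 * poisson_ratio))
    )
    return lam, mu


def engineering_from_lame(lam: float, mu: float) -> tuple[float, float]:
    """Inverse of :func:`lame_from_engineering`."""
    young = mu * (3.0 * lam + 2.0 * mu) / (lam + mu)
    nu = lam / (2.0 * (lam + mu))
    return young, nu


def equivalent_solid_from_fluid(
    fluid: FluidProps,
    omega: float,
    shear_floor: float = 100.0,
    shear_damping: float = 0.5,
) -> ViscoelasticEquivalent:
    """Equivalent viscoelastic solid for a viscous fluid layer.

    The longitudinal stiffness honours the fluid bulk modulus exactly:
    ``Re(λ + 2μ/3) = K``.  The shear modulus is whichever of

    * the Newtonian term ``−iωη`` (magnitude ωη, purely imaginary under
      the e^{-iωt} convention), or
    * the numerical floor ``ρ c_s² (1 − i d)²`` with shear-wave speed
      floor ``c_s = shear_floor`` and damping ratio ``d = shear_damping``

    has the larger magnitude.  The floor suppresses mesh-scale spurious
    shear modes of the discretised fluid region; results should be
    sensitivity-checked against it (the regularised shear speed is far
    below the phase-velocity window of interest, so retained bone-guided
    modes depend on it only weakly).
    """
    if not omega > 0:
        raise ValueError("omega must be > 0")
    mu_newton = -1j * omega * fluid.viscosity
    mu_floor = fluid.density * shear_floor**2 * (1.0 - 1j * shear_damping) ** 2
    mu = mu_floor if abs(mu_floor) >= abs(mu_newton) else mu_newton
    lam = fluid.bulk_modulus - 2.0 * mu / 3.0
    return ViscoelasticEquivalent(lame_lambda=lam, lame_mu=mu, density=fluid.density)


def apply_degradation(mat: ElasticIsotropic, level: DegradationLevel) -> ElasticIsotropic:
    """Degrade an elastic solid: E' = E(1−ΔE/E), ρ' = ρ(1−Δρ/ρ), ν fixed."""
    return replace(
        mat,
        young_modulus=mat.young_modulus * (1.0 - level.modulus_reduction),
        density=mat.density * (1.0 - level.density_reduction),
    )


def low_freq_bar_velocity(young_modulus: float, density: float, k_factor: float = 1.0) -> float:
    """Low-frequency asymptote of the fundamental longitudinal mode.

    ``V = K(ν)·sqrt(E/ρ)`` with the thin-rod limit K = 1 by default;
    the Poisson-ratio correction factor is exposed as a pass-through.
    """
    if young_modulus < 0 or density <= 0:
        raise ValueError("require E >= 0 and rho > 0")
    return k_factor * math.sqrt(young_modulus / density)


def relative_velocity_change(dE_over_E: float, drho_over_rho: float) -> float:
    """Predicted relative drop of the bar velocity: ½(ΔE/E − Δρ/ρ).

    Follows from differentiating V = K(ν)·sqrt(E/ρ) at fixed ν.
    """
    for frac in (dE_over_E, drho_over_rho):
        if not 0 <= frac < 1:
            raise ValueError("reduction fractions must lie in [0, 1)")
    return 0.5 * (dE_over_E - drho_over_rho)


# ---------------------------------------------------------------------------
# built-in configurations

#: Cortex geometry shared by all built-in models: inner radius 7 mm,
#: thickness 3 mm; the trilayer adds a 5 mm soft-tissue coating.
CORTEX_INNER_RADIUS = 7e-3
CORTEX_OUTER_RADIUS = 10e-3
TISSUE_OUTER_RADIUS = 15e-3

#: Marrow acoustic surrogate: polyurethane core matching bone marrow
#: (bulk modulus 2.2 GPa, viscosity 37 cP, density 1000 kg/m³).
MARROW_FLUID = FluidProps(bulk_modulus=2.2e9, density=1000.0, viscosity=0.037)

#: Validation-model cortical bone (literature tube).
MODEL1_CORTEX = ElasticIsotropic(16.46e9, 0.373, 1850.0)

#: Bone-phantom cortical materials and the soft-tissue coating.
HEALTHY_CORTEX = ElasticIsotropic(14.95e9, 0.31, 2300.0)
OSTEO_CORTEX = ElasticIsotropic(12.17e9, 0.31, 2150.0)
SOFT_TISSUE = ElasticIsotropic(6.0e9, 0.43, 1250.0)

#: Graded degradation levels: ΔE/E of 20/30/40 % with Δρ/ρ of 7/10/13 %
#: (ratio ≈ 3).  The built-in degraded cortices use the printed absolute
#: values (E in GPa / ρ in kg/m³): 11.96/2145, 10.465/2070, 8.97/1993.
DEGRADATION_LEVELS = (
    DegradationLevel(0.20, 0.07, label="level1"),
    DegradationLevel(0.30, 0.10, label="level2"),
    DegradationLevel(0.40, 0.13, label="level3"),
)

_DEGRADED_CORTEX = {
    "level1": ElasticIsotropic(11.96e9, 0.31, 2145.0),
    "level2": ElasticIsotropic(10.465e9, 0.31, 2070.0),
    "level3": ElasticIsotropic(8.97e9, 0.31, 1993.0),
}


def _marrow_layer(shear_floor: float = 100.0, shear_damping: float = 0.5) -> Layer:
    return Layer(
        outer_radius=CORTEX_INNER_RADIUS,
        material=FluidLayerMaterial(MARROW_FLUID, shear_floor, shear_damping),
        region_tag="marrow",
    )


def _trilayer(cortex: ElasticIsotropic) -> LayeredCylinderSpec:
    return LayeredCylinderSpec(
        layers=(
            _marrow_layer(),
            Layer(CORTEX_OUTER_RADIUS, cortex, "cortex"),
            Layer(TISSUE_OUTER_RADIUS, SOFT_TISSUE, "tissue"),
        )
    )


def builtin_models(fluid_coating_thickness: float | None = None) -> dict[str, LayeredCylinderSpec]:
    """The built-in layered-cylinder configurations.

    * ``model1_free`` — literature validation tube, free annulus.
    * ``model1_fluid`` — same tube with an exterior fluid coating; its
      thickness is not standardised, so it must be supplied explicitly
      (the entry is omitted when ``fluid_coating_thickness`` is None).
    * ``model2_healthy`` / ``model2_osteo`` — bone-phantom tube with a
      viscous marrow core.
    * ``model2ext_healthy`` / ``model2ext_osteo`` — the same plus a
      5 mm soft-tissue coating (trilayer).
    * ``model3_healthy`` and ``model3_level{1,2,3}`` — the trilayer at
      graded degradation of the cortex.  The healthy trilayer is the
      same configuration as ``model2ext_healthy``.
    """
    models: dict[str, LayeredCylinderSpec] = {}
    models["model1_free"] = LayeredCylinderSpec(
        layers=(Layer(CORTEX_OUTER_RADIUS, MODEL1_CORTEX, "cortex"),),
        inner_radius=CORTEX_INNER_RADIUS,
    )
    if fluid_coating_thickness is not None:
        if not fluid_coating_thickness > 0:
            raise ValueError("fluid_coating_thickness must be > 0")
        models["model1_fluid"] = LayeredCylinderSpec(
            layers=(
                Layer(CORTEX_OUTER_RADIUS, MODEL1_CORTEX, "cortex"),
                Layer(
                    CORTEX_OUTER_RADIUS + fluid_coating_thickness,
                    FluidLayerMaterial(FluidProps(2.2e9, 1000.0, 0.0)),
                    "fluid_coating",
                ),
            ),
            inner_radius=CORTEX_INNER_RADIUS,
        )
    for name, cortex in (("model2_healthy", HEALTHY_CORTEX), ("model2_osteo", OSTEO_CORTEX)):
        models[name] = LayeredCylinderSpec(
            layers=(_marrow_layer(), Layer(CORTEX_OUTER_RADIUS, cortex, "cortex"))
        )
    models["model2ext_healthy"] = _trilayer(HEALTHY_CORTEX)
    models["model2ext_osteo"] = _trilayer(OSTEO_CORTEX)
    models["model3_healthy"] = _trilayer(HEALTHY_CORTEX)
    for label, cortex in _DEGRADED_CORTEX.items():
        models[f"model3_{label}"] = _trilayer(cortex)
    return models
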