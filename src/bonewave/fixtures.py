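"""Randomised layered-cylinder fixtures for property-based testing.

The generator spans the parameter envelope of the built-in bone models
(radii 3–20 mm, E 5–20 GPa, ν 0.25–0.45, ρ 1000–2500 kg/m³) and is
deterministic for a given seed.  Randomness lives only here: the
physics pipeline itself has no stochastic steps.
"""

from __future__ import annotations

import numpy as np

from .materials import ElasticIsotropic, Layer, LayeredCylinderSpec

__all__ = ["random_waveguide_fixture"]

_TAGS = {1: ("cortex",), 2: ("cortex", "tissue"), 3: ("marrow", "cortex", "tissue")}

#: layers thinner than this are not meshable at sensible element sizes
MIN_THICKNESS = 1.5e-3


def random_waveguide_fixture(seed: int) -> LayeredCylinderSpec:
    """A deterministic-for-seed 1–3 layer elastic cylinder spec."""
    rng = np.random.default_rng(seed)
    n_layers = int(rng.integers(1, 4))
    hollow = bool(rng.integers(0, 2))
    inner = float(rng.uniform(3e-3, 8e-3)) if hollow else 0.0
    lo = inner if hollow else 0.0
    if not hollow:
        # solid core: give the first layer enough radius to mesh
        lo = 0.0
    radii = []
    r = max(lo, 3e-3 if not hollow else lo)
    for _ in range(n_layers):
        r = r + float(rng.uniform(MIN_THICKNESS, 6e-3))
        radii.append(min(r, 20e-3))
    # enforce strict increase after clipping at 20 mm
    for i in range(1, len(radii)):
        if radii[i] <= radii[i - 1]:
            radii[i] = radii[i - 1] + MIN_THICKNESS
    layers = []
    for r, tag in zip(radii, _TAGS[n_layers]):
        mat = ElasticIsotropic(
            young_modulus=float(rng.uniform(5e9, 20e9)),
            poisson_ratio=float(rng.uniform(0.25, 0.45)),
            density=float(rng.uniform(1000.0, 2500.0)),
        )
        layers.append(Layer(outer_radius=r, material=mat, region_tag=tag))
    return LayeredCylinderSpec(layers=tuple(layers), inner_radius=inner)
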