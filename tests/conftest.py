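"""Shared fixtures: small meshes and pre-solved mode sets.

Everything here is generated at run time; the expensive trilayer study
used by the acceptance tests lives in test_acceptance.py.
"""

from __future__ import annotations

import numpy as np
import pytest

from bonewave.materials import (
    ElasticIsotropic,
    Layer,
    LayeredCylinderSpec,
    builtin_models,
)
from bonewave.mesh import mesh_layered_annulus
from bonewave.solver import assemble_operators, filter_physical, solve_wavenumbers

ROD_MATERIAL = ElasticIsotropic(14.95e9, 0.31, 2300.0)


@pytest.fixture(scope="session")
def rod_spec() -> LayeredCylinderSpec:
    """Solid isotropic rod, radius 5 mm, healthy-cortex material."""
    return LayeredCylinderSpec(
        layers=(Layer(5e-3, ROD_MATERIAL, "cortex"),)
    )


@pytest.fixture(scope="session")
def rod_mesh(rod_spec):
    return mesh_layered_annulus(rod_spec, 1.2e-3)


@pytest.fixture(scope="session")
def rod_modes_low_freq(rod_spec, rod_mesh):
    """Rod modes at 5 kHz (ka ≈ 0.06, deep thin-rod regime)."""
    ops = assemble_operators(rod_mesh, rod_spec.material_by_region(), 2 * np.pi * 5e3)
    modes = solve_wavenumbers(ops, n_modes=12, v_ph_window=(800.0, 6000.0), n_shifts=2)
    return ops, modes


@pytest.fixture(scope="session")
def free_tube_spec() -> LayeredCylinderSpec:
    return builtin_models()["model1_free"]


@pytest.fixture(scope="session")
def free_tube_mesh(free_tube_spec):
    return mesh_layered_annulus(free_tube_spec, 1.5e-3)


@pytest.fixture(scope="session")
def free_tube_modes_100k(free_tube_spec, free_tube_mesh):
    """Retained modes of the free validation tube at 100 kHz."""
    ops = assemble_operators(
        free_tube_mesh, free_tube_spec.material_by_region(), 2 * np.pi * 100e3
    )
    modes = filter_physical(
        solve_wavenumbers(ops, n_modes=40, v_ph_window=(1200.0, 9000.0), n_shifts=3)
    )
    return ops, modes
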