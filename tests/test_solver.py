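"""SAFE assembly and quadratic eigensolve: structure, oracles, contracts."""

import math

import numpy as np
import pytest
import scipy.linalg as sla
import scipy.sparse as sp

from bonewave.materials import ElasticIsotropic, Layer, LayeredCylinderSpec
from bonewave.mesh import mesh_layered_annulus
from bonewave.solver import (
    ModeSolution,
    assemble_operators,
    element_bmatrices,
    filter_physical,
    solve_wavenumbers,
)

from conftest import ROD_MATERIAL


class TestAssembly:
    def test_element_operator_dimensions(self, rod_mesh):
        B1, B2, wdet, dofmap = element_bmatrices(rod_mesh)
        # 6 nodes × 3 displacement components = 18 element dofs
        assert B1.shape[-2:] == (6, 18)
        assert B2.shape[-2:] == (6, 18)
        assert dofmap.shape[1] == 18

    def test_rigid_axial_translation_has_zero_in_plane_energy(self, rod_modes_low_freq):
        ops, _ = rod_modes_low_freq
        q = np.zeros(ops.ndof, dtype=complex)
        q[2::3] = 1.0  # constant axial displacement
        scale = abs(ops.K1).max() * np.linalg.norm(q)
        assert np.linalg.norm(ops.K1 @ q) < 1e-10 * scale

    def test_lossless_operators_symmetric(self, rod_modes_low_freq):
        ops, _ = rod_modes_low_freq
        def max_entry(mat):
            coo = mat.tocoo()
            return abs(coo.data).max() if coo.nnz else 0.0

        for name, K in (("K1", ops.K1), ("K3", ops.K3), ("M", ops.M)):
            assert max_entry(K - K.T) < 1e-9 * max_entry(K), name
            assert max_entry(K.imag) == 0.0, name  # lossless: real operators
        assert max_entry(ops.K2 + ops.K2.T) < 1e-9 * max_entry(ops.K2)

    def test_mass_positive_definite(self, rod_modes_low_freq):
        ops, _ = rod_modes_low_freq
        rng = np.random.default_rng(0)
        for _ in range(5):
            v = rng.standard_normal(ops.ndof)
            assert (v @ (ops.M @ v)).real > 0

    def test_missing_material_rejected(self, rod_mesh):
        with pytest.raises(KeyError, match="cortex"):
            assemble_operators(rod_mesh, {}, 2 * np.pi * 1e4)

    def test_nonpositive_frequency_rejected(self, rod_mesh, rod_spec):
        with pytest.raises(ValueError):
            assemble_operators(rod_mesh, rod_spec.material_by_region(), 0.0)


class TestRodOracles:
    def test_fundamental_longitudinal_is_bar_velocity(self, rod_modes_low_freq):
        """Thin-rod limit: L(0,1) phase velocity → sqrt(E/ρ) within 1 %."""
        _, modes = rod_modes_low_freq
        bar = math.sqrt(ROD_MATERIAL.young_modulus / ROD_MATERIAL.density)
        longitudinal = [
            m for m in modes if m.circumferential_order == 0 and not m.torsional
        ]
        assert longitudinal, "no axisymmetric longitudinal mode retained"
        closest = min(longitudinal, key=lambda m: abs(m.v_ph - bar))
        assert closest.v_ph == pytest.approx(bar, rel=0.01)

    def test_fundamental_torsional_is_shear_speed(self, rod_modes_low_freq):
        _, modes = rod_modes_low_freq
        torsional = [m for m in modes if m.torsional]
        assert torsional
        assert torsional[0].v_ph == pytest.approx(ROD_MATERIAL.shear_speed, rel=5e-3)

    def test_residuals_below_threshold(self, rod_modes_low_freq):
        ops, modes = rod_modes_low_freq
        for m in modes:
            assert ops.residual(m.k, m.eigvec) < 1e-8

    def test_lossless_modes_have_negligible_attenuation(self, rod_modes_low_freq):
        _, modes = rod_modes_low_freq
        for m in modes:
            assert abs(m.k.imag) < 1e-6 * abs(m.k.real)


class TestSpectralSymmetry:
    def test_plus_minus_k_pairs_on_lossless_tube(self):
        """Real lossless pencil: eigenvalues come in ±k pairs."""
        spec = LayeredCylinderSpec(
            layers=(Layer(5e-3, ElasticIsotropic(10e9, 0.3, 2000.0), "cortex"),),
            inner_radius=2.5e-3,
        )
        mesh = mesh_layered_annulus(spec, 2.4e-3)
        ops = assemble_operators(mesh, spec.material_by_region(), 2 * np.pi * 5e4)
        n = ops.ndof
        K0 = (ops.K1 - ops.omega**2 * ops.M).toarray()
        A = np.block(
            [[np.zeros((n, n)), np.eye(n)], [-K0, -1j * ops.K2.toarray()]]
        )
        B = np.block(
            [[np.eye(n), np.zeros((n, n))], [np.zeros((n, n)), ops.K3.toarray()]]
        )
        vals = sla.eig(A, B, right=False)
        finite = vals[np.isfinite(vals)]
        propagating = finite[
            (abs(finite.imag) < 1e-6 * abs(finite)) & (abs(finite.real) > 1.0)
        ]
        for k in propagating:
            partner = finite[np.argmin(abs(finite + k))]
            assert abs(partner + k) < 1e-6 * abs(k)


class TestSolveContracts:
    def test_empty_window_returns_empty_list(self, rod_modes_low_freq):
        ops, _ = rod_modes_low_freq
        assert solve_wavenumbers(ops, n_modes=8, v_ph_window=(100.0, 110.0)) == []

    def test_invalid_arguments(self, rod_modes_low_freq):
        ops, _ = rod_modes_low_freq
        with pytest.raises(ValueError):
            solve_wavenumbers(ops, n_modes=0)
        with pytest.raises(ValueError):
            solve_wavenumbers(ops, v_ph_window=(500.0, 100.0))

    def test_deterministic_repeat(self, rod_spec, rod_mesh):
        ops = assemble_operators(rod_mesh, rod_spec.material_by_region(), 2 * np.pi * 5e3)
        a = solve_wavenumbers(ops, n_modes=8, v_ph_window=(800.0, 6000.0), n_shifts=2)
        b = solve_wavenumbers(ops, n_modes=8, v_ph_window=(800.0, 6000.0), n_shifts=2)
        assert [m.k for m in a] == [m.k for m in b]
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.eigvec, mb.eigvec)

    def test_unit_power_normalisation(self, free_tube_modes_100k):
        _, modes = free_tube_modes_100k
        for m in modes:
            assert sum(m.power_by_region.values()) == pytest.approx(1.0, abs=1e-6)


class TestFilterPhysical:
    @staticmethod
    def _mode(k, solid=1.0):
        return ModeSolution(
            omega=1.0, k=k, eigvec=np.ones(3), v_ph=1.0 / k.real,
            attenuation=abs(k.imag), solid_power_fraction=solid,
        )

    def test_high_attenuation_ratio_rejected(self):
        noisy = self._mode(10 + 100j)
        clean = self._mode(100 + 0.1j)
        assert filter_physical([noisy, clean], max_att_ratio=1.0) == [clean]

    def test_fluid_borne_mode_rejected(self):
        marrow_bound = self._mode(100 + 0j, solid=0.1)
        guided = self._mode(100 + 0j, solid=0.9)
        kept = filter_physical([marrow_bound, guided], min_solid_power_fraction=0.5)
        assert kept == [guided]

    def test_ordering_preserved(self):
        modes = [self._mode(100 + 0j), self._mode(50 + 0j), self._mode(200 + 0j)]
        assert filter_physical(modes) == modes
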