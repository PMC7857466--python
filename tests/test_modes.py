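"""Mode classification, branch tracking and group velocity."""

import numpy as np
import pytest

from bonewave.modes import (
    Branch,
    BranchSample,
    circumferential_order,
    group_velocity,
    label_modes,
    mac,
    track_branches,
)
from bonewave.solver import DispersionSet, ModeSolution


def synthetic_mode(mesh, ur_fn=None, ut_fn=None, uz_fn=None, k=100 + 0j, omega=1e5):
    """Build a ModeSolution with a prescribed cylindrical displacement field."""
    x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
    theta = np.arctan2(y, x)
    ur = ur_fn(theta) if ur_fn else np.zeros_like(theta)
    ut = ut_fn(theta) if ut_fn else np.zeros_like(theta)
    uz = uz_fn(theta) if uz_fn else np.zeros_like(theta)
    vec = np.zeros(3 * len(x), dtype=complex)
    vec[0::3] = ur * np.cos(theta) - ut * np.sin(theta)
    vec[1::3] = ur * np.sin(theta) + ut * np.cos(theta)
    vec[2::3] = uz
    return ModeSolution(
        omega=omega, k=k, eigvec=vec, v_ph=omega / k.real, attenuation=abs(k.imag)
    )


class TestCircumferentialOrder:
    def test_axisymmetric_field(self, rod_mesh):
        mode = synthetic_mode(rod_mesh, ur_fn=lambda th: np.ones_like(th))
        assert circumferential_order(mode, rod_mesh, 3e-3) == 0

    def test_third_harmonic(self, rod_mesh):
        mode = synthetic_mode(rod_mesh, ur_fn=lambda th: np.cos(3 * th))
        assert circumferential_order(mode, rod_mesh, 3e-3) == 3

    def test_rotating_harmonic(self, rod_mesh):
        mode = synthetic_mode(rod_mesh, ur_fn=lambda th: np.exp(2j * th))
        assert circumferential_order(mode, rod_mesh, 3e-3) == 2

    def test_torsional_flag_via_dominant_order(self, rod_mesh):
        from bonewave.solver import _dominant_order

        mode = synthetic_mode(rod_mesh, ut_fn=lambda th: np.ones_like(th))
        n, torsional = _dominant_order(rod_mesh, mode.eigvec, 3e-3)
        assert n == 0 and torsional

    def test_sampling_radius_outside_mesh(self, rod_mesh):
        mode = synthetic_mode(rod_mesh, ur_fn=lambda th: np.ones_like(th))
        with pytest.raises(ValueError, match="outside"):
            circumferential_order(mode, rod_mesh, 1.0)


class TestMac:
    def test_phase_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(50) + 1j * rng.standard_normal(50)
        assert mac(v, np.exp(0.7j) * v) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_vectors(self):
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([0.0, 1.0, 0.0])
        assert mac(a, b) == 0.0


def _fake_dispersion(freqs, vec_sets, rod_mesh):
    """DispersionSet from lists of (eigvec, v_ph) per frequency."""
    slices = []
    for f, vecs in zip(freqs, vec_sets):
        slices.append(
            [
                ModeSolution(
                    omega=2 * np.pi * f, k=2 * np.pi * f / v + 0j, eigvec=vec,
                    v_ph=v, attenuation=0.0, circumferential_order=0,
                )
                for vec, v in vecs
            ]
        )
    return DispersionSet(np.asarray(freqs, float), slices, rod_mesh, {})


class TestTracking:
    def test_single_frequency_one_branch_per_mode(self, rod_mesh):
        rng = np.random.default_rng(2)
        vecs = [(rng.standard_normal(12), 2000.0 + i) for i in range(4)]
        ds = _fake_dispersion([1e4], [vecs], rod_mesh)
        branches = track_branches(ds)
        assert len(branches) == 4
        assert all(len(b.samples) == 1 for b in branches)

    def test_permutation_recovered_under_noise(self, rod_mesh):
        """Eigenvector permutation plus 1 % noise must not confuse matching."""
        rng = np.random.default_rng(3)
        basis, _ = np.linalg.qr(rng.standard_normal((30, 5)))
        perm = [3, 0, 4, 1, 2]
        first = [(basis[:, i], 2000.0 + 10 * i) for i in range(5)]
        second = [
            (basis[:, i] + 0.01 * rng.standard_normal(30), 2100.0 + 10 * i)
            for i in perm
        ]
        ds = _fake_dispersion([1e4, 2e4], [first, second], rod_mesh)
        branches = track_branches(ds, mac_threshold=0.7)
        assert len(branches) == 5
        for br in branches:
            assert len(br.samples) == 2  # every mode continued its branch
        # the branch carrying basis vector i at f1 must carry it at f2 too
        for br in branches:
            i0 = round((br.samples[0].v_ph - 2000.0) / 10.0)
            i1 = round((br.samples[1].v_ph - 2100.0) / 10.0)
            assert i1 == i0

    def test_partition_property(self, rod_mesh):
        rng = np.random.default_rng(4)
        sets = [
            [(rng.standard_normal(20), 1500.0 + 100 * i) for i in range(3)]
            for _ in range(4)
        ]
        ds = _fake_dispersion([1e4, 2e4, 3e4, 4e4], sets, rod_mesh)
        branches = track_branches(ds)
        total = sum(len(b.samples) for b in branches)
        assert total == 12  # every mode in exactly one branch


def _bare_branch(n, torsional, f0, v0, nfreq=3):
    samples = [
        BranchSample(
            frequency_hz=f0 + 1e4 * i, k=1.0 + 0j, v_ph=v0, attenuation=0.0,
            cortex_power_fraction=0.5, solid_power_fraction=1.0,
        )
        for i in range(nfreq)
    ]
    return Branch(circumferential_order=n, torsional=torsional, samples=samples)


class TestLabelling:
    def test_families_and_ordering(self):
        branches = [
            _bare_branch(0, False, 1e4, 2500.0),   # L, appears first
            _bare_branch(0, False, 5e4, 4000.0),   # L, appears later -> m=2
            _bare_branch(0, True, 1e4, 1800.0),    # torsional
            _bare_branch(1, False, 1e4, 900.0),    # F(1,1)
            _bare_branch(1, False, 1e4, 3100.0),   # same appearance, higher v -> F(1,2)
            _bare_branch(2, False, 3e4, 1100.0),   # F(2,1)
        ]
        label_modes(branches)
        assert [b.label for b in branches] == [
            "L(0,1)", "L(0,2)", "T(0,1)", "F(1,1)", "F(1,2)", "F(2,1)"
        ]

    def test_single_branch_gets_m1(self):
        br = _bare_branch(4, False, 2e4, 2000.0)
        label_modes([br])
        assert br.label == "F(4,1)"


class TestGroupVelocity:
    def test_nondispersive_branch(self):
        c = 2500.0
        freqs = np.linspace(1e4, 1e5, 10)
        samples = [
            BranchSample(
                frequency_hz=f, k=2 * np.pi * f / c + 0j, v_ph=c, attenuation=0.0,
                cortex_power_fraction=0.5, solid_power_fraction=1.0,
            )
            for f in freqs
        ]
        br = Branch(0, False, samples)
        v_g = group_velocity(br)
        assert v_g == pytest.approx(np.full_like(freqs, c), rel=1e-9)
        assert all(s.v_g == pytest.approx(c, rel=1e-9) for s in br.samples)

    def test_cut_off_branch_matches_closed_form(self):
        """k = sqrt(ω² − ω_c²)/c  ⇒  v_g = c² Re k / ω."""
        c, f_c = 3000.0, 4e4
        freqs = np.linspace(5e4, 2e5, 61)
        omega = 2 * np.pi * freqs
        omega_c = 2 * np.pi * f_c
        k = np.sqrt(omega**2 - omega_c**2) / c
        samples = [
            BranchSample(
                frequency_hz=f, k=kk + 0j, v_ph=w / kk, attenuation=0.0,
                cortex_power_fraction=0.5, solid_power_fraction=1.0,
            )
            for f, w, kk in zip(freqs, omega, k)
        ]
        v_g = group_velocity(Branch(0, False, samples))
        exact = c**2 * k / omega
        assert v_g[1:-1] == pytest.approx(exact[1:-1], rel=5e-3)

    def test_too_few_samples_rejected(self):
        br = _bare_branch(0, False, 1e4, 2000.0, nfreq=2)
        with pytest.raises(ValueError):
            group_velocity(br)
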