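"""SAFE operator assembly and the quadratic wavenumber eigenproblem.

The cross-section is meshed with quadratic triangles; the axial
dependence is the analytic factor e^{i(k x3 - ω t)}.  Galerkin assembly
yields the quadratic pencil

    [K1 + i k K2 + k² K3 − ω² M] q = 0

with K1 = ∫B1ᵀCB1, K2 = ∫(B1ᵀCB2 − B2ᵀCB1) (skew for symmetric C),
K3 = ∫B2ᵀCB2 and the consistent mass M; B1 carries the in-plane
derivatives and B2 the axial (ik) terms of the strain operator.  The
pencil is linearised in companion form of doubled size and solved by
shift-invert Arnoldi around targets inside the requested phase-velocity
window.

For lossless sections the operators are real, the spectrum is symmetric
under k → −k, and retained propagating modes have real k; dissipative
moduli (Im ≤ 0 under this convention) move forward modes to Im k ≥ 0.

Flexural modes of an axisymmetric section come in exactly degenerate
cos/sin pairs.  Each pair is collapsed to a single canonical
rotating-wave representative (pure e^{+inθ} azimuthal content, fixed
phase) so that modal-assurance-criterion tracking across frequency is
well defined.
"""

from __future__ import annotations

import weakref
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import QUAD_POINTS, QUAD_WEIGHTS, geometry, shape_functions
from .materials import FluidLayerMaterial, MaterialModel
from .mesh import CrossSectionMesh
from .rings import harmonic_coefficient, sample_ring

__all__ = [
    "AssembledOperators",
    "ModeSolution",
    "DispersionSet",
    "assemble_operators",
    "solve_wavenumbers",
    "filter_physical",
    "isotropic_stiffness",
    "element_bmatrices",
]

#: Voigt order used throughout: [xx, yy, zz, yz, xz, xy].
VOIGT = ("xx", "yy", "zz", "yz", "xz", "xy")


class SolverError(RuntimeError):
    """Eigensolver failure; carries the shift that was being used."""


def isotropic_stiffness(lam: complex, mu: complex) -> np.ndarray:
    """6×6 Voigt stiffness of an isotropic solid with Lamé constants (λ, μ)."""
    C = np.zeros((6, 6), dtype=complex)
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2.0 * mu
    C[3, 3] = C[4, 4] = C[5, 5] = mu
    return C


_BMAT_CACHE = weakref.WeakKeyDictionary()


def element_bmatrices(mesh: CrossSectionMesh):
    """Strain-displacement factors for every element and quadrature point.

    Returns ``(B1, B2, wdet, dofmap)`` with shapes (e, q, 6, 18),
    (e, q, 6, 18), (e, q) and (e, 18).  The strain of a mode with
    nodal vector q_e is ε = (B1 + i k B2) q_e in Voigt order.
    Results are cached per mesh (the factors are frequency-independent).
    """
    cached = _BMAT_CACHE.get(mesh)
    if cached is not None:
        return cached
    coords = mesh.element_coords()
    dNdx, detJ = geometry(coords)  # (e,q,6,2), (e,q)
    N = shape_functions(QUAD_POINTS)  # (q,6)
    ne, nq = detJ.shape
    B1 = np.zeros((ne, nq, 6, 18))
    B2 = np.zeros((ne, nq, 6, 18))
    dNx = dNdx[..., 0]
    dNy = dNdx[..., 1]
    cols = np.arange(6)
    B1[:, :, 0, 3 * cols + 0] = dNx       # εxx ← ∂ux/∂x
    B1[:, :, 1, 3 * cols + 1] = dNy       # εyy ← ∂uy/∂y
    B1[:, :, 3, 3 * cols + 2] = dNy       # γyz ← ∂uz/∂y
    B1[:, :, 4, 3 * cols + 2] = dNx       # γxz ← ∂uz/∂x
    B1[:, :, 5, 3 * cols + 0] = dNy       # γxy ← ∂ux/∂y + ∂uy/∂x
    B1[:, :, 5, 3 * cols + 1] = dNx
    Nq = np.broadcast_to(N, (ne, nq, 6))
    B2[:, :, 2, 3 * cols + 2] = Nq        # εzz ← ik uz
    B2[:, :, 3, 3 * cols + 1] = Nq        # γyz ← ik uy
    B2[:, :, 4, 3 * cols + 0] = Nq        # γxz ← ik ux
    wdet = detJ * QUAD_WEIGHTS[None, :]
    dofmap = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 18)
    result = (B1, B2, wdet, dofmap)
    _BMAT_CACHE[mesh] = result
    return result


@dataclass(frozen=True)
class AssembledOperators:
    """The four SAFE operators at one angular frequency, plus context."""

    K1: sp.csr_matrix
    K2: sp.csr_matrix
    K3: sp.csr_matrix
    M: sp.csr_matrix
    omega: float
    mesh: CrossSectionMesh
    materials: dict[str, MaterialModel]

    @property
    def ndof(self) -> int:
        return self.K1.shape[0]

    def residual(self, k: complex, q: np.ndarray) -> float:
        """Relative residual ‖(K1 + ikK2 + k²K3 − ω²M) q‖ / scale."""
        r = self.K1 @ q + 1j * k * (self.K2 @ q) + k**2 * (self.K3 @ q) \
            - self.omega**2 * (self.M @ q)
        scale = (
            _spnorm(self.K1) + abs(k) * _spnorm(self.K2)
            + abs(k) ** 2 * _spnorm(self.K3) + self.omega**2 * _spnorm(self.M)
        )
        return float(np.linalg.norm(r) / (scale * np.linalg.norm(q)))


def _spnorm(a: sp.spmatrix) -> float:
    return float(abs(a).sum(axis=1).max())  # infinity norm


@dataclass
class ModeSolution:
    """One eigenpair at one frequency.

    ``v_ph = ω / Re k`` (m/s) and ``attenuation = |Im k|`` (Np/m).  The
    eigenvector is normalised to unit total axial power flow when that
    power is meaningfully positive; ``power_by_region`` then sums to 1.
    """

    omega: float
    k: complex
    eigvec: np.ndarray
    v_ph: float
    attenuation: float
    power_by_region: dict[str, float] = field(default_factory=dict)
    solid_power_fraction: float = float("nan")
    circumferential_order: int | None = None
    torsional: bool = False

    @property
    def frequency(self) -> float:
        return self.omega / (2.0 * np.pi)

    @property
    def cortex_power_fraction(self) -> float:
        total = sum(self.power_by_region.values())
        return self.power_by_region.get("cortex", 0.0) / total if total else float("nan")


@dataclass
class DispersionSet:
    """Retained mode solutions on a strictly increasing frequency grid."""

    frequencies_hz: np.ndarray
    modes: list[list[ModeSolution]]
    mesh: CrossSectionMesh
    materials: dict[str, MaterialModel]

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        if f.size and not (np.diff(f) > 0).all():
            raise ValueError("frequencies must be strictly increasing")
        self.frequencies_hz = f


def assemble_operators(
    mesh: CrossSectionMesh,
    materials: dict[str, MaterialModel],
    omega: float,
) -> AssembledOperators:
    """Galerkin assembly of the SAFE pencil blocks at angular frequency ω."""
    if not omega > 0:
        raise ValueError("omega must be > 0")
    missing = set(mesh.region_tags) - set(materials)
    if missing:
        raise KeyError(f"no material supplied for region(s) {sorted(missing)}")

    B1, B2, wdet, dofmap = element_bmatrices(mesh)
    ndof = mesh.ndof
    K1 = sp.csr_matrix((ndof, ndof), dtype=complex)
    K2 = sp.csr_matrix((ndof, ndof), dtype=complex)
    K3 = sp.csr_matrix((ndof, ndof), dtype=complex)
    M = sp.csr_matrix((ndof, ndof), dtype=complex)
    N = shape_functions(QUAD_POINTS)

    for region in mesh.region_tags:
        mat = materials[region]
        lam, mu = mat.lame_at(omega)
        if not (np.isfinite(lam) and np.isfinite(mu) and np.isfinite(mat.density)):
            raise ValueError(f"non-finite material constants for region {region!r}")
        C = isotropic_stiffness(lam, mu)
        els = mesh.region_elements(region)
        b1, b2, w = B1[els], B2[els], wdet[els]

        def scatter(target, ke):
            r = np.repeat(dofmap[els], 18, axis=1).ravel()
            c = np.tile(dofmap[els], (1, 18)).ravel()
            return target + sp.csr_matrix((ke.ravel(), (r, c)), shape=(ndof, ndof))

        G11 = np.einsum("eqip,ij,eqjr,eq->epr", b1, C, b1, w, optimize=True)
        G12 = np.einsum("eqip,ij,eqjr,eq->epr", b1, C, b2, w, optimize=True)
        G21 = np.einsum("eqip,ij,eqjr,eq->epr", b2, C, b1, w, optimize=True)
        G22 = np.einsum("eqip,ij,eqjr,eq->epr", b2, C, b2, w, optimize=True)
        K1 = scatter(K1, G11)
        K2 = scatter(K2, G12 - G21)
        K3 = scatter(K3, G22)
        ms = np.einsum("qa,qb,eq->eab", N, N, w) * mat.density  # (e,6,6)
        me = np.einsum("eab,cd->eacbd", ms, np.eye(3)).reshape(-1, 18, 18)
        M = scatter(M, me.astype(complex))

    return AssembledOperators(
        K1=K1.tocsr(), K2=K2.tocsr(), K3=K3.tocsr(), M=M.tocsr(),
        omega=omega, mesh=mesh, materials=materials,
    )


# ---------------------------------------------------------------------------
# eigen solve


class _ShiftInvert:
    """Shift-invert operator for the companion linearisation.

    With z = [q; kq] the companion pencil A z = k B z has
    A = [[0, I], [−K0, −iK2]] and B = diag(I, K3), K0 = K1 − ω²M.
    Applying (A − σB)⁻¹B needs only an LU factorisation of the n×n
    evaluated pencil P(σ) = K1 + iσK2 + σ²K3 − ω²M (block
    elimination), not of the doubled companion matrix.
    """

    def __init__(self, ops: AssembledOperators, sigma: complex):
        self.sigma = sigma
        self.K3 = ops.K3.tocsr()
        self.Q = (1j * ops.K2 + sigma * ops.K3).tocsr()
        P = ops.K1 + 1j * sigma * ops.K2 + sigma**2 * ops.K3 - ops.omega**2 * ops.M
        try:
            self.lu = spla.splu((-P).tocsc())
        except RuntimeError as exc:
            raise SolverError(f"factorisation failed at shift {sigma}") from exc
        self.n = ops.ndof

    def matvec(self, x: np.ndarray) -> np.ndarray:
        n = self.n
        y1, y2 = x[:n], self.K3 @ x[n:]
        z1 = self.lu.solve(y2 + self.Q @ y1)
        z2 = y1 + self.sigma * z1
        return np.concatenate([z1, z2])

    def operator(self) -> spla.LinearOperator:
        return spla.LinearOperator(
            (2 * self.n, 2 * self.n), matvec=self.matvec, dtype=complex
        )


def _default_sampling_radius(mesh: CrossSectionMesh) -> float:
    """Mid-radius of the cortex layer, else 3/4 of the outer radius."""
    tags = list(mesh.region_tags)
    rings = sorted(mesh.boundary_rings)
    bounds = rings if len(rings) == len(tags) + 1 else [0.0] + rings
    if "cortex" in tags:
        i = tags.index("cortex")
        return 0.5 * (bounds[i] + bounds[i + 1])
    return 0.75 * bounds[-1]


def _dominant_order(mesh: CrossSectionMesh, vec: np.ndarray, radius: float) -> tuple[int, bool]:
    """Dominant |n| on the sampling ring and a torsional flag for n = 0."""
    _, ur, ut, uz = sample_ring(mesh, vec, radius)
    m = len(ur)
    spec = (
        np.abs(np.fft.fft(ur)) ** 2
        + np.abs(np.fft.fft(ut)) ** 2
        + np.abs(np.fft.fft(uz)) ** 2
    )
    half = m // 2
    folded = spec[: half + 1].copy()
    folded[1:half] += spec[m - half + (half - np.arange(1, half))]  # add −n bins
    n = int(np.argmax(folded))
    torsional = False
    if n == 0:
        t_power = np.abs(ut).sum()
        lr_power = np.abs(ur).sum() + np.abs(uz).sum()
        torsional = bool(t_power > lr_power)
    return n, torsional


def _phase_fix(mesh, vec, n, radius):
    """Rotate the global phase so the +n ring harmonic of u_r (or u_z) is real > 0."""
    _, ur, ut, uz = sample_ring(mesh, vec, radius)
    for comp in (ur, uz, ut):
        c = harmonic_coefficient(comp, n)
        if abs(c) > 1e-9 * (np.abs(comp).max() + 1e-300):
            return vec * (np.conj(c) / abs(c))
    return vec


def _canonical_rotating(mesh, vecs, n, radius):
    """Combine a degenerate cos/sin pair into a pure e^{+inθ} rotating wave."""
    rows = []
    for v in vecs[:2]:
        _, ur, ut, uz = sample_ring(mesh, v, radius)
        rows.append([harmonic_coefficient(c, -n) for c in (ur, ut, uz)])
    Bm = np.array(rows, dtype=complex).T  # (3 components, 2 vectors)
    _, _, vh = np.linalg.svd(Bm)
    c = vh[-1].conj()
    v = c[0] * vecs[0] + c[1] * vecs[1]
    nv = np.linalg.norm(v)
    if nv < 1e-12 * max(np.linalg.norm(vecs[0]), 1e-300):
        v = vecs[0]
    return _phase_fix(mesh, v / np.linalg.norm(v), n, radius)


def solve_wavenumbers(
    ops: AssembledOperators,
    n_modes: int = 80,
    v_ph_window: tuple[float, float] = (1500.0, 9000.0),
    n_shifts: int = 4,
    dedupe_rtol: float = 1e-5,
    sampling_radius: float | None = None,
) -> list[ModeSolution]:
    """Solve the quadratic pencil for wavenumbers in a phase-velocity window.

    The companion linearisation is solved by shift-invert Arnoldi at
    ``n_shifts`` targets spread over the wavenumber window
    [ω/v_max, ω/v_min]; results are merged, degenerate flexural pairs
    collapsed to canonical rotating representatives, eigenvectors
    normalised to unit total axial power flow, and the retained forward
    modes (Re k > 0) returned sorted by attenuation then phase velocity.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    v_lo, v_hi = v_ph_window
    if not (0 < v_lo < v_hi):
        raise ValueError("v_ph_window bounds must be positive and increasing")
    omega = ops.omega
    k_lo, k_hi = omega / v_hi, omega / v_lo
    per_shift = max(8, int(np.ceil(1.6 * n_modes / n_shifts)))
    per_shift = min(per_shift, 2 * ops.ndof - 2)

    pairs: list[tuple[complex, np.ndarray]] = []
    fractions = np.linspace(0.15, 0.85, n_shifts)
    # fixed start vector: the physics is deterministic, so the Arnoldi
    # iteration must be too (ARPACK would otherwise seed randomly)
    v0 = np.random.default_rng(20170506).standard_normal(2 * ops.ndof)
    for frac in fractions:
        sigma = (k_lo + frac * (k_hi - k_lo)) * (1.0 + 1e-3j)
        op = _ShiftInvert(ops, sigma).operator()
        try:
            vals, vecs = spla.eigs(op, k=per_shift, which="LM", tol=1e-10, v0=v0)
        except spla.ArpackNoConvergence as exc:
            raise SolverError(f"Arnoldi did not converge at shift {sigma}") from exc
        ks = sigma + 1.0 / vals
        for kk, zz in zip(ks, vecs.T):
            pairs.append((complex(kk), zz[: ops.ndof].copy()))

    # forward modes inside the window
    kept = []
    for kk, q in pairs:
        if kk.real <= 0:
            continue
        v_ph = omega / kk.real
        if not (v_lo <= v_ph <= v_hi):
            continue
        if kk.imag < -1e-6 * abs(kk):
            continue  # growing along +x3: backward partner
        kept.append((kk, q))
    if not kept:
        return []

    kept.sort(key=lambda p: p[0].real)
    radius = sampling_radius if sampling_radius is not None else _default_sampling_radius(ops.mesh)

    groups: list[list[tuple[complex, np.ndarray]]] = []
    for kk, q in kept:
        if groups and abs(kk - groups[-1][-1][0]) <= dedupe_rtol * abs(kk):
            groups[-1].append((kk, q))
        else:
            groups.append([(kk, q)])

    from . import powerflow  # deferred: powerflow imports this module's types

    modes: list[ModeSolution] = []
    for grp in groups:
        kk = grp[0][0]
        vecs = [q / np.linalg.norm(q) for _, q in grp]
        n, torsional = _dominant_order(ops.mesh, vecs[0], radius)
        if len(vecs) >= 2 and n > 0:
            vec = _canonical_rotating(ops.mesh, vecs, n, radius)
        else:
            vec = _phase_fix(ops.mesh, vecs[0], n, radius)
        mode = ModeSolution(
            omega=omega, k=kk, eigvec=vec,
            v_ph=omega / kk.real, attenuation=abs(kk.imag),
            circumferential_order=n, torsional=torsional,
        )
        br = powerflow.power_breakdown(mode, ops.materials, ops.mesh)
        if br.total > 0:
            mode.eigvec = vec / np.sqrt(br.total)
            per = {r: p / br.total for r, p in br.per_region.items()}
        else:
            per = dict(br.per_region)
        mode.power_by_region = per
        solid = [
            r for r in ops.mesh.region_tags
            if not isinstance(ops.materials[r], FluidLayerMaterial)
        ]
        tot = sum(per.values())
        mode.solid_power_fraction = (
            sum(per[r] for r in solid) / tot if tot else float("nan")
        )
        modes.append(mode)

    modes.sort(key=lambda m: (m.attenuation, m.v_ph))
    return modes


def filter_physical(
    modes: Sequence[ModeSolution],
    max_att_ratio: float = 0.1,
    min_solid_power_fraction: float = 0.5,
) -> list[ModeSolution]:
    """Keep weakly attenuated modes guided by the solid (bone + tissue).

    A mode survives when ``|Im k| / |Re k| <= max_att_ratio`` and the
    fraction of its axial power carried by non-fluid regions is at least
    ``min_solid_power_fraction``.  Ordering is preserved.
    """
    out = []
    for m in modes:
        if abs(m.k.imag) > max_att_ratio * abs(m.k.real):
            continue
        frac = m.solid_power_fraction
        if np.isfinite(frac) and frac < min_solid_power_fraction:
            continue
        out.append(m)
    return out
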