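"""Time-averaged axial power flow of SAFE modes.

The axial Poynting component of a time-harmonic mode is

    P_x3 = −Re[ (iω/2) (u1* σ31 + u2* σ32 + u3* σ33) ]

with stresses recovered from the eigenvector through the constitutive
law and the (ik) axial-derivative rule, evaluated at quadrature points
(no nodal averaging, so material interfaces are not smeared).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import QUAD_POINTS, shape_functions
from .mesh import CrossSectionMesh

__all__ = [
    "PowerBreakdown",
    "axial_poynting_density",
    "regional_power",
    "power_breakdown",
    "normalized_cortex_power_table",
]


@dataclass(frozen=True)
class PowerBreakdown:
    """Total axial power of a mode and its split across regions (W per
    unit eigenvector normalisation)."""

    total: float
    per_region: dict[str, float]

    @property
    def cortex_fraction(self) -> float:
        return self.per_region.get("cortex", 0.0) / self.total if self.total else float("nan")


def _mode_fields(mode, materials, mesh: CrossSectionMesh):
    """(u, sigma_axial, wdet) at quadrature points for every element."""
    from .solver import element_bmatrices, isotropic_stiffness

    B1, B2, wdet, dofmap = element_bmatrices(mesh)
    q = np.asarray(mode.eigvec)[dofmap]  # (e, 18)
    eps = np.einsum("eqip,ep->eqi", B1, q) + 1j * mode.k * np.einsum(
        "eqip,ep->eqi", B2, q
    )
    sig = np.empty_like(eps)
    for region in mesh.region_tags:
        lam, mu = materials[region].lame_at(mode.omega)
        C = isotropic_stiffness(lam, mu)
        els = mesh.region_elements(region)
        sig[els] = np.einsum("ij,eqj->eqi", C, eps[els])
    N = shape_functions(QUAD_POINTS)  # (q, 6)
    qn = q.reshape(q.shape[0], 6, 3)
    u = np.einsum("qa,eac->eqc", N, qn)  # (e, q, 3)
    return u, sig, wdet


def axial_poynting_density(mode, materials, mesh: CrossSectionMesh) -> np.ndarray:
    """Axial Poynting density (W/m²) at each (element, quadrature point)."""
    u, sig, _ = _mode_fields(mode, materials, mesh)
    # Voigt rows: 2 = zz (σ33), 3 = yz (σ32), 4 = xz (σ31)
    flux = (
        np.conj(u[..., 0]) * sig[..., 4]
        + np.conj(u[..., 1]) * sig[..., 3]
        + np.conj(u[..., 2]) * sig[..., 2]
    )
    return -np.real(0.5j * mode.omega * flux)


def regional_power(density: np.ndarray, mesh: CrossSectionMesh, region: str) -> float:
    """Quadrature integral of a per-(element, point) density over a region."""
    from .solver import element_bmatrices

    _, _, wdet, _ = element_bmatrices(mesh)
    els = mesh.region_elements(region)
    return float((density[els] * wdet[els]).sum())


def power_breakdown(mode, materials, mesh: CrossSectionMesh) -> PowerBreakdown:
    """Total and per-region axial power of one mode (single field pass)."""
    from .solver import element_bmatrices

    density = axial_poynting_density(mode, materials, mesh)
    _, _, wdet, _ = element_bmatrices(mesh)
    contrib = density * wdet
    per = {
        region: float(contrib[mesh.region_elements(region)].sum())
        for region in mesh.region_tags
    }
    return PowerBreakdown(total=float(contrib.sum()), per_region=per)


def normalized_cortex_power_table(branches, freqs_hz) -> dict[str, dict[float, float]]:
    """Cortex axial power per (branch, frequency), normalised to a unit maximum.

    Each eigenvector carries unit *total* cross-section power (the
    solver's normalisation), so the tabulated quantity is the scale-free
    cortex power fraction; every entry is then divided by the global
    maximum over all (branch, frequency) pairs, which becomes exactly 1.
    Branches missing a requested frequency simply have no entry there.
    """
    table: dict[str, dict[float, float]] = {}
    peak = 0.0
    for br in branches:
        row = {}
        for f in freqs_hz:
            s = br.sample_at(f)
            if s is not None and np.isfinite(s.cortex_power_fraction):
                row[float(f)] = s.cortex_power_fraction
                peak = max(peak, s.cortex_power_fraction)
        if row:
            table[br.label] = row
    if peak > 0:
        for row in table.values():
            for f in row:
                row[f] /= peak
    return table
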