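"""Analytic dispersion function for a single-layer elastic cylinder.

Independent oracle for the SAFE solver: the classical frequency
equation of a traction-free isotropic hollow cylinder (or solid rod),
built from the three scalar potentials

    φ = f(r) e^{i(nθ + kz − ωt)},          f ∈ {J_n(αr), Y_n(αr)}
    u = ∇φ + ∇×(χ ê_z) + ∇×∇×(ψ ê_z),     χ, ψ ∈ {J_n(βr), Y_n(βr)}

with α² = ω²/c_L² − k² and β² = ω²/c_T² − k².  The boundary rows
(σ_rr, σ_rθ, σ_rz at each free surface) are derived symbolically with
sympy and lambdified onto scipy's complex Bessel functions, so no
matrix entry is transcribed by hand.  A guided mode exists where the
boundary matrix is singular; roots are located as deep minima of its
smallest singular value (the determinant of the column-normalised
matrix changes phase freely for complex α, β, so singular values are
the robust indicator).

The potential basis degenerates where α = 0 or β = 0, i.e. at the bulk
speeds; a small neighbourhood of c_L and c_T is therefore excluded from
root acceptance.  The fundamental torsional mode is exactly v = c_T at
all frequencies and is checked in closed form instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar

from .materials import ElasticIsotropic

__all__ = ["HollowCylinder", "boundary_matrix", "singular_value_metric", "find_roots", "refine_root"]


@dataclass(frozen=True)
class HollowCylinder:
    """Free single-layer cylinder: ``inner_radius == 0`` means a solid rod."""

    inner_radius: float
    outer_radius: float
    material: ElasticIsotropic


@lru_cache(maxsize=1)
def _column_functions():
    """Lambdified traction rows (σ_rr, σ_rθ, σ_rz)/E for the six potentials."""
    import sympy as sy

    r, th, z = sy.symbols("r theta z", positive=True)
    n = sy.Symbol("n", integer=True, nonnegative=True)
    k, alpha, beta, lam, mu = sy.symbols("k alpha beta lamda mu")
    E = sy.exp(sy.I * (n * th + k * z))

    def tractions(u_r, u_t, u_z):
        e_rr = sy.diff(u_r, r)
        e_tt = u_r / r + sy.diff(u_t, th) / r
        e_zz = sy.diff(u_z, z)
        e_rt = (sy.diff(u_r, th) / r + sy.diff(u_t, r) - u_t / r) / 2
        e_rz = (sy.diff(u_r, z) + sy.diff(u_z, r)) / 2
        dil = e_rr + e_tt + e_zz
        return (
            lam * dil + 2 * mu * e_rr,  # σ_rr
            2 * mu * e_rt,              # σ_rθ
            2 * mu * e_rz,              # σ_rz
        )

    columns = []
    for bessel in (sy.besselj, sy.bessely):
        f = bessel(n, alpha * r) * E
        g = bessel(n, beta * r) * E
        # dilatational potential: u = ∇φ
        u_phi = (sy.diff(f, r), sy.diff(f, th) / r, sy.diff(f, z))
        # SH potential: u = ∇×(χ ê_z)
        u_chi = (sy.diff(g, th) / r, -sy.diff(g, r), sy.Integer(0))
        # SV potential: u = ∇×∇×(ψ ê_z) = ∇(∂ψ/∂z) − ê_z ∇²ψ
        lap = (
            sy.diff(g, r, 2) + sy.diff(g, r) / r
            + sy.diff(g, th, 2) / r**2 + sy.diff(g, z, 2)
        )
        u_psi = (
            sy.diff(g, r, z),
            sy.diff(g, th, z) / r,
            sy.diff(g, z, 2) - lap,
        )
        for u in (u_phi, u_chi, u_psi):
            rows = [sy.simplify(t / E) for t in tractions(*u)]
            columns.append(
                [
                    sy.lambdify((r, n, k, alpha, beta, lam, mu), row,
                                modules=["scipy", "numpy"])
                    for row in rows
                ]
            )
    return columns  # 6 columns (J then Y), each 3 row functions


def boundary_matrix(geom: HollowCylinder, f_hz: float, n: int, v_ph: float) -> np.ndarray:
    """Traction boundary matrix whose singularity marks a guided mode.

    6×6 for a hollow cylinder (both surfaces free), 3×3 for a solid rod
    (J-potentials only, outer surface free).
    """
    mat = geom.material
    lam, mu = mat.lame
    omega = 2.0 * np.pi * f_hz
    k = omega / v_ph
    alpha = np.sqrt(complex((omega / mat.longitudinal_speed) ** 2 - k**2))
    beta = np.sqrt(complex((omega / mat.shear_speed) ** 2 - k**2))
    cols = _column_functions()
    solid = geom.inner_radius == 0.0
    use_cols = cols[:3] if solid else cols
    radii = (geom.outer_radius,) if solid else (geom.outer_radius, geom.inner_radius)
    M = np.empty((3 * len(radii), len(use_cols)), dtype=complex)
    for j, col in enumerate(use_cols):
        for s, radius in enumerate(radii):
            for i, fn in enumerate(col):
                M[3 * s + i, j] = fn(radius, n, k, alpha, beta, lam, mu)
    return M


def singular_value_metric(geom: HollowCylinder, f_hz: float, n: int, v_ph: float) -> float:
    """Smallest singular value of the column-normalised boundary matrix."""
    M = boundary_matrix(geom, f_hz, n, v_ph)
    norms = np.abs(M).max(axis=0)
    norms[norms == 0] = 1.0
    s = np.linalg.svd(M / norms, compute_uv=False)
    return float(s[-1] / s[0])


def _bulk_exclusion(geom: HollowCylinder, v: float, margin: float = 15.0) -> bool:
    m = geom.material
    return (
        abs(v - m.longitudinal_speed) < margin or abs(v - m.shear_speed) < margin
    )


def refine_root(
    geom: HollowCylinder, f_hz: float, n: int, v_guess: float,
    half_width: float = 0.03,
) -> tuple[float, float]:
    """Polish a dispersion root near ``v_guess`` (± ``half_width`` relative).

    Returns ``(v_root, metric)`` where the metric is the smallest
    normalised singular value at the root; a genuine root drives it
    several orders of magnitude below its bracket-edge value.
    """
    lo, hi = v_guess * (1 - half_width), v_guess * (1 + half_width)
    grid = np.linspace(lo, hi, 121)
    vals = np.array([singular_value_metric(geom, f_hz, n, v) for v in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda v: singular_value_metric(geom, f_hz, n, v),
        bounds=(a, b), method="bounded",
        options={"xatol": 1e-4},
    )
    return float(res.x), float(res.fun)


def find_roots(
    geom: HollowCylinder, f_hz: float, n: int,
    v_window: tuple[float, float], step: float = 4.0,
    accept_ratio: float = 1e-3,
) -> list[float]:
    """Phase-velocity roots of the dispersion function in a window.

    Scans the window with ``step`` (m/s), refines every local minimum of
    the smallest-singular-value metric and accepts it as a root when the
    refined metric falls below ``accept_ratio`` times the window median.
    Neighbourhoods of the bulk speeds are excluded (degenerate basis).
    """
    lo, hi = v_window
    grid = np.arange(lo, hi + step, step)
    vals = np.array([singular_value_metric(geom, f_hz, n, v) for v in grid])
    med = float(np.median(vals))
    roots: list[float] = []
    for i in range(1, len(grid) - 1):
        if vals[i] <= vals[i - 1] and vals[i] <= vals[i + 1]:
            if _bulk_exclusion(geom, grid[i]):
                continue
            v, m = refine_root(geom, f_hz, n, float(grid[i]),
                               half_width=step / grid[i])
            if m < accept_ratio * med and not _bulk_exclusion(geom, v):
                if not roots or abs(v - roots[-1]) > step:
                    roots.append(v)
    return roots
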