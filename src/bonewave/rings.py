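"""Azimuthal sampling of nodal fields on vertex rings.

The structured mesh keeps full rings of vertices at fixed radii with
uniform azimuthal spacing, so a mode shape can be read off a ring
without interpolation and its circumferential harmonic content obtained
by a plain DFT.
"""

from __future__ import annotations

import numpy as np

from .mesh import CrossSectionMesh

__all__ = ["sample_ring", "azimuthal_spectrum", "harmonic_coefficient"]


def sample_ring(mesh: CrossSectionMesh, eigvec: np.ndarray, radius: float):
    """Cylindrical displacement components on the vertex ring nearest ``radius``.

    Returns ``(theta, u_r, u_theta, u_z)``, each of length ``n_theta``.
    ``eigvec`` is the interleaved (ux, uy, uz) nodal vector of length
    ``3 * n_nodes``.
    """
    r, ids = mesh.nearest_vertex_ring(radius)
    xy = mesh.nodes[ids]
    theta = np.arctan2(xy[:, 1], xy[:, 0])
    ux = eigvec[3 * ids]
    uy = eigvec[3 * ids + 1]
    uz = eigvec[3 * ids + 2]
    ur = ux * np.cos(theta) + uy * np.sin(theta)
    ut = -ux * np.sin(theta) + uy * np.cos(theta)
    return theta, ur, ut, uz


def azimuthal_spectrum(values: np.ndarray) -> np.ndarray:
    """Unnormalised azimuthal DFT coefficients c_n = Σ_j v_j e^{-i n θ_j} / N.

    Index ``n`` runs over ``numpy.fft.fftfreq`` ordering.
    """
    return np.fft.fft(values) / len(values)


def harmonic_coefficient(values: np.ndarray, n: int) -> complex:
    """Single azimuthal harmonic coefficient of order ``n`` (signed)."""
    m = len(values)
    return complex(azimuthal_spectrum(values)[n % m])
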