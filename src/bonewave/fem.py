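"""Reference-element machinery for 6-node (quadratic) triangles.

Node convention: corners 1-2-3 counter-clockwise, then midsides of
edges (1-2), (2-3), (3-1).  Elements are isoparametric: midside nodes
may be displaced onto circular interfaces, so the Jacobian is evaluated
per quadrature point.
"""

from __future__ import annotations

import numpy as np

__all__ = ["QUAD_POINTS", "QUAD_WEIGHTS", "shape_functions", "shape_gradients", "geometry"]

# 7-point degree-5 rule on the unit triangle (area 1/2), barycentric form.
_a = 0.059715871789770
_b = 0.470142064105115
_c = 0.797426985353087
_d = 0.101286507323456
QUAD_POINTS = np.array(
    [
        [1.0 / 3.0, 1.0 / 3.0],
        [_b, _b],
        [_a, _b],
        [_b, _a],
        [_d, _d],
        [_c, _d],
        [_d, _c],
    ]
)
QUAD_WEIGHTS = 0.5 * np.array(
    [
        0.225,
        0.132394152788506,
        0.132394152788506,
        0.132394152788506,
        0.125939180544827,
        0.125939180544827,
        0.125939180544827,
    ]
)


def shape_functions(xi: np.ndarray) -> np.ndarray:
    """P2 shape functions at reference points ``xi`` of shape (q, 2) -> (q, 6)."""
    xi = np.atleast_2d(xi)
    l2 = xi[:, 0]
    l3 = xi[:, 1]
    l1 = 1.0 - l2 - l3
    return np.stack(
        [
            l1 * (2 * l1 - 1),
            l2 * (2 * l2 - 1),
            l3 * (2 * l3 - 1),
            4 * l1 * l2,
            4 * l2 * l3,
            4 * l3 * l1,
        ],
        axis=1,
    )


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """Reference gradients dN/d(xi, eta) at points (q, 2) -> (q, 6, 2)."""
    xi = np.atleast_2d(xi)
    l2 = xi[:, 0]
    l3 = xi[:, 1]
    l1 = 1.0 - l2 - l3
    z = np.zeros_like(l1)
    d_dxi = np.stack(
        [1 - 4 * l1, 4 * l2 - 1, z, 4 * (l1 - l2), 4 * l3, -4 * l3], axis=1
    )
    d_deta = np.stack(
        [1 - 4 * l1, z, 4 * l3 - 1, -4 * l2, 4 * l2, 4 * (l1 - l3)], axis=1
    )
    return np.stack([d_dxi, d_deta], axis=2)


def geometry(coords: np.ndarray, xi: np.ndarray | None = None):
    """Per-element, per-quadrature-point geometry factors.

    Parameters
    ----------
    coords : (n_elem, 6, 2) physical node coordinates.
    xi : optional (q, 2) reference points; defaults to the quadrature rule.

    Returns
    -------
    dNdx : (n_elem, q, 6, 2) physical shape-function gradients.
    detJ : (n_elem, q) Jacobian determinants.
    """
    if xi is None:
        xi = QUAD_POINTS
    dN = shape_gradients(xi)  # (q, 6, 2)
    # J[e, q, i, j] = sum_a coords[e, a, i] * dN[q, a, j]
    J = np.einsum("eai,qaj->eqij", coords, dN)
    detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
    invJ = np.empty_like(J)
    invJ[..., 0, 0] = J[..., 1, 1]
    invJ[..., 1, 1] = J[..., 0, 0]
    invJ[..., 0, 1] = -J[..., 0, 1]
    invJ[..., 1, 0] = -J[..., 1, 0]
    invJ /= detJ[..., None, None]
    dNdx = np.einsum("qaj,eqji->eqai", dN, invJ)
    return dNdx, detJ
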