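"""Structured cross-section meshing of layered discs/annuli.

The mesher is deterministic: rings of vertices at fixed radii, a fixed
number of sectors, fan triangles around the centre (solid core) and
diagonal-split quads elsewhere.  Midside nodes of circumferential edges
are snapped onto their circle, so material interfaces are resolved by
(curved) element edges and no element straddles a boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from .fem import QUAD_WEIGHTS, geometry
from .materials import LayeredCylinderSpec

__all__ = ["CrossSectionMesh", "mesh_layered_annulus", "MeshError"]


class MeshError(ValueError):
    """Raised for invalid meshing requests (resolution, degenerate layers)."""


@dataclass(frozen=True, eq=False)
class CrossSectionMesh:
    """A conforming 6-node-triangle mesh of the waveguide cross-section.

    ``nodes`` is (n_nodes, 2) in metres; ``elements`` is (n_elem, 6)
    node indices; ``element_region`` holds one region tag per element.
    ``vertex_rings`` maps each vertex-ring radius to the ordered node
    indices of that ring (uniform in azimuth) — used for azimuthal
    sampling of mode shapes.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_region: np.ndarray
    boundary_rings: tuple[float, ...]
    region_tags: tuple[str, ...]
    vertex_rings: dict[float, np.ndarray] = field(repr=False, default_factory=dict)
    n_theta: int = 0

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def ndof(self) -> int:
        """Three displacement components per node."""
        return 3 * self.n_nodes

    def region_elements(self, region: str) -> np.ndarray:
        """Indices of the elements carrying ``region``."""
        if region not in self.region_tags:
            raise KeyError(f"unknown region tag {region!r}; have {self.region_tags}")
        return np.flatnonzero(self.element_region == region)

    def region_dof_mask(self, region: str) -> np.ndarray:
        """Global dof indices supported on ``region`` (3 per node)."""
        els = self.region_elements(region)
        node_ids = np.unique(self.elements[els])
        return (3 * node_ids[:, None] + np.arange(3)[None, :]).ravel()

    def element_coords(self, element_ids: np.ndarray | None = None) -> np.ndarray:
        ids = slice(None) if element_ids is None else element_ids
        return self.nodes[self.elements[ids]]

    def areas(self) -> np.ndarray:
        """Per-element areas from the quadrature rule (curved edges included)."""
        _, detJ = geometry(self.element_coords())
        return detJ @ QUAD_WEIGHTS

    def region_area(self, region: str) -> float:
        els = self.region_elements(region)
        _, detJ = geometry(self.element_coords(els))
        return float((detJ @ QUAD_WEIGHTS).sum())

    def nearest_vertex_ring(self, radius: float) -> tuple[float, np.ndarray]:
        """The vertex ring closest to ``radius`` and its node indices."""
        rs = np.array(sorted(self.vertex_rings))
        r = rs[np.argmin(np.abs(rs - radius))]
        return float(r), self.vertex_rings[r]


def _ring_radii(spec: LayeredCylinderSpec, h: float) -> list[float]:
    """Radii of the vertex rings, one list across all layers."""
    radii = [spec.inner_radius]
    lo = spec.inner_radius
    for layer in spec.layers:
        hi = layer.outer_radius
        n = max(1, math.ceil((hi - lo) / h - 1e-9))
        radii.extend(np.linspace(lo, hi, n + 1)[1:].tolist())
        lo = hi
    return radii


def mesh_layered_annulus(spec: LayeredCylinderSpec, target_element_size: float) -> CrossSectionMesh:
    """Mesh a layered disc/annulus with quadratic triangles.

    ``target_element_size`` bounds both the radial band height and the
    outer-circumference sector arc; it must not exceed the thinnest
    layer thickness (each layer needs at least one band of elements).
    """
    h = float(target_element_size)
    if not h > 0:
        raise MeshError("target_element_size must be > 0")
    thinnest = spec.thinnest_layer()
    if h > thinnest + 1e-12:
        raise MeshError(
            f"target_element_size {h:g} m exceeds the thinnest layer "
            f"thickness {thinnest:g} m; refine the mesh"
        )

    n_theta = max(12, math.ceil(2.0 * math.pi * spec.outer_radius / h))
    thetas = 2.0 * math.pi * np.arange(n_theta) / n_theta

    radii = _ring_radii(spec, h)
    # map each radial band to its layer tag
    band_tags: list[str] = []
    for lo, hi in zip(radii, radii[1:]):
        mid = 0.5 * (lo + hi)
        for layer, lo_l in zip(spec.layers, (spec.inner_radius,) + tuple(
            la.outer_radius for la in spec.layers[:-1]
        )):
            if lo_l - 1e-12 <= mid <= layer.outer_radius + 1e-12:
                band_tags.append(layer.region_tag)
                break
        else:  # pragma: no cover - bands are constructed inside layers
            raise MeshError("band outside all layers")

    nodes: list[tuple[float, float]] = []
    vertex_rings: dict[float, np.ndarray] = {}
    ring_ids: list[np.ndarray] = []
    centre_id = None
    if spec.inner_radius == 0.0:
        centre_id = 0
        nodes.append((0.0, 0.0))
        ring_ids.append(np.full(n_theta, centre_id))
    for r in radii:
        if r == 0.0:
            continue
        ids = np.arange(len(nodes), len(nodes) + n_theta)
        nodes.extend(zip(r * np.cos(thetas), r * np.sin(thetas)))
        ring_ids.append(ids)
        vertex_rings[float(r)] = ids

    corner_tris: list[tuple[int, int, int]] = []
    tri_tags: list[str] = []
    for band, tag in enumerate(band_tags):
        inner, outer = ring_ids[band], ring_ids[band + 1]
        for j in range(n_theta):
            jp = (j + 1) % n_theta
            if centre_id is not None and band == 0:
                corner_tris.append((centre_id, outer[j], outer[jp]))
                tri_tags.append(tag)
            else:
                a, b = inner[j], inner[jp]
                c, d = outer[jp], outer[j]
                corner_tris.append((a, b, c))
                corner_tris.append((a, c, d))
                tri_tags.extend((tag, tag))

    coords = np.asarray(nodes, dtype=float)
    # enforce counter-clockwise corners
    tris = np.asarray(corner_tris, dtype=np.int64)
    p = coords[tris]
    signed = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    flip = signed < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]

    # midside nodes per unique undirected edge
    radius_of = np.hypot(coords[:, 0], coords[:, 1])
    edge_mid: dict[tuple[int, int], int] = {}
    mid_coords: list[tuple[float, float]] = []

    def midside(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        idx = edge_mid.get(key)
        if idx is not None:
            return idx
        ra, rb = radius_of[a], radius_of[b]
        xm = 0.5 * (coords[a] + coords[b])
        if abs(ra - rb) < 1e-12 * max(ra, rb, 1.0) and ra > 0:
            # circumferential edge: snap midside onto the circle
            th = math.atan2(xm[1], xm[0])
            xm = np.array([ra * math.cos(th), ra * math.sin(th)])
        idx = coords.shape[0] + len(mid_coords)
        mid_coords.append((float(xm[0]), float(xm[1])))
        edge_mid[key] = idx
        return idx

    elements = np.empty((tris.shape[0], 6), dtype=np.int64)
    elements[:, :3] = tris
    for e, (a, b, c) in enumerate(tris):
        elements[e, 3] = midside(a, b)
        elements[e, 4] = midside(b, c)
        elements[e, 5] = midside(c, a)

    all_nodes = np.vstack([coords, np.asarray(mid_coords, dtype=float)])
    mesh = CrossSectionMesh(
        nodes=all_nodes,
        elements=elements,
        element_region=np.asarray(tri_tags),
        boundary_rings=spec.interface_radii,
        region_tags=spec.region_tags,
        vertex_rings=vertex_rings,
        n_theta=n_theta,
    )
    _, detJ = geometry(mesh.element_coords())
    if not (detJ > 0).all():
        raise MeshError("mesh contains inverted elements")  # pragma: no cover
    return mesh
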