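"""Branch tracking and L(0,m) / T(0,m) / F(n,m) labelling.

Eigen-solutions at adjacent frequencies are paired greedily by the
modal assurance criterion MAC(a, b) = |aᴴb|² / (‖a‖²‖b‖²); a pair below
the threshold starts a new branch.  Matching tolerates a one-step gap,
so a mode the eigensolver misses at a single frequency does not split
its branch (which would corrupt the m-numbering).

Families are numbered the classical way: within fixed circumferential
order n (or the torsional family), branches get m = 1, 2, … by
ascending appearance (cut-off) frequency on the computed grid, ties
broken by ascending phase velocity at the lowest shared frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import CrossSectionMesh
from .solver import DispersionSet, ModeSolution, _dominant_order

__all__ = [
    "Branch",
    "BranchSample",
    "circumferential_order",
    "track_branches",
    "label_modes",
    "group_velocity",
    "mac",
]


def mac(a: np.ndarray, b: np.ndarray) -> float:
    """Modal assurance criterion between two complex mode shapes."""
    num = abs(np.vdot(a, b)) ** 2
    den = (np.vdot(a, a).real * np.vdot(b, b).real)
    return float(num / den) if den else 0.0


@dataclass
class BranchSample:
    """One frequency point of a tracked branch."""

    frequency_hz: float
    k: complex
    v_ph: float
    attenuation: float
    cortex_power_fraction: float
    solid_power_fraction: float
    v_g: float | None = None
    power_by_region: dict[str, float] = field(default_factory=dict)


@dataclass
class Branch:
    """A frequency-tracked guided-wave mode."""

    circumferential_order: int
    torsional: bool
    samples: list[BranchSample] = field(default_factory=list)
    label: str = ""

    def frequencies(self) -> np.ndarray:
        return np.array([s.frequency_hz for s in self.samples])

    def v_ph(self) -> np.ndarray:
        return np.array([s.v_ph for s in self.samples])

    def sample_at(self, f_hz: float, tol: float = 1e-6) -> BranchSample | None:
        for s in self.samples:
            if abs(s.frequency_hz - f_hz) <= tol * max(abs(f_hz), 1.0):
                return s
        return None

    @property
    def appearance_frequency(self) -> float:
        return self.samples[0].frequency_hz


def circumferential_order(
    mode: ModeSolution, mesh: CrossSectionMesh, sampling_radius: float
) -> int:
    """Dominant azimuthal harmonic order of a mode shape.

    The displacement is read on the vertex ring nearest the sampling
    radius and the azimuthal DFT power of all three cylindrical
    components is folded over ±n; the order with dominant magnitude is
    returned.  (Using every component keeps the classification defined
    for torsional modes, whose radial component vanishes.)
    """
    rings = sorted(mesh.vertex_rings)
    if not rings[0] <= sampling_radius <= rings[-1] * (1 + 1e-9):
        raise ValueError(
            f"sampling radius {sampling_radius:g} m lies outside the meshed "
            f"annulus [{rings[0]:g}, {rings[-1]:g}] m"
        )
    n, _ = _dominant_order(mesh, mode.eigvec, sampling_radius)
    return n


def _mode_to_sample(m: ModeSolution) -> BranchSample:
    return BranchSample(
        frequency_hz=m.frequency,
        k=m.k,
        v_ph=m.v_ph,
        attenuation=m.attenuation,
        cortex_power_fraction=m.cortex_power_fraction
        if np.isfinite(m.cortex_power_fraction)
        else m.power_by_region.get("cortex", 0.0),
        solid_power_fraction=m.solid_power_fraction,
        power_by_region=dict(m.power_by_region),
    )


class _Track:
    def __init__(self, mode: ModeSolution, slice_index: int):
        self.modes = [mode]
        self.samples = [_mode_to_sample(mode)]
        self.last_index = slice_index

    def extend(self, mode: ModeSolution, slice_index: int) -> None:
        self.modes.append(mode)
        self.samples.append(_mode_to_sample(mode))
        self.last_index = slice_index


def track_branches(
    dispersion: DispersionSet,
    mac_threshold: float = 0.7,
    max_gap: int = 1,
) -> list[Branch]:
    """Greedy MAC pairing of modes across the frequency grid.

    Every retained mode ends up in exactly one branch.  Tracks whose
    last sample lies at most ``max_gap`` grid steps back remain
    eligible for matching, bridging isolated solver misses.
    """
    if len(dispersion.frequencies_hz) < 1:
        raise ValueError("dispersion set is empty")
    tracks: list[_Track] = []
    for i, slice_modes in enumerate(dispersion.modes):
        candidates = [t for t in tracks if i - t.last_index <= max_gap + 1 and t.last_index < i]
        unmatched = list(range(len(slice_modes)))
        if candidates and unmatched:
            scores = np.zeros((len(candidates), len(slice_modes)))
            for a, t in enumerate(candidates):
                va = t.modes[-1].eigvec
                for b, m in enumerate(slice_modes):
                    scores[a, b] = mac(va, m.eigvec)
            taken_tracks: set[int] = set()
            while True:
                a, b = np.unravel_index(np.argmax(scores), scores.shape)
                if scores[a, b] < mac_threshold:
                    break
                candidates[a].extend(slice_modes[b], i)
                taken_tracks.add(a)
                unmatched.remove(b)
                scores[a, :] = -1.0
                scores[:, b] = -1.0
        for b in unmatched:
            tracks.append(_Track(slice_modes[b], i))

    branches = []
    for t in tracks:
        orders = [m.circumferential_order for m in t.modes if m.circumferential_order is not None]
        n = int(np.bincount(orders).argmax()) if orders else 0
        torsional = bool(
            n == 0 and sum(bool(m.torsional) for m in t.modes) > len(t.modes) / 2
        )
        branches.append(Branch(circumferential_order=n, torsional=torsional, samples=t.samples))
    return branches


def label_modes(branches: list[Branch]) -> list[Branch]:
    """Assign L(0,m) / T(0,m) / F(n,m) labels in place; returns the input.

    m counts branches of a family by ascending appearance frequency on
    the tracked grid, then by ascending phase velocity at the lowest
    shared frequency (higher branches rise toward cut-off).
    """
    families: dict[tuple[str, int], list[Branch]] = {}
    for br in branches:
        if br.torsional:
            key = ("T", 0)
        elif br.circumferential_order == 0:
            key = ("L", 0)
        else:
            key = ("F", br.circumferential_order)
        families.setdefault(key, []).append(br)
    for (fam, n), brs in families.items():
        brs.sort(key=lambda b: (b.appearance_frequency, b.samples[0].v_ph))
        for m, br in enumerate(brs, start=1):
            br.label = f"{fam}({n},{m})"
    return branches


def group_velocity(branch: Branch) -> np.ndarray:
    """Group velocity dω/d(Re k) along a branch by finite differences.

    Central differences at interior grid points, one-sided at the ends;
    the result is also stored on the branch samples.
    """
    if len(branch.samples) < 3:
        raise ValueError("group velocity needs at least 3 branch samples")
    f = branch.frequencies()
    if not (np.diff(f) > 0).all():
        raise ValueError("branch samples must be sorted by frequency")
    omega = 2.0 * np.pi * f
    re_k = np.array([s.k.real for s in branch.samples])
    v_g = 1.0 / np.gradient(re_k, omega)
    for s, vg in zip(branch.samples, v_g):
        s.v_g = float(vg)
    return v_g
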