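"""Healthy-vs-degraded dispersion studies and mode ranking.

Runs the full chain (mesh → assemble → solve → filter → track → label)
for each configured model, builds per-mode velocity-difference tables
with band averages, ranks candidate modes, and sanity-checks the
low-frequency longitudinal asymptote against bar theory.

Branch selection for table comparisons: the published mode nomenclature
counts low-order branches that depend on which modes a particular
solver retains, so a requested label such as "L(0,3)" is resolved
structurally when an exact label match is not found in every
configuration — within the requested family (same type and
circumferential order), the branch covering the whole comparison band
with the highest in-band phase velocity is selected.  Reports carry
both the requested (published-style) label and the computed label of
the matched branch.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .materials import ElasticIsotropic, LayeredCylinderSpec, low_freq_bar_velocity
from .mesh import CrossSectionMesh, mesh_layered_annulus
from .modes import Branch, BranchSample, group_velocity, label_modes, track_branches
from .solver import (
    DispersionSet,
    assemble_operators,
    filter_physical,
    solve_wavenumbers,
)

__all__ = [
    "ModelStudy",
    "DegradationReport",
    "run_dispersion_study",
    "select_band_branch",
    "branch_from_velocities",
    "velocity_difference_table",
    "rank_modes",
    "asymptote_consistency_check",
]


@dataclass
class ModelStudy:
    """Dispersion result for one named model configuration."""

    name: str
    spec: LayeredCylinderSpec
    mesh: CrossSectionMesh
    dispersion: DispersionSet
    branches: list[Branch]


def run_dispersion_study(config) -> dict[str, ModelStudy]:
    """Run the dispersion pipeline for every model in a run configuration.

    ``config`` is a :class:`bonewave.config.RunConfig` (or anything with
    the same attributes).  Deterministic for fixed inputs.  Solver and
    mesh errors propagate with the model name attached.
    """
    freqs = np.asarray(config.frequencies_hz, dtype=float)
    if freqs.size == 0:
        raise ValueError("frequency grid is empty")
    studies: dict[str, ModelStudy] = {}
    for name, spec in config.resolved_models().items():
        try:
            mesh = mesh_layered_annulus(spec, config.element_size)
            mats = spec.material_by_region()
            slices = []
            for f in freqs:
                ops = assemble_operators(mesh, mats, 2.0 * np.pi * f)
                modes = solve_wavenumbers(
                    ops,
                    n_modes=config.n_modes,
                    v_ph_window=config.v_ph_window,
                    n_shifts=config.n_shifts,
                )
                slices.append(
                    filter_physical(
                        modes,
                        max_att_ratio=config.max_att_ratio,
                        min_solid_power_fraction=config.min_solid_power_fraction,
                    )
                )
            ds = DispersionSet(freqs, slices, mesh, mats)
            branches = label_modes(track_branches(ds, mac_threshold=config.mac_threshold))
            for br in branches:
                if len(br.samples) >= 3:
                    group_velocity(br)
            if not config.keep_eigenvectors:
                for sl in ds.modes:
                    for m in sl:
                        m.eigvec = None
        except Exception as exc:
            raise type(exc)(f"[model {name!r}] {exc}") from exc
        studies[name] = ModelStudy(name, spec, mesh, ds, branches)
    return studies


# ---------------------------------------------------------------------------
# branch selection and velocity-difference tables

_LABEL_RE = re.compile(r"^([LTF])\((\d+),(\d+)\)$")


def parse_label(label: str) -> tuple[str, int, int]:
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"not a mode label: {label!r}")
    return m.group(1), int(m.group(2)), int(m.group(3))


def select_band_branch(
    branches: list[Branch], family: tuple[str, int], freqs_hz
) -> Branch:
    """The family branch spanning all of ``freqs_hz`` with highest velocity.

    ``family`` is e.g. ``("L", 0)`` or ``("F", 1)``.  Among branches of
    that type and circumferential order that have a sample at every
    requested frequency, returns the one with the largest mean in-band
    phase velocity (higher-order branches lie above lower ones within a
    band, so this pins the highest such branch present throughout).
    """
    fam, n = family
    candidates = []
    for br in branches:
        if not br.label:
            continue
        f0, n0, _ = parse_label(br.label)
        if (f0, n0) != (fam, n):
            continue
        samples = [br.sample_at(f) for f in freqs_hz]
        if all(s is not None for s in samples):
            candidates.append((np.mean([s.v_ph for s in samples]), br))
    if not candidates:
        raise LookupError(
            f"no {fam}({n},m) branch spans {[f / 1e3 for f in freqs_hz]} kHz"
        )
    return max(candidates, key=lambda t: t[0])[1]


def resolve_branch(branches: list[Branch], mode_label: str, freqs_hz) -> Branch:
    """Resolve a requested label to a branch: exact match, else band rule.

    An exact-label branch that only partially covers the band is
    returned last-resort so the caller can report the precise gaps.
    """
    exact = next((br for br in branches if br.label == mode_label), None)
    if exact is not None and all(exact.sample_at(f) for f in freqs_hz):
        return exact
    fam, n, _ = parse_label(mode_label)
    try:
        return select_band_branch(branches, (fam, n), freqs_hz)
    except LookupError:
        if exact is not None:
            return exact
        raise


def branch_from_velocities(label: str, freqs_hz, v_ph) -> Branch:
    """A bare branch carrying only phase velocities (e.g. printed table data)."""
    fam, n, _ = parse_label(label)
    samples = [
        BranchSample(
            frequency_hz=float(f), k=float("nan"), v_ph=float(v),
            attenuation=float("nan"), cortex_power_fraction=float("nan"),
            solid_power_fraction=float("nan"),
        )
        for f, v in zip(freqs_hz, v_ph)
    ]
    return Branch(circumferential_order=n, torsional=fam == "T",
                  samples=samples, label=label)


@dataclass
class DegradationReport:
    """Per-mode healthy-vs-degraded phase-velocity comparison.

    ``differences[config]`` is healthy − degraded per frequency (m/s);
    ``band_average_difference[config]`` its arithmetic mean;
    ``percent_reduction[config]`` the band average relative to the
    healthy band-mean velocity, in percent.
    """

    mode_label: str
    frequencies_hz: list[float]
    healthy_v_ph: list[float]
    degraded_v_ph: dict[str, list[float]]
    differences: dict[str, list[float]]
    band_average_difference: dict[str, float]
    percent_reduction: dict[str, float]
    matched_labels: dict[str, str] = field(default_factory=dict)
    mean_cortex_fraction: float = float("nan")


def velocity_difference_table(
    healthy: list[Branch],
    degraded: dict[str, list[Branch]],
    mode_label: str,
    freqs_hz,
    selection: str = "label",
) -> DegradationReport:
    """Velocity differences of one mode between healthy and degraded configs.

    Every configuration must contain the mode at every requested
    frequency; a missing sample raises with an explicit gap report.
    ``selection="label"`` resolves the mode by exact label first (band
    rule as fallback); ``selection="band"`` always applies the
    structural band rule to the label's family, which is robust when
    branch numbering differs between solver runs.
    """
    freqs = [float(f) for f in freqs_hz]
    if selection not in ("label", "band"):
        raise ValueError("selection must be 'label' or 'band'")

    def column(branches, cfg_name):
        if selection == "band":
            fam, n, _ = parse_label(mode_label)
            br = select_band_branch(branches, (fam, n), freqs)
        else:
            br = resolve_branch(branches, mode_label, freqs)
        vals, gaps = [], []
        for f in freqs:
            s = br.sample_at(f)
            if s is None:
                gaps.append(f)
            else:
                vals.append(s.v_ph)
        if gaps:
            raise LookupError(
                f"branch {br.label} of config {cfg_name!r} has no sample at "
                f"{[g / 1e3 for g in gaps]} kHz"
            )
        return br, vals

    h_branch, h_vals = column(healthy, "healthy")
    matched = {"healthy": h_branch.label}
    cortex = [
        s.cortex_power_fraction
        for f in freqs
        if (s := h_branch.sample_at(f)) is not None
        and np.isfinite(s.cortex_power_fraction)
    ]
    deg_vals, diffs, band_avg, pct = {}, {}, {}, {}
    h_mean = float(np.mean(h_vals))
    for cfg_name, branches in degraded.items():
        br, vals = column(branches, cfg_name)
        matched[cfg_name] = br.label
        deg_vals[cfg_name] = vals
        d = [h - v for h, v in zip(h_vals, vals)]
        diffs[cfg_name] = d
        band_avg[cfg_name] = float(np.mean(d))
        pct[cfg_name] = 100.0 * band_avg[cfg_name] / h_mean
    return DegradationReport(
        mode_label=mode_label,
        frequencies_hz=freqs,
        healthy_v_ph=h_vals,
        degraded_v_ph=deg_vals,
        differences=diffs,
        band_average_difference=band_avg,
        percent_reduction=pct,
        matched_labels=matched,
        mean_cortex_fraction=float(np.mean(cortex)) if cortex else float("nan"),
    )


def rank_modes(reports: list[DegradationReport]) -> list[DegradationReport]:
    """Rank candidate modes by band-averaged velocity difference.

    Sorted descending by the mean of the band averages over all
    degraded configurations; ties broken by mean cortex power fraction.
    """
    if not reports:
        raise ValueError("no reports to rank")

    def key(r: DegradationReport):
        avg = np.mean(list(r.band_average_difference.values()))
        cf = r.mean_cortex_fraction
        return (-avg, -(cf if np.isfinite(cf) else 0.0))

    return sorted(reports, key=key)


# ---------------------------------------------------------------------------
# low-frequency asymptote check


@dataclass
class AsymptoteRow:
    config: str
    frequency_hz: float
    v_ph: float
    bar_velocity: float
    relative_deviation: float
    predicted_reduction: float | None
    observed_reduction: float | None
    flagged: bool


def asymptote_consistency_check(
    studies: dict[str, ModelStudy],
    cortex_materials: dict[str, ElasticIsotropic],
    healthy: str,
    flag_tolerance: float = 0.05,
) -> list[AsymptoteRow]:
    """Compare the lowest-frequency fundamental longitudinal velocity with
    bar theory sqrt(E/ρ) and the predicted per-level relative reduction
    ½(ΔE/E − Δρ/ρ); rows deviating more than ``flag_tolerance`` are flagged.

    On a loaded (marrow/tissue-coated) waveguide the absolute bar-theory
    comparison is only indicative — mass loading lowers the fundamental
    below sqrt(E/ρ) — but the *relative* healthy-to-degraded reduction
    tracks the prediction closely and is the quantity of interest.
    """

    def fundamental(study: ModelStudy):
        cands = [
            b for b in study.branches
            if b.label.startswith("L(0,") and b.samples
        ]
        if not cands:
            raise LookupError(f"no longitudinal branch resolved for {study.name!r}")
        low = min(b.appearance_frequency for b in cands)
        first = [b for b in cands if b.appearance_frequency == low]
        return min(first, key=lambda b: b.samples[0].v_ph)

    h_mat = cortex_materials[healthy]
    h_mode = fundamental(studies[healthy])
    h_v = h_mode.samples[0].v_ph
    h_bar = low_freq_bar_velocity(h_mat.young_modulus, h_mat.density)
    rows = [
        AsymptoteRow(
            config=healthy,
            frequency_hz=h_mode.samples[0].frequency_hz,
            v_ph=h_v,
            bar_velocity=h_bar,
            relative_deviation=(h_v - h_bar) / h_bar,
            predicted_reduction=None,
            observed_reduction=None,
            flagged=abs(h_v - h_bar) / h_bar > flag_tolerance,
        )
    ]
    for name, study in studies.items():
        if name == healthy:
            continue
        mat = cortex_materials[name]
        mode = fundamental(study)
        s = mode.sample_at(h_mode.samples[0].frequency_hz) or mode.samples[0]
        bar = low_freq_bar_velocity(mat.young_modulus, mat.density)
        d_e = 1.0 - mat.young_modulus / h_mat.young_modulus
        d_rho = 1.0 - mat.density / h_mat.density
        predicted = 0.5 * (d_e - d_rho)
        observed = (h_v - s.v_ph) / h_v
        rows.append(
            AsymptoteRow(
                config=name,
                frequency_hz=s.frequency_hz,
                v_ph=s.v_ph,
                bar_velocity=bar,
                relative_deviation=(s.v_ph - bar) / bar,
                predicted_reduction=predicted,
                observed_reduction=observed,
                flagged=abs(observed - predicted) > flag_tolerance,
            )
        )
    return rows
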