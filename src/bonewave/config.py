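"""Run-configuration schema (YAML/JSON), version 1.

Config files use practitioner units — GPa, mm, kHz — and are converted
to SI on load.  Unknown keys are rejected with an error naming them.

Schema (all top-level keys optional unless marked):

.. code-block:: yaml

    version: 1
    models:                 # required: builtin names and/or inline specs
      - model3_healthy
      - name: my_tube
        inner_radius_mm: 7.0
        layers:
          - outer_radius_mm: 10.0
            region: cortex
            material: {young_modulus_gpa: 14.95, poisson_ratio: 0.31,
                       density_kg_m3: 2300}
          - outer_radius_mm: 15.0
            region: tissue
            material: {fluid: {bulk_modulus_gpa: 2.2, density_kg_m3: 1000,
                               viscosity_pa_s: 0.037},
                       shear_floor_m_s: 100, shear_damping: 0.5}
    frequencies_khz: {start: 30, stop: 200, step: 10}   # or explicit list
    element_size_mm: 1.6
    solver:
      v_ph_window_m_s: [1500, 9000]
      n_modes: 80
      n_shifts: 4
      max_att_ratio: 0.1
      min_solid_power_fraction: 0.5
      mac_threshold: 0.7
    output_dir: out
    seed: 0                 # randomized fixtures only; physics is deterministic
    keep_eigenvectors: false
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .materials import (
    ElasticIsotropic,
    FluidLayerMaterial,
    FluidProps,
    Layer,
    LayeredCylinderSpec,
    builtin_models,
)

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]

SCHEMA_VERSION = 1

_SOLVER_DEFAULTS = {
    "v_ph_window_m_s": [1500.0, 9000.0],
    "n_modes": 80,
    "n_shifts": 4,
    "max_att_ratio": 0.1,
    "min_solid_power_fraction": 0.5,
    "mac_threshold": 0.7,
}


class ConfigError(ValueError):
    """Schema violation; message lists the offending keys or values."""


@dataclass
class RunConfig:
    """Validated, unit-normalised run configuration (SI internally)."""

    models: list[str | LayeredCylinderSpec]
    model_names: list[str]
    frequencies_hz: np.ndarray
    element_size: float = 1.0e-3
    v_ph_window: tuple[float, float] = (1500.0, 9000.0)
    n_modes: int = 80
    n_shifts: int = 4
    max_att_ratio: float = 0.1
    min_solid_power_fraction: float = 0.5
    mac_threshold: float = 0.7
    output_dir: Path = Path("out")
    seed: int = 0
    keep_eigenvectors: bool = False
    raw: dict = field(default_factory=dict, repr=False)

    def resolved_models(self) -> dict[str, LayeredCylinderSpec]:
        builtin = builtin_models()
        out: dict[str, LayeredCylinderSpec] = {}
        for name, model in zip(self.model_names, self.models):
            if isinstance(model, LayeredCylinderSpec):
                out[name] = model
            else:
                if model not in builtin:
                    raise ConfigError(
                        f"unknown builtin model {model!r}; "
                        f"available: {sorted(builtin)}"
                    )
                out[name] = builtin[model]
        return out


def _reject_unknown(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _material_from_dict(d: dict, where: str):
    if "fluid" in d:
        _reject_unknown(d, {"fluid", "shear_floor_m_s", "shear_damping"}, where)
        fd = d["fluid"]
        _reject_unknown(
            fd, {"bulk_modulus_gpa", "density_kg_m3", "viscosity_pa_s"}, where + ".fluid"
        )
        fluid = FluidProps(
            bulk_modulus=float(fd["bulk_modulus_gpa"]) * 1e9,
            density=float(fd["density_kg_m3"]),
            viscosity=float(fd.get("viscosity_pa_s", 0.0)),
        )
        return FluidLayerMaterial(
            fluid,
            shear_floor=float(d.get("shear_floor_m_s", 100.0)),
            shear_damping=float(d.get("shear_damping", 0.5)),
        )
    _reject_unknown(d, {"young_modulus_gpa", "poisson_ratio", "density_kg_m3"}, where)
    try:
        return ElasticIsotropic(
            young_modulus=float(d["young_modulus_gpa"]) * 1e9,
            poisson_ratio=float(d["poisson_ratio"]),
            density=float(d["density_kg_m3"]),
        )
    except KeyError as exc:
        raise ConfigError(f"missing material key {exc} in {where}") from None


def _spec_from_dict(d: dict, where: str) -> tuple[str, LayeredCylinderSpec]:
    _reject_unknown(d, {"name", "inner_radius_mm", "layers"}, where)
    if "name" not in d or "layers" not in d:
        raise ConfigError(f"inline model in {where} needs 'name' and 'layers'")
    layers = []
    for i, ld in enumerate(d["layers"]):
        lw = f"{where}.layers[{i}]"
        _reject_unknown(ld, {"outer_radius_mm", "region", "material"}, lw)
        r = float(ld["outer_radius_mm"]) * 1e-3
        if r <= 0:
            raise ConfigError(f"non-positive outer radius in {lw}")
        layers.append(
            Layer(r, _material_from_dict(ld["material"], lw + ".material"), str(ld["region"]))
        )
    try:
        spec = LayeredCylinderSpec(
            layers=tuple(layers),
            inner_radius=float(d.get("inner_radius_mm", 0.0)) * 1e-3,
        )
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from None
    return str(d["name"]), spec


def _frequencies(d, where: str) -> np.ndarray:
    if isinstance(d, dict):
        _reject_unknown(d, {"start", "stop", "step"}, where)
        start, stop, step = (float(d[k]) for k in ("start", "stop", "step"))
        if step <= 0 or stop < start:
            raise ConfigError(f"bad frequency range in {where}")
        f = np.arange(start, stop + step / 2, step) * 1e3
    else:
        f = np.asarray([float(x) for x in d]) * 1e3
    if f.size == 0:
        raise ConfigError(f"empty frequency grid in {where}")
    if not (np.diff(f) > 0).all() or (f <= 0).any():
        raise ConfigError(f"frequencies must be positive and strictly increasing ({where})")
    return f


def parse_config(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("top level of the config must be a mapping")
    allowed = {
        "version", "models", "frequencies_khz", "element_size_mm",
        "solver", "output_dir", "seed", "keep_eigenvectors",
    }
    _reject_unknown(data, allowed, "top level")
    version = data.get("version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported config version {version!r}")
    if "models" not in data or not data["models"]:
        raise ConfigError("config must list at least one model")
    if "frequencies_khz" not in data:
        raise ConfigError("config must give frequencies_khz")

    models: list[str | LayeredCylinderSpec] = []
    names: list[str] = []
    for i, m in enumerate(data["models"]):
        if isinstance(m, str):
            models.append(m)
            names.append(m)
        else:
            name, spec = _spec_from_dict(m, f"models[{i}]")
            models.append(spec)
            names.append(name)
    if len(set(names)) != len(names):
        raise ConfigError("model names must be unique")

    solver = dict(_SOLVER_DEFAULTS)
    user_solver = data.get("solver", {})
    _reject_unknown(user_solver, set(_SOLVER_DEFAULTS), "solver")
    solver.update(user_solver)
    window = tuple(float(v) for v in solver["v_ph_window_m_s"])
    if len(window) != 2 or not 0 < window[0] < window[1]:
        raise ConfigError("solver.v_ph_window_m_s must be [lo, hi] with 0 < lo < hi")

    element_size = float(data.get("element_size_mm", 1.0)) * 1e-3
    if element_size <= 0:
        raise ConfigError("element_size_mm must be > 0")

    return RunConfig(
        models=models,
        model_names=names,
        frequencies_hz=_frequencies(data["frequencies_khz"], "frequencies_khz"),
        element_size=element_size,
        v_ph_window=window,  # type: ignore[arg-type]
        n_modes=int(solver["n_modes"]),
        n_shifts=int(solver["n_shifts"]),
        max_att_ratio=float(solver["max_att_ratio"]),
        min_solid_power_fraction=float(solver["min_solid_power_fraction"]),
        mac_threshold=float(solver["mac_threshold"]),
        output_dir=Path(data.get("output_dir", "out")),
        seed=int(data.get("seed", 0)),
        keep_eigenvectors=bool(data.get("keep_eigenvectors", False)),
        raw=data,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    cfg = parse_config(data)
    if not cfg.raw.get("output_dir"):
        cfg.output_dir = path.parent / "out"
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the raw (practitioner-unit) config back out; load∘dump = id."""
    Path(path).write_text(yaml.safe_dump(cfg.raw, sort_keys=False))
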