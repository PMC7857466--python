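"""CSV/JSON outputs with a run manifest.

CSV columns are documented here once and kept stable:

* dispersion CSV — ``frequency_hz, mode_index, mode_label, circ_order,
  re_k_per_m, im_k_per_m, v_ph_m_s, v_g_m_s, att_np_per_m,
  att_db_per_m`` plus one ``power_<region>`` column per region.
* power CSV — ``frequency_hz, mode_label, cortex_fraction,
  normalized_power``.
* degradation CSV — ``mode_label, matched_label, frequency_hz,
  healthy_v_ph_m_s`` plus per-config velocity/difference columns.

Writes are atomic (temp file + replace) and byte-deterministic for a
fixed study, so re-running a config overwrites with identical files.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .pipeline import DegradationReport, ModelStudy

__all__ = [
    "dispersion_frame",
    "degradation_frame",
    "power_frame",
    "write_outputs",
]

NP_TO_DB = 20.0 / np.log(10.0)
_FLOAT_FMT = "%.9g"


def dispersion_frame(study: ModelStudy) -> pd.DataFrame:
    """Labeled dispersion table, one row per (branch, frequency)."""
    regions = study.mesh.region_tags
    rows = []
    for idx, br in enumerate(
        sorted(study.branches, key=lambda b: (b.appearance_frequency, b.samples[0].v_ph))
    ):
        for s in br.samples:
            row = {
                "frequency_hz": s.frequency_hz,
                "mode_index": idx,
                "mode_label": br.label,
                "circ_order": br.circumferential_order,
                "re_k_per_m": s.k.real,
                "im_k_per_m": s.k.imag,
                "v_ph_m_s": s.v_ph,
                "v_g_m_s": s.v_g if s.v_g is not None else np.nan,
                "att_np_per_m": s.attenuation,
                "att_db_per_m": s.attenuation * NP_TO_DB,
            }
            for r in regions:
                row[f"power_{r}"] = s.power_by_region.get(r, np.nan)
            row["power_solid"] = s.solid_power_fraction
            rows.append(row)
    columns = [
        "frequency_hz", "mode_index", "mode_label", "circ_order",
        "re_k_per_m", "im_k_per_m", "v_ph_m_s", "v_g_m_s",
        "att_np_per_m", "att_db_per_m",
        *[f"power_{r}" for r in regions], "power_solid",
    ]
    frame = pd.DataFrame(rows, columns=columns)
    return frame.sort_values(["frequency_hz", "mode_index"], kind="stable").reset_index(drop=True)


def power_frame(table: dict[str, dict[float, float]]) -> pd.DataFrame:
    """Flatten a normalised cortex power table to a tidy frame."""
    rows = [
        {"frequency_hz": f, "mode_label": label, "normalized_power": p}
        for label, row in sorted(table.items())
        for f, p in sorted(row.items())
    ]
    return pd.DataFrame(rows)


def degradation_frame(report: DegradationReport) -> pd.DataFrame:
    rows = []
    for i, f in enumerate(report.frequencies_hz):
        row = {
            "mode_label": report.mode_label,
            "matched_label": report.matched_labels.get("healthy", ""),
            "frequency_hz": f,
            "healthy_v_ph_m_s": report.healthy_v_ph[i],
        }
        for cfg, vals in report.degraded_v_ph.items():
            row[f"v_ph_{cfg}_m_s"] = vals[i]
            row[f"diff_{cfg}_m_s"] = report.differences[cfg][i]
        rows.append(row)
    return pd.DataFrame(rows)


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_outputs(
    studies: dict[str, ModelStudy],
    directory: str | Path,
    reports: list[DegradationReport] | None = None,
    config_raw: dict | None = None,
) -> dict:
    """Write per-model dispersion CSVs (plus optional degradation tables)
    and a manifest; returns the manifest dict."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, study in studies.items():
        frame = dispersion_frame(study)
        path = directory / f"dispersion_{name}.csv"
        _atomic_write(path, frame.to_csv(index=False, float_format=_FLOAT_FMT))
        files[path.name] = {
            "rows": int(frame.shape[0]),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }
    for report in reports or []:
        frame = degradation_frame(report)
        safe = report.mode_label.replace("(", "").replace(")", "").replace(",", "_")
        path = directory / f"degradation_{safe}.csv"
        _atomic_write(path, frame.to_csv(index=False, float_format=_FLOAT_FMT))
        files[path.name] = {
            "rows": int(frame.shape[0]),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }
    manifest = {
        "bonewave_version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(config_raw or {}, sort_keys=True).encode()
        ).hexdigest(),
        "mesh_stats": {
            name: {
                "n_nodes": s.mesh.n_nodes,
                "n_elements": s.mesh.n_elements,
                "n_theta": s.mesh.n_theta,
            }
            for name, s in studies.items()
        },
        "files": files,
    }
    _atomic_write(directory / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
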