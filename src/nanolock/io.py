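"""File formats: raw traces with sidecar metadata, TSV tables, configs.

Traces are raw little-endian 64-bit floats (current in pA) with a
textual ``key = value`` sidecar carrying the acquisition and pore
metadata, and a ground-truth event table alongside when the trace is
synthetic.  All tables are tab-separated text.  Numeric fields embed
their units in the key name (``voltage_mv``, ``duration_s``) to prevent
unit drift across the pipeline.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .detect import EVENT_COLUMNS
from .synth import AcquisitionConfig, PoreModel, SyntheticTrace
from .classify import RulerCalibration

__all__ = [
    "write_trace",
    "read_trace",
    "write_table",
    "read_table",
    "write_calibration",
    "read_calibration",
    "read_config",
    "write_config",
    "read_manifest",
    "validate_formats",
]

SIDECAR_KEYS = [
    "sampling_rate",
    "analog_bandwidth",
    "digital_filter_cutoff",
    "filter_poles",
    "voltage_mv",
    "duration_s",
    "rng_seed",
    "open_pore_conductance_ns",
    "blockade_1x_ns",
    "noise_rms_pa",
    "baseline_drift_pa_per_s",
]

MANIFEST_COLUMNS = ["run_id", "role", "concentration", "units", "dilution", "duration_s", "seed"]
MANIFEST_ROLES = {"ruler", "blank", "standard", "sample"}


def write_config(path: str | Path, mapping: dict) -> None:
    lines = [f"{k} = {v}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> dict:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def write_trace(prefix: str | Path, trace: SyntheticTrace) -> None:
    """Write ``<prefix>.raw`` (float64 pA), ``<prefix>.meta`` (sidecar)
    and ``<prefix>.truth.tsv`` (ground-truth events)."""
    prefix = Path(prefix)
    trace.samples.astype("<f8").tofile(prefix.with_suffix(".raw"))
    meta = {
        "sampling_rate": trace.acq.sampling_rate,
        "analog_bandwidth": trace.acq.analog_bandwidth,
        "digital_filter_cutoff": trace.acq.digital_filter_cutoff,
        "filter_poles": trace.acq.filter_poles,
        "voltage_mv": trace.acq.voltage_mv,
        "duration_s": trace.acq.duration_s,
        "rng_seed": trace.acq.rng_seed,
        "open_pore_conductance_ns": trace.pore.open_pore_conductance_ns,
        "blockade_1x_ns": trace.pore.blockade_1x_ns,
        "noise_rms_pa": trace.pore.noise_rms_pa,
        "baseline_drift_pa_per_s": trace.pore.baseline_drift_pa_per_s,
    }
    write_config(prefix.with_suffix(".meta"), meta)
    write_table(prefix.with_suffix(".truth.tsv"), trace.events)


def read_trace(prefix: str | Path) -> SyntheticTrace:
    prefix = Path(prefix)
    meta = read_config(prefix.with_suffix(".meta"))
    missing = [k for k in SIDECAR_KEYS if k not in meta]
    if missing:
        raise ValueError(f"sidecar missing keys: {missing}")
    acq = AcquisitionConfig(
        sampling_rate=float(meta["sampling_rate"]),
        analog_bandwidth=float(meta["analog_bandwidth"]),
        digital_filter_cutoff=float(meta["digital_filter_cutoff"]),
        filter_poles=int(float(meta["filter_poles"])),
        voltage_mv=float(meta["voltage_mv"]),
        duration_s=float(meta["duration_s"]),
        rng_seed=int(float(meta["rng_seed"])),
    )
    pore = PoreModel(
        open_pore_conductance_ns=float(meta["open_pore_conductance_ns"]),
        blockade_1x_ns=float(meta["blockade_1x_ns"]),
        noise_rms_pa=float(meta["noise_rms_pa"]),
        baseline_drift_pa_per_s=float(meta["baseline_drift_pa_per_s"]),
    )
    samples = np.fromfile(prefix.with_suffix(".raw"), dtype="<f8")
    truth_path = prefix.with_suffix(".truth.tsv")
    events = read_table(truth_path) if truth_path.exists() else pd.DataFrame()
    return SyntheticTrace(samples, acq, pore, events)


def write_table(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_calibration(path: str | Path, cal: RulerCalibration) -> None:
    write_config(
        path,
        {
            "delta_g_1x_ns": cal.delta_g_1x_ns,
            "sigma_ns": cal.sigma_ns,
            "source": cal.source,
            "n_events": cal.n_events,
        },
    )


def read_calibration(path: str | Path) -> RulerCalibration:
    c = read_config(path)
    return RulerCalibration(
        float(c["delta_g_1x_ns"]), float(c["sigma_ns"]), c.get("source", ""),
        int(float(c.get("n_events", 0))),
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    frame = read_table(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if frame["run_id"].duplicated().any():
        raise ValueError("manifest run_ids must be unique")
    bad_roles = set(frame["role"]) - MANIFEST_ROLES
    if bad_roles:
        raise ValueError(f"unknown manifest roles: {sorted(bad_roles)}")
    std = frame[frame["role"] == "standard"]
    if std["concentration"].isna().any():
        raise ValueError("every standard needs a concentration")
    return frame


# ---------------------------------------------------------------------------
# Validation diagnostics


def validate_formats(path: str | Path) -> list[dict]:
    """Machine-readable format diagnostics for a pipeline artifact.

    Dispatches on the file extension (``.meta`` sidecar, ``.raw`` trace,
    ``.tsv`` tables); returns an empty list when the file is
    well-formed, otherwise one dict per violation.
    """
    path = Path(path)
    if not path.exists():
        return [{"path": str(path), "violation": "missing_file"}]
    issues: list[dict] = []
    if path.suffix == ".meta":
        try:
            meta = read_config(path)
        except ValueError as e:
            return [{"path": str(path), "violation": "malformed_sidecar", "detail": str(e)}]
        for k in SIDECAR_KEYS:
            if k not in meta:
                issues.append({"path": str(path), "violation": "sidecar_missing_key", "key": k})
    elif path.suffix == ".raw":
        samples = np.fromfile(path, dtype="<f8")
        if len(samples) == 0:
            issues.append({"path": str(path), "violation": "empty_trace"})
        bad = np.flatnonzero(~np.isfinite(samples))
        if len(bad):
            issues.append(
                {"path": str(path), "violation": "non_finite_samples", "first_index": int(bad[0])}
            )
    elif path.suffix == ".tsv":
        frame = read_table(path)
        name = path.name
        if name.endswith("truth.tsv"):
            required = ["start_s", "species", "p", "true_bit", "duration_s"]
        elif "manifest" in name or "runs" in name:
            required = MANIFEST_COLUMNS
        elif "classified" in name:
            required = EVENT_COLUMNS + ["b", "event_type", "digital_bit"]
        else:
            required = EVENT_COLUMNS
        for c in required:
            if c not in frame.columns:
                issues.append({"path": str(path), "violation": "missing_column", "column": c})
    else:
        issues.append({"path": str(path), "violation": "unknown_format"})
    return issues
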