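"""Text-first file formats: traces, cell-record tables, manifests, reports.

Traces are two-column delimited text (time_s, current) — or a single current
column — with a JSON metadata sidecar (``<trace>.meta.json``) carrying the
sample rate, baseline, device id and seed.  Cell records are CSV with the
schema produced by :mod:`mechanonps.phenotype`; the prolonged-recovery
marker and absent tau survive a round trip.  Readers are gzip-tolerant
(any ``.gz`` path is decompressed transparently by pandas/numpy).
"""

from __future__ import annotations

import gzip
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .phenotype import CellRecord, records_to_dataframe
from .preprocess import Trace
from .simulate import GroundTruthManifest

__all__ = [
    "read_trace", "write_trace", "read_records", "write_records",
    "write_manifest", "write_json",
]

RECORD_COLUMNS = [
    "cell_id", "device_id", "window_start_s", "d0_um", "v0_um_per_ms",
    "vc_um_per_ms", "wcdi", "tau_ms", "delta_t_r_ms", "recovery_category",
    "statistical_outlier", "erroneous",
]

MAX_RELATIVE_JITTER = 1e-6


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_trace(trace: Trace, path: str | Path,
                include_time_column: bool = True) -> Path:
    """Write a trace as delimited text plus its JSON metadata sidecar."""
    path = Path(path)
    if include_time_column:
        data = np.column_stack([trace.times_s, trace.samples])
        np.savetxt(path, data, fmt="%.17g", delimiter="\t",
                   header="time_s\tcurrent", comments="# ")
    else:
        np.savetxt(path, trace.samples, fmt="%.17g",
                   header="current", comments="# ")
    meta = {"sample_rate_hz": trace.sample_rate_hz, **trace.metadata}
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_trace(path: str | Path) -> Trace:
    """Read a trace file, validating uniform sampling against the time column."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        data = np.loadtxt(fh, comments="#", ndmin=2)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if data.shape[1] >= 2:
        t, current = data[:, 0], data[:, 1]
        dt = np.diff(t)
        if len(dt) == 0 or dt[0] <= 0 or \
                np.max(np.abs(dt - dt[0])) > MAX_RELATIVE_JITTER * dt[0] + 1e-15:
            raise ValueError(f"{path}: time column is not uniformly increasing")
        fs = 1.0 / float(np.mean(dt))
        declared = meta.get("sample_rate_hz")
        if declared is not None and abs(declared - fs) > 1e-3 * fs:
            raise ValueError(
                f"{path}: sidecar sample rate {declared} Hz disagrees with "
                f"time column ({fs:.3f} Hz)")
    else:
        current = data[:, 0]
        fs = meta.get("sample_rate_hz")
        if fs is None:
            raise ValueError(
                f"{path}: single-column trace requires a sidecar "
                f"({sidecar.name}) with sample_rate_hz")
    meta.pop("sample_rate_hz", None)
    return Trace(current, float(fs), meta)


def write_records(records: Sequence[CellRecord] | pd.DataFrame,
                  path: str | Path) -> Path:
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) \
        else records_to_dataframe(records)
    out = df.copy()
    out["delta_t_r_ms"] = [
        "prolonged" if (isinstance(v, float) and math.isinf(v)) else v
        for v in out["delta_t_r_ms"]]
    out.to_csv(path, index=False, float_format="%.12g")
    return path


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing record columns {missing}")
    df["delta_t_r_ms"] = [
        math.inf if str(v).strip() == "prolonged" else float(v)
        for v in df["delta_t_r_ms"]]
    df["tau_ms"] = pd.to_numeric(df["tau_ms"], errors="coerce")
    for col in ("statistical_outlier", "erroneous"):
        df[col] = df[col].astype(bool)
    return df


def write_manifest(manifest: GroundTruthManifest, prefix: str | Path) -> tuple[Path, Path]:
    """Ground truth as CSV (per-cell) + JSON (geometry and acquisition)."""
    prefix = Path(prefix)
    csv_path = prefix.with_name(prefix.name + "_manifest.csv")
    json_path = prefix.with_name(prefix.name + "_manifest.json")
    manifest.to_dataframe().to_csv(csv_path, index=False, float_format="%.12g")
    json_path.write_text(json.dumps({
        "geometry": manifest.geometry.to_dict(),
        "acquisition": {k: v for k, v in vars(manifest.acquisition).items()},
    }, indent=2))
    return csv_path, json_path


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"cannot serialize {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path
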