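"""File formats: trace CSV dialect, detector config files, event exports.

The canonical trace dialect is a UTF-8, comma-separated file with header
``timestamp_s, ax_mg, ay_mg, az_mg, gx_dps, gy_dps, gz_dps`` — one row per
sample at the declared rate.  Floats are written at full repr precision, so
a written trace re-reads to identical samples.  Foreign CSV layouts are
accommodated through a column-mapping option rather than guessed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .detector import DetectorConfig, FallEvent
from .features import ImuTrace

__all__ = [
    "TRACE_COLUMNS",
    "TraceFormatError",
    "ConfigError",
    "read_trace",
    "write_trace",
    "load_config",
    "events_to_csv",
    "events_to_json",
    "write_manifest",
]

#: canonical column order of the trace dialect
TRACE_COLUMNS = ("timestamp_s", "ax_mg", "ay_mg", "az_mg",
                 "gx_dps", "gy_dps", "gz_dps")


class TraceFormatError(ValueError):
    """A trace file failed validation; the message names the line."""


class ConfigError(ValueError):
    """A config document had unknown keys or violated an invariant."""


def write_trace(trace: ImuTrace, path: Union[str, Path]) -> Path:
    """Write a trace in the canonical dialect; returns the path.

    Deterministic byte output for a fixed trace (full float precision).
    An empty write target is only possible via a length-1 trace minimum,
    enforced by :class:`ImuTrace` itself.
    """
    path = Path(path)
    df = pd.DataFrame({
        "timestamp_s": trace.t,
        "ax_mg": trace.acc[:, 0], "ay_mg": trace.acc[:, 1],
        "az_mg": trace.acc[:, 2],
        "gx_dps": trace.gyro[:, 0], "gy_dps": trace.gyro[:, 1],
        "gz_dps": trace.gyro[:, 2],
    })
    # 17 significant digits round-trip any float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_trace(path: Union[str, Path],
               column_map: Optional[Mapping[str, str]] = None,
               fs: Optional[float] = None) -> ImuTrace:
    """Read and validate a trace CSV.

    Parameters
    ----------
    column_map
        Optional mapping from canonical names (:data:`TRACE_COLUMNS`) to
        the file's actual column names, for foreign CSV layouts.
    fs
        Sampling rate.  If the file has no timestamp column, ``fs`` is
        required and timestamps are synthesised at exact spacing
        (index-only mode); otherwise it defaults to the rate implied by the
        median timestamp spacing.

    Rows with non-finite cells are reported with their file line number
    (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    names = {c: (column_map or {}).get(c, c) for c in TRACE_COLUMNS}
    missing = [v for k, v in names.items()
               if v not in df.columns and k != "timestamp_s"]
    if missing:
        raise TraceFormatError(f"{path}: missing columns {missing}")
    data_cols = [names[c] for c in TRACE_COLUMNS[1:]]
    data = df[data_cols].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(data).all(axis=1))
    if bad.size:
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise TraceFormatError(
            f"{path}: non-finite values on line(s) {lines}"
        )
    if names["timestamp_s"] in df.columns:
        t = df[names["timestamp_s"]].to_numpy(dtype=float)
        if not np.isfinite(t).all():
            bad_t = int(np.flatnonzero(~np.isfinite(t))[0]) + 2
            raise TraceFormatError(
                f"{path}: non-finite timestamp on line {bad_t}"
            )
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 100.0
    else:
        if fs is None:
            raise TraceFormatError(
                f"{path}: no timestamp column and no fs given"
            )
        t = np.arange(data.shape[0]) / fs
    try:
        return ImuTrace(t=t, acc=data[:, 0:3], gyro=data[:, 3:6], fs=fs)
    except ValueError as exc:
        raise TraceFormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# detector configuration files (YAML or JSON; JSON is a YAML subset)
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(DetectorConfig)}
_SLICE_FIELDS = {"std_slice", "psi_slice"}


def load_config(path: Optional[Union[str, Path]] = None) -> DetectorConfig:
    """Load a :class:`DetectorConfig` from a YAML/JSON key-value document.

    Missing keys take the deployed defaults; an empty file (or no path)
    yields the all-defaults config.  Unknown keys and invariant violations
    (e.g. trigger threshold at or above the impact threshold) are rejected.
    """
    if path is None:
        return DetectorConfig()
    raw = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(raw)
    if doc is None:
        return DetectorConfig()
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a key/value mapping")
    unknown = set(doc) - _CONFIG_FIELDS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    kwargs = dict(doc)
    for key in _SLICE_FIELDS & set(kwargs):
        val = kwargs[key]
        if not (isinstance(val, (list, tuple)) and len(val) == 2):
            raise ConfigError(f"{path}: {key} must be a [start, stop] pair")
        kwargs[key] = (int(val[0]), int(val[1]))
    try:
        return DetectorConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# event and manifest exports
# ---------------------------------------------------------------------------

_EVENT_FIELDS = ("trigger_time", "trigger_index", "impact_index",
                 "sigma_acc", "sigma_gyro", "psi_bar")


def events_to_csv(events: Iterable[FallEvent], path: Union[str, Path]) -> Path:
    path = Path(path)
    df = pd.DataFrame([e.to_dict() for e in events], columns=_EVENT_FIELDS)
    df.to_csv(path, index=False)
    return path


def events_to_json(events: Iterable[FallEvent],
                   path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(json.dumps([e.to_dict() for e in events], indent=2),
                    encoding="utf-8")
    return path


def write_manifest(rows: Iterable[dict], path: Union[str, Path]) -> Path:
    """Write a corpus manifest (filename, subject, label, variant, seed,
    ground-truth fields) as CSV."""
    path = Path(path)
    pd.DataFrame(list(rows)).to_csv(path, index=False)
    return path
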