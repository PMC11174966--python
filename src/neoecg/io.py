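"""Reading and writing the package's plain-text formats.

ECG CSV dialect: header ``time_s,ch1_mv[,ch2_mv]``, decimal point, comma
separator, UTF-8.  Events CSV: ``time_s,ph``.  WFDB records are read through
the ``wfdb`` package when it is installed (it is an optional extra).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ECGRecord

__all__ = [
    "read_ecg", "write_ecg", "read_events", "write_events",
    "write_features", "read_features", "write_report", "write_cycle",
]

_ECG_COLUMNS = ("time_s", "ch1_mv", "ch2_mv")


class FormatError(ValueError):
    """Malformed input file."""


def read_ecg(path: str | Path, format: str = "csv") -> ECGRecord:
    """Read an ECG record from CSV (default) or a WFDB record."""
    if format == "wfdb":
        return _read_wfdb(path)
    if format != "csv":
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'wfdb')")
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise FormatError(f"{path}: first column must be 'time_s', got {df.columns[0]!r}")
    chan_cols = [c for c in df.columns[1:]]
    for c in chan_cols:
        if not (c.startswith("ch") and c.endswith("_mv")):
            raise FormatError(f"{path}: unexpected channel column {c!r} (expected chN_mv)")
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise FormatError(f"{path}: column {c!r} is not numeric")
    if not chan_cols:
        raise FormatError(f"{path}: no channel columns found")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    fs = 1.0 / float(np.median(dt))
    return ECGRecord(data=df[chan_cols].to_numpy(dtype=float), fs=fs, start_time=float(t[0]))


def _read_wfdb(path: str | Path) -> ECGRecord:
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package"
        ) from exc
    rec = wfdb.rdrecord(str(path))
    return ECGRecord(data=np.asarray(rec.p_signal, dtype=float), fs=float(rec.fs))


def write_ecg(record: ECGRecord, path: str | Path) -> None:
    cols = {"time_s": record.time()}
    for c in range(record.n_channels):
        cols[f"ch{c + 1}_mv"] = record.data[:, c]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("time_s", "ph"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise FormatError(f"{path}: non-numeric {col!r} value at row {row}")
        df[col] = pd.to_numeric(df[col])
    if df[["time_s", "ph"]].isna().any().any():
        raise FormatError(f"{path}: missing values in time_s/ph")
    return df[["time_s", "ph"]]


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events[["time_s", "ph"]].to_csv(path, index=False, float_format="%.6g")


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    """Feature table as TSV with a fixed column order and float format."""
    from .features import FEATURE_COLUMNS

    table[FEATURE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))


def write_cycle(cycle, path: str | Path) -> None:
    """Representative cycle as CSV (phase, amplitude) plus a JSON sidecar
    with its provenance (variance fraction, cycle count, M, RRAvg)."""
    path = Path(path)
    pd.DataFrame({
        "phase": np.arange(cycle.m) / cycle.m,
        "amplitude": cycle.physical(),
    }).to_csv(path, index=False, float_format="%.9g")
    meta = {
        "variance_fraction": cycle.variance_fraction,
        "n_cycles": cycle.n_cycles,
        "m": cycle.m,
        "rravg_s": cycle.rravg,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
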