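"""Readers and writers for multichannel ECG records.

Two formats are supported:

* CSV - samples as rows, one header row of channel names.  CSV carries no
  sampling frequency, so ``fs`` must be supplied by the caller.  Channel
  roles are encoded in the header names (``abdominal1``, ``thoracic1``,
  ...) and recovered on read.
* WFDB format 16 - a text ``.hea`` header plus an interleaved
  little-endian 16-bit ``.dat`` signal file, the subset of the WFDB
  specification used by the PhysioNet records this tool targets.  Floats
  are quantised by a per-channel gain chosen to span the 16-bit range, so a
  write/read round trip is exact only to quantisation.

Simulated records can persist their ground truth as sidecar CSVs (source
waveforms and true peak indices).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .records import CHANNEL_ROLES, MultichannelRecord, RecordTruth

__all__ = [
    "read_record",
    "write_record",
    "read_record_csv",
    "write_record_csv",
    "read_record_wfdb",
    "write_record_wfdb",
    "write_truth_sidecar",
    "read_truth_sidecar",
]


def _role_from_name(name: str) -> str:
    for role in CHANNEL_ROLES:
        if name.lower().startswith(role):
            return role
    return "unknown"


def _channel_names(record: MultichannelRecord) -> list[str]:
    counts: dict[str, int] = {}
    names = []
    for role in record.channel_roles:
        counts[role] = counts.get(role, 0) + 1
        names.append(f"{role}{counts[role]}")
    return names


# ---------------------------------------------------------------------------
# CSV

def write_record_csv(record: MultichannelRecord, path: str | Path) -> Path:
    """Write samples x channels CSV with a header row of channel names."""
    path = Path(path)
    df = pd.DataFrame(record.X.T, columns=_channel_names(record))
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_record_csv(
    path: str | Path, fs: float, channel_roles: tuple[str, ...] | None = None
) -> MultichannelRecord:
    """Read a samples x channels CSV; ``fs`` comes from configuration."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: records need at least 2 channels, found {df.shape[1]}")
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 2  # header + 1-based
        raise FormatError(f"{path}: missing/non-numeric value near line {row}")
    roles = channel_roles or tuple(_role_from_name(c) for c in df.columns)
    return MultichannelRecord(X=df.to_numpy().T, fs=fs, channel_roles=roles)


# ---------------------------------------------------------------------------
# WFDB format 16 (minimal native implementation)

def write_record_wfdb(record: MultichannelRecord, basepath: str | Path) -> Path:
    """Write ``<base>.hea`` + ``<base>.dat`` (format 16, per-channel gain)."""
    basepath = Path(basepath)
    name = basepath.name
    m, n = record.X.shape
    gains = []
    quantised = np.empty((m, n), dtype=np.int16)
    for i, ch in enumerate(record.X):
        peak = float(np.max(np.abs(ch)))
        gain = 32000.0 / peak if peak > 0 else 1.0
        gains.append(gain)
        quantised[i] = np.round(ch * gain).astype(np.int16)
    lines = [f"{name} {m} {record.fs:g} {n}"]
    for i in range(m):
        first = int(quantised[i, 0])
        lines.append(
            f"{name}.dat 16 {gains[i]:.6f}(0)/mV 16 0 {first} 0 0 "
            f"{record.channel_roles[i]}"
        )
    basepath.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    quantised.T.reshape(-1).astype("<i2").tofile(basepath.with_suffix(".dat"))
    return basepath.with_suffix(".hea")


def read_record_wfdb(basepath: str | Path) -> MultichannelRecord:
    """Read a format-16 WFDB record written by :func:`write_record_wfdb`."""
    basepath = Path(basepath)
    hea = basepath.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"{hea}: header file not found")
    lines = [ln for ln in hea.read_text().splitlines() if ln and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea}:1: record line needs 'name nsig fs nsamples'")
    try:
        m, fs, n = int(head[1]), float(head[2]), int(head[3])
    except ValueError as exc:
        raise FormatError(f"{hea}:1: cannot parse record line ({exc})") from exc
    if len(lines) - 1 < m:
        raise FormatError(f"{hea}: header declares {m} signals, found {len(lines) - 1}")
    gains, roles = [], []
    for k, ln in enumerate(lines[1 : 1 + m], start=2):
        tok = ln.split()
        if len(tok) < 3:
            raise FormatError(f"{hea}:{k}: malformed signal line")
        if tok[1] != "16":
            raise FormatError(f"{hea}:{k}: only format 16 is supported, got {tok[1]}")
        gspec = tok[2].split("/")[0]
        gain = float(gspec.split("(")[0])
        gains.append(gain if gain != 0 else 1.0)
        roles.append(_role_from_name(tok[-1]))
    raw = np.fromfile(basepath.with_suffix(".dat"), dtype="<i2")
    if raw.size != m * n:
        raise FormatError(
            f"{basepath.with_suffix('.dat')}: expected {m * n} samples, got {raw.size}"
        )
    X = raw.reshape(n, m).T.astype(float) / np.asarray(gains)[:, None]
    return MultichannelRecord(X=X, fs=fs, channel_roles=tuple(roles))


# ---------------------------------------------------------------------------
# dispatch + truth sidecars

def read_record(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    channel_roles: tuple[str, ...] | None = None,
) -> MultichannelRecord:
    """Read a record, inferring the format from the extension if omitted."""
    path = Path(path)
    fmt = format or ("wfdb" if path.suffix in (".hea", ".dat") else "csv")
    if fmt == "csv":
        if fs is None:
            raise ParameterError("CSV records carry no sampling frequency; pass fs")
        return read_record_csv(path, fs=fs, channel_roles=channel_roles)
    if fmt == "wfdb":
        return read_record_wfdb(path.with_suffix(""))
    raise ParameterError(f"unknown record format {fmt!r}")


def write_record(
    record: MultichannelRecord, path: str | Path, format: str | None = None
) -> Path:
    path = Path(path)
    fmt = format or ("wfdb" if path.suffix in (".hea", ".dat", "") else "csv")
    if fmt == "csv":
        return write_record_csv(record, path)
    if fmt == "wfdb":
        return write_record_wfdb(record, path.with_suffix(""))
    raise ParameterError(f"unknown record format {fmt!r}")


def write_truth_sidecar(record: MultichannelRecord, basepath: str | Path) -> list[Path]:
    """Persist simulation truth: `<base>_truth.csv` (source waveforms as
    columns) and `<base>_peaks.csv` (label,index rows)."""
    if record.truth is None:
        raise ParameterError("record carries no ground truth")
    basepath = Path(basepath)
    truth_path = basepath.with_name(basepath.name + "_truth.csv")
    peaks_path = basepath.with_name(basepath.name + "_peaks.csv")
    pd.DataFrame(
        record.truth.S.T, columns=list(record.truth.source_labels)
    ).to_csv(truth_path, index=False, float_format="%.17g")
    rows = [
        {"label": lab, "index": int(i)}
        for lab, idx in record.truth.peak_indices.items()
        for i in idx
    ]
    pd.DataFrame(rows, columns=["label", "index"]).to_csv(peaks_path, index=False)
    return [truth_path, peaks_path]


def read_truth_sidecar(basepath: str | Path) -> RecordTruth:
    basepath = Path(basepath)
    truth_path = basepath.with_name(basepath.name + "_truth.csv")
    peaks_path = basepath.with_name(basepath.name + "_peaks.csv")
    df = pd.read_csv(truth_path, float_precision="round_trip")
    peaks: dict[str, np.ndarray] = {}
    if peaks_path.exists():
        pk = pd.read_csv(peaks_path)
        for lab, grp in pk.groupby("label"):
            peaks[str(lab)] = grp["index"].to_numpy(dtype=int)
    return RecordTruth(
        S=df.to_numpy().T,
        source_labels=tuple(df.columns),
        peak_indices=peaks,
    )
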