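"""Session file formats.

A session is stored as a two-column CSV (``time_s,value``; UTF-8, '.'
decimal) next to a JSON sidecar carrying subject_id, condition, signal kind
(``ecg``/``gsr``), sampling rate and units. EDF (European Data Format) files
are also readable for ECG; only the first channel is used. Cohorts carry a
manifest CSV and per-session ground-truth JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .hrv import ECGRecording
from .eda import GSRRecording

__all__ = [
    "write_session",
    "read_session_csv",
    "read_sidecar",
    "read_edf",
    "load_signal",
    "write_truth",
    "read_truth",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_session(
    path: str | Path,
    times: np.ndarray,
    values: np.ndarray,
    subject_id: str,
    condition: str,
    kind: str,
    fs: float,
    units: str,
) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": times, "value": values}).to_csv(path, index=False)
    meta = {
        "subject_id": subject_id,
        "condition": condition,
        "kind": kind,
        "fs": fs,
        "units": units,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_sidecar(path: str | Path) -> dict:
    sidecar = _sidecar_path(Path(path))
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise FormatError(f"sidecar {sidecar} lacks sampling rate 'fs'")
    return meta


def read_session_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time_s", "value"]:
        raise FormatError(f"{path}: expected columns time_s,value")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: time column is not strictly increasing")
    return t, v


def read_edf(path: str | Path) -> tuple[np.ndarray, float]:
    """Minimal EDF reader: first signal only, 16-bit little-endian samples
    scaled by the physical/digital calibration from the header."""
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            n_records = int(header[236:244].decode("ascii").strip())
            record_dur = float(header[244:252].decode("ascii").strip())
            n_signals = int(header[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"{path}: malformed EDF header") from exc
        if n_signals < 1:
            raise FormatError(f"{path}: EDF file declares no signals")
        sig_header = fh.read(256 * n_signals)

        def _field(offset: int, width: int, idx: int) -> str:
            base = offset * n_signals + idx * width
            return sig_header[base : base + width].decode("ascii").strip()

        phys_min = float(_field(104, 8, 0))
        phys_max = float(_field(112, 8, 0))
        dig_min = float(_field(120, 8, 0))
        dig_max = float(_field(128, 8, 0))
        samples_per_record = [int(_field(216, 8, i)) for i in range(n_signals)]
        if record_dur <= 0:
            raise FormatError(f"{path}: record duration missing; cannot derive fs")
        fs = samples_per_record[0] / record_dur

        gain = (phys_max - phys_min) / (dig_max - dig_min)
        chunks = []
        for _ in range(n_records):
            for i, nspr in enumerate(samples_per_record):
                raw = fh.read(2 * nspr)
                if len(raw) < 2 * nspr:
                    raise FormatError(f"{path}: truncated EDF data record")
                if i == 0:
                    dig = np.frombuffer(raw, dtype="<i2").astype(float)
                    chunks.append(phys_min + (dig - dig_min) * gain)
        return np.concatenate(chunks), fs


def load_signal(path: str | Path, format: str | None = None) -> ECGRecording | GSRRecording:
    """Load a session file into the matching recording type.

    Format is inferred from the extension unless given; the signal kind
    (ecg/gsr) comes from the sidecar (CSV) or defaults to ECG (EDF).
    """
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        samples, fs = read_edf(path)
        return ECGRecording(samples, fs)
    if fmt != "csv":
        raise FormatError(f"unknown format {fmt!r}")
    meta = read_sidecar(path)
    _, values = read_session_csv(path)
    fs = float(meta["fs"])
    if meta.get("kind") == "gsr":
        return GSRRecording(values, fs=fs)
    return ECGRecording(values, fs)


def write_truth(path: str | Path, truth) -> None:
    payload = {
        "condition": truth.condition,
        "r_peak_times": np.asarray(truth.r_peak_times).tolist(),
        "scr_events": [[float(o), float(a)] for o, a in truth.scr_events],
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
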