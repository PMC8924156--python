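"""Reading and writing recordings, tracking traces and sidecar metadata.

Delimited text (TSV) is the canonical on-disk format: an LFP file has a
header row ``time  OB  EC  dHPC`` with time in seconds in column 1; a
tracking file has columns ``t  x_body  y_body  x_nose  y_nose`` in cm
with the arena origin at the lower-left. EDF recordings are read
through :mod:`mne` when it is installed (``pip install norcircuit[edf]``).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CHANNELS, ArenaObject, Recording, TrackingTrace

_REQUIRED = tuple(c.lower() for c in CHANNELS)

TRACKING_COLUMNS = ("t", "x_body", "y_body", "x_nose", "y_nose")


def _check_channels(found: list) -> dict:
    """Map canonical channel name -> column name, case-insensitively."""
    lower = {c.lower(): c for c in found}
    missing = [name for name, key in zip(CHANNELS, _REQUIRED) if key not in lower]
    if missing:
        raise ValueError(
            f"missing channel(s) {missing}; found channels: {sorted(found)}"
        )
    return {name: lower[key] for name, key in zip(CHANNELS, _REQUIRED)}


def read_recording(path, fmt: str | None = None, animal_id: str = "",
                   group_label: str = "") -> Recording:
    """Read a 3-channel LFP recording from TSV/CSV or EDF.

    ``fmt`` is inferred from the extension when omitted ("edf" or
    "text"). The OB, EC and dHPC channels must all be present
    (case-insensitive); a missing channel is a hard error naming the
    channels that were found.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "text"
    if fmt == "edf":
        return _read_edf(path, animal_id, group_label)
    sep = "," if path.suffix.lower() == ".csv" else r"\s+"
    df = pd.read_csv(path, sep=sep)
    cols = [c for c in df.columns if c.lower() not in ("time", "t")]
    colmap = _check_channels(cols)
    tcol = [c for c in df.columns if c.lower() in ("time", "t")]
    if not tcol:
        raise ValueError("first column must be time (s); no 'time' column found")
    t = df[tcol[0]].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("recording must hold at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    data = np.vstack([df[colmap[name]].to_numpy(dtype=float) for name in CHANNELS])
    return Recording(CHANNELS, data, fs=round(fs, 6), animal_id=animal_id,
                     group_label=group_label)


def _read_edf(path: Path, animal_id: str, group_label: str) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "EDF reading requires the 'mne' package (install norcircuit[edf]); "
            "alternatively convert to delimited text"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    colmap = _check_channels(list(raw.ch_names))
    data = np.vstack([raw.get_data(picks=[colmap[name]])[0] for name in CHANNELS])
    return Recording(CHANNELS, data * 1e6, fs=float(raw.info["sfreq"]),
                     animal_id=animal_id, group_label=group_label)


def write_recording(rec: Recording, path, float_fmt: str = "%.5f") -> Path:
    """Write a recording as TSV with a time column (seconds)."""
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time": t})
    for name in rec.channels:
        df[name] = rec.channel(name)
    df.to_csv(path, sep="\t", index=False, float_format=float_fmt)
    return path


def read_tracking(path, arena=(75.0, 75.0), objects=None) -> TrackingTrace:
    """Read a tracking trace (TSV, columns t,x_body,y_body,x_nose,y_nose)."""
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+")
    lower = {c.lower(): c for c in df.columns}
    missing = [c for c in TRACKING_COLUMNS if c not in lower]
    if missing:
        raise ValueError(f"tracking file missing column(s) {missing}")
    get = lambda c: df[lower[c]].to_numpy(dtype=float)
    body = np.column_stack([get("x_body"), get("y_body")])
    nose = np.column_stack([get("x_nose"), get("y_nose")])
    return TrackingTrace(get("t"), body, nose, arena=tuple(arena),
                         objects=list(objects or []))


def write_tracking(trace: TrackingTrace, path, float_fmt: str = "%.4f") -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "t": trace.t,
        "x_body": trace.body_xy[:, 0], "y_body": trace.body_xy[:, 1],
        "x_nose": trace.nose_xy[:, 0], "y_nose": trace.nose_xy[:, 1],
    })
    df.to_csv(path, sep="\t", index=False, float_format=float_fmt)
    return path


def objects_from_config(entries) -> list:
    """Build ArenaObject list from config entries (label/center/radius dicts)."""
    out = []
    for e in entries:
        out.append(ArenaObject(e["label"], tuple(e["center"]),
                               float(e.get("radius", 5.0))))
    return out


def sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> Path:
    """Write JSON deterministically (sorted keys, fixed separators)."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
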