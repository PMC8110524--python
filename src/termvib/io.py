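"""Readers and writers for the pipeline's file formats.

Formats
-------
* Trace: mono WAV (float or 16-bit PCM) or two-column CSV ``time,velocity``.
  Metadata (colony, treatment, flash time, and — for CSV without a uniform
  grid or WAV without a usable header — the sample rate) travels in a YAML
  sidecar, by convention ``<trace>.yaml``.
* Behavior log: CSV with columns ``worker_id,behavior,onset,offset``.
* Event table: one row per classified vibration event, wide per-part
  columns ``part1..part6`` left blank where a type has fewer parts.

All CSVs are comma-separated, dot-decimal, UTF-8, with a mandatory header
row.  Writers and readers round-trip losslessly at the declared precision
(velocities to 1e-9, times to well under one sample).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .types import (
    BehaviorLog,
    BehaviorRecord,
    Part,
    Trace,
    Treatment,
    VibrationEvent,
)

log = logging.getLogger(__name__)

#: Relative tolerance for the uniform-spacing check on CSV time columns.
UNIFORMITY_RTOL = 1e-6

_BEHAVIOR_COLUMNS = ["worker_id", "behavior", "onset", "offset"]


# --------------------------------------------------------------------------
# sidecar metadata

def _metadata_dict(trace: Trace) -> dict:
    d = {"sample_rate": float(trace.sample_rate), "t0": float(trace.t0)}
    if trace.colony_id is not None:
        d["colony_id"] = trace.colony_id
    if trace.treatment is not None:
        d["reproductives"] = bool(trace.treatment.reproductives)
        d["flashlight"] = bool(trace.treatment.flashlight)
    if trace.flash_time is not None:
        d["flash_time"] = float(trace.flash_time)
    return d


def _apply_metadata(meta: dict, samples: np.ndarray,
                    sample_rate: Optional[float]) -> Trace:
    rate = meta.get("sample_rate", sample_rate)
    if rate is None:
        raise ValueError("sample rate unavailable: not in file header, time "
                         "column, or sidecar metadata")
    treatment = None
    if "reproductives" in meta or "flashlight" in meta:
        treatment = Treatment(bool(meta.get("reproductives", False)),
                              bool(meta.get("flashlight", False)))
    return Trace(samples=samples, sample_rate=float(rate),
                 t0=float(meta.get("t0", 0.0)),
                 colony_id=meta.get("colony_id"),
                 treatment=treatment,
                 flash_time=meta.get("flash_time"))


def _load_sidecar(path: Path, sidecar) -> dict:
    if sidecar is None:
        candidate = Path(str(path) + ".yaml")
        if candidate.exists():
            sidecar = candidate
        else:
            return {}
    meta = yaml.safe_load(Path(sidecar).read_text())
    if meta is None:
        return {}
    if not isinstance(meta, dict):
        raise ValueError(f"{sidecar}: sidecar must be a YAML mapping")
    return meta


# --------------------------------------------------------------------------
# traces

def read_trace(path, fmt: Optional[str] = None, sidecar=None) -> Trace:
    """Read a velocity trace from WAV or CSV, validating as it goes.

    ``fmt`` defaults to the file extension.  WAV supplies the sample rate
    from its header (16-bit PCM is rescaled to [-1, 1); float data is kept
    as is).  CSV must have ``time`` and ``velocity`` columns; the time
    column must be uniformly spaced to within 1 ppm relative tolerance and
    yields the sample rate.  NaN samples and non-uniform time grids are
    hard errors (the error names the first offending row).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    meta = _load_sidecar(path, sidecar)

    if fmt == "wav":
        rate, data = wavfile.read(path)
        if data.ndim != 1:
            raise ValueError(f"{path}: expected a mono WAV")
        if data.dtype == np.int16:
            data = data.astype(float) / 32768.0
        else:
            data = data.astype(float)
        if np.any(~np.isfinite(data)):
            bad = int(np.flatnonzero(~np.isfinite(data))[0])
            raise ValueError(f"{path}: non-finite sample at index {bad}")
        meta.setdefault("sample_rate", float(rate))
        return _apply_metadata(meta, data, float(rate))

    if fmt == "csv":
        df = pd.read_csv(path)
        cols = {c.lower().strip(): c for c in df.columns}
        if "time" not in cols or "velocity" not in cols:
            raise ValueError(f"{path}: CSV trace needs 'time' and 'velocity' columns")
        t = df[cols["time"]].to_numpy(dtype=float)
        v = df[cols["velocity"]].to_numpy(dtype=float)
        if np.any(~np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise ValueError(f"{path}: non-finite velocity at row {bad}")
        if np.any(~np.isfinite(t)):
            bad = int(np.flatnonzero(~np.isfinite(t))[0])
            raise ValueError(f"{path}: non-finite time at row {bad}")
        if t.size < 2:
            raise ValueError(f"{path}: need at least 2 samples")
        dt = np.diff(t)
        dt0 = float(np.median(dt))
        if dt0 <= 0:
            bad = int(np.flatnonzero(dt <= 0)[0])
            raise ValueError(f"{path}: time not strictly increasing at row {bad + 1}")
        rel = np.abs(dt / dt0 - 1.0)
        if np.any(rel > UNIFORMITY_RTOL):
            bad = int(np.argmax(rel > UNIFORMITY_RTOL))
            raise ValueError(
                f"{path}: non-uniform time spacing at row {bad + 1} "
                f"(dt={dt[bad]:.9g}, expected {dt0:.9g})"
            )
        rate = 1.0 / dt0
        if abs(rate - round(rate)) < 1e-6 * rate:
            rate = float(round(rate))
        meta.setdefault("sample_rate", rate)
        meta.setdefault("t0", float(t[0]))
        return _apply_metadata(meta, v, rate)

    raise ValueError(f"unsupported trace format: {fmt!r}")


def write_trace(trace: Trace, path, fmt: Optional[str] = None,
                sidecar: bool = True) -> None:
    """Write a trace as float64 WAV or ``time,velocity`` CSV.

    Float64 WAV keeps the round trip bit-exact.  A YAML metadata sidecar
    ``<path>.yaml`` is written unless suppressed.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "wav":
        rate = trace.sample_rate
        if abs(rate - round(rate)) > 1e-9:
            raise ValueError("WAV requires an integer sample rate; use CSV")
        wavfile.write(path, int(round(rate)), trace.samples.astype(np.float64))
    elif fmt == "csv":
        t = trace.times
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("time,velocity\n")
            for ti, vi in zip(t, trace.samples):
                fh.write(f"{ti:.17g},{vi:.17g}\n")
    else:
        raise ValueError(f"unsupported trace format: {fmt!r}")
    if sidecar:
        Path(str(path) + ".yaml").write_text(
            yaml.safe_dump(_metadata_dict(trace), sort_keys=True))


# --------------------------------------------------------------------------
# behavior logs

def read_behavior_log(path) -> BehaviorLog:
    """Read a scored-behavior CSV; rows come back sorted by onset.

    Unknown columns are ignored with a logged warning; a row whose offset
    precedes its onset is a hard error.
    """
    df = pd.read_csv(path)
    missing = [c for c in _BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in _BEHAVIOR_COLUMNS]
    if extra:
        log.warning("%s: ignoring unknown columns %s", path, extra)
    records = []
    for i, row in df.iterrows():
        onset, offset = float(row["onset"]), float(row["offset"])
        if offset < onset:
            raise ValueError(
                f"{path}: row {i}: offset {offset} precedes onset {onset}")
        records.append(BehaviorRecord(str(row["worker_id"]),
                                      str(row["behavior"]), onset, offset))
    return BehaviorLog(records)


def write_behavior_log(log_: BehaviorLog, path) -> None:
    df = pd.DataFrame(
        [{"worker_id": r.worker_id, "behavior": r.behavior,
          "onset": r.onset, "offset": r.offset} for r in log_],
        columns=_BEHAVIOR_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.9f")


# --------------------------------------------------------------------------
# event tables

_EVENT_BASE_COLUMNS = [
    "colony_id", "reproductives", "flashlight", "onset", "offset",
    "bs_type", "n_parts", "beyond_range", "total_duration", "total_pulses",
    "mean_amplitude", "unique_flag",
]


def _event_columns() -> List[str]:
    cols = list(_EVENT_BASE_COLUMNS)
    for i in range(1, 7):
        cols += [f"part{i}_duration", f"part{i}_pulses",
                 f"part{i}_frequency", f"part{i}_amplitude"]
    return cols


def events_to_frame(events: Sequence[VibrationEvent]) -> pd.DataFrame:
    """Tabulate classified events, wide per-part columns blank when absent."""
    rows = []
    for ev in events:
        row = {
            "colony_id": ev.colony_id,
            "reproductives": None if ev.treatment is None else ev.treatment.reproductives,
            "flashlight": None if ev.treatment is None else ev.treatment.flashlight,
            "onset": ev.onset, "offset": ev.offset,
            "bs_type": ev.bs_type, "n_parts": ev.n_parts,
            "beyond_range": ev.beyond_range,
            "total_duration": ev.total_duration,
            "total_pulses": ev.total_pulses,
            "mean_amplitude": ev.mean_amplitude,
            "unique_flag": ev.unique_flag,
        }
        for p in ev.parts[:6]:
            row[f"part{p.index}_duration"] = p.duration
            row[f"part{p.index}_pulses"] = p.n_pulses
            row[f"part{p.index}_frequency"] = p.frequency
            row[f"part{p.index}_amplitude"] = p.amplitude
        rows.append(row)
    return pd.DataFrame(rows, columns=_event_columns())


def write_event_table(events: Sequence[VibrationEvent], path) -> None:
    """Write one row per event; zero events still writes the header."""
    events_to_frame(events).to_csv(path, index=False)


def read_event_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _event_columns() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing event-table columns {missing}")
    return df
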