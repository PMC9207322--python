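"""Canonical epoch representation and long-CSV waveform I/O.

A flash-ERG study is held as a :class:`StudyTable` of :class:`ERGRecording`
epochs, one per (participant, eye, flash strength, repeat).  The on-disk
dialect is a long CSV with one sample per row and mandatory header
``participant,group,eye,flash,repeat,time_ms,microvolts``; flash onset defines
t = 0 ms, so pre-stimulus samples carry negative times.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "EYES",
    "ERGRecording",
    "StudyTable",
    "SchemaError",
    "StructuralError",
    "read_waveforms",
    "write_waveforms",
]

GROUPS = ("ASD", "ADHD", "control", "other")
EYES = ("right", "left")

REQUIRED_COLUMNS = ("participant", "group", "eye", "flash", "time_ms", "microvolts")

#: relative tolerance on time-grid uniformity
_GRID_RTOL = 1e-9
#: relative tolerance between the declared sampling rate and the time spacing
_RATE_RTOL = 1e-6


class SchemaError(ValueError):
    """A required column is missing or a field has the wrong type."""


class StructuralError(ValueError):
    """Rows are present but do not form valid uniformly sampled epochs."""


@dataclass
class ERGRecording:
    """One epoch of amplitude vs time for one participant/eye/flash.

    Parameters
    ----------
    participant_id : str
        Study identifier of the participant.
    group : str
        One of ``ASD``, ``ADHD``, ``control``, ``other``.
    eye : str
        ``right`` or ``left``.
    flash_strength : float
        Flash luminous energy in log photopic cd·s·m⁻².
    time_ms : ndarray
        Strictly increasing, uniformly spaced sample times in ms; flash
        onset at 0 ms.
    amplitude_uv : ndarray
        Signal in μV, same length as ``time_ms``, finite everywhere.
    sampling_rate_hz : float
        Must agree with the time spacing to 1e-6 relative.
    metadata : dict
        Free-form per-recording metadata (iris_color_index,
        electrode_height_mm, age_years, sex, repeat, n_kept, ...).
    """

    participant_id: str
    group: str
    eye: str
    flash_strength: float
    time_ms: np.ndarray
    amplitude_uv: np.ndarray
    sampling_rate_hz: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.amplitude_uv = np.asarray(self.amplitude_uv, dtype=float)
        if self.group not in GROUPS:
            raise SchemaError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.eye not in EYES:
            raise SchemaError(f"unknown eye {self.eye!r}; expected one of {EYES}")
        if self.time_ms.ndim != 1 or self.amplitude_uv.shape != self.time_ms.shape:
            raise StructuralError("time_ms and amplitude_uv must be 1-D and equal length")
        if self.time_ms.size < 2:
            raise StructuralError("an epoch needs at least two samples")
        if not np.all(np.isfinite(self.amplitude_uv)):
            raise StructuralError("amplitude_uv contains non-finite values")
        dt = np.diff(self.time_ms)
        if np.any(dt <= 0):
            raise StructuralError("time_ms must be strictly increasing")
        dt0 = dt[0]
        if np.any(np.abs(dt - dt0) > _GRID_RTOL * abs(dt0)):
            raise StructuralError("time grid is not uniform")
        implied = 1000.0 / dt0
        if abs(implied - self.sampling_rate_hz) > _RATE_RTOL * implied:
            raise StructuralError(
                f"sampling_rate_hz {self.sampling_rate_hz} inconsistent with "
                f"time spacing (implies {implied:.6f} Hz)"
            )

    @property
    def n_samples(self) -> int:
        return self.time_ms.size

    @property
    def key(self) -> tuple:
        """(participant_id, eye, flash_strength, repeat) identity of the epoch."""
        return (
            self.participant_id,
            self.eye,
            self.flash_strength,
            int(self.metadata.get("repeat", 0)),
        )


@dataclass
class StudyTable:
    """A collection of recordings plus provenance of how they were obtained."""

    recordings: list[ERGRecording]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self) -> Iterator[ERGRecording]:
        return iter(self.recordings)

    def check_unique_keys(self) -> None:
        keys = [r.key for r in self.recordings]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise StructuralError(f"duplicate recording key {dup}")

    def groups(self) -> list[str]:
        return sorted({r.group for r in self.recordings})


def read_waveforms(path: str | Path, dialect: str = "long_csv") -> StudyTable:
    """Read a long-CSV waveform table into a :class:`StudyTable`.

    One :class:`ERGRecording` is produced per (participant, eye, flash,
    repeat); rows within a recording are sorted by time.  A missing
    ``repeat`` column defaults to repeat 0.
    """
    if dialect != "long_csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant": str, "group": str, "eye": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if "repeat" not in df.columns:
        df["repeat"] = 0
    for col in ("flash", "time_ms", "microvolts"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise SchemaError(
                f"non-numeric value in column {col!r} at row {int(bad.idxmax())}"
            )
        if coerced.isna().any():
            raise SchemaError(f"missing value in column {col!r}")
        df[col] = coerced

    meta_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS + ("repeat",)]
    recordings: list[ERGRecording] = []
    for (pid, group, eye, flash, repeat), sub in df.groupby(
        ["participant", "group", "eye", "flash", "repeat"], sort=True
    ):
        sub = sub.sort_values("time_ms")
        t = sub["time_ms"].to_numpy()
        if np.unique(t).size != t.size:
            raise StructuralError(
                f"duplicate time sample for (participant={pid}, eye={eye}, "
                f"flash={flash}, repeat={repeat})"
            )
        dt = np.diff(t)
        if np.any(np.abs(dt - dt[0]) > _GRID_RTOL * abs(dt[0])):
            raise StructuralError(
                f"non-uniform time grid for (participant={pid}, eye={eye}, "
                f"flash={flash}, repeat={repeat})"
            )
        meta = {"repeat": int(repeat)}
        for c in meta_cols:
            v = sub[c].iloc[0]
            if pd.notna(v):
                meta[c] = v
        recordings.append(
            ERGRecording(
                participant_id=str(pid),
                group=str(group),
                eye=str(eye),
                flash_strength=float(flash),
                time_ms=t,
                amplitude_uv=sub["microvolts"].to_numpy(),
                sampling_rate_hz=1000.0 / dt[0],
                metadata=meta,
            )
        )
    study = StudyTable(recordings, provenance={"source": str(path), "dialect": dialect})
    study.check_unique_keys()
    return study


def write_waveforms(study: StudyTable, path: str | Path) -> Path:
    """Write a :class:`StudyTable` as long CSV readable by :func:`read_waveforms`.

    Numeric fields are serialized with 12 significant digits so that a
    read/write round trip reproduces amplitudes to better than 1e-9 relative.
    """
    if len(study) == 0:
        raise ValueError("refusing to write an empty study")
    path = Path(path)
    buf = io.StringIO()
    buf.write("participant,group,eye,flash,repeat,time_ms,microvolts\n")
    # canonical key order so write∘read∘write is byte-stable
    for rec in sorted(study, key=lambda r: r.key):
        head = (
            f"{rec.participant_id},{rec.group},{rec.eye},"
            f"{rec.flash_strength:.12g},{int(rec.metadata.get('repeat', 0))},"
        )
        for t, a in zip(rec.time_ms, rec.amplitude_uv):
            buf.write(f"{head}{t:.12g},{a:.12g}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_participant_metadata(path: str | Path) -> Mapping[str, dict]:
    """Read a participant metadata table (CSV or JSON) keyed by participant id."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        import json

        data = json.loads(path.read_text())
        return {str(k): dict(v) for k, v in data.items()}
    df = pd.read_csv(path, dtype={"participant": str})
    if "participant" not in df.columns:
        raise SchemaError("missing required column 'participant'")
    return {
        str(row["participant"]): {
            k: v for k, v in row.items() if k != "participant" and pd.notna(v)
        }
        for _, row in df.iterrows()
    }
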