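"""Sweep averaging with centile rejection, QC filtering, and epoch resampling.

The recording protocol averages ~60 sweeps per flash; sweeps whose
peak-to-peak amplitude falls outside the interquartile band of the sweep set
are rejected before averaging.  Inclusion rules: a-wave amplitude must exceed
1 μV, and recordings with the electrode placed more than 2 mm below the
reference position are excluded.  The analysis grid for the dyadic wavelet
transform is 256 samples at 2048 Hz starting at -20 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import EpochSpec
from .waveform_io import ERGRecording

__all__ = [
    "QCReport",
    "DegenerateInputError",
    "A_WAVE_MIN_UV",
    "ELECTRODE_MIN_MM",
    "centile_rejection",
    "average_traces",
    "qc_filter",
    "resample_epoch",
]

#: inclusion threshold on a-wave amplitude (μV); waveforms at or below fail QC
A_WAVE_MIN_UV = 1.0
#: electrode heights below this (mm relative to reference) are excluded
ELECTRODE_MIN_MM = -2


class DegenerateInputError(ValueError):
    """Too few sweeps (or otherwise degenerate input) for the operation."""


@dataclass(frozen=True)
class QCReport:
    """Inclusion decision for one recording, with machine-readable reasons."""

    key: tuple
    passed: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.passed == (len(self.reasons) == 0)

    def as_row(self) -> dict:
        pid, eye, flash, repeat = self.key
        return {
            "participant": pid,
            "eye": eye,
            "flash": flash,
            "repeat": repeat,
            "passed": self.passed,
            "reasons": ";".join(self.reasons),
        }


def _peak_to_peak(traces: np.ndarray) -> np.ndarray:
    return traces.max(axis=1) - traces.min(axis=1)


def centile_rejection(traces: np.ndarray) -> np.ndarray:
    """Keep sweeps whose peak-to-peak amplitude lies in the interquartile band.

    Parameters
    ----------
    traces : ndarray, shape (n_sweeps, n_samples)
        Equal-length sweeps on identical time grids.

    Returns
    -------
    ndarray
        The kept subset (rows of ``traces``); always at least one sweep.
        Sweeps with peak-to-peak amplitude inside [25th, 75th] percentile
        (inclusive) of the sweep set are kept, rejecting both high- and
        low-amplitude outliers.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 4:
        raise DegenerateInputError("centile rejection needs at least 4 sweeps")
    ptp = _peak_to_peak(traces)
    lo, hi = np.percentile(ptp, [25.0, 75.0])
    keep = (ptp >= lo) & (ptp <= hi)
    if not keep.any():  # unreachable for finite data, but guarantee >= 1 sweep
        keep[np.argmin(np.abs(ptp - np.median(ptp)))] = True
    return traces[keep]


def average_traces(
    traces: np.ndarray,
    template: ERGRecording,
    rejection: bool = True,
) -> ERGRecording:
    """Pointwise mean of (optionally centile-filtered) sweeps.

    ``template`` supplies the time grid and identifying metadata; the output
    records ``n_kept``/``n_total`` in its metadata.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim == 1:
        traces = traces[None, :]
    if traces.shape[1] != template.n_samples:
        raise ValueError("sweep length does not match the template grid")
    n_total = traces.shape[0]
    kept = centile_rejection(traces) if rejection else traces
    meta = dict(template.metadata)
    meta.update(n_kept=kept.shape[0], n_total=n_total)
    return ERGRecording(
        participant_id=template.participant_id,
        group=template.group,
        eye=template.eye,
        flash_strength=template.flash_strength,
        time_ms=template.time_ms.copy(),
        amplitude_uv=kept.mean(axis=0),
        sampling_rate_hz=template.sampling_rate_hz,
        metadata=meta,
    )


def qc_filter(
    recording: ERGRecording,
    a_amp_uv: float,
    electrode_height_mm: int | None = None,
) -> QCReport:
    """Apply the study inclusion rules to one recording.

    Fails with ``a_wave_too_small`` iff the measured a-wave amplitude is
    ≤ 1 μV, and with ``electrode_too_low`` iff the electrode sat more than
    2 mm below the reference position.  Missing electrode metadata does not
    fail.  Pure predicate: depends only on this recording's measurements.
    """
    if electrode_height_mm is None:
        electrode_height_mm = recording.metadata.get("electrode_height_mm")
    reasons = []
    if not np.isfinite(a_amp_uv):
        reasons.append("missing_samples")
    elif a_amp_uv <= A_WAVE_MIN_UV:
        reasons.append("a_wave_too_small")
    if electrode_height_mm is not None and electrode_height_mm < ELECTRODE_MIN_MM:
        reasons.append("electrode_too_low")
    return QCReport(key=recording.key, passed=not reasons, reasons=tuple(reasons))


def resample_epoch(
    recording: ERGRecording,
    epoch: EpochSpec = EpochSpec(),
) -> ERGRecording:
    """Linearly interpolate a recording onto the uniform analysis grid.

    No extrapolation: the requested epoch must lie inside the recorded time
    range.  If the recording is already on the target grid it is returned
    with only the ``analysis_ready`` flag added.
    """
    t_new = epoch.times()
    t_old = recording.time_ms
    if t_new[0] < t_old[0] - 1e-9 or t_new[-1] > t_old[-1] + 1e-9:
        raise ValueError(
            f"requested epoch [{t_new[0]}, {t_new[-1]}] ms outside recorded "
            f"range [{t_old[0]}, {t_old[-1]}] ms"
        )
    if t_new.size == t_old.size and np.allclose(t_new, t_old, rtol=0, atol=1e-9):
        x = recording.amplitude_uv.copy()
    else:
        x = np.interp(t_new, t_old, recording.amplitude_uv)
    meta = dict(recording.metadata)
    meta["analysis_ready"] = True
    return ERGRecording(
        participant_id=recording.participant_id,
        group=recording.group,
        eye=recording.eye,
        flash_strength=recording.flash_strength,
        time_ms=t_new,
        amplitude_uv=x,
        sampling_rate_hz=epoch.sampling_rate_hz,
        metadata=meta,
    )
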