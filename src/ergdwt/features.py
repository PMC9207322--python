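"""Haar DWT scalogram and the band/window energy descriptors of the flash ERG.

The epoch (256 samples at 2048 Hz from -20 ms) is decomposed with the
orthonormal Haar wavelet into a full dyadic pyramid.  Detail level j spans
the nominal frequency band [fs/2^(j+1), fs/2^j]; at 2048 Hz levels 6, 5, 4
and 3 bracket the nominal band centers 20, 40, 80 and 160 Hz.  Each detail
coefficient d(j,k) has compact time support of 2^j samples, which tiles the
epoch and lets coefficients be assigned to the physiologic time windows of
the a-wave, b-wave and oscillatory potentials (OPs):

======  =========  ==================  ===================
 name    band Hz    window (ms)         ERG component
======  =========  ==================  ===================
 a20       20       [-20, 17.5]         ON-pathway, a-wave
 a40       40       [0, 17.5]           OFF-pathway, a-wave
 b20       20       [17.5, 55]          ON-pathway, b-wave
 b40       40       [17.5, 55]          OFF-pathway, b-wave
 op80      80       [8.125, 55]         slow OPs
 op160    160       [8.125, 55]         fast OPs
======  =========  ==================  ===================

%OPs = 100·(op80 + op160)/(b20 + b40 + op80 + op160) quantifies the OPs'
share of the summed b-wave + OP band energies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .waveform_io import ERGRecording

__all__ = [
    "BAND_LEVELS_2048",
    "DEFAULT_WINDOWS_MS",
    "DESCRIPTOR_NAMES",
    "CoefficientPyramid",
    "Scalogram",
    "DWTDescriptors",
    "TimeDomainFeatures",
    "haar_dwt",
    "inverse_haar_dwt",
    "build_scalogram",
    "extract_descriptors",
    "percent_ops",
    "time_domain_features",
    "describe_recording",
]

#: nominal band center (Hz) -> dyadic detail level at a 2048 Hz sampling rate
BAND_LEVELS_2048 = {160: 3, 80: 4, 40: 5, 20: 6}

#: descriptor name -> (band center Hz, (window start ms, window end ms))
DEFAULT_WINDOWS_MS = {
    "a20": (20, (-20.0, 17.5)),
    "a40": (40, (0.0, 17.5)),
    "b20": (20, (17.5, 55.0)),
    "b40": (40, (17.5, 55.0)),
    "op80": (80, (8.125, 55.0)),
    "op160": (160, (8.125, 55.0)),
}

DESCRIPTOR_NAMES = tuple(DEFAULT_WINDOWS_MS)

_MODES = ("max_abs", "rss", "sum_abs")


@dataclass
class CoefficientPyramid:
    """Full dyadic orthonormal Haar decomposition of one epoch.

    ``levels[j]`` holds the detail coefficients d(j, k), k = 0..n/2^j - 1;
    ``approximation`` is the single coarsest-level scaling coefficient.
    The transform is orthonormal: Parseval's identity and perfect
    reconstruction hold to floating-point precision.
    """

    levels: dict[int, np.ndarray]
    approximation: np.ndarray
    sampling_rate_hz: float
    epoch_start_ms: float

    @property
    def n_samples(self) -> int:
        return 2 ** max(self.levels)

    def energy(self) -> float:
        return float(
            sum(np.sum(d**2) for d in self.levels.values())
            + np.sum(self.approximation**2)
        )

    def segment_bounds_ms(self, level: int) -> np.ndarray:
        """Time-support edges (ms) of the level's coefficients, tiling the epoch."""
        width = 2**level / self.sampling_rate_hz * 1000.0
        n = self.n_samples // 2**level
        return self.epoch_start_ms + width * np.arange(n + 1)


@dataclass
class Scalogram:
    """Coefficient magnitudes organized by nominal frequency band.

    ``bands[center_hz]`` is a list of ``(t_start_ms, t_end_ms, magnitude)``
    segments tiling the epoch, plus the signed coefficients kept alongside
    for window extraction.
    """

    bands: dict[int, list[tuple[float, float, float]]]
    coefficients: dict[int, np.ndarray]
    epoch_span_ms: tuple[float, float]
    sampling_rate_hz: float

    def band_midpoints_ms(self, center_hz: int) -> np.ndarray:
        return np.array([(s + e) / 2.0 for s, e, _ in self.bands[center_hz]])


@dataclass
class DWTDescriptors:
    """The six band/window energies plus %OPs for one recording."""

    a20: float
    a40: float
    b20: float
    b40: float
    op80: float
    op160: float
    pct_ops: float | None = None
    mode: str = "rss"

    def __post_init__(self) -> None:
        if self.pct_ops is None:
            denom = self.b20 + self.b40 + self.op80 + self.op160
            self.pct_ops = (
                100.0 * (self.op80 + self.op160) / denom if denom > 0 else None
            )

    def as_dict(self) -> dict:
        return {
            "a20": self.a20, "a40": self.a40, "b20": self.b20, "b40": self.b40,
            "op80": self.op80, "op160": self.op160, "pct_ops": self.pct_ops,
        }


@dataclass
class TimeDomainFeatures:
    """Conventional time-domain measures: a-wave and b-wave amplitude/time."""

    a_amp: float
    a_time_ms: float
    b_amp: float
    b_time_ms: float


def _require_power_of_two(n: int) -> int:
    j = int(math.log2(n))
    if 2**j != n:
        raise ValueError(
            f"epoch length {n} is not a power of two; resample onto the "
            "analysis grid first (see preprocess.resample_epoch)"
        )
    return j


def haar_dwt(recording: ERGRecording | np.ndarray) -> CoefficientPyramid:
    """Full dyadic orthonormal Haar decomposition.

    Accepts an analysis-ready recording or a bare power-of-two-length signal.
    Coefficient d(j, k) equals the inner product of the signal with the
    discrete orthonormal Haar basis function at scale 2^j and translate k
    (+1/√(2^j) on the first half of its support, -1/√(2^j) on the second).
    """
    if isinstance(recording, ERGRecording):
        x = recording.amplitude_uv
        fs = recording.sampling_rate_hz
        start = float(recording.time_ms[0])
    else:
        x = np.asarray(recording, dtype=float)
        fs = 2048.0
        start = -20.0
    depth = _require_power_of_two(x.size)
    coeffs = pywt.wavedec(x, "haar", mode="periodization", level=depth)
    approx = np.asarray(coeffs[0], dtype=float)
    levels = {
        depth - i + 1: np.asarray(c, dtype=float)
        for i, c in enumerate(coeffs[1:], start=1)
    }
    return CoefficientPyramid(
        levels=levels, approximation=approx, sampling_rate_hz=fs, epoch_start_ms=start
    )


def inverse_haar_dwt(pyramid: CoefficientPyramid) -> np.ndarray:
    """Reconstruct the signal from a coefficient pyramid (exact inverse)."""
    depth = max(pyramid.levels)
    coeffs = [pyramid.approximation] + [
        pyramid.levels[j] for j in range(depth, 0, -1)
    ]
    return pywt.waverec(coeffs, "haar", mode="periodization")


def build_scalogram(
    pyramid: CoefficientPyramid,
    band_levels: dict[int, int] | None = None,
) -> Scalogram:
    """Map DWT levels to nominal ERG frequency bands with time supports.

    At 2048 Hz the default map assigns level 3 (128–256 Hz) to the 160 Hz
    band, level 4 (64–128 Hz) to 80 Hz, level 5 (32–64 Hz) to 40 Hz and
    level 6 (16–32 Hz) to 20 Hz.  Any other sampling rate requires an
    explicit ``band_levels`` map.
    """
    if band_levels is None:
        if abs(pyramid.sampling_rate_hz - 2048.0) > 1e-6:
            raise ValueError(
                f"no default band map for sampling rate {pyramid.sampling_rate_hz} Hz; "
                "pass band_levels explicitly"
            )
        band_levels = BAND_LEVELS_2048
    bands: dict[int, list[tuple[float, float, float]]] = {}
    coefficients: dict[int, np.ndarray] = {}
    for center, level in band_levels.items():
        if level not in pyramid.levels:
            raise ValueError(f"pyramid has no level {level} for band {center} Hz")
        d = pyramid.levels[level]
        edges = pyramid.segment_bounds_ms(level)
        bands[center] = [
            (float(edges[k]), float(edges[k + 1]), float(abs(d[k])))
            for k in range(d.size)
        ]
        coefficients[center] = d
    span = (
        pyramid.epoch_start_ms,
        pyramid.epoch_start_ms + pyramid.n_samples / pyramid.sampling_rate_hz * 1000.0,
    )
    return Scalogram(
        bands=bands,
        coefficients=coefficients,
        epoch_span_ms=span,
        sampling_rate_hz=pyramid.sampling_rate_hz,
    )


def _window_value(
    scalogram: Scalogram, center_hz: int, window: tuple[float, float], mode: str
) -> float:
    mids = scalogram.band_midpoints_ms(center_hz)
    inside = (mids >= window[0]) & (mids <= window[1])
    if not inside.any():
        warnings.warn(
            f"no coefficient midpoint of the {center_hz} Hz band falls in "
            f"window {window}; descriptor set to 0",
            stacklevel=3,
        )
        return 0.0
    mags = np.abs(scalogram.coefficients[center_hz][inside])
    if mode == "max_abs":
        return float(mags.max())
    if mode == "rss":
        return float(np.sqrt(np.sum(mags**2)))
    if mode == "sum_abs":
        return float(mags.sum())
    raise ValueError(f"unknown mode {mode!r}; expected one of {_MODES}")


def extract_descriptors(
    scalogram: Scalogram,
    windows: dict | None = None,
    mode: str = "rss",
) -> DWTDescriptors:
    """Reduce the scalogram to the six band/window descriptors.

    A coefficient belongs to a window iff its time-segment midpoint lies in
    the closed window interval.  ``mode`` selects the reduction over the
    window's coefficient magnitudes: ``rss`` (default; root sum of squares,
    i.e. the square root of the window's energy — phase-insensitive by
    Parseval), ``max_abs`` (scalogram-maxima descriptors) or ``sum_abs``.
    """
    windows = windows or DEFAULT_WINDOWS_MS
    values = {
        name: _window_value(scalogram, center, win, mode)
        for name, (center, win) in windows.items()
    }
    return DWTDescriptors(**values, mode=mode)


def percent_ops(d: DWTDescriptors) -> float | None:
    """OPs' percentage share of the summed b-wave + OP band energies.

    Returns ``None`` (undefined) when the denominator is zero.
    """
    denom = d.b20 + d.b40 + d.op80 + d.op160
    if denom <= 0:
        return None
    return 100.0 * (d.op80 + d.op160) / denom


def time_domain_features(
    recording: ERGRecording,
    a_window_ms: tuple[float, float] = (5.0, 25.0),
    b_max_ms: float = 60.0,
) -> TimeDomainFeatures:
    """Baseline-referenced a-wave and trough-to-peak b-wave measures.

    The baseline is the mean of the pre-stimulus (t < 0) samples.  The
    a-trough is the minimum in ``a_window_ms``; a_amp = max(0, baseline -
    trough).  The b-peak is the maximum in (a_time, ``b_max_ms``]; b_amp is
    measured trough-to-peak, the conventional clinical definition.
    """
    t = recording.time_ms
    x = recording.amplitude_uv
    if t[0] > a_window_ms[0] or t[-1] < b_max_ms:
        raise ValueError(
            f"epoch [{t[0]}, {t[-1]}] ms does not cover the search windows"
        )
    pre = x[t < 0]
    baseline = float(pre.mean()) if pre.size else 0.0
    a_mask = (t >= a_window_ms[0]) & (t <= a_window_ms[1])
    i_a = np.flatnonzero(a_mask)[np.argmin(x[a_mask])]
    a_time = float(t[i_a])
    trough = float(x[i_a])
    b_mask = (t > a_time) & (t <= b_max_ms)
    i_b = np.flatnonzero(b_mask)[np.argmax(x[b_mask])]
    return TimeDomainFeatures(
        a_amp=max(0.0, baseline - trough),
        a_time_ms=a_time,
        b_amp=float(x[i_b]) - trough,
        b_time_ms=float(t[i_b]),
    )


def describe_recording(
    recording: ERGRecording, mode: str = "rss", windows: dict | None = None
) -> dict:
    """One flat feature row for a recording: descriptors + time-domain measures."""
    pyr = haar_dwt(recording)
    desc = extract_descriptors(build_scalogram(pyr), windows=windows, mode=mode)
    td = time_domain_features(recording)
    row = {
        "participant": recording.participant_id,
        "group": recording.group,
        "eye": recording.eye,
        "flash": recording.flash_strength,
    }
    row.update(desc.as_dict())
    row.update(
        a_amp=td.a_amp, a_time_ms=td.a_time_ms, b_amp=td.b_amp, b_time_ms=td.b_time_ms
    )
    return row


def plot_scalogram(scalogram: Scalogram, ax=None, vmax: float | None = None):
    """Render per-band segment rectangles colored by coefficient magnitude.

    ``vmax`` lets several scalograms share a color scale (normalization to a
    reference recording).  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    centers = sorted(scalogram.bands)
    if vmax is None:
        vmax = max(
            (m for segs in scalogram.bands.values() for _, _, m in segs), default=1.0
        ) or 1.0
    cmap = plt.get_cmap("jet")
    for row, center in enumerate(centers):
        for t0, t1, mag in scalogram.bands[center]:
            ax.add_patch(
                Rectangle(
                    (t0, row), t1 - t0, 1.0,
                    facecolor=cmap(min(mag / vmax, 1.0)), edgecolor="none",
                )
            )
    ax.set_xlim(scalogram.epoch_span_ms)
    ax.set_ylim(0, len(centers))
    ax.set_yticks([r + 0.5 for r in range(len(centers))])
    ax.set_yticklabels([f"{c} Hz" for c in centers])
    ax.set_xlabel("time (ms)")
    return ax
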