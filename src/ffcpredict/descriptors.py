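"""Facial activity descriptors (FADs).

A FAD condenses one participant's channel time-series over one contiguous
temporal segment into a fixed-length vector: each channel is low-pass
smoothed (first-order Butterworth, 1 Hz cutoff, zero-phase), its first and
second finite-difference derivatives are taken, and 16 summary statistics are
computed on each of the three signals.  The vector layout is channel-major:

    (channel, signal-variant in {smoothed, d1, d2}, statistic 1..16)

so the length is ``n_channels * 48``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .errors import ConfigurationError, InsufficientDataError
from .io import FeatureSetSpec, FrameFeatureTable

CUTOFF_HZ = 1.0
N_STATISTICS = 16
N_VARIANTS = 3  # smoothed, first derivative, second derivative
STATS_PER_CHANNEL = N_STATISTICS * N_VARIANTS

#: Names of the 16 summary statistics, in layout order.
STATISTIC_NAMES = (
    "mean",
    "std",
    "min",
    "max",
    "range",
    "median",
    "iqr",
    "rms",
    "rel_time_of_max",
    "rel_time_of_min",
    "rel_duration_above_mean",
    "rel_mean_crossings",
    "mad_median",
    "slope",
    "q1",
    "q3",
)

VARIANT_NAMES = ("smoothed", "d1", "d2")


# --------------------------------------------------------------------------
# Temporal segments
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentSpec:
    """A selection of 1-based parts from a k-way equal split of the video.

    ``divisions=1, parts=(1,)`` is the whole video.  Multi-part specs keep
    their parts in temporal order; each part is descriptor-extracted
    independently and concatenated downstream.
    """

    divisions: int = 1
    parts: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        if self.divisions < 1:
            raise ConfigurationError("divisions must be >= 1")
        if not self.parts:
            raise ConfigurationError("parts must be non-empty")
        if any(not (1 <= p <= self.divisions) for p in self.parts):
            raise ConfigurationError(
                f"parts {self.parts} out of range for {self.divisions} divisions"
            )
        if len(set(self.parts)) != len(self.parts):
            raise ConfigurationError("parts must be distinct")
        object.__setattr__(self, "parts", tuple(sorted(self.parts)))

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    def __str__(self) -> str:
        return f"{'&'.join(map(str, self.parts))}/{self.divisions}"


WHOLE_VIDEO = SegmentSpec(1, (1,))


def segment_bounds(n_frames: int, k: int) -> list[tuple[int, int]]:
    """Half-open frame intervals of a k-way equal split of ``n_frames``.

    Interval i is [round((i-1)*n/k), round(i*n/k)) with round-half-up; the
    intervals partition [0, n) and their lengths differ by at most one.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if n_frames < k:
        raise InsufficientDataError(f"cannot split {n_frames} frames into {k} parts")
    edges = [int(np.floor(i * n_frames / k + 0.5)) for i in range(k + 1)]
    edges[0], edges[k] = 0, n_frames
    return [(edges[i], edges[i + 1]) for i in range(k)]


# --------------------------------------------------------------------------
# Signal processing
# --------------------------------------------------------------------------


def smooth_channel(x: np.ndarray, fps: float) -> np.ndarray:
    """Zero-phase first-order Butterworth low-pass at 1 Hz.

    Applied forward and backward (filtfilt) so extrema are not phase-shifted;
    the effective magnitude response is |H(f)|^2 = 1 / (1 + (f / 1 Hz)^2).
    """
    x = np.asarray(x, dtype=float)
    if fps <= 2 * CUTOFF_HZ:
        raise ConfigurationError(f"fps must exceed {2 * CUTOFF_HZ} Hz (cutoff below Nyquist)")
    n = x.shape[0]
    if n < 2:
        raise InsufficientDataError("smoothing requires at least 2 samples")
    b, a = _signal.butter(1, CUTOFF_HZ, btype="low", fs=fps)
    padlen = min(3 * max(len(a), len(b)), n - 1)
    return _signal.filtfilt(b, a, x, axis=0, padlen=padlen)


def derivatives(x: np.ndarray, fps: float) -> tuple[np.ndarray, np.ndarray]:
    """First and second backward-difference derivatives, length-preserving.

    d1[n] = (x[n] - x[n-1]) * fps with d1[0] = d1[1]; d2 applies the same
    operator to d1.  Edge replication avoids spurious extrema at t = 0.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise InsufficientDataError("derivatives require at least 3 samples")

    def _d(v: np.ndarray) -> np.ndarray:
        d = np.empty_like(v)
        d[1:] = np.diff(v, axis=0) * fps
        d[0] = d[1]
        return d

    d1 = _d(x)
    return d1, _d(d1)


# --------------------------------------------------------------------------
# Summary statistics
# --------------------------------------------------------------------------


def summarize_statistics(x: np.ndarray) -> np.ndarray:
    """The 16 summary statistics of a 1-D (or column-stacked 2-D) signal.

    For 2-D input of shape (n, c) the result has shape (c, 16); statistics
    follow :data:`STATISTIC_NAMES`.  Relative times are argext/(N-1) (0 for
    N = 1), durations and crossing counts are fractions of the segment, the
    slope is least-squares versus relative time in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    if n == 0:
        raise InsufficientDataError("cannot summarise an empty signal")
    if not np.all(np.isfinite(x)):
        raise InsufficientDataError("signal contains non-finite values")

    mean = x.mean(axis=0)
    std = x.std(axis=0)  # population
    mn = x.min(axis=0)
    mx = x.max(axis=0)
    q1, median, q3 = np.percentile(x, [25, 50, 75], axis=0)
    rms = np.sqrt(np.mean(x * x, axis=0))
    if n == 1:
        rt_max = np.zeros_like(mean)
        rt_min = np.zeros_like(mean)
        crossings = np.zeros_like(mean)
        slope = np.zeros_like(mean)
    else:
        rt_max = np.argmax(x, axis=0) / (n - 1)
        rt_min = np.argmin(x, axis=0) / (n - 1)
        centred = x - mean
        crossings = np.sum(centred[:-1] * centred[1:] < 0, axis=0) / (n - 1)
        t = np.arange(n) / (n - 1)
        tc = t - t.mean()
        slope = (tc @ (x - mean)) / (tc @ tc)
    above = np.mean(x > mean, axis=0)
    mad = np.mean(np.abs(x - median), axis=0)

    out = np.stack(
        [mean, std, mn, mx, mx - mn, median, q3 - q1, rms,
         rt_max, rt_min, above, crossings, mad, slope, q1, q3],
        axis=1,
    )
    return out[0] if squeeze else out


# --------------------------------------------------------------------------
# FAD assembly
# --------------------------------------------------------------------------


@dataclass
class FadVector:
    """Fixed-length descriptor of one participant over one contiguous part."""

    participant_id: str
    feature_set: str
    segment_divisions: int
    segment_part: int
    values: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        expected = len(self.channel_names) * STATS_PER_CHANNEL
        if self.values.shape != (expected,):
            raise ConfigurationError(
                f"FAD length {self.values.shape} != {expected} for "
                f"{len(self.channel_names)} channels"
            )


def fad_length(n_channels: int) -> int:
    return n_channels * STATS_PER_CHANNEL


def fad_layout_names(channel_names) -> list[str]:
    """Column names of the flattened FAD, in layout order."""
    return [
        f"{ch}:{var}:{stat}"
        for ch in channel_names
        for var in VARIANT_NAMES
        for stat in STATISTIC_NAMES
    ]


def compute_fad_part(
    table: FrameFeatureTable,
    spec: FeatureSetSpec,
    divisions: int = 1,
    part: int = 1,
) -> FadVector:
    """FAD of one contiguous part of a k-way split.

    Per channel: slice the part's frames, smooth, differentiate twice, then
    take the 16 statistics of each of the three signals.
    """
    sub = table.select(spec)
    bounds = segment_bounds(sub.n_frames, divisions)
    lo, hi = bounds[part - 1]
    seg = sub.values[lo:hi]
    if seg.shape[0] < 3:
        raise InsufficientDataError(
            f"segment {part}/{divisions} of {table.participant_id} has "
            f"{seg.shape[0]} frames (< 3)"
        )
    sm = smooth_channel(seg, table.fps)
    d1, d2 = derivatives(sm, table.fps)
    stats = np.stack(
        [summarize_statistics(sm), summarize_statistics(d1), summarize_statistics(d2)],
        axis=1,
    )  # (channels, variants, 16)
    return FadVector(
        participant_id=table.participant_id,
        feature_set=spec.name,
        segment_divisions=divisions,
        segment_part=part,
        values=stats.reshape(-1),
        channel_names=tuple(spec.selected),
    )


def compute_fads(
    table: FrameFeatureTable, spec: FeatureSetSpec, segment: SegmentSpec = WHOLE_VIDEO
) -> list[FadVector]:
    """One FAD per contiguous part of ``segment``, in temporal order."""
    return [compute_fad_part(table, spec, segment.divisions, p) for p in segment.parts]


def compute_fad(
    table: FrameFeatureTable, spec: FeatureSetSpec, segment: SegmentSpec = WHOLE_VIDEO
) -> FadVector:
    """Whole-segment convenience wrapper for single-part specs."""
    if segment.n_parts != 1:
        raise ConfigurationError("compute_fad takes a single contiguous part; use compute_fads")
    return compute_fads(table, spec, segment)[0]
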