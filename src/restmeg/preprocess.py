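"""Parcel-level signal conditioning.

Standardisation (z-scoring), zero-phase band-pass filtering and
bad-segment detection based on abnormally high windowed variance.
Bad segments are dropped and the remaining data concatenated before any
spectral estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


def zscore_timecourse(x: np.ndarray) -> np.ndarray:
    """Standardise a time course to zero mean and unit (population) variance.

    Works on a single time course or on a (parcels, samples) array, in which
    case each parcel is standardised independently along the last axis.

    Raises
    ------
    ValueError
        If any time course is constant (zero variance) or shorter than 2.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("time course must have at least 2 samples")
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant time course: z-score undefined (zero variance)")
    return (x - mu) / sd


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth band-pass between lo and hi Hz.

    Forward-backward filtering (``sosfiltfilt``) is used so that no group
    delay is introduced — important for amplitude-envelope work downstream.
    """
    if not (0 < lo < hi):
        raise ValueError(f"require 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= fs / 2:
        raise ValueError(f"upper edge {hi} Hz must be below Nyquist {fs / 2} Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


@dataclass
class SegmentMask:
    """Bad-sample intervals, half-open [start, stop), 0-based, sorted."""

    n_samples: int
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        merged: list[tuple[int, int]] = []
        for start, stop in sorted((int(a), int(b)) for a, b in self.intervals):
            if not (0 <= start < stop <= self.n_samples):
                raise ValueError(f"interval ({start}, {stop}) outside [0, {self.n_samples})")
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], stop))
            else:
                merged.append((start, stop))
        self.intervals = merged

    @property
    def n_bad(self) -> int:
        return sum(stop - start for start, stop in self.intervals)

    def good_indices(self) -> np.ndarray:
        keep = np.ones(self.n_samples, dtype=bool)
        for start, stop in self.intervals:
            keep[start:stop] = False
        return np.nonzero(keep)[0]

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Drop flagged samples and concatenate the remaining good data."""
        x = np.asarray(x)
        if x.shape[-1] != self.n_samples:
            raise ValueError("mask length does not match recording length")
        if not self.intervals:
            return x
        return np.take(x, self.good_indices(), axis=-1)


def detect_bad_segments(
    x: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    z_thresh: float = 3.0,
) -> SegmentMask:
    """Flag windows whose variance is abnormally high.

    The recording is cut into non-overlapping windows of ``window_s``
    seconds; the log-variance of each window is z-scored across windows and
    windows exceeding ``z_thresh`` are flagged. A 2-D (parcels, samples)
    input is pooled by averaging per-parcel window variances, producing a
    single temporal mask for the recording.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[-1]
    w = int(round(window_s * fs))
    if w < 2:
        raise ValueError("window must contain at least 2 samples")
    if w > n:
        raise ValueError(f"window ({w} samples) longer than recording ({n})")
    n_win = n // w
    segs = x[:, : n_win * w].reshape(x.shape[0], n_win, w)
    var = segs.var(axis=-1).mean(axis=0)
    if np.any(var <= 0):
        raise ValueError("window with zero variance: cannot assess variance profile")
    logv = np.log(var)
    sd = logv.std()
    if sd == 0:
        raise ValueError("identical variance in every window: z-scoring undefined")
    z = (logv - logv.mean()) / sd
    bad = np.nonzero(z > z_thresh)[0]
    intervals = [(int(i * w), int(min((i + 1) * w, n))) for i in bad]
    return SegmentMask(n_samples=n, intervals=intervals)


def clean_timecourses(
    x: np.ndarray,
    fs: float,
    lo: float = 1.0,
    hi: float = 80.0,
    window_s: float = 1.0,
    z_thresh: float = 3.0,
) -> tuple[np.ndarray, SegmentMask]:
    """Band-pass, drop bad segments, and re-z-score a (parcels, samples) array.

    Returns the cleaned data and the segment mask that was applied.
    """
    xf = bandpass(x, fs, lo, hi)
    mask = detect_bad_segments(xf, fs, window_s=window_s, z_thresh=z_thresh)
    return zscore_timecourse(mask.apply(xf)), mask
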