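"""Welch power spectral density and canonical band powers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .bands import Band, get_band


@dataclass
class PowerSpectrum:
    """One-sided PSD on a regular frequency grid.

    ``density`` has shape (n_parcels, n_freqs); a single time course is
    stored as one row. Density is in power per Hz, so with 2 s Hann windows
    the grid spacing is 0.5 Hz and the integral over frequency of each row
    approximates the signal variance.
    """

    freqs: np.ndarray
    density: np.ndarray
    window_s: float = 2.0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.density = np.atleast_2d(np.asarray(self.density, dtype=float))
        if self.freqs.ndim != 1 or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be 1-D and strictly increasing")
        if self.density.shape[-1] != self.freqs.size:
            raise ValueError("density and frequency grid sizes differ")
        if np.any(self.density < 0):
            raise ValueError("negative power density")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    @property
    def n_parcels(self) -> int:
        return self.density.shape[0]


def welch_psd(x: np.ndarray, fs: float, window_s: float = 2.0) -> PowerSpectrum:
    """One-sided Welch PSD with a Hann window and 50 % overlap.

    With the default 2 s window the frequency resolution is 0.5 Hz. Input is
    expected to be z-scored; no detrending is applied.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"recording ({x.shape[-1]} samples) shorter than one window ({nperseg})"
        )
    freqs, density = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
        axis=-1,
    )
    return PowerSpectrum(freqs=freqs, density=density, window_s=window_s)


def band_power(psd: PowerSpectrum, band) -> np.ndarray | float:
    """Mean power density over a band's bins, per parcel.

    Bins satisfy lo <= f < hi (half-open), so adjacent canonical bands share
    no bin. The mean (rather than the integral) makes bands of different
    widths comparable. Returns a scalar for a single-parcel spectrum.
    """
    band = get_band(band)
    if band.lo < psd.freqs[0] or band.hi > psd.freqs[-1] + psd.df:
        raise ValueError(
            f"band {band.name} [{band.lo}, {band.hi}) outside grid "
            f"[{psd.freqs[0]}, {psd.freqs[-1]}]"
        )
    sel = (psd.freqs >= band.lo) & (psd.freqs < band.hi)
    if not np.any(sel):
        raise ValueError(f"band {band.name} covers no frequency bin")
    out = psd.density[:, sel].mean(axis=-1)
    return float(out[0]) if out.size == 1 else out


def band_power_table(psd: PowerSpectrum, bands: tuple[Band, ...]) -> np.ndarray:
    """Band powers for every parcel and band; shape (n_parcels, n_bands)."""
    return np.column_stack([np.atleast_1d(band_power(psd, b)) for b in bands])
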