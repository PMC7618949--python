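"""Amplitude-envelope-correlation (AEC) connectivity.

For each canonical band the parcel time courses are band-pass filtered, the
analytic-signal magnitude (Hilbert envelope) is taken, and the pairwise
Pearson correlation of envelopes forms the AEC matrix. Because correlation
is scale-free, AEC is an amplitude-normalised measure: parcels with higher
power do not automatically show higher connectivity. A parcel's global
connectivity is the mean of its correlations with every other parcel.

No leakage correction (signal orthogonalisation) is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .bands import get_band
from .preprocess import bandpass


@dataclass
class AECMatrix:
    band: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("AEC matrix must be square")
        self.matrix = m

    @property
    def n_parcels(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GlobalConnectivity:
    band: str
    values: np.ndarray


def amplitude_envelope(
    x: np.ndarray, fs: float, band, trim_s: float = 1.0
) -> np.ndarray:
    """Band-limited amplitude envelope of one or more time courses.

    Band-pass to the band, take the analytic-signal magnitude, and trim
    ``trim_s`` seconds from each end to discard filter/Hilbert edge effects.
    """
    band = get_band(band)
    xf = bandpass(np.asarray(x, dtype=float), fs, band.lo, band.hi)
    env = np.abs(hilbert(xf, axis=-1))
    trim = int(round(trim_s * fs))
    if 2 * trim >= env.shape[-1]:
        raise ValueError("recording too short for the requested edge trim")
    return env[..., trim : env.shape[-1] - trim] if trim else env


def aec_matrix(timecourses: np.ndarray, fs: float, band, trim_s: float = 1.0) -> AECMatrix:
    """Pairwise Pearson correlation of band-limited amplitude envelopes.

    Parcels whose envelope is constant produce NaN rows/columns (with a
    warning) rather than failing the whole matrix.
    """
    band = get_band(band)
    x = np.atleast_2d(np.asarray(timecourses, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("need at least 2 parcels for connectivity")
    env = amplitude_envelope(x, fs, band, trim_s=trim_s)
    sd = env.std(axis=-1)
    constant = sd == 0
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} parcel(s) with constant envelope; "
            "their AEC entries are set to NaN",
            stacklevel=2,
        )
        env = env.copy()
        env[constant] += np.nan
    with np.errstate(invalid="ignore"):
        m = np.corrcoef(env)
    np.fill_diagonal(m, 1.0)
    m[constant, :] = np.nan
    m[:, constant] = np.nan
    return AECMatrix(band=band.name, matrix=m)


def global_connectivity(m: AECMatrix) -> GlobalConnectivity:
    """Per-parcel mean AEC with every other parcel (diagonal excluded).

    Excluding the unit diagonal avoids biasing every value upward by 1/n.
    """
    mat = m.matrix.copy()
    np.fill_diagonal(mat, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(mat, axis=1)
    return GlobalConnectivity(band=m.band, values=values)
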