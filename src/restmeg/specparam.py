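"""Aperiodic/periodic decomposition of power spectra.

Each PSD is modelled in log10-power as an aperiodic component plus Gaussian
oscillatory peaks::

    log10 P(f) = b - chi * log10 f + sum_k PW_k * exp(-(f - CF_k)^2 / (2 sigma_k^2))

with fixed (knee-free) aperiodic mode. ``chi`` is the 1/f exponent — the
negative slope of the log-log spectral background, often read as an index of
cortical excitation/inhibition balance. Peaks are extracted iteratively from
the aperiodic-flattened spectrum (tallest residual first), jointly refined by
least squares, and pruned by a minimum height and a threshold relative to the
residual noise; the aperiodic fit is then refined on the peak-removed
spectrum. This mirrors the standard spectral-parameterisation algorithm with
settings: peak width limit 0.5-12 Hz, minimum peak height 0.05, peak
threshold 2.0 (relative SD), unlimited peaks (capped at 20), fit range
1-70 Hz (frequencies above 70 Hz are excluded to avoid spectral-plateau bias).

The module also provides the derived spectral-shape metrics: the centre of
energy (CoE) of the periodic spectrum — a balance-point measure of
oscillatory speed — and alpha/beta peak selection, imputation and
missing-peak counting across a cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .bands import PEAK_BANDS, get_band
from .spectral import PowerSpectrum

__all__ = [
    "SpectralFit",
    "parameterize_spectrum",
    "fit_cohort",
    "exponent",
    "centre_of_energy",
    "select_band_peak",
    "peak_table",
    "impute_missing_peaks",
    "count_missing_peaks",
]

# Peak-width limits in Hz are full bandwidths BW = 2 * sigma.
_BW_LIMITS = (0.5, 12.0)
_MIN_PEAK_HEIGHT = 0.05
_PEAK_THRESHOLD = 2.0
_MAX_PEAKS = 20
_AP_PERCENTILE = 2.5


@dataclass
class SpectralFit:
    """Parameterised spectrum for a single parcel.

    peaks is an (n_peaks, 3) array of (CF, PW, BW): centre frequency in Hz,
    log10-power above the aperiodic component, and bandwidth (2 sigma) in Hz.
    ``periodic`` is the aperiodic-flattened log10 spectrum on ``freqs``.
    """

    offset: float
    exponent: float
    peaks: np.ndarray
    freqs: np.ndarray
    periodic: np.ndarray
    fit_error: float

    def aperiodic_model(self, freqs: np.ndarray | None = None) -> np.ndarray:
        f = self.freqs if freqs is None else np.asarray(freqs, dtype=float)
        return self.offset - self.exponent * np.log10(f)

    def peak_model(self, freqs: np.ndarray | None = None) -> np.ndarray:
        f = self.freqs if freqs is None else np.asarray(freqs, dtype=float)
        return _gaussian_sum(f, self.peaks)

    def model(self, freqs: np.ndarray | None = None) -> np.ndarray:
        """Full model in log10 power."""
        return self.aperiodic_model(freqs) + self.peak_model(freqs)


def _gaussian_sum(freqs: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    out = np.zeros_like(freqs, dtype=float)
    for cf, pw, bw in np.atleast_2d(peaks) if len(peaks) else []:
        sigma = bw / 2.0
        out += pw * np.exp(-((freqs - cf) ** 2) / (2 * sigma**2))
    return out


def _fit_aperiodic_simple(log_f: np.ndarray, log_p: np.ndarray) -> tuple[float, float]:
    design = np.column_stack([np.ones_like(log_f), -log_f])
    coef, *_ = np.linalg.lstsq(design, log_p, rcond=None)
    return float(coef[0]), float(coef[1])


def _fit_aperiodic_robust(log_f: np.ndarray, log_p: np.ndarray) -> tuple[float, float]:
    """Line fit that down-weights oscillatory bumps.

    After an initial fit, positive residuals (candidate peaks) above the
    2.5th percentile of the clipped residual distribution are excluded and
    the line refitted, so the aperiodic estimate hugs the spectral floor.
    """
    b, chi = _fit_aperiodic_simple(log_f, log_p)
    resid = log_p - (b - chi * log_f)
    clipped = np.clip(resid, 0, None)
    thresh = np.percentile(clipped, _AP_PERCENTILE)
    keep = clipped <= thresh
    if keep.sum() >= 2:
        b, chi = _fit_aperiodic_simple(log_f[keep], log_p[keep])
    return b, chi


def _guess_sigma(freqs: np.ndarray, flat: np.ndarray, idx: int, height: float) -> float:
    half = height / 2.0
    df = freqs[1] - freqs[0]
    left = idx
    while left > 0 and flat[left] > half:
        left -= 1
    right = idx
    while right < flat.size - 1 and flat[right] > half:
        right += 1
    fwhm = (right - left) * df
    sigma = fwhm / 2.355 if fwhm > 0 else 1.0
    return float(np.clip(sigma, _BW_LIMITS[0] / 2, _BW_LIMITS[1] / 2))


def parameterize_spectrum(
    psd,
    f_range: tuple[float, float] = (1.0, 70.0),
    freqs: np.ndarray | None = None,
    max_n_peaks: int = _MAX_PEAKS,
    min_peak_height: float = _MIN_PEAK_HEIGHT,
    peak_threshold: float = _PEAK_THRESHOLD,
) -> SpectralFit:
    """Fit the aperiodic + Gaussian-peaks model to one PSD.

    ``psd`` may be a single-parcel :class:`~restmeg.spectral.PowerSpectrum`
    or a 1-D density array accompanied by ``freqs``.
    """
    if isinstance(psd, PowerSpectrum):
        if psd.n_parcels != 1:
            raise ValueError("pass a single-parcel spectrum (use fit_cohort for many)")
        freqs_all, density = psd.freqs, psd.density[0]
    else:
        if freqs is None:
            raise ValueError("freqs required when psd is a plain array")
        freqs_all, density = np.asarray(freqs, dtype=float), np.asarray(psd, dtype=float)

    sel = (freqs_all >= f_range[0]) & (freqs_all <= f_range[1])
    f = freqs_all[sel]
    p = density[sel]
    if f.size < 8:
        raise ValueError("frequency grid does not cover the fit range")
    if np.any(p <= 0):
        raise ValueError("non-positive power density inside the fit range")

    log_f = np.log10(f)
    log_p = np.log10(p)

    b0, chi0 = _fit_aperiodic_robust(log_f, log_p)
    flat = log_p - (b0 - chi0 * log_f)

    # Iterative extraction of the tallest residual peak.
    guesses: list[tuple[float, float, float]] = []
    work = flat.copy()
    for _ in range(max_n_peaks):
        idx = int(np.argmax(work))
        height = work[idx]
        if height < min_peak_height or height < peak_threshold * np.std(work):
            break
        cf = f[idx]
        sigma = _guess_sigma(f, work, idx, height)
        guesses.append((float(cf), float(height), sigma))
        work = work - height * np.exp(-((f - cf) ** 2) / (2 * sigma**2))

    peaks = np.empty((0, 3))
    if guesses:
        peaks = _refine_peaks(f, flat, guesses, f_range, min_peak_height)

    # Refit aperiodic on the peak-removed spectrum.
    b, chi = _fit_aperiodic_robust(log_f, log_p - _gaussian_sum(f, peaks))
    periodic = log_p - (b - chi * log_f)
    fit_error = float(np.mean(np.abs(periodic - _gaussian_sum(f, peaks))))

    return SpectralFit(
        offset=b, exponent=chi, peaks=peaks, freqs=f, periodic=periodic, fit_error=fit_error
    )


def _refine_peaks(f, flat, guesses, f_range, min_peak_height) -> np.ndarray:
    """Joint least-squares refinement of all peak guesses, then pruning."""

    def model(x, *params):
        pk = np.asarray(params).reshape(-1, 3)
        pk = np.column_stack([pk[:, 0], pk[:, 1], 2 * pk[:, 2]])
        return _gaussian_sum(x, pk)

    p0, lo, hi = [], [], []
    for cf, h, sigma in guesses:
        p0 += [cf, h, sigma]
        lo += [f_range[0], 0.0, _BW_LIMITS[0] / 2]
        hi += [f_range[1], np.inf, _BW_LIMITS[1] / 2]
    p0 = np.clip(p0, lo, hi)
    try:
        popt, _ = curve_fit(model, f, flat, p0=p0, bounds=(lo, hi), maxfev=5000)
    except RuntimeError:
        popt = np.asarray(p0, dtype=float)
    pk = popt.reshape(-1, 3)
    peaks = np.column_stack([pk[:, 0], pk[:, 1], 2 * pk[:, 2]])
    keep = (peaks[:, 1] >= min_peak_height) & (peaks[:, 0] >= f_range[0]) & (
        peaks[:, 0] <= f_range[1]
    )
    peaks = peaks[keep]
    return peaks[np.argsort(peaks[:, 0])] if len(peaks) else np.empty((0, 3))


def fit_cohort(psd: PowerSpectrum, **kwargs) -> list[SpectralFit]:
    """Parameterise every parcel of a multi-parcel spectrum."""
    return [
        parameterize_spectrum(psd.density[i], freqs=psd.freqs, **kwargs)
        for i in range(psd.n_parcels)
    ]


def exponent(fit: SpectralFit) -> float:
    """The 1/f exponent chi (negative log-log slope of the aperiodic fit)."""
    return float(fit.exponent)


def centre_of_energy(fit: SpectralFit, weighted: bool = False) -> float:
    """Oscillatory speed: balance frequency of the periodic spectrum.

    The periodic (aperiodic-flattened) spectrum is floored at zero and the
    smallest frequency at which the cumulative periodic power reaches half
    the total is returned, linearly interpolated between bins. A leftward
    shift of the CoE indicates oscillatory slowing. With ``weighted=True``
    the power-weighted mean frequency is returned instead (sensitivity
    variant). Returns NaN when there is no periodic power at all.
    """
    power = np.clip(fit.periodic, 0, None)
    total = power.sum()
    if total <= 0:
        return float("nan")
    if weighted:
        return float((fit.freqs * power).sum() / total)
    cum = np.cumsum(power)
    half = total / 2.0
    i = int(np.searchsorted(cum, half))
    if i == 0:
        return float(fit.freqs[0])
    # Treat each bin's mass as centred on its grid frequency: the crossing
    # bin spans [f_i - df/2, f_i + df/2), so a symmetric peak centred on a
    # grid point yields exactly that frequency.
    df = float(fit.freqs[i] - fit.freqs[i - 1])
    frac = (half - cum[i - 1]) / (cum[i] - cum[i - 1])
    return float(min(fit.freqs[i] - df / 2 + frac * df, fit.freqs[-1]))


def select_band_peak(fit: SpectralFit, band) -> tuple[float, float] | None:
    """Highest-power retained peak with centre frequency in the band.

    Ties are broken towards the lower centre frequency. Returns
    (centre frequency, peak power) or None when the band holds no peak.
    """
    band = get_band(band)
    candidates = [
        (float(cf), float(pw)) for cf, pw, _bw in fit.peaks if band.contains(cf)
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda c: (c[1], -c[0]))


def peak_table(
    fits: dict[str, list[SpectralFit]],
    bands: dict | None = None,
) -> pd.DataFrame:
    """Alpha/beta peak bookkeeping for a cohort.

    ``fits`` maps subject id to the per-parcel fit list. Returns a long-form
    table with one row per (subject, parcel, band) and NaN where no peak was
    detected.
    """
    bands = PEAK_BANDS if bands is None else bands
    rows = []
    for subject_id, subject_fits in fits.items():
        for parcel, fit in enumerate(subject_fits):
            for band_name, band in bands.items():
                pk = select_band_peak(fit, band)
                rows.append(
                    {
                        "subject_id": subject_id,
                        "parcel": parcel,
                        "band": band_name,
                        "peak_freq": pk[0] if pk else np.nan,
                        "peak_power": pk[1] if pk else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def impute_missing_peaks(table: pd.DataFrame) -> pd.DataFrame:
    """Replace missing peak values with the cross-participant mean.

    For each (parcel, band) cell the mean over all participants with a
    detected peak is imputed; an ``imputed`` flag column is added. Cells
    missing for every participant stay NaN with a warning (they should be
    excluded from any downstream model).
    """
    out = table.copy()
    out["imputed"] = out["peak_freq"].isna()
    for col in ("peak_freq", "peak_power"):
        means = out.groupby(["parcel", "band"])[col].transform("mean")
        out[col] = out[col].fillna(means)
    still = out["peak_freq"].isna()
    if still.any():
        cells = out.loc[still, ["parcel", "band"]].drop_duplicates()
        warnings.warn(
            f"{len(cells)} (parcel, band) cells have no detected peak in any "
            "participant; left missing",
            stacklevel=2,
        )
    return out


def count_missing_peaks(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject count of parcels without a detected peak, per band.

    Must be computed on the pre-imputation table (the ``imputed`` flag is
    honoured if present).
    """
    t = table.copy()
    missing = t["imputed"] if "imputed" in t else t["peak_freq"].isna()
    t["missing"] = missing.astype(int)
    counts = t.pivot_table(
        index="subject_id", columns="band", values="missing", aggfunc="sum"
    )
    return counts.rename(columns=lambda b: f"missing_{b}_peaks")
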