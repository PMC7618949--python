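"""Synthetic parcellated MEG cohorts with known spectral ground truth.

Each subject is a (parcels, samples) matrix of z-scored source time courses
at 250 Hz, built as

    x_p(t) = n_chi(t) + sum_k a_k * env_k(t) * c_k(t)

where ``n_chi`` is unit-variance noise whose PSD follows 1/f^chi above 1 Hz
(flat below; shaped exactly in the frequency domain), each ``c_k`` is a
unit-variance narrow-band carrier with a Gaussian spectral profile centred
on the component's frequency, and ``env_k`` is a slow (< 1 Hz) positive
amplitude envelope. Envelopes are mixtures of a subject-wide shared process
and a parcel-specific process with weight w, which sets the
amplitude-envelope correlation between parcels; covariates (age, sex, group
membership) shift the exponent, the log amplitude and the peak frequency of
components linearly, matching the linear model used for inference. Per
subject, parameters additionally receive random jitter (between-subject
variability).

The generator reproduces the spectral and connectivity structure the
downstream metrics consume; it makes no attempt at head geometry, sensor
physics or forward/inverse modelling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import signal, stats

from .bands import Band, get_band

__all__ = [
    "CohortSpec",
    "OscillatoryComponent",
    "SpectralGroundTruth",
    "ParcelTimecourseSet",
    "Cohort",
    "generate_subject_timecourses",
    "generate_cohort",
    "expected_band_power",
    "neurodegeneration_ground_truth",
    "save_cohort",
]

_ENV_GAIN = 0.5  # envelope = clip(1 + gain * slow, 0) before RMS normalisation


@dataclass
class CohortSpec:
    """Cohort structure: group sizes, demographics and recording geometry."""

    n_subjects_per_group: int = 30
    groups: tuple[str, ...] = ("HC", "AD", "PD", "ALS")
    age_range: tuple[float, float] = (50.0, 80.0)
    sex_ratio: float = 0.55
    n_parcels: int = 52
    fs: float = 250.0
    duration: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parcels < 2:
            raise ValueError("need at least 2 parcels")
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.duration * self.fs < 2 * 2 * self.fs:
            raise ValueError("recording must cover at least two 2 s analysis windows")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class OscillatoryComponent:
    """One band-limited oscillation shared by a set of parcels.

    ``amplitude`` is the component RMS relative to the unit-variance
    aperiodic background; ``freq_sigma`` the Gaussian spectral half-width of
    the carrier (Hz); ``envelope_weight`` w mixes the subject-wide shared
    envelope (w = 1: fully shared across parcels) with parcel-specific
    envelopes (w = 0: independent). Covariate effects are additive on log10
    amplitude (``amp_effects``) and on centre frequency in Hz
    (``freq_effects``); keys are covariate names ('age', 'sex') or
    'group:<label>' indicators. Subject-level jitter SDs give
    between-subject variability.
    """

    name: str
    centre: float
    amplitude: float
    freq_sigma: float = 1.0
    envelope_weight: float = 0.5
    parcels: tuple[int, ...] | None = None
    amp_effects: dict[str, float] = field(default_factory=dict)
    freq_effects: dict[str, float] = field(default_factory=dict)
    amp_subject_sd: float = 0.1
    freq_subject_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"component {self.name}: amplitude must be >= 0")
        if not 0 <= self.envelope_weight <= 1:
            raise ValueError(f"component {self.name}: envelope weight must be in [0, 1]")
        if self.centre <= 0 or self.freq_sigma <= 0:
            raise ValueError(f"component {self.name}: frequencies must be positive")


@dataclass
class SpectralGroundTruth:
    """Per-parcel aperiodic structure plus oscillatory components."""

    exponent: float = 1.0
    offset: float = 0.0
    components: list[OscillatoryComponent] = field(default_factory=list)
    exponent_effects: dict[str, float] = field(default_factory=dict)
    exponent_subject_sd: float = 0.1
    envelope_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.exponent) < 0):
            raise ValueError("aperiodic exponent must be >= 0")
        if not 0 < self.envelope_cutoff < 1.0:
            raise ValueError("envelope cutoff must lie in (0, 1) Hz")

    def exponent_per_parcel(self, n_parcels: int) -> np.ndarray:
        chi = np.asarray(self.exponent, dtype=float)
        if chi.ndim == 0:
            return np.full(n_parcels, float(chi))
        if chi.size != n_parcels:
            raise ValueError("per-parcel exponent length != n_parcels")
        return chi


@dataclass
class ParcelTimecourseSet:
    """One subject's parcellated source time courses."""

    subject_id: str
    data: np.ndarray
    fs: float
    parcel_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (parcels, samples)")
        if len(self.parcel_labels) != self.data.shape[0]:
            raise ValueError("parcel label count != number of rows")


@dataclass
class Cohort:
    subjects: list[ParcelTimecourseSet]
    covariates: pd.DataFrame
    truth: SpectralGroundTruth
    spec: CohortSpec
    effective: list[dict]


def _covariate_value(key: str, covariates: dict, spec: CohortSpec) -> float:
    """Centred value of one covariate for effect computation.

    Age is centred at the midpoint of the cohort age range, sex (male = 1)
    at 0.5, and 'group:<label>' keys are raw 0/1 indicators.
    """
    if key == "age":
        return float(covariates["age"]) - 0.5 * (spec.age_range[0] + spec.age_range[1])
    if key == "sex":
        v = covariates["sex"]
        v = {"M": 1.0, "F": 0.0}.get(v, v)
        return float(v) - 0.5
    if key.startswith("group:"):
        return 1.0 if covariates.get("group") == key.split(":", 1)[1] else 0.0
    if key in covariates:
        return float(covariates[key])
    raise KeyError(f"effect references unknown covariate {key!r}")


def _effect_sum(effects: dict[str, float], covariates: dict, spec: CohortSpec) -> float:
    return sum(b * _covariate_value(k, covariates, spec) for k, b in effects.items())


def _draw_effective(
    spec: CohortSpec, truth: SpectralGroundTruth, covariates: dict, rng: np.random.Generator
) -> dict:
    """Realised per-subject parameters: covariate effects plus jitter."""
    chi = truth.exponent_per_parcel(spec.n_parcels).copy()
    chi += _effect_sum(truth.exponent_effects, covariates, spec)
    chi += rng.normal(0, truth.exponent_subject_sd)
    if np.any(chi < 0):
        warnings.warn("effective exponent < 0 clipped to 0", stacklevel=2)
        chi = np.clip(chi, 0, None)
    comps = []
    nyq = spec.fs / 2
    for comp in truth.components:
        log_amp = np.log10(comp.amplitude) if comp.amplitude > 0 else -np.inf
        log_amp += _effect_sum(comp.amp_effects, covariates, spec)
        log_amp += rng.normal(0, comp.amp_subject_sd)
        cf = comp.centre + _effect_sum(comp.freq_effects, covariates, spec)
        cf += rng.normal(0, comp.freq_subject_sd)
        if not 0.5 <= cf <= nyq - 1:
            warnings.warn(
                f"component {comp.name}: effective frequency {cf:.2f} Hz clipped",
                stacklevel=2,
            )
            cf = float(np.clip(cf, 0.5, nyq - 1))
        comps.append(
            {
                "name": comp.name,
                "amplitude": float(10**log_amp) if np.isfinite(log_amp) else 0.0,
                "centre": float(cf),
                "freq_sigma": comp.freq_sigma,
                "envelope_weight": comp.envelope_weight,
                "parcels": list(comp.parcels) if comp.parcels is not None else None,
            }
        )
    return {"exponent": chi, "components": comps}


def _shaped_noise(rng, n: int, fs: float, chi: float) -> np.ndarray:
    """Unit-variance noise with one-sided PSD proportional to f^-chi above 1 Hz."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = np.ones_like(freqs)
    above = freqs >= 1.0
    shape[above] = freqs[above] ** (-chi / 2)
    shape[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) * shape, n)
    return x / x.std()


def _narrowband_carrier(rng, n: int, fs: float, cf: float, sigma: float) -> np.ndarray:
    """Unit-variance carrier with a Gaussian PSD profile centred at cf."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    g = np.exp(-0.5 * ((freqs - cf) / sigma) ** 2)
    g[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) * g, n)
    return x / x.std()


def _slow_process(rng, n: int, fs: float, cutoff: float) -> np.ndarray:
    """Unit-variance low-pass (< 1 Hz) Gaussian process."""
    sos = signal.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _envelope(shared: np.ndarray, indep: np.ndarray, w: float) -> np.ndarray:
    """Positive slow envelope mixing shared and independent drive."""
    norm = np.sqrt(w**2 + (1 - w) ** 2)
    s = (w * shared + (1 - w) * indep) / norm
    env = np.clip(1.0 + _ENV_GAIN * s, 0.0, None)
    return env / np.sqrt(np.mean(env**2))


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, subject_index]))


def generate_subject_timecourses(
    spec: CohortSpec,
    truth: SpectralGroundTruth,
    covariates: dict,
    subject_index: int = 0,
    return_effective: bool = False,
):
    """Simulate one subject's z-scored parcel time courses.

    The random stream is derived deterministically from
    (spec.seed, subject_index), so the same call always produces identical
    arrays. With ``return_effective=True`` the realised per-subject
    parameters (effective exponent per parcel, per-component amplitude and
    centre frequency) are returned alongside for recovery tests.
    """
    rng = _subject_rng(spec.seed, subject_index)
    eff = _draw_effective(spec, truth, covariates, rng)
    n = spec.n_samples
    chi = eff["exponent"]

    shared = {
        comp["name"]: _slow_process(rng, n, spec.fs, truth.envelope_cutoff)
        for comp in eff["components"]
    }
    data = np.empty((spec.n_parcels, n))
    for p in range(spec.n_parcels):
        x = _shaped_noise(rng, n, spec.fs, chi[p])
        for comp in eff["components"]:
            if comp["parcels"] is not None and p not in comp["parcels"]:
                continue
            if comp["amplitude"] <= 0:
                continue
            carrier = _narrowband_carrier(rng, n, spec.fs, comp["centre"], comp["freq_sigma"])
            indep = _slow_process(rng, n, spec.fs, truth.envelope_cutoff)
            env = _envelope(shared[comp["name"]], indep, comp["envelope_weight"])
            x = x + comp["amplitude"] * env * carrier
        data[p] = (x - x.mean()) / x.std()

    subject_id = covariates.get("subject_id", f"sub-{subject_index:04d}")
    out = ParcelTimecourseSet(
        subject_id=subject_id,
        data=data,
        fs=spec.fs,
        parcel_labels=[f"parcel-{p:02d}" for p in range(spec.n_parcels)],
    )
    return (out, eff) if return_effective else out


def _sample_covariates(spec: CohortSpec) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) % 2**31, 999_983]))
    rows = []
    idx = 0
    for group in spec.groups:
        for _ in range(spec.n_subjects_per_group):
            age = rng.uniform(*spec.age_range)
            sex = "M" if rng.random() < spec.sex_ratio else "F"
            scanner = "A" if rng.random() < 0.5 else "B"
            # grey matter volume (mL): declines with age, plus individual noise
            gm = 620.0 - 1.5 * (age - 65.0) + rng.normal(0, 25.0)
            rows.append(
                {
                    "subject_id": f"sub-{idx:04d}",
                    "group": group,
                    "age": age,
                    "sex": sex,
                    "scanner": scanner,
                    "gm_volume": gm,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec, truth: SpectralGroundTruth) -> Cohort:
    """Simulate a full cohort: time courses, covariate table, ground truth.

    Ages are uniform over the spec'd range, sex is Bernoulli(sex_ratio),
    scanner is split evenly between two sites, and grey-matter volume is an
    age-correlated Gaussian. The returned ground-truth record includes the
    realised per-subject effective parameters so that recovery tests can
    condition on them.
    """
    covariates = _sample_covariates(spec)
    subjects, effective = [], []
    for i, row in covariates.iterrows():
        tc, eff = generate_subject_timecourses(
            spec, truth, row.to_dict(), subject_index=int(i), return_effective=True
        )
        subjects.append(tc)
        effective.append(eff)
    return Cohort(
        subjects=subjects, covariates=covariates, truth=truth, spec=spec, effective=effective
    )


# Envelope moments of clip(1 + g*s, 0)/rms for s ~ N(0, 1): the DC fraction
# of the envelope power determines how much carrier power stays at the
# carrier's own spectral width versus being smeared by the slow modulation.
def _envelope_dc_fraction(gain: float = _ENV_GAIN) -> float:
    z = 1.0 / gain
    phi, Phi = stats.norm.pdf(z), stats.norm.cdf(z)
    mean = Phi + gain * phi
    second = (1 + gain**2) * Phi + gain * phi
    return mean**2 / second


def expected_band_power(
    effective: dict,
    band: Band | str,
    fs: float,
    parcel: int = 0,
    env_sigma_hz: float = 0.3,
) -> float:
    """Expected measured band power for one subject/parcel given realised
    generator parameters.

    Band power is the mean PSD over the band of the z-scored signal, i.e.
    the band-integrated power fraction divided by the band width. The
    aperiodic fraction is integrated analytically; each component
    contributes its amplitude-squared times the Gaussian spectral mass in
    the band, split between the carrier width and an envelope-broadened
    width (Gaussian convolution approximation).
    """
    band = get_band(band)
    nyq = fs / 2
    chi = float(np.asarray(effective["exponent"]).ravel()[parcel])

    def powerlaw_integral(lo, hi):
        lo, hi = max(lo, 1.0), max(hi, 1.0)
        if hi <= lo:
            return 0.0
        if abs(chi - 1.0) < 1e-12:
            return np.log(hi / lo)
        return (hi ** (1 - chi) - lo ** (1 - chi)) / (1 - chi)

    ap_total = 1.0 + powerlaw_integral(1.0, nyq)  # flat below 1 Hz
    ap_band = (
        max(0.0, min(band.hi, 1.0) - band.lo) + powerlaw_integral(band.lo, band.hi)
    ) / ap_total

    total_var = 1.0
    band_var = ap_band
    dc = _envelope_dc_fraction()
    for comp in effective["components"]:
        if comp["parcels"] is not None and parcel not in comp["parcels"]:
            continue
        a2 = comp["amplitude"] ** 2
        if a2 <= 0:
            continue
        cf, sig = comp["centre"], comp["freq_sigma"]
        wide = np.hypot(sig, env_sigma_hz)

        def mass(s):
            return stats.norm.cdf(band.hi, cf, s) - stats.norm.cdf(band.lo, cf, s)

        band_var += a2 * (dc * mass(sig) + (1 - dc) * mass(wide))
        total_var += a2
    return band_var / total_var / band.width


def neurodegeneration_ground_truth(n_parcels: int = 52) -> SpectralGroundTruth:
    """Default ground truth emulating resting-state cortical spectra.

    An aperiodic background (chi = 1), an alpha oscillation near 10 Hz and a
    beta oscillation near 20 Hz on every parcel. Covariate effects encode
    the qualitative directions reported for ageing and the three disease
    groups: beta amplitude rises with age in health and is reduced in all
    disease groups (most strongly AD); the alpha peak shifts to slower
    frequencies in disease; the 1/f exponent falls with age, rises in AD and
    PD, and falls in ALS.
    """
    alpha = OscillatoryComponent(
        name="alpha",
        centre=10.0,
        amplitude=0.8,
        freq_sigma=1.0,
        envelope_weight=0.6,
        freq_effects={"group:AD": -1.0, "group:PD": -0.8, "group:ALS": -0.8},
    )
    beta = OscillatoryComponent(
        name="beta",
        centre=20.0,
        amplitude=0.6,
        freq_sigma=2.5,
        envelope_weight=0.4,
        amp_effects={
            "age": 0.004,
            "group:AD": -0.30,
            "group:PD": -0.15,
            "group:ALS": -0.10,
        },
    )
    return SpectralGroundTruth(
        exponent=1.0,
        components=[alpha, beta],
        exponent_effects={
            "age": -0.005,
            "group:AD": 0.15,
            "group:PD": 0.15,
            "group:ALS": -0.15,
        },
    )


def _truth_to_jsonable(truth: SpectralGroundTruth, effective: list[dict]) -> dict:
    def clean(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return {"truth": clean(asdict(truth)), "effective": clean(effective)}


def save_cohort(cohort: Cohort, h5_path, csv_path, truth_path=None) -> None:
    """Write a cohort to the HDF5 + CSV (+ JSON ground truth) layout.

    HDF5 layout: one dataset per subject at ``/subjects/<id>/timecourses``
    (parcels x samples) with ``fs`` and ``parcel_labels`` attributes.
    """
    with h5py.File(h5_path, "w") as h5:
        grp = h5.create_group("subjects")
        for subject in cohort.subjects:
            g = grp.create_group(subject.subject_id)
            dset = g.create_dataset("timecourses", data=subject.data, track_times=False)
            dset.attrs["fs"] = subject.fs
            dset.attrs["parcel_labels"] = [s.encode() for s in subject.parcel_labels]
    cohort.covariates.to_csv(csv_path, index=False)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(_truth_to_jsonable(cohort.truth, cohort.effective), fh, indent=1)
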