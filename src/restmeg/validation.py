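"""End-to-end validation experiments on synthetic cohorts.

Each function sets up a cohort (or constructed signals) with known ground
truth, runs the corresponding pipeline operations, and returns the measured
recovery quantities: demographic chi-squared, aperiodic-exponent recovery,
centre-of-energy identities, AEC oracle agreement, family-wise error
calibration of the max-t permutation GLM, injected-effect recovery, and the
Welch/Parseval check. The acceptance script and the acceptance test suite
both drive these.

Problem sizes are chosen for single-CPU desk-scale runs; see
docs/methods.md for the exact conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .bands import ALPHA, BETA
from .connectivity import aec_matrix
from .glm import Contrast, build_design, chi_squared_sex_balance, fit_glm, maxt_permutation, sex_counts_from_percent
from .preprocess import zscore_timecourse
from .specparam import centre_of_energy, fit_cohort, parameterize_spectrum
from .spectral import band_power, welch_psd
from .synth import (
    CohortSpec,
    OscillatoryComponent,
    SpectralGroundTruth,
    expected_band_power,
    generate_cohort,
    generate_subject_timecourses,
)

#: Published cohort demographics (group sizes and % male) used for the
#: sex-balance check: AD, PD, ALS, age-matched HC, young HC.
COHORT_SIZES = (29, 25, 33, 114, 77)
COHORT_PCT_MALE = (48.3, 60.0, 57.6, 57.9, 49.3)


def demographic_chi_squared() -> dict:
    """Sex-balance chi-squared on the reconstructed male/female table."""
    counts = sex_counts_from_percent(COHORT_SIZES, COHORT_PCT_MALE)
    chi2, df = chi_squared_sex_balance(counts)
    return {"chi2": chi2, "df": df, "n": int(sum(COHORT_SIZES))}


def exponent_recovery(
    seed: int,
    chis: tuple[float, ...] = (0.5, 1.0, 2.0),
    n_subjects: int = 2,
    n_parcels: int = 4,
    duration: float = 300.0,
) -> dict:
    """Fit pure-aperiodic synthetic cohorts; report |chi_hat - chi| errors."""
    errors = []
    for k, chi in enumerate(chis):
        spec = CohortSpec(
            n_subjects_per_group=n_subjects,
            groups=("HC",),
            n_parcels=n_parcels,
            duration=duration,
            seed=(seed + 7919 * k) % 2**31,
        )
        truth = SpectralGroundTruth(exponent=chi, components=[], exponent_subject_sd=0.0)
        cohort = generate_cohort(spec, truth)
        for subject in cohort.subjects:
            psd = welch_psd(zscore_timecourse(subject.data), spec.fs)
            for fit in fit_cohort(psd):
                errors.append(abs(fit.exponent - chi))
    return {"mae": float(np.mean(errors)), "max_error": float(np.max(errors)), "n_fits": len(errors)}


def coe_identities() -> dict:
    """Single-peak balance and leftward-shift monotonicity of the CoE."""
    freqs = np.arange(0.5, 125.1, 0.5)
    base = 0.5 - 1.5 * np.log10(np.clip(freqs, 1e-12, None))

    def coe_for(cf):
        g = 0.5 * np.exp(-((freqs - cf) ** 2) / 2.0)
        fit = parameterize_spectrum(10 ** (base + g), freqs=freqs)
        return centre_of_energy(fit)

    coe10, coe8 = coe_for(10.0), coe_for(8.0)
    return {
        "single_peak_error": abs(coe10 - 10.0),
        "coe_at_10": coe10,
        "coe_at_8": coe8,
        "shift_decreases": bool(coe8 < coe10),
    }


def _slow(rng, n, fs, cutoff=0.5):
    sos = signal.butter(4, cutoff, btype="low", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def aec_oracle(seed: int, fs: float = 250.0, duration: float = 120.0, w: float = 0.7) -> dict:
    """AEC of constructed shared-envelope parcels vs. the direct envelope
    correlation, and invariance to per-parcel rescaling."""
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    t = np.arange(n) / fs
    shared = _slow(rng, n, fs)
    envs, xs = [], []
    for k in range(3):
        s = (w * shared + (1 - w) * _slow(rng, n, fs)) / np.hypot(w, 1 - w)
        env = np.clip(1 + 0.5 * s, 0, None)
        envs.append(env)
        xs.append(env * np.sin(2 * np.pi * 10 * t + 1.3 * k))
    xs = np.vstack(xs)
    m = aec_matrix(xs, fs, ALPHA)
    trim = int(fs)
    deviations = []
    for i in range(3):
        for j in range(i + 1, 3):
            direct = np.corrcoef(envs[i][trim:-trim], envs[j][trim:-trim])[0, 1]
            deviations.append(abs(m.matrix[i, j] - direct))
    scaled = xs.copy()
    scaled[1] *= 7.0
    m2 = aec_matrix(scaled, fs, ALPHA)
    return {
        "max_oracle_deviation": float(np.max(deviations)),
        "rescaling_deviation": float(np.nanmax(np.abs(m.matrix - m2.matrix))),
        "n_pairs": len(deviations),
    }


def _null_records(rng, n_per_group=30) -> pd.DataFrame:
    n = 2 * n_per_group
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["A"] * n_per_group + ["B"] * n_per_group,
            "age": rng.uniform(50, 80, n),
            "sex": [("M", "F")[i % 2] for i in range(n)],
            "scanner": [("A", "B")[(i // 2) % 2] for i in range(n)],
            "gm_volume": rng.normal(620, 25, n),
        }
    )


def fwe_calibration(
    seed: int,
    n_replicates: int = 200,
    n_per_group: int = 30,
    n_cells: int = 20,
    n_perm: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Family-wise rejection rate of the max-t procedure under a global null.

    Metric tables (10 parcels x 2 metrics by default) are drawn independent
    of the design, so any FWE-significant cell is a false positive.
    """
    rng = np.random.default_rng(seed)
    records = _null_records(rng, n_per_group)
    design, contrasts = build_design(records, "group_compare")
    rejections = 0
    for rep in range(n_replicates):
        Y = rng.standard_normal((2 * n_per_group, n_cells))
        res = maxt_permutation(
            Y, design, contrasts[0], n_perm=n_perm, seed=(seed + 104729 * rep) % 2**31
        )
        rejections += bool(res.p_fwe.min() < alpha)
    return {"fwe_rate": rejections / n_replicates, "n_replicates": n_replicates}


def _beta_truth(ad_log10_factor=None, age_slope=None) -> SpectralGroundTruth:
    effects = {}
    if ad_log10_factor is not None:
        effects["group:AD"] = ad_log10_factor
    if age_slope is not None:
        effects["age"] = age_slope
    comp = OscillatoryComponent(
        name="beta",
        centre=20.0,
        amplitude=0.6,
        freq_sigma=2.5,
        envelope_weight=0.4,
        amp_effects=effects,
    )
    return SpectralGroundTruth(exponent=1.0, components=[comp])


def _beta_power_matrix(cohort, fs):
    return np.array(
        [band_power(welch_psd(s.data, fs), BETA) for s in cohort.subjects]
    )


def group_effect_recovery(
    seed: int,
    n_replicates: int = 20,
    n_per_group: int = 30,
    n_parcels: int = 10,
    duration: float = 120.0,
    n_perm: int = 500,
) -> dict:
    """Detection of a halved beta amplitude in an AD-like group.

    The amplitude factor of 0.5 reduces measured beta band power by well
    over one healthy-group standard deviation; success means every parcel's
    AD-HC beta cope is negative and at least one parcel is FWE-significant.
    """
    detected, negative, effect_sds = 0, 0, []
    for rep in range(n_replicates):
        spec = CohortSpec(
            n_subjects_per_group=n_per_group,
            groups=("AD", "HC"),
            n_parcels=n_parcels,
            duration=duration,
            seed=(seed + 15485863 * rep) % 2**31,
        )
        cohort = generate_cohort(spec, _beta_truth(ad_log10_factor=np.log10(0.5)))
        Y = _beta_power_matrix(cohort, spec.fs)
        groups = cohort.covariates["group"].to_numpy()
        hc, ad = Y[groups == "HC"], Y[groups == "AD"]
        effect_sds.append(((hc.mean(0) - ad.mean(0)) / hc.std(0, ddof=1)).mean())
        design, contrasts = build_design(cohort.covariates, "group_compare")
        assert contrasts[0].name == "AD-HC"
        res = maxt_permutation(
            Y, design, contrasts[0], n_perm=n_perm, seed=(seed + 32452843 * rep) % 2**31
        )
        negative += bool(np.all(res.copes < 0))
        detected += bool(np.all(res.copes < 0) and res.p_fwe.min() < 0.05)
    return {
        "detection_rate": detected / n_replicates,
        "negative_cope_rate": negative / n_replicates,
        "mean_effect_sd": float(np.mean(effect_sds)),
        "n_replicates": n_replicates,
    }


def age_slope_recovery(
    seed: int,
    n_replicates: int = 20,
    n_subjects: int = 60,
    n_parcels: int = 10,
    duration: float = 120.0,
    age_slope: float = 0.004,
) -> dict:
    """Recovery of an injected per-year age slope on beta amplitude.

    Per replicate the ageing-GLM cope for parcel-mean beta power is compared
    with the slope implied by the generator's realised subject parameters
    (regression of conditionally expected band power on age); success is
    agreement within two standard errors.
    """
    covered = 0
    for rep in range(n_replicates):
        spec = CohortSpec(
            n_subjects_per_group=n_subjects,
            groups=("HC",),
            n_parcels=n_parcels,
            duration=duration,
            seed=(seed + 49979687 * rep) % 2**31,
        )
        cohort = generate_cohort(spec, _beta_truth(age_slope=age_slope))
        y = _beta_power_matrix(cohort, spec.fs).mean(axis=1)
        expected = np.array(
            [
                np.mean(
                    [expected_band_power(e, BETA, spec.fs, parcel=p) for p in range(n_parcels)]
                )
                for e in cohort.effective
            ]
        )
        age = cohort.covariates["age"].to_numpy()
        A = np.column_stack([np.ones_like(age), age])
        true_slope = np.linalg.lstsq(A, expected, rcond=None)[0][1]
        design, contrasts = build_design(cohort.covariates, "ageing")
        fit = fit_glm(y, design, contrasts[0])
        covered += bool(abs(fit.cope - true_slope) <= 2 * fit.se)
    return {"coverage_rate": covered / n_replicates, "n_replicates": n_replicates}


def parseval_check(seed: int, fs: float = 250.0, duration: float = 300.0) -> dict:
    """Integral of the one-sided Welch PSD of a z-scored signal."""
    spec = CohortSpec(
        n_subjects_per_group=1, groups=("HC",), n_parcels=2, duration=duration, seed=seed % 2**31
    )
    tc = generate_subject_timecourses(
        spec, _beta_truth(), {"age": 65.0, "sex": "M", "group": "HC"}
    )
    psd = welch_psd(tc.data, fs)
    integrals = psd.density.sum(axis=-1) * psd.df
    return {
        "max_integral_error": float(np.max(np.abs(integrals - 1.0))),
        "integrals": integrals.tolist(),
    }
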