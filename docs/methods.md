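# Methods

This note documents the models, numerical choices and known limitations of
`restmeg`: what each stage computes, what the synthetic-data generator does
and does not emulate, and which problem sizes the validation experiments
use.

## Parcel preprocessing

Analyses operate on parcellated source time courses (by convention 52
cortical parcels sampled at 250 Hz). Each recording is band-pass filtered
1–80 Hz with a zero-phase (forward–backward) 5th-order Butterworth filter —
zero phase so that no group delay distorts amplitude envelopes downstream.
Bad segments are detected from abnormally high windowed variance:
non-overlapping 1 s windows, log-variance z-scored across windows, windows
with z > 3 dropped and the remaining data concatenated; the window length
and threshold are this package's choices for a simple, testable rule.
Cleaned time courses are z-scored per parcel (population SD), so every
subsequent PSD integrates to ≈ 1 and power is expressed as a fraction of
total signal power.

Resampling is not implemented: inputs are expected at 250 Hz, and the
simulator emits 250 Hz directly.

## Spectral power

PSDs use Welch's method with 2 s Hann windows and 50 % overlap
(0.5 Hz resolution), no detrending (the data are already z-scored). Band
power is the *mean* density over a band's bins — not the integral — so
bands of different widths are comparable. Bands are half-open [lo, hi):
delta 1–4, theta 4–7, alpha 7–13, beta 13–30, low-gamma 30–48, high-gamma
52–80 Hz; the 48–52 Hz gap is the line-noise notch region and is left
uncovered.

## Spectral parameterisation

Each PSD is modelled between 1 and 70 Hz (higher frequencies excluded to
avoid spectral-plateau bias) in log10 power as an aperiodic line plus
Gaussian peaks, fixed (knee-free) aperiodic mode:

    log10 P(f) = b − χ·log10 f + Σₖ PWₖ·exp(−(f − CFₖ)² / 2σₖ²)

Settings: peak bandwidth (2σ) limited to 0.5–12 Hz, minimum peak height
0.05 log10 units, peak threshold 2.0 × residual SD, unlimited peaks (capped
at 20 for safety). The aperiodic line is fitted robustly (positive residual
bumps excluded, so the line hugs the spectral floor), peaks are extracted
iteratively from the flattened spectrum (tallest residual first, half-height
width guess), jointly refined with bounded least squares, pruned by the
height rules, and the aperiodic component is refitted on the peak-removed
spectrum.

On Welch-estimated spectra the per-bin residual SD at 300 s is ≈ 0.03
log10 units, so the 0.05 minimum height admits occasional small
noise-driven peaks; these have low power and random centre frequencies and
do not affect the highest-power-per-band peak selection, but "zero peaks"
should only be expected of noise-free spectra.

**Centre of energy (CoE).** The periodic (aperiodic-flattened) spectrum is
floored at zero; the CoE is the smallest frequency at which the cumulative
periodic power reaches half the total, linearly interpolated within the
crossing bin. Bin mass is treated as centred on the bin frequency, so a
symmetric peak centred on a grid point yields exactly that frequency. The
balance-point definition is used rather than the power-weighted mean
frequency because it is what the operational description of the metric
specifies; the weighted-mean variant is available behind a flag
(`weighted=True`) for sensitivity analysis. When two spectral modes hold
exactly half the power each, the crossing lies on a plateau and is
numerically delicate; the smallest-crossing convention resolves it to the
lower mode's upper tail. A spectrum with no periodic power returns NaN.

**Peak bookkeeping.** Within the alpha (7–13 Hz) and beta (13–30 Hz) search
ranges the highest-power retained peak is selected (ties towards the lower
frequency). Missing cells are imputed with the mean over all participants
for that parcel and band, pooled across groups, with an `imputed` flag;
missing-peak counts per subject and band are taken before imputation.

## Connectivity

AEC: band-pass to the band, analytic-signal (Hilbert) magnitude, 1 s
trimmed from each end, pairwise Pearson correlation. Envelopes are not
downsampled before correlation. Global connectivity is a parcel's mean
correlation with all other parcels, excluding the unit diagonal (including
it would bias all values upward by 1/n). No leakage correction
(orthogonalisation) is applied; on real beamformed data AEC values
therefore include a spatial-leakage component, which the synthetic
validation does not probe.

## Permutation GLM

Every metric cell (parcel × band/metric) is fitted by OLS against a shared
subject-level design. Three designs are provided: healthy ageing
(intercept, age, centred sex and scanner; contrast on age), pairwise group
comparison (one indicator per group plus centred age, sex, scanner and
grey-matter volume; +1/−1 contrasts), and per-group age slopes for the
beta-ageing analysis (slope-difference contrasts). Constant covariate
columns (e.g. a single-scanner cohort) are dropped with a warning; rank
deficiency is an error naming the most collinear columns.

FWE correction permutes the rows of the regressors of interest (the
columns with non-zero contrast weight) across subjects, nuisance columns
fixed, and records the maximum |t| over all cells per permutation. The
corrected p-value is the exceedance form
p = (1 + #{null ≥ |t_obs|}) / (n_perm + 1), two-tailed, 5000 permutations
by default in the pipeline configuration. Residual degrees of freedom for
inference are n − rank(X); a conventional reporting formula
(n − (n_comparisons + n_regressors − 1 + 1)) is echoed alongside in the df
report, with the rank-based value authoritative.

The demographic helper reconstructs a groups × sex contingency table from
group sizes and percent-male and applies Pearson's chi-squared without
continuity correction, df = (rows−1)(cols−1).

## Synthetic cohorts

Each subject's parcel signal is

    x_p(t) = n_χ(t) + Σₖ aₖ·envₖ(t)·cₖ(t),   then z-scored,

with the three pieces constructed exactly in the frequency domain:

- **Aperiodic background** `n_χ`: white Gaussian noise shaped by f^(−χ/2)
  above 1 Hz, flat below 1 Hz, unit variance. This gives an exact target
  log-log slope over the fitting range.
- **Carriers** `cₖ`: unit-variance noise with a Gaussian spectral profile
  (centre CF, width σ_f), so fitted peak parameters map directly onto
  generator parameters.
- **Envelopes** `envₖ`: slow (< 1 Hz low-pass, 4th-order Butterworth,
  0.5 Hz cutoff) Gaussian processes, mixed as w·shared + (1−w)·independent
  (unit-variance mixture), shifted, floored at zero
  (env = max(1 + 0.5·s, 0)) and RMS-normalised. The sharing weight w sets
  the between-parcel AEC; w = 1 gives fully shared envelopes.

Covariate effects are linear and additive on the exponent, on log10
amplitude, and on centre frequency (Hz), matching the linear model used
for inference; 'group:<label>' keys act on 0/1 indicators, age is centred
at the cohort age-range midpoint. Because amplitude effects are additive
on the log scale they cannot drive amplitude negative; quantities that can
leave their domain (effective exponent below 0, frequency outside
(0.5 Hz, Nyquist−1)) are clipped with a warning. Each subject additionally
receives Gaussian jitter (defaults: exponent SD 0.1, log10-amplitude SD
0.1, frequency SD 0.5 Hz) to provide between-subject variability.
Covariates are sampled as: age uniform over the range, sex
Bernoulli(sex_ratio), scanner split evenly over two sites, grey-matter
volume 620 − 1.5·(age − 65) + N(0, 25) mL (an age-correlated stand-in for
the MRI-derived covariate, which is out of scope).

All randomness derives from (seed, subject index) via `SeedSequence`, so a
fixed seed reproduces a cohort byte-for-byte.

`expected_band_power` computes the conditionally expected measured band
power for a subject's realised parameters: the aperiodic band integral
analytically, each component as amplitude² times Gaussian spectral mass in
the band, split between the carrier width and an envelope-broadened width
(Gaussian convolution approximation; the envelope's DC power fraction,
0.808 for the default gain, stays at the carrier width). It agrees with
Welch measurements within a few percent and serves as the oracle for
effect-recovery validation.

**What the generator does not emulate:** sensor physics, head geometry,
forward/inverse modelling, spatial leakage between parcels, line noise,
artifacts, non-Gaussian or non-stationary backgrounds beyond the slow
envelopes, and realistic parcel-amplitude distributions (beamformer output
is unitless; only spectral/connectivity structure is promised). Passing
validation therefore demonstrates correctness of the metric and inference
machinery, not robustness to real-data artefacts.

## Validation experiment sizes

The validation suite (`restmeg.validation`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) uses desk-scale
problem sizes, chosen once:

- Exponent recovery: χ ∈ {0.5, 1.0, 2.0}, 2 subjects × 4 parcels each,
  300 s at 250 Hz, no subject jitter; reports the mean absolute error of
  the fitted exponent.
- CoE identities: exact synthetic spectra (noise-free), peak at 10 Hz vs
  8 Hz.
- AEC oracle: 3 constructed parcels with envelope sharing w = 0.7, 120 s;
  reports the maximum deviation from the direct envelope correlation and
  the effect of rescaling one parcel by 7.
- FWE calibration: 200 replicate global-null metric tables, n = 60
  (30/group), 10 parcels × 2 metrics, 500 permutations, threshold 0.05.
- Group-effect recovery: 20 replicate cohorts, 30/group, 10 parcels,
  120 s, beta amplitude × 0.5 in the AD-like group (≥ 1 healthy-group SD
  of measured beta power); success = all beta copes negative and at least
  one parcel FWE-significant at 500 permutations.
- Age-slope recovery: 20 replicate single-group cohorts, n = 60,
  10 parcels, 120 s, +0.004 log10-amplitude per year on beta; the ageing
  cope for parcel-mean beta power must lie within 2 SE of the slope implied
  by the realised generator parameters.
- Parseval: default-condition subject (300 s), maximum deviation of the
  PSD integral from 1. At 300 s the integral's realisation SD is ≈ 1 %
  (slow amplitude envelopes make the beta band's realised power fluctuate);
  much shorter recordings would not support a 5 % check.

## Known limitations

- The spectral parameterisation is a reimplementation of the standard
  aperiodic + Gaussian-peaks algorithm; small numerical differences from
  other implementations (robust-fit percentile, width-guess heuristics)
  are expected, though both recover exact model-family inputs to high
  precision.
- Knee-mode aperiodic fitting is not implemented; spectra with a visible
  knee in 1–70 Hz will bias χ.
- Permutation inference assumes exchangeability of subjects under the
  null within the permuted regressors; no block or within-site permutation
  scheme is provided.
- The CoE of a spectrum with no detectable periodic power is undefined
  (NaN) and such cells are excluded from the GLM stage with a warning.
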