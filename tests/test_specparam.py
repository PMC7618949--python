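import numpy as np
import pandas as pd
import pytest

from restmeg.specparam import (
    centre_of_energy,
    count_missing_peaks,
    exponent,
    impute_missing_peaks,
    parameterize_spectrum,
    select_band_peak,
)

FREQS = np.arange(0.5, 125.1, 0.5)


def make_psd(offset=0.5, chi=1.5, peaks=()):
    """Exact synthetic PSD from the aperiodic + Gaussian-peaks model."""
    logp = offset - chi * np.log10(np.clip(FREQS, 1e-12, None))
    for cf, pw, sigma in peaks:
        logp = logp + pw * np.exp(-((FREQS - cf) ** 2) / (2 * sigma**2))
    return 10**logp


def grid_search_peak(flat, freqs):
    """Independent least-squares oracle: brute-force (CF, PW, sigma) search."""
    best, best_err = None, np.inf
    for cf in np.arange(4.0, 16.01, 0.05):
        for pw in np.arange(0.1, 1.01, 0.01):
            for sigma in np.arange(0.5, 2.01, 0.05):
                model = pw * np.exp(-((freqs - cf) ** 2) / (2 * sigma**2))
                err = np.sum((flat - model) ** 2)
                if err < best_err:
                    best, best_err = (cf, pw, 2 * sigma), err
    return best


class TestParameterize:
    def test_pure_aperiodic_recovered_exactly(self):
        fit = parameterize_spectrum(make_psd(0.5, 1.5), freqs=FREQS)
        assert fit.exponent == pytest.approx(1.5, abs=0.01)
        assert fit.offset == pytest.approx(0.5, abs=0.01)
        assert len(fit.peaks) == 0

    def test_flat_spectrum_zero_exponent(self):
        fit = parameterize_spectrum(make_psd(0.0, 0.0), freqs=FREQS)
        assert exponent(fit) == pytest.approx(0.0, abs=0.01)

    def test_exponent_monotone_in_true_slope(self):
        est = [
            parameterize_spectrum(make_psd(0.5, chi), freqs=FREQS).exponent
            for chi in (0.5, 1.0, 2.0)
        ]
        assert est[0] < est[1] < est[2]
        assert np.allclose(est, [0.5, 1.0, 2.0], atol=0.01)

    def test_single_peak_matches_grid_search_oracle(self):
        psd = make_psd(0.5, 1.5, peaks=[(10.0, 0.5, 1.0)])
        fit = parameterize_spectrum(psd, freqs=FREQS)
        assert len(fit.peaks) == 1
        cf, pw, bw = fit.peaks[0]
        sel = (FREQS >= 1) & (FREQS <= 70)
        flat = np.log10(psd[sel]) - (0.5 - 1.5 * np.log10(FREQS[sel]))
        ocf, opw, obw = grid_search_peak(flat, FREQS[sel])
        assert cf == pytest.approx(ocf, abs=0.25)
        assert pw == pytest.approx(opw, abs=0.05)
        assert bw == pytest.approx(obw, abs=0.5)

    def test_subthreshold_peak_not_retained(self):
        # Height 0.02 is below the minimum peak height of 0.05.
        fit = parameterize_spectrum(
            make_psd(0.5, 1.5, peaks=[(10.0, 0.02, 1.0)]), freqs=FREQS
        )
        assert len(fit.peaks) == 0

    def test_scaling_shifts_offset_not_exponent(self):
        fit1 = parameterize_spectrum(make_psd(0.5, 1.5), freqs=FREQS)
        fit2 = parameterize_spectrum(7.0 * make_psd(0.5, 1.5), freqs=FREQS)
        assert fit2.exponent == pytest.approx(fit1.exponent, abs=1e-6)
        assert fit2.offset - fit1.offset == pytest.approx(np.log10(7.0), abs=1e-6)

    def test_periodic_spectrum_of_aperiodic_input_near_zero(self):
        fit = parameterize_spectrum(make_psd(0.5, 1.5), freqs=FREQS)
        resid_sd = max(np.std(fit.periodic), 1e-12)
        assert np.all(np.abs(fit.periodic) < 3 * resid_sd + 1e-9)

    def test_round_trip_refit(self):
        truth = dict(offset=0.3, chi=1.2, peaks=[(10.0, 0.4, 1.0), (21.0, 0.3, 2.0)])
        fit = parameterize_spectrum(
            make_psd(truth["offset"], truth["chi"], truth["peaks"]), freqs=FREQS
        )
        refit = parameterize_spectrum(10 ** fit.model(FREQS), freqs=FREQS)
        assert refit.exponent == pytest.approx(fit.exponent, abs=0.02)
        assert refit.offset == pytest.approx(fit.offset, abs=0.02)
        assert len(refit.peaks) == len(fit.peaks)
        assert np.allclose(refit.peaks[:, 0], fit.peaks[:, 0], atol=0.25)

    def test_nonpositive_density_rejected(self):
        psd = make_psd()
        psd[40] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            parameterize_spectrum(psd, freqs=FREQS)


class TestCentreOfEnergy:
    def test_symmetric_peak_balances_at_centre(self):
        fit = parameterize_spectrum(
            make_psd(0.5, 1.5, peaks=[(10.0, 0.5, 1.0)]), freqs=FREQS
        )
        assert centre_of_energy(fit) == pytest.approx(10.0, abs=0.25)

    def test_two_narrow_peaks_smallest_crossing(self):
        # Two narrow peaks at 8 and 20 Hz, the first marginally stronger so
        # the half-power crossing lands robustly in the low peak's tail.
        psd = make_psd(0.5, 1.5, peaks=[(8.0, 0.5, 0.25), (20.0, 0.49, 0.25)])
        fit = parameterize_spectrum(psd, freqs=FREQS)
        # independent cumulative-sum oracle on the constructed periodic part
        sel = (FREQS >= 1) & (FREQS <= 70)
        f = FREQS[sel]
        per = np.log10(psd[sel]) - (0.5 - 1.5 * np.log10(f))
        cum = np.cumsum(per)
        i = int(np.searchsorted(cum, cum[-1] / 2))
        oracle = f[i]
        assert centre_of_energy(fit) == pytest.approx(oracle, abs=0.5)
        assert abs(centre_of_energy(fit) - 8.0) < 1.0

    def test_leftward_peak_shift_decreases_coe(self):
        coes = [
            centre_of_energy(
                parameterize_spectrum(
                    make_psd(0.5, 1.5, peaks=[(cf, 0.5, 1.0)]), freqs=FREQS
                )
            )
            for cf in (10.0, 8.0)
        ]
        assert coes[1] < coes[0]

    def test_invariant_to_periodic_scaling(self):
        fit = parameterize_spectrum(
            make_psd(0.5, 1.5, peaks=[(10.0, 0.5, 1.0)]), freqs=FREQS
        )
        scaled = type(fit)(
            offset=fit.offset,
            exponent=fit.exponent,
            peaks=fit.peaks,
            freqs=fit.freqs,
            periodic=3.0 * fit.periodic,
            fit_error=fit.fit_error,
        )
        assert centre_of_energy(scaled) == pytest.approx(centre_of_energy(fit))

    def test_no_periodic_power_gives_nan(self):
        fit = parameterize_spectrum(make_psd(0.5, 1.5), freqs=FREQS)
        fit.periodic = np.full_like(fit.periodic, -0.01)
        assert np.isnan(centre_of_energy(fit))


class TestPeakBookkeeping:
    def _fit_with(self, peaks):
        return parameterize_spectrum(make_psd(0.5, 1.5, peaks=peaks), freqs=FREQS)

    def test_highest_power_peak_selected(self):
        # Selection logic on a fit holding two alpha peaks: the stronger
        # 11 Hz peak wins regardless of order.
        fit = self._fit_with([(10.0, 0.5, 1.0)])
        fit.peaks = np.array([[9.0, 0.3, 2.0], [11.0, 0.5, 2.0]])
        assert select_band_peak(fit, "alpha") == (11.0, 0.5)
        fit.peaks = fit.peaks[::-1]
        assert select_band_peak(fit, "alpha") == (11.0, 0.5)

    def test_tie_broken_towards_lower_frequency(self):
        fit = self._fit_with([(10.0, 0.5, 1.0)])
        fit.peaks = np.array([[9.0, 0.5, 2.0], [11.0, 0.5, 2.0]])
        assert select_band_peak(fit, "alpha") == (9.0, 0.5)

    def test_band_without_peak_is_missing(self):
        fit = self._fit_with([(10.0, 0.5, 1.0)])
        assert select_band_peak(fit, "beta") is None

    def test_single_peak_returned_as_is(self):
        fit = self._fit_with([(10.0, 0.5, 1.0)])
        cf, _ = select_band_peak(fit, "alpha")
        assert cf == pytest.approx(10.0, abs=0.25)


class TestImputation:
    def _table(self):
        return pd.DataFrame(
            {
                "subject_id": ["s1", "s2", "s3"] * 2,
                "parcel": [0] * 3 + [1] * 3,
                "band": ["alpha"] * 6,
                "peak_freq": [10.0, 12.0, np.nan, 9.0, np.nan, np.nan],
                "peak_power": [0.5, 0.3, np.nan, 0.2, np.nan, np.nan],
            }
        )

    def test_missing_cell_gets_cross_participant_mean(self):
        out = impute_missing_peaks(self._table())
        row = out[(out.subject_id == "s3") & (out.parcel == 0)]
        assert row.peak_freq.item() == pytest.approx(11.0)
        assert row.imputed.item()

    def test_no_missing_values_table_unchanged(self):
        t = self._table().dropna().reset_index(drop=True)
        out = impute_missing_peaks(t)
        pd.testing.assert_frame_equal(out.drop(columns="imputed"), t)

    def test_imputation_preserves_observed_mean(self):
        t = self._table()
        observed = t.dropna().groupby(["parcel", "band"]).peak_freq.mean()
        out = impute_missing_peaks(t)
        after = out.groupby(["parcel", "band"]).peak_freq.mean()
        pd.testing.assert_series_equal(observed, after.loc[observed.index])

    def test_counts_match_imputed_flags(self):
        t = self._table()
        counts = count_missing_peaks(t)
        assert counts.loc["s3", "missing_alpha_peaks"] == 2
        assert counts.loc["s1", "missing_alpha_peaks"] == 0
        out = impute_missing_peaks(t)
        flagged = out.groupby("subject_id").imputed.sum()
        assert (counts["missing_alpha_peaks"] == flagged).all()
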