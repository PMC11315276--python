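"""Welch/state PSDs and the aperiodic + Gaussian-peak spectral model."""

import numpy as np
import pytest

import vigispec as v

from conftest import make_recording


def power_law_spectrum(chi, b=0.0, peaks=(), df=0.5):
    f = np.arange(1.0, 65.0 + df / 2, df)
    logp = b - chi * np.log10(f)
    for c, h, sd in peaks:
        logp = logp + h * np.exp(-((f - c) ** 2) / (2 * sd**2))
    return v.PowerSpectrum(freqs=f, power=10.0**logp)


class TestWelchPsd:
    def test_white_noise_density_flat_at_two_over_fs(self, rng):
        x = rng.standard_normal(250 * 120)
        ps = v.welch_psd(x, 250)
        expected = 2.0 * np.var(x) / 250.0
        assert np.median(ps.power) == pytest.approx(expected, rel=0.15)
        assert ps.power.max() / ps.power.min() < 3.0

    def test_sinusoid_peak_lands_in_right_bin(self):
        t = np.arange(250 * 30) / 250
        ps = v.welch_psd(np.sin(2 * np.pi * 10.0 * t), 250)
        assert abs(ps.freqs[np.argmax(ps.power)] - 10.0) <= 0.5

    def test_doubling_signal_length_keeps_spectrum(self, rng):
        x = rng.standard_normal(250 * 60)
        p1 = v.welch_psd(x, 250)
        p2 = v.welch_psd(np.concatenate([x, x]), 250)
        np.testing.assert_allclose(p2.power, p1.power, rtol=0.35)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            v.welch_psd(np.zeros(100), 250)


class TestStatePsd:
    def test_single_state_equals_epoch_average(self, rng):
        x = rng.standard_normal(250 * 60)
        rec = make_recording(x)
        hyp = v.Hypnogram(np.full(60, "a1", dtype=object))
        ps = v.state_psd(rec, hyp, "a1")[0]
        assert ps.n_epochs == 60
        # Parseval: integral of density ~ variance (rectangular epochs)
        total = np.trapezoid(ps.power, ps.freqs)
        band_var = total  # 1-65 Hz of white noise at fs 250: (65-1)/125 of var
        assert band_var == pytest.approx(np.var(x) * 64 / 125, rel=0.1)

    def test_low_occupancy_state_skipped_with_warning(self, white_recording):
        labels = np.full(10, "a1", dtype=object)
        labels[:2] = "a3"
        hyp = v.Hypnogram(labels)
        with pytest.warns(UserWarning, match="skipped"):
            out = v.state_psd(white_recording, hyp, "a3")
        assert out == []

    def test_planted_a3_exponent_recovered(self):
        """End-to-end: planted χ=0.737 in a3 comes back within 0.05."""
        states = v.human_state_specs()
        seq = np.full(480, "a3", dtype=object)
        rec, truth = v.synthesize_recording(states, seq, 250, seed=40,
                                            include_emg=False)
        filt = v.bandpass_filter(rec)
        fit = v.fit_spectral_model(v.state_psd(filt, truth, "a3")[0])
        assert fit.exponent == pytest.approx(0.737, abs=0.05)


class TestSpectralParameterization:
    def test_exact_power_law_fit_is_exact(self):
        fit = v.fit_spectral_model(power_law_spectrum(1.0))
        assert fit.exponent == pytest.approx(1.0, abs=1e-3)
        assert fit.offset == pytest.approx(0.0, abs=1e-3)
        assert fit.n_peaks == 0
        assert fit.r_squared > 0.999

    def test_flat_spectrum_gives_zero_exponent(self):
        fit = v.fit_spectral_model(power_law_spectrum(0.0))
        assert fit.exponent == pytest.approx(0.0, abs=0.01)

    def test_peak_removal_beats_naive_ols(self):
        """A 10 Hz Gaussian peak barely moves χ̂; straight-line OLS it drags."""
        spec = power_law_spectrum(1.0, peaks=[(10.0, 0.5, 1.0)])
        fit = v.fit_spectral_model(spec)
        naive = -np.polyfit(np.log10(spec.freqs), np.log10(spec.power), 1)[0]
        assert fit.exponent == pytest.approx(1.0, abs=0.03)
        assert abs(naive - 1.0) > 0.05
        assert fit.n_peaks == 1
        center, height, sd = fit.peaks[0]
        assert center == pytest.approx(10.0, abs=0.5)
        assert height == pytest.approx(0.5, abs=0.1)

    def test_peak_robustness_for_any_single_inband_peak(self):
        """χ̂ shifts ≤ 0.05 for any one peak of height ≤ 1 log10 unit."""
        for center, height, sd in [(6, 1.0, 1.5), (10, 0.8, 1.5),
                                   (20, 0.5, 3.0), (40, 1.0, 4.0)]:
            fit = v.fit_spectral_model(
                power_law_spectrum(1.0, peaks=[(center, height, sd)]))
            assert fit.exponent == pytest.approx(1.0, abs=0.05), (center, height)

    def test_power_scaling_law(self):
        """power ×c ⇒ offset +log10 c, exponent unchanged."""
        spec = power_law_spectrum(1.2, peaks=[(10.0, 0.4, 1.5)])
        f0 = v.fit_spectral_model(spec)
        scaled = v.PowerSpectrum(freqs=spec.freqs, power=spec.power * 50.0)
        f1 = v.fit_spectral_model(scaled)
        assert f1.exponent == pytest.approx(f0.exponent, abs=0.01)
        assert f1.offset - f0.offset == pytest.approx(np.log10(50.0), abs=0.01)

    def test_exponent_recovery_across_grid(self):
        """|χ̂ − χ| ≤ 0.05 on 300-s signals for the χ grid (spot check)."""
        for chi in (0.5, 1.25, 2.0):
            x = v.generate_aperiodic_noise(250 * 300, 250, chi, seed=int(10 * chi))
            fit = v.fit_spectral_model(v.welch_psd(x, 250))
            assert fit.exponent == pytest.approx(chi, abs=0.05)

    def test_state_ordering_preserved(self):
        """Planted χ(a1) > χ(a2) > χ(a3) survives the full pipeline."""
        seq = v.generate_state_sequence(
            360, {"a1": 1 / 3, "a2": 1 / 3, "a3": 1 / 3}, 10, seed=50)
        rec, _ = v.synthesize_recording(v.ordering_subject_specs(), seq, 250,
                                        seed=51, include_emg=False)
        filt = v.bandpass_filter(rec)
        hyp = v.score_recording(filt, v.reject_artifacts(filt), "human")
        chi = {s: v.fit_spectral_model(v.state_psd(filt, hyp, s)[0]).exponent
               for s in ("a1", "a2", "a3")}
        assert chi["a1"] > chi["a2"] > chi["a3"]

    def test_invalid_spectra_rejected(self):
        f = np.arange(1.0, 65.0)
        with pytest.raises(ValueError):
            v.fit_spectral_model(v.PowerSpectrum(freqs=f, power=np.zeros_like(f)))
        with pytest.raises(ValueError):
            v.fit_spectral_model(v.PowerSpectrum(freqs=f[:5], power=np.ones(5)))

    def test_summary_reports_parameters(self):
        fit = v.fit_spectral_model(power_law_spectrum(1.0, peaks=[(10, 0.5, 1)]))
        text = fit.summary()
        assert "exponent" in text and "peaks" in text


class TestSubjectPooling:
    def test_single_channel_passthrough_and_mean(self):
        import pandas as pd
        fits = pd.DataFrame({
            "subject": ["s1", "s1", "s2"],
            "group": ["g", "g", "g"],
            "sex": ["m", "m", "f"],
            "state": ["a1", "a1", "a1"],
            "channel": ["c1", "c2", "c1"],
            "exponent": [1.0, 1.2, 0.9],
        })
        pooled = v.subject_state_exponents(fits)
        assert len(pooled) == 2
        assert pooled.set_index("subject").loc["s1", "exponent"] == pytest.approx(1.1)
        assert pooled.set_index("subject").loc["s2", "exponent"] == pytest.approx(0.9)
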