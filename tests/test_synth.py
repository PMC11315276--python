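"""Generators: planted spectra, state sequences, recordings and cohorts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vigispec as v
from vigispec.synth import equal_power_offset


def loglog_slope(x, fs):
    ps = v.welch_psd(x, fs)
    return np.polyfit(np.log10(ps.freqs), np.log10(ps.power), 1)[0]


class TestAperiodicNoise:
    @pytest.mark.parametrize("chi", [0.0, 1.0])
    def test_welch_slope_matches_planted_exponent(self, chi):
        x = v.generate_aperiodic_noise(250 * 120, 250, chi, seed=1)
        assert loglog_slope(x, 250) == pytest.approx(-chi, abs=0.05)

    def test_same_seed_reproduces_sample_path(self):
        a = v.generate_aperiodic_noise(1000, 250, 1.3, offset=-0.5, seed=9)
        b = v.generate_aperiodic_noise(1000, 250, 1.3, offset=-0.5, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_offset_sets_absolute_density(self):
        # at b=0 the density at 1 Hz is 1 µV²/Hz; b=1 scales power tenfold
        x0 = v.generate_aperiodic_noise(250 * 120, 250, 1.0, offset=0.0, seed=2)
        x1 = v.generate_aperiodic_noise(250 * 120, 250, 1.0, offset=1.0, seed=2)
        assert np.var(x1) / np.var(x0) == pytest.approx(10.0, rel=1e-9)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            v.generate_aperiodic_noise(100, 250, 1.0)  # < 2 s
        with pytest.raises(ValueError):
            v.generate_aperiodic_noise(1000, 250, -0.5)

    @settings(max_examples=8, derandomize=True, deadline=None)
    @given(c=st.floats(0.1, 100.0), seed=st.integers(0, 10))
    def test_scaling_signal_shifts_offset_not_exponent(self, c, seed):
        """x -> c·x leaves χ̂ unchanged and moves b̂ by 2·log10(c)."""
        x = v.generate_aperiodic_noise(250 * 60, 250, 1.0, seed=seed)
        f0 = v.fit_spectral_model(v.welch_psd(x, 250))
        f1 = v.fit_spectral_model(v.welch_psd(c * x, 250))
        assert f1.exponent == pytest.approx(f0.exponent, abs=0.02)
        assert f1.offset - f0.offset == pytest.approx(2 * np.log10(c), abs=0.02)


class TestStateSequence:
    def test_degenerate_mix_gives_single_state(self):
        seq = v.generate_state_sequence(60, {"a1": 1.0}, seed=0)
        assert len(seq) == 60
        assert set(seq) == {"a1"}

    def test_occupancy_converges_to_mix(self):
        seq = v.generate_state_sequence(3600, {"a1": 0.6, "a3": 0.4}, 10, seed=7)
        occ = np.mean(seq == "a1")
        assert occ == pytest.approx(0.6, abs=0.03)

    def test_mean_run_length_matches_dwell(self):
        seq = v.generate_state_sequence(10_000, {"a1": 0.6, "a3": 0.4}, 10, seed=11)
        switches = np.flatnonzero(seq[1:] != seq[:-1])
        n_runs = len(switches) + 1
        assert len(seq) / n_runs == pytest.approx(10.0, abs=1.0)

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            v.generate_state_sequence(100, {"a1": 0.5, "a2": 0.6}, seed=0)
        with pytest.raises(ValueError):
            v.generate_state_sequence(5, {"a1": 1.0}, seed=0)


class TestSynthesizeRecording:
    def test_unknown_label_rejected(self):
        states = v.human_state_specs()
        seq = np.array(["a1", "bogus"], dtype=object)
        with pytest.raises(ValueError, match="unknown"):
            v.synthesize_recording(states, seq, 250, seed=0)

    def test_no_artifacts_means_no_extreme_samples(self):
        states = [v.StateSpec("a1", 1.0, equal_power_offset(1.0))]
        seq = np.full(120, "a1", dtype=object)
        rec, _ = v.synthesize_recording(states, seq, 250, artifact_rate=0.0,
                                        seed=3, include_emg=False)
        x = rec.channels[0].data
        # Gaussian tail: P(|z| > 5) ~ 6e-7; 30k samples -> expect ~0 hits
        assert np.sum(np.abs(x - x.mean()) > 5 * x.std()) <= 2

    def test_a3_epochs_carry_alpha_peak(self):
        """Alpha-state epochs show an 8–12 Hz peak ≥ 2× the local 1/f level."""
        states = v.human_state_specs()
        seq = np.full(120, "a3", dtype=object)
        rec, _ = v.synthesize_recording(states, seq, 250, seed=4, include_emg=False)
        ps = v.welch_psd(rec.channels[0].data, 250)
        alpha = ps.power[(ps.freqs >= 8) & (ps.freqs <= 12)].max()
        # local aperiodic level interpolated from flanking bands
        flank = np.mean([ps.power[(ps.freqs >= 5) & (ps.freqs <= 6)].mean(),
                         ps.power[(ps.freqs >= 14) & (ps.freqs <= 16)].mean()])
        assert alpha >= 2 * flank

    def test_planted_exponent_contrast_recovered_downstream(self):
        """Two states planted at χ=1.25 vs 0.737 fit ~0.51 apart."""
        states = v.human_state_specs()  # a1: 1.25, a3: 0.737
        rng = np.random.default_rng(0)
        labels = np.where(rng.random(600) < 0.5, "a1", "a3").astype(object)
        rec, truth = v.synthesize_recording(states, labels, 250, seed=1,
                                            include_emg=False)
        filt = v.bandpass_filter(rec)
        chis = {}
        for s in ("a1", "a3"):
            spec = v.state_psd(filt, truth, s)[0]
            chis[s] = v.fit_spectral_model(spec).exponent
        assert chis["a1"] - chis["a3"] == pytest.approx(1.25 - 0.737, abs=0.08)

    def test_ground_truth_labels_returned(self):
        states = v.mouse_state_specs()
        seq = v.generate_state_sequence(
            60, {"a1": 0.5, "nrem": 0.5}, 10, seed=2)
        rec, truth = v.synthesize_recording(states, seq, 250, seed=2)
        np.testing.assert_array_equal(truth.labels.astype(str), seq.astype(str))
        assert truth.species_mode == "mouse"
        assert rec.emg_channels()  # mouse preset includes an EMG channel


class TestCohort:
    def test_masking_preset_pooled_means_equal_by_construction(self):
        design = v.masking_design()
        pooled = []
        for g in design.groups:
            mix = design.mix_for(g)
            pooled.append(sum(
                mix[s.name] * (s.exponent + g.shift_for(s.name))
                for s in design.states
            ))
        assert pooled[0] == pytest.approx(pooled[1], abs=1e-12)

    def test_same_seed_reproduces_cohort(self):
        design = v.masking_design(n_per_group=2, duration_s=60)
        (recs_a, truth_a) = v.generate_cohort(design)
        (recs_b, truth_b) = v.generate_cohort(design)
        np.testing.assert_array_equal(
            recs_a[0][0].channels[0].data, recs_b[0][0].channels[0].data)
        assert truth_a.equals(truth_b)

    def test_exponent_table_structure_and_effects(self):
        design = v.masking_design(n_per_group=20)
        tab = v.simulate_exponent_table(design, seed=5)
        assert set(tab.columns) >= {"subject", "group", "sex", "state",
                                    "exponent", "n_epochs"}
        means = tab.groupby(["group", "state"])["exponent"].mean()
        for s in ("a1", "a2", "a3"):
            assert means["hc", s] - means["pt", s] == pytest.approx(0.2, abs=0.08)

    def test_cohort_design_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            v.CohortDesign(states=v.human_state_specs(),
                           groups=[v.GroupSpec("a"), v.GroupSpec("b")],
                           state_mix={"a1": 0.5, "a3": 0.4})

    def test_state_spec_validation(self):
        with pytest.raises(ValueError):
            v.StateSpec("a1", -1.0)
        with pytest.raises(ValueError, match="0.2-3"):
            v.StateSpec("a1", 1.0, oscillations=((9.0, 1.0, 1.0),))
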