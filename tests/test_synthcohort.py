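"""Generator tests: protocol traces, cohorts, and the validation rig."""

import numpy as np
import pytest

from tremorforce import (
    CohortDesign,
    EncoderLog,
    ProtocolConfig,
    RigParams,
    SimuParams,
    default_cohort_design,
    default_healthy_params,
    default_pd_params_by_ftmtrs,
    encoder_frequency,
    exclude_thumbs,
    simulate_cohort,
    simulate_rig,
    simulate_trace,
)
from tremorforce.preprocess import find_hold_window, preprocess_trace
from tremorforce.spectral import dominant_frequency, power_spectral_density
from tremorforce.trace import HoldWindow


class TestSimulateTrace:
    def test_noise_free_plateau_is_exactly_target(self, protocol):
        params = SimuParams(tremor_amp_gf=0, noise_sd_gf=0, drift_gf_per_s=0, seed=0)
        trace = simulate_trace(params, protocol)
        plateau = trace.samples[int(params.ramp_s * protocol.rate_hz) + 1 :]
        assert np.all(plateau == protocol.target_gf)

    def test_trace_covers_ramp_hold_and_margin(self, protocol):
        params = SimuParams(seed=0)
        trace = simulate_trace(params, protocol)
        assert trace.duration_s == pytest.approx(params.ramp_s + protocol.hold_s + 1.0)

    def test_hold_window_spectrum_peaks_at_tremor_frequency(self, protocol):
        params = SimuParams(tremor_freq_hz=6.0, tremor_amp_gf=20, noise_sd_gf=0,
                            amp_mod_depth=0, seed=1)
        window = preprocess_trace(simulate_trace(params, protocol), protocol)
        psd = power_spectral_density(window)
        assert dominant_frequency(psd) == pytest.approx(6.0)

    def test_same_seed_gives_identical_samples(self, protocol):
        params = SimuParams(tremor_amp_gf=10, noise_sd_gf=2, tap_dropout_prob=0.3, seed=42)
        a = simulate_trace(params, protocol)
        b = simulate_trace(params, protocol)
        assert np.array_equal(a.samples, b.samples)

    def test_different_seeds_differ(self, protocol):
        from dataclasses import replace

        params = SimuParams(noise_sd_gf=2, seed=1)
        a = simulate_trace(params, protocol)
        b = simulate_trace(replace(params, seed=2), protocol)
        assert not np.array_equal(a.samples, b.samples)

    def test_dropouts_clamp_force_to_zero(self, protocol):
        params = SimuParams(tap_dropout_prob=1.0, noise_sd_gf=0, tremor_amp_gf=0, seed=3)
        trace = simulate_trace(params, protocol)
        assert np.sum(trace.samples == 0.0) >= 4  # at least one 0.1 s dropout

    @pytest.mark.parametrize(
        "bad",
        [
            dict(tremor_freq_hz=0.0),
            dict(tremor_amp_gf=-1.0),
            dict(amp_mod_depth=1.5),
            dict(tap_dropout_prob=-0.1),
            dict(ramp_s=0.0),
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            SimuParams(**bad)

    @pytest.mark.parametrize("freq", [4.0, 6.0, 7.0])
    def test_energy_concentrates_at_tremor_frequency(self, protocol, freq):
        """Noise- and modulation-free tremor at a window-resolvable frequency
        puts >= 99% of band-passed hold-window power within +/-0.35 Hz."""
        params = SimuParams(tremor_freq_hz=freq, tremor_amp_gf=20, noise_sd_gf=0,
                            amp_mod_depth=0, seed=5)
        window = preprocess_trace(simulate_trace(params, protocol), protocol)
        psd = power_spectral_density(window)
        near = np.abs(psd.freqs_hz - freq) <= 0.35
        assert psd.values[near].sum() / psd.values.sum() >= 0.99


class TestCohort:
    def test_default_design_yields_490_measurements(self):
        traces = simulate_cohort(default_cohort_design(), seed=0)
        assert len(traces) == 490

    def test_default_design_session_count(self):
        assert default_cohort_design().n_sessions == 49

    def test_single_subject_single_session_yields_10_traces(self):
        design = CohortDesign(subjects=[("S1", "pd", 2, 1)])
        assert len(simulate_cohort(design, seed=0)) == 10

    def test_cohort_is_deterministic_per_seed(self):
        design = CohortDesign(subjects=[("H1", "healthy", 0, 1), ("P1", "pd", 3, 1)])
        a = simulate_cohort(design, seed=11)
        b = simulate_cohort(design, seed=11)
        assert [t.label for t in a] == [t.label for t in b]
        assert all(np.array_equal(x.samples, y.samples) for x, y in zip(a, b))

    def test_labels_follow_group(self):
        design = CohortDesign(subjects=[("H1", "healthy", 0, 1), ("P1", "pd", 3, 1)])
        traces = simulate_cohort(design, seed=0)
        assert {t.label for t in traces if t.subject_id == "H1"} == {0}
        assert {t.label for t in traces if t.subject_id == "P1"} == {1}

    def test_missing_rating_entry_is_configuration_error(self):
        design = CohortDesign(subjects=[("P1", "pd", 4, 1)])
        with pytest.raises(KeyError, match="rating 4"):
            simulate_cohort(design, pd_params_by_ftmtrs={3: SimuParams()}, seed=0)

    def test_pd_amplitude_monotone_in_rating(self):
        params = default_pd_params_by_ftmtrs()
        amps = [params[r].tremor_amp_gf for r in sorted(params)]
        assert amps == sorted(amps)

    def test_healthy_tremor_above_analysis_band(self):
        assert default_healthy_params().tremor_freq_hz >= 8.0


class TestExcludeThumbs:
    def test_default_cohort_removes_98(self):
        traces = simulate_cohort(default_cohort_design(), seed=0)
        kept = exclude_thumbs(traces)
        assert len(traces) - len(kept) == 98
        assert len(kept) == 392

    def test_no_thumbs_unchanged(self):
        traces = simulate_cohort(CohortDesign(subjects=[("S1", "healthy", 0, 1)]), seed=0)
        kept = [t for t in traces if t.finger != "thumb"]
        assert exclude_thumbs(kept) == kept

    def test_single_session_keeps_8(self):
        traces = simulate_cohort(CohortDesign(subjects=[("S1", "healthy", 0, 1)]), seed=0)
        assert len(exclude_thumbs(traces)) == 8

    def test_removes_two_per_session(self):
        design = CohortDesign(subjects=[("S1", "pd", 1, 3)])
        traces = simulate_cohort(design, seed=0)
        assert len(traces) - len(exclude_thumbs(traces)) == 2 * design.n_sessions


class TestRig:
    def test_uniform_rotation_pulse_intervals(self):
        rig = RigParams(rev_per_s=7.0, velocity_fluct_beta=0.0,
                        encoder_counts_per_rev=1, noise_sd_gf=0.0)
        _, log = simulate_rig(rig)
        assert np.allclose(np.diff(log.pulse_times_s), 1 / 7, atol=1e-9)

    def test_gauge_dominant_frequency_matches_rotation(self):
        rig = RigParams(rev_per_s=3.0, velocity_fluct_beta=0.0, noise_sd_gf=0.0, seed=0)
        trace, _ = simulate_rig(rig)
        psd = power_spectral_density(
            HoldWindow(start_index=0, samples=trace.samples, rate_hz=trace.rate_hz)
        )
        f = dominant_frequency(psd, band=(psd.bin_hz, 20.0))
        assert abs(f - 3.0) <= psd.bin_hz

    def test_velocity_fluctuation_creates_harmonics(self):
        """A loaded motor (beta > 0) distorts the rotation, so the gauge
        spectrum gains harmonics above the fundamental."""
        rig = RigParams(rev_per_s=1.5, velocity_fluct_beta=0.5, noise_sd_gf=0.0,
                        duration_s=10.0, seed=0)
        trace, _ = simulate_rig(rig)
        psd = power_spectral_density(
            HoldWindow(start_index=0, samples=trace.samples, rate_hz=trace.rate_hz)
        )
        fund = 1.5
        harmonic_band = (psd.freqs_hz > fund * 1.5) & (psd.freqs_hz < 20.0)
        fund_band = np.abs(psd.freqs_hz - fund) <= psd.bin_hz
        assert psd.values[harmonic_band].sum() > 0.01 * psd.values[fund_band].sum()

    def test_encoder_rig_frequency_agreement(self):
        """beta=0: encoder and gauge-spectrum estimates agree to one PSD bin."""
        for rev in (3.0, 5.0, 7.5):
            rig = RigParams(rev_per_s=rev, velocity_fluct_beta=0.0, noise_sd_gf=1.0, seed=2)
            trace, log = simulate_rig(rig)
            psd = power_spectral_density(
                HoldWindow(start_index=0, samples=trace.samples, rate_hz=trace.rate_hz)
            )
            f_gauge = dominant_frequency(psd, band=(psd.bin_hz, 20.0))
            assert abs(encoder_frequency(log) - f_gauge) <= psd.bin_hz

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            RigParams(rev_per_s=20.0)

    def test_non_integer_sample_count_rejected(self):
        with pytest.raises(ValueError, match="integer sample count"):
            RigParams(duration_s=3.014)


class TestEncoderFrequency:
    def test_three_pulses_over_one_second(self):
        log = EncoderLog(pulse_times_s=[0.0, 0.5, 1.0], counts_per_rev=1)
        assert encoder_frequency(log) == pytest.approx(2.0)

    def test_uniform_seven_rev_per_s(self):
        log = EncoderLog(pulse_times_s=np.arange(22) / 7, counts_per_rev=1)
        assert encoder_frequency(log) == pytest.approx(7.0)

    def test_jittered_pulses_within_jitter_bound(self):
        rng = np.random.default_rng(0)
        clean = np.arange(30) / 5.0
        jitter = rng.uniform(-0.01, 0.01, size=30)
        times = np.sort(clean + jitter)
        # brute-force bound: elapsed time perturbed by at most 2*max jitter
        est = encoder_frequency(EncoderLog(pulse_times_s=times, counts_per_rev=1))
        elapsed = clean[-1] - clean[0]
        worst = 29 / (elapsed - 0.02)
        best = 29 / (elapsed + 0.02)
        assert best <= est <= worst

    def test_fewer_than_two_pulses_is_error(self):
        with pytest.raises(ValueError, match="2 encoder pulses"):
            encoder_frequency(EncoderLog(pulse_times_s=[0.1], counts_per_rev=1))
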