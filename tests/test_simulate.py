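"""Simulator unit and property tests: beat timing, waveform morphology,
PTT ground truth, noise injection and session profiles."""

import numpy as np
import pytest

import pttkit as pk
from pttkit.errors import ParameterError, TimelineError


class TestBeatTimes:
    def test_zero_jitter_exact_grid(self):
        tl = pk.generate_beat_times(60, 60, rr_jitter_sd=0.0)
        assert tl.n_beats == 60
        assert np.allclose(np.diff(tl.beat_times), 1.0)

    def test_rr_arithmetic_75bpm(self):
        tl = pk.generate_beat_times(120, 75, rr_jitter_sd=0.0)
        assert tl.n_beats == 150
        assert np.allclose(np.diff(tl.beat_times), 0.8)

    def test_jittered_mean_rr_close_to_nominal(self):
        tl = pk.generate_beat_times(600, 70, rr_jitter_sd=0.02, seed=1)
        assert abs(tl.rr_intervals.mean() - 60 / 70) / (60 / 70) < 0.01

    def test_deterministic_given_seed(self):
        a = pk.generate_beat_times(120, 80, rr_jitter_sd=0.05, seed=7)
        b = pk.generate_beat_times(120, 80, rr_jitter_sd=0.05, seed=7)
        assert np.array_equal(a.beat_times, b.beat_times)

    def test_refractory_floor_respected(self):
        tl = pk.generate_beat_times(120, 220, rr_jitter_sd=0.2, seed=2)
        assert np.all(np.diff(tl.beat_times) >= 0.3 - 1e-12)

    @pytest.mark.parametrize("kwargs", [
        {"duration": 0, "mean_hr": 60},
        {"duration": -5, "mean_hr": 60},
        {"duration": 60, "mean_hr": 20},
        {"duration": 60, "mean_hr": 250},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            pk.generate_beat_times(**kwargs)


class TestECGSynthesis:
    def test_r_apex_on_beat_sample(self):
        tl = pk.CardiacTimeline(np.array([1.0]), 60, 0)
        ecg = pk.synthesize_ecg(tl, fs=1000)
        assert np.argmax(ecg) == 1000

    def test_peak_count_matches_beats(self):
        tl = pk.generate_beat_times(10, 60, 0.0)
        ecg = pk.synthesize_ecg(tl, fs=1000, duration=10)
        r_amp = ecg.max()
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(ecg, height=0.8 * r_amp)
        assert peaks.size == tl.n_beats == 10

    def test_empty_timeline_all_zero(self):
        tl = pk.CardiacTimeline(np.empty(0), 60, 0)
        ecg = pk.synthesize_ecg(tl, fs=1000, duration=2.0)
        assert ecg.shape == (2000,)
        assert np.all(ecg == 0)

    def test_overlapping_complexes_rejected_when_not_adaptive(self):
        tl = pk.generate_beat_times(10, 180, 0.0)
        morph = pk.ECGMorphology(rate_adaptive=False)
        with pytest.raises(TimelineError):
            pk.synthesize_ecg(tl, fs=1000, morphology=morph)

    def test_r_must_dominate(self):
        with pytest.raises(ParameterError):
            pk.ECGMorphology(t=(1.5, 0.3, 0.06))

    def test_low_fs_rejected(self):
        tl = pk.generate_beat_times(10, 60, 0.0)
        with pytest.raises(ParameterError):
            pk.synthesize_ecg(tl, fs=100)


class TestPTTGroundTruth:
    def test_no_events_constant(self):
        tl = pk.generate_beat_times(60, 60, 0.0)
        ptt = pk.ptt_ground_truth(tl, 0.25)
        assert np.all(ptt == 0.25)

    def test_onset_contributes_zero_at_start(self):
        ev = pk.VasoEvent(t_on=10, t_off=60, delta=-0.05, tau_on=30, tau_recovery=60)
        tl = pk.CardiacTimeline(np.array([10.0]), 60, 0)
        ptt = pk.ptt_ground_truth(tl, 0.25, [ev])
        assert ptt[0] == pytest.approx(0.25)

    def test_closed_form_one_tau_after_onset(self):
        ev = pk.VasoEvent(t_on=10, t_off=60, delta=-0.03, tau_on=30, tau_recovery=60)
        tl = pk.CardiacTimeline(np.array([40.0]), 60, 0)
        ptt = pk.ptt_ground_truth(tl, 0.25, [ev])
        assert ptt[0] == pytest.approx(0.25 - 0.03 * (1 - np.exp(-1)), abs=1e-12)

    def test_disjoint_events_superpose(self):
        e1 = pk.VasoEvent(t_on=10, t_off=50, delta=-0.02, tau_on=10, tau_recovery=10)
        e2 = pk.VasoEvent(t_on=200, t_off=250, delta=-0.04, tau_on=20, tau_recovery=20)
        tl = pk.generate_beat_times(300, 60, 0.0)
        both = pk.ptt_ground_truth(tl, 0.3, [e1, e2])
        only1 = pk.ptt_ground_truth(tl, 0.3, [e1])
        only2 = pk.ptt_ground_truth(tl, 0.3, [e2])
        assert np.allclose(both, only1 + only2 - 0.3, atol=1e-14)

    def test_nonpositive_ptt_rejected(self):
        ev = pk.VasoEvent(t_on=1, t_off=500, delta=-0.4, tau_on=5, tau_recovery=5)
        tl = pk.generate_beat_times(300, 60, 0.0)
        with pytest.raises(ParameterError):
            pk.ptt_ground_truth(tl, 0.3, [ev])

    def test_baseline_range_enforced(self):
        tl = pk.generate_beat_times(10, 60, 0.0)
        with pytest.raises(ParameterError):
            pk.ptt_ground_truth(tl, 0.7)


class TestPPGSynthesis:
    def test_inflection_lands_on_beat_plus_ptt(self):
        tl = pk.CardiacTimeline(np.array([0.0]), 60, 0)
        ppg = pk.synthesize_ppg(tl, np.array([0.25]), fs=1000)
        assert abs(np.argmax(np.gradient(ppg)) - 250) <= 1

    def test_default_pulse_systolic_window(self):
        m = pk.PPGMorphology()
        assert 0.10 <= m.systolic_peak_delay <= 0.15

    def test_default_pulse_dicrotic_window(self):
        assert 0.35 <= pk.PPGMorphology().dicrotic_delay <= 0.45

    def test_mismatched_lengths_rejected(self):
        tl = pk.generate_beat_times(10, 60, 0.0)
        with pytest.raises(ParameterError):
            pk.synthesize_ppg(tl, np.array([0.25]), fs=1000)

    def test_ground_truth_inflection_recoverable_numerically(self):
        """Each pulse's max-upslope sample sits within one sample period of
        beat_time + PTT on the clean superposed signal."""
        tl = pk.generate_beat_times(30, 75, 0.0)
        ptt = pk.ptt_ground_truth(tl, 0.22)
        fs = 1000.0
        ppg = pk.synthesize_ppg(tl, ptt, fs=fs, duration=31)
        d = np.gradient(ppg) * fs
        for bt, p in zip(tl.beat_times, ptt):
            lo, hi = int((bt + p - 0.05) * fs), int((bt + p + 0.05) * fs)
            k = lo + np.argmax(d[lo:hi])
            assert abs(k / fs - (bt + p)) <= 1.0 / fs


class TestNoise:
    def test_zero_spec_is_identity(self):
        x = np.sin(np.arange(5000) / 50)
        out = pk.add_noise(x, 1000, pk.NoiseSpec(), seed=1)
        assert np.array_equal(out, x)

    def test_mains_energy_at_50hz_bin(self):
        n = 10_000
        out = pk.add_noise(np.zeros(n), 1000, pk.NoiseSpec(mains_amplitude=1.0), seed=1)
        spec = np.abs(np.fft.rfft(out))
        freqs = np.fft.rfftfreq(n, 1 / 1000)
        assert freqs[np.argmax(spec)] == pytest.approx(50.0)
        assert spec[np.argmax(spec)] > 10 * np.median(spec)

    def test_white_noise_sd(self):
        out = pk.add_noise(np.zeros(100_000), 1000, pk.NoiseSpec(white_sd=0.1), seed=2)
        assert abs(out.std() - 0.1) / 0.1 < 0.05

    def test_deterministic_given_seed(self):
        spec = pk.NoiseSpec(white_sd=0.1, mains_amplitude=0.5, wander_amplitude=1.0,
                            artifact_rate=2.0, artifact_amplitude=3.0)
        a = pk.add_noise(np.zeros(20_000), 1000, spec, seed=9)
        b = pk.add_noise(np.zeros(20_000), 1000, spec, seed=9)
        assert np.array_equal(a, b)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ParameterError):
            pk.NoiseSpec(white_sd=-0.1)


class TestSessionProfile:
    def test_ts240_90_structure(self):
        prof = pk.generate_session_profile()
        o2 = [p for p in prof.phases if p.gas == "oxygen" and p.pressure_ata == 2.4]
        air_breaks = [p for p in prof.phases if p.gas == "air" and p.label.startswith("air-break")]
        assert len(o2) == 3 and all(p.duration_min == 30 for p in o2)
        assert len(air_breaks) == 2 and all(p.duration_min == 10 for p in air_breaks)

    def test_max_pressure(self):
        assert pk.generate_session_profile().max_pressure_ata == 2.4

    def test_oxygen_duty_fraction_exact(self):
        prof = pk.generate_session_profile()
        assert prof.oxygen_isopressure_minutes() == 90.0
        assert prof.oxygen_duty_fraction() == 90.0 / 1440.0

    def test_phases_contiguous_no_gaps(self):
        prof = pk.generate_session_profile(compression_min=12, decompression_min=18)
        total = sum(p.duration_min for p in prof.phases)
        assert total == pytest.approx(prof.total_minutes)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ParameterError):
            pk.generate_session_profile("TS300-120")


class TestNicotineTimeline:
    def test_protocol_phases(self):
        tl = pk.nicotine_trial_timeline()
        assert tl[-1][2] == 1200.0
        assert tl[1] == ("intake", 300.0, 600.0)
        assert all(a[2] == b[1] for a, b in zip(tl, tl[1:]))


class TestSimulateRecording:
    def test_bit_reproducible(self):
        a, _ = pk.simulate_recording(duration=20, seed=5)
        b, _ = pk.simulate_recording(duration=20, seed=5)
        assert a == b

    def test_truth_lengths_consistent(self, clean_recording):
        rec, truth = clean_recording
        assert truth.beat_times.size == truth.ptt.size
        assert rec.n_frames == 300_000
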