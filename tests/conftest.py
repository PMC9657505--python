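import numpy as np
import pytest

import pttkit as pk
from pttkit.simulate import COUNTS_PER_UNIT


@pytest.fixture(scope="session")
def clean_recording():
    """5 min clean simulated recording with mild RR jitter."""
    rec, truth = pk.simulate_recording(
        duration=300.0, mean_hr=70.0, rr_jitter_sd=0.03,
        baseline_ptt=0.25, seed=3,
    )
    return rec, truth


@pytest.fixture(scope="session")
def noisy_recording():
    """Same conditions plus moderate noise: white SD 5% of pulse amplitude,
    mains interference and baseline wander."""
    noise = pk.NoiseSpec(
        white_sd=0.05, mains_amplitude=0.2, wander_amplitude=0.5, wander_freq=0.2
    )
    rec, truth = pk.simulate_recording(
        duration=300.0, mean_hr=70.0, rr_jitter_sd=0.03,
        baseline_ptt=0.25, seed=4, ecg_noise=noise, ppg_noise=noise,
    )
    return rec, truth


def conditioned(rec):
    """Default-filtered float ECG and green-PPG channels."""
    fs = rec.sample_rate
    ecg = pk.apply_filters(rec.ecg / COUNTS_PER_UNIT, fs, pk.ECG_FILTERS)
    ppg = pk.apply_filters(rec.ppg_green / COUNTS_PER_UNIT, fs, pk.PPG_FILTERS)
    return ecg, ppg


def ptt_errors_ms(rec, truth):
    """Per-beat |PTT - ground truth| (ms) for the full pipeline."""
    fs = rec.sample_rate
    ecg, ppg = conditioned(rec)
    ann = pk.detect_r_peaks(ecg, fs)
    fids = pk.detect_ppg_fiducials(ppg, fs, search_guides=ann.r_times)
    series = pk.pair_beats(ann.r_times, np.array([f.inflection_s for f in fids]))
    errs = []
    for t, p in zip(series.beat_time, series.ptt):
        i = int(np.argmin(np.abs(truth.beat_times - t)))
        if abs(truth.beat_times[i] - t) < 0.05:
            errs.append(abs(p - truth.ptt[i]))
    return np.asarray(errs) * 1000.0, series
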