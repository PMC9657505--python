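"""R-peak and PPG fiducial-point detection plus HR/HRV derivation.

The QRS detector follows the classic Pan–Tompkins recipe: band-pass
emphasis of the QRS energy (5–15 Hz), differentiation, squaring, 150 ms
moving-window integration, then an adaptive dual-threshold decision stage
with a refractory period and a search-back pass for missed beats.  Every
accepted detection is refined to the local maximum of the conditioned ECG
so the reported time is the R apex itself, not the integrator peak.

PPG fiducials per pulse: systolic peak, pulse onset (foot), the upstroke
inflection point (maximum first derivative — the standard PTT fiducial,
refined to sub-sample precision by parabolic interpolation), and, when
resolvable, the dicrotic wave.  All decisions are relative to local signal
amplitude, which makes the detectors invariant to positive rescaling and
equivariant under time shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import AnalysisError, ParameterError
from .preprocess import _filtfilt

__all__ = [
    "BeatAnnotation",
    "PulseFiducials",
    "HRVSummary",
    "detect_r_peaks",
    "heart_rate_series",
    "hrv_metrics",
    "detect_ppg_fiducials",
]

# physiologic RR gate applied before HR/HRV statistics (s)
RR_GATE = (0.3, 3.0)


@dataclass(frozen=True)
class BeatAnnotation:
    """Detected R-peak times (s) and the derived R-to-R intervals."""

    r_times: np.ndarray

    def __post_init__(self):
        rt = np.asarray(self.r_times, dtype=float)
        object.__setattr__(self, "r_times", rt)
        if rt.size > 1 and not np.all(np.diff(rt) > 0):
            raise ParameterError("R-peak times must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.r_times.size)

    @property
    def rr_intervals(self) -> np.ndarray:
        return np.diff(self.r_times)

    def gated_rr(self) -> np.ndarray:
        """RR intervals within the physiologic [0.3, 3.0] s window."""
        rr = self.rr_intervals
        return rr[(rr >= RR_GATE[0]) & (rr <= RR_GATE[1])]


@dataclass(frozen=True)
class PulseFiducials:
    """Fiducial times (s) of one PPG pulse; dicrotic may be unresolvable."""

    onset_s: float
    inflection_s: float
    peak_s: float
    dicrotic_s: float | None = None

    def __post_init__(self):
        if not self.onset_s < self.inflection_s < self.peak_s:
            raise ParameterError("fiducial ordering onset < inflection < peak violated")
        if self.dicrotic_s is not None and self.dicrotic_s <= self.peak_s:
            raise ParameterError("dicrotic wave must follow the systolic peak")


@dataclass(frozen=True)
class HRVSummary:
    mean_hr: float  # BPM
    sdnn: float     # ms
    rmssd: float    # ms
    n_beats: int


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample apex position (in samples) of a discrete local maximum."""
    if not 0 < i < y.size - 1:
        return float(i)
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(i)
    return float(i + 0.5 * (y0 - y2) / denom)


def detect_r_peaks(
    ecg: np.ndarray,
    fs: float,
    refractory_s: float = 0.2,
) -> BeatAnnotation:
    """Pan–Tompkins-style R-peak detection on a conditioned (detrended) ECG.

    A flat signal yields zero beats; signals shorter than one second are
    rejected as too short to carry a detectable beat plus thresholds.
    """
    if fs < 250:
        raise ParameterError(f"R-peak detection requires fs >= 250 Hz, got {fs}")
    x = np.asarray(ecg, dtype=float)
    if x.size < fs:
        raise ParameterError("signal shorter than 1 s; cannot detect beats")
    if np.ptp(x) == 0:
        return BeatAnnotation(np.empty(0))

    # 1) band-pass emphasis of QRS energy
    b, a = sps.butter(2, [5.0, 15.0], btype="band", fs=fs)
    bp = _filtfilt(b, a, x, fs, 5.0)
    # 2) derivative, 3) squaring, 4) moving-window integration (150 ms)
    feat = np.gradient(bp) ** 2
    win = max(int(0.150 * fs), 1)
    mwi = np.convolve(feat, np.ones(win) / win, mode="same")

    dist = max(int(refractory_s * fs), 1)
    cand, _ = sps.find_peaks(mwi, distance=dist)
    if cand.size == 0:
        return BeatAnnotation(np.empty(0))

    # 5) adaptive dual thresholds (running signal/noise peak estimates)
    head = mwi[: int(min(2 * fs, mwi.size))]
    spki = 0.25 * float(head.max())
    npki = 0.5 * float(head.mean())
    accepted = []
    for p in cand:
        thr1 = npki + 0.25 * (spki - npki)
        if mwi[p] > thr1:
            accepted.append(p)
            spki = 0.125 * mwi[p] + 0.875 * spki
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki

    # 6) search-back: re-examine long gaps with the lower threshold
    if len(accepted) >= 2:
        rr_med = np.median(np.diff(accepted)) / fs
        thr2 = 0.5 * (npki + 0.25 * (spki - npki))
        filled = list(accepted)
        for a_i, b_i in zip(accepted, accepted[1:]):
            if (b_i - a_i) / fs > 1.66 * rr_med:
                gap = cand[(cand > a_i + dist) & (cand < b_i - dist)]
                for g in gap:
                    if mwi[g] > thr2:
                        filled.append(g)
        accepted = sorted(filled)

    # refine each detection to the R apex on the conditioned ECG (+-50 ms)
    half = int(0.050 * fs)
    times = []
    for p in accepted:
        i0, i1 = max(0, p - half), min(x.size, p + half + 1)
        k = i0 + int(np.argmax(x[i0:i1]))
        times.append(_parabolic_refine(x, k) / fs)
    times = np.array(sorted(set(times)))

    # enforce the refractory period on refined times (keep the taller peak)
    keep = []
    for t in times:
        if keep and t - keep[-1] < refractory_s:
            prev = keep[-1]
            if x[int(round(t * fs))] > x[int(round(prev * fs))]:
                keep[-1] = t
        else:
            keep.append(t)
    return BeatAnnotation(np.array(keep))


def heart_rate_series(
    annotation: BeatAnnotation,
    window_s: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window heart rate, emitted once per second.

    Each output point at time ``t`` is 60 / mean(RR) over intervals whose
    midpoint lies in ``[t - window_s, t]`` (matching a device that reports
    an updated rate every second).
    """
    if annotation.n_beats < 2:
        raise AnalysisError("heart-rate series needs at least 2 beats")
    rr = annotation.rr_intervals
    mid = annotation.r_times[:-1] + rr / 2
    t_grid = np.arange(np.ceil(annotation.r_times[0]), annotation.r_times[-1] + 0.5, 1.0)
    times, bpm = [], []
    for t in t_grid:
        sel = rr[(mid >= t - window_s) & (mid <= t)]
        sel = sel[(sel >= RR_GATE[0]) & (sel <= RR_GATE[1])]
        if sel.size:
            times.append(t)
            bpm.append(60.0 / sel.mean())
    return np.array(times), np.array(bpm)


def hrv_metrics(annotation: BeatAnnotation) -> HRVSummary:
    """Time-domain HRV summary: SDNN and RMSSD in milliseconds.

    RR intervals outside the physiologic [0.3, 3.0] s window are excluded
    before computing the statistics.
    """
    if annotation.n_beats < 3:
        raise AnalysisError("HRV metrics need at least 3 beats")
    rr = annotation.gated_rr()
    if rr.size < 2:
        raise AnalysisError("fewer than 2 physiologic RR intervals")
    sdnn = float(np.std(rr, ddof=1) * 1000.0)
    rmssd = float(np.sqrt(np.mean(np.diff(rr) ** 2)) * 1000.0) if rr.size > 1 else 0.0
    return HRVSummary(
        mean_hr=float(60.0 / rr.mean()),
        sdnn=sdnn,
        rmssd=rmssd,
        n_beats=annotation.n_beats,
    )


def _pulse_onset(x: np.ndarray, fs: float, peak: int, foot_frac: float = 0.01) -> float | None:
    """Pulse foot: last crossing of 1% relative amplitude before the peak.

    The minimum within 0.35 s before the peak anchors the baseline; the
    onset is where the signal last rises through
    ``min + foot_frac * (peak - min)``, refined by linear interpolation.
    """
    w0 = max(0, peak - int(0.35 * fs))
    if peak - w0 < 2:
        return None
    seg = x[w0:peak]
    vmin = seg.min()
    thresh = vmin + foot_frac * (x[peak] - vmin)
    below = np.flatnonzero(seg <= thresh)
    if below.size == 0:
        return None
    i = w0 + below[-1]
    if i + 1 >= x.size or x[i + 1] == x[i]:
        return i / fs
    frac = (thresh - x[i]) / (x[i + 1] - x[i])
    return (i + np.clip(frac, 0.0, 1.0)) / fs


def detect_ppg_fiducials(
    ppg: np.ndarray,
    fs: float,
    search_guides: np.ndarray | None = None,
    min_pulse_gap_s: float = 0.3,
    dicrotic_window_s: float = 0.5,
) -> list[PulseFiducials]:
    """Locate onset, inflection, systolic peak and dicrotic wave per pulse.

    ``search_guides`` (e.g. detected R-peak times) optionally restricts
    systolic-peak candidates to within one second after a guide.  Pulses
    whose fiducials cannot be resolved are skipped, never fabricated.
    """
    if fs < 100:
        raise ParameterError(f"PPG fiducial detection requires fs >= 100 Hz, got {fs}")
    x = np.asarray(ppg, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return []

    lo, hi = np.percentile(x, [1, 99])
    prominence = 0.25 * (hi - lo) if hi > lo else None
    peaks, _ = sps.find_peaks(x, distance=max(int(min_pulse_gap_s * fs), 1),
                              prominence=prominence)
    if search_guides is not None and len(search_guides):
        guides = np.asarray(search_guides, dtype=float)
        pt = peaks / fs
        lag = pt[:, None] - guides[None, :]
        ok = ((lag > 0) & (lag <= 1.0)).any(axis=1)
        peaks = peaks[ok]

    deriv = np.gradient(x) * fs
    out = []
    for p in peaks:
        onset = _pulse_onset(x, fs, p)
        if onset is None:
            continue
        o_idx = int(np.ceil(onset * fs))
        if p - o_idx < 2:
            continue
        im = o_idx + int(np.argmax(deriv[o_idx:p]))
        inflection = _parabolic_refine(deriv, im) / fs
        peak_t = _parabolic_refine(x, p) / fs
        if not onset < inflection < peak_t:
            continue

        dicrotic = None
        d1 = min(x.size, p + int(dicrotic_window_s * fs) + 1)
        if d1 - p > 3:
            seg = x[p + 1: d1]
            cand, props = sps.find_peaks(seg, prominence=0.0)
            if cand.size:
                best = cand[int(np.argmax(props["prominences"]))]
                dic_i = p + 1 + best
                dicrotic = _parabolic_refine(x, dic_i) / fs
                if dicrotic <= peak_t:
                    dicrotic = None
        out.append(PulseFiducials(onset, inflection, peak_t, dicrotic))
    return out
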