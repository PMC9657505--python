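"""Synthetic synchronized ECG/PPG generation with known ground truth.

Every downstream stage of the toolkit (binary storage, filtering, fiducial
detection, PTT pairing, intervention fitting) is tested against recordings
produced here, because for simulated data the beat times, per-beat pulse
transit times and every noise component are known exactly.

The ECG is a per-beat sum-of-Gaussians PQRST template; the PPG pulse is a
two-lobe (systolic + dicrotic) Gaussian waveform whose default morphology
reproduces the classic pulse-wave timing windows: systolic peak 0.10-0.15 s
after pulse onset and dicrotic wave 0.35-0.45 s after the start of the
initial wave.  Vasoconstriction episodes are modelled as saturating
exponential onsets with exponential recovery, applied to per-beat PTT
(and optionally to RR intervals, since heart rate reacts to the same
stimuli).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, TimelineError

__all__ = [
    "VasoEvent",
    "CardiacTimeline",
    "NoiseSpec",
    "SessionPhase",
    "SessionProfile",
    "ECGMorphology",
    "PPGMorphology",
    "generate_beat_times",
    "synthesize_ecg",
    "ptt_ground_truth",
    "synthesize_ppg",
    "add_noise",
    "generate_session_profile",
    "nicotine_trial_timeline",
    "SimulationTruth",
    "simulate_recording",
]

# Physiological refractory floor on RR intervals (s): no two beats closer.
RR_FLOOR_S = 0.3


@dataclass(frozen=True)
class VasoEvent:
    """One vasoconstriction (or vasodilation) episode.

    The perturbation ramps in as ``delta * (1 - exp(-(t - t_on)/tau_on))``
    for ``t_on <= t <= t_off`` and relaxes back to zero with time constant
    ``tau_recovery`` afterwards.  ``delta`` is negative for a PTT drop
    (vasoconstriction shortens the transit time).
    """

    t_on: float
    t_off: float
    delta: float
    tau_on: float
    tau_recovery: float

    def __post_init__(self):
        if not self.t_on < self.t_off:
            raise ParameterError(f"event requires t_on < t_off, got {self.t_on} >= {self.t_off}")
        if self.tau_on <= 0 or self.tau_recovery <= 0:
            raise ParameterError("event time constants must be positive")

    def response(self, t: np.ndarray) -> np.ndarray:
        """Perturbation contributed by this event at times ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        during = (t >= self.t_on) & (t <= self.t_off)
        out[during] = self.delta * (1.0 - np.exp(-(t[during] - self.t_on) / self.tau_on))
        after = t > self.t_off
        level = self.delta * (1.0 - np.exp(-(self.t_off - self.t_on) / self.tau_on))
        out[after] = level * np.exp(-(t[after] - self.t_off) / self.tau_recovery)
        return out


def _total_response(t: np.ndarray, events) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for ev in events:
        out += ev.response(t)
    return out


@dataclass(frozen=True)
class CardiacTimeline:
    """Ground-truth beat times of a simulated recording."""

    beat_times: np.ndarray  # s from recording start, strictly increasing
    mean_hr: float          # configured mean heart rate, BPM
    rr_jitter_sd: float     # configured RR jitter SD, s

    def __post_init__(self):
        bt = np.asarray(self.beat_times, dtype=float)
        object.__setattr__(self, "beat_times", bt)
        if bt.size > 1 and not np.all(np.diff(bt) > 0):
            raise ParameterError("beat times must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)

    @property
    def rr_intervals(self) -> np.ndarray:
        return np.diff(self.beat_times)


def generate_beat_times(
    duration: float,
    mean_hr: float,
    rr_jitter_sd: float = 0.0,
    rr_events=(),
    seed: int = 0,
) -> CardiacTimeline:
    """Draw a beat-time sequence for ``duration`` seconds.

    RR intervals are ``60/mean_hr`` plus i.i.d. Gaussian jitter plus the
    summed perturbation of any ``rr_events`` (evaluated at the current beat
    time), clipped to the 0.3 s physiological floor.  The first beat is
    placed half a nominal RR interval after t=0 so that a jitter-free
    minute at 60 BPM contains exactly 60 beats.

    Deterministic for a fixed ``seed``.
    """
    if duration <= 0:
        raise ParameterError(f"duration must be positive, got {duration}")
    if not 30.0 <= mean_hr <= 220.0:
        raise ParameterError(f"mean_hr must be within [30, 220] BPM, got {mean_hr}")
    if rr_jitter_sd < 0:
        raise ParameterError("rr_jitter_sd must be non-negative")

    rng = np.random.default_rng(seed)
    rr_base = 60.0 / mean_hr
    beats = []
    t = 0.5 * rr_base
    while t < duration:
        beats.append(t)
        rr = rr_base
        if rr_jitter_sd > 0:
            rr += rng.normal(0.0, rr_jitter_sd)
        if rr_events:
            rr += float(_total_response(np.array([t]), rr_events)[0])
        t += max(rr, RR_FLOOR_S)
    return CardiacTimeline(np.asarray(beats), mean_hr=mean_hr, rr_jitter_sd=rr_jitter_sd)


# ---------------------------------------------------------------------------
# ECG synthesis


@dataclass(frozen=True)
class ECGMorphology:
    """Sum-of-Gaussians PQRST template.

    Each lobe is ``(amplitude, center_s, sigma_s)`` with centers relative to
    the R peak.  The R lobe amplitude must strictly dominate every other
    lobe so that R-peak detection is unambiguous.  When ``rate_adaptive``
    is true the non-R lobe centers and widths are compressed in proportion
    to the local RR interval (relative to a nominal 0.8 s cycle), mimicking
    the physiological shortening of the PQ/QT segments at high heart rate
    and keeping adjacent complexes from overlapping down to the 0.3 s RR
    floor.
    """

    p: tuple = (0.12, -0.22, 0.025)
    q: tuple = (-0.10, -0.035, 0.010)
    r: tuple = (1.0, 0.0, 0.012)
    s: tuple = (-0.12, 0.045, 0.014)
    t: tuple = (0.30, 0.30, 0.060)
    rate_adaptive: bool = True

    def __post_init__(self):
        amps = {k: abs(getattr(self, k)[0]) for k in ("p", "q", "r", "s", "t")}
        if self.r[0] <= 0 or any(amps[k] >= amps["r"] for k in ("p", "q", "s", "t")):
            raise ParameterError("R lobe amplitude must strictly dominate all other lobes")

    @property
    def lobes(self):
        return (self.p, self.q, self.r, self.s, self.t)

    def support(self, scale: float = 1.0) -> tuple[float, float]:
        """(left, right) extent in s beyond which the template is negligible."""
        left = min((c - 4 * s) * scale for _, c, s in self.lobes)
        right = max((c + 4 * s) * scale for _, c, s in self.lobes)
        return left, right


def _template_eval(morph: ECGMorphology, t: np.ndarray, scale: float = 1.0) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    for i, (a, c, s) in enumerate(morph.lobes):
        if i != 2:  # R lobe keeps its own timing and width
            c, s = c * scale, s * scale
        out += a * np.exp(-((t - c) ** 2) / (2 * s * s))
    return out


def _r_apex_offset(morph: ECGMorphology) -> float:
    """Offset of the template's true maximum from the nominal R center.

    The Q/S/T neighbours pull the summed maximum a few microseconds off the
    R lobe center; the synthesizer subtracts this so the rendered maximum
    lands exactly on each beat time.
    """
    grid = np.linspace(-0.01, 0.01, 40001)
    dt = grid[1] - grid[0]
    vals = _template_eval(morph, grid)
    i = int(np.argmax(vals))
    if 0 < i < grid.size - 1:  # parabolic apex refinement
        y0, y1, y2 = vals[i - 1], vals[i], vals[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            return float(grid[i] + 0.5 * (y0 - y2) / denom * dt)
    return float(grid[i])


def synthesize_ecg(
    timeline: CardiacTimeline,
    fs: float = 1000.0,
    morphology: ECGMorphology | None = None,
    duration: float | None = None,
) -> np.ndarray:
    """Render the ECG sample array for a timeline.

    One PQRST complex is placed per beat with the template's R maximum on
    the beat time.  Output length is ``round(duration * fs)``; when
    ``duration`` is omitted it extends 0.6 s past the last beat.
    """
    if fs < 250:
        raise ParameterError(f"ECG synthesis requires fs >= 250 Hz, got {fs}")
    morph = morphology or ECGMorphology()
    bt = timeline.beat_times
    if duration is None:
        duration = float(bt[-1]) + 0.6 if bt.size else 0.0
    n = int(round(duration * fs))
    out = np.zeros(n)
    if bt.size == 0:
        return out

    apex = _r_apex_offset(morph)
    rr = np.diff(bt)
    # local cycle length per beat: min of the two adjacent RR intervals
    local = np.empty(bt.size)
    local[:] = 0.8
    if rr.size:
        local[0] = rr[0]
        local[-1] = rr[-1]
        if rr.size > 1:
            local[1:-1] = np.minimum(rr[:-1], rr[1:])

    for i, beat in enumerate(bt):
        scale = min(local[i] / 0.8, 1.0) if morph.rate_adaptive else 1.0
        left, right = morph.support(scale)
        if rr.size and not morph.rate_adaptive:
            prev_gap = rr[i - 1] if i > 0 else np.inf
            next_gap = rr[i] if i < rr.size else np.inf
            if right - left > min(prev_gap, next_gap):
                raise TimelineError(
                    f"RR interval {min(prev_gap, next_gap):.3f} s shorter than the "
                    f"template support {right - left:.3f} s around beat {i}"
                )
        i0 = max(0, int(np.floor((beat + left) * fs)))
        i1 = min(n, int(np.ceil((beat + right) * fs)) + 1)
        if i0 >= i1:
            continue
        t_local = np.arange(i0, i1) / fs - (beat - apex)
        out[i0:i1] += _template_eval(morph, t_local, scale)
    return out


# ---------------------------------------------------------------------------
# PTT ground truth and PPG synthesis


def ptt_ground_truth(
    timeline: CardiacTimeline,
    baseline_ptt: float,
    events=(),
) -> np.ndarray:
    """Per-beat pulse transit time: baseline plus summed event responses.

    All values must stay positive; events deep enough to drive PTT to zero
    are rejected.
    """
    if not 0.05 <= baseline_ptt <= 0.6:
        raise ParameterError(f"baseline_ptt must be within [0.05, 0.6] s, got {baseline_ptt}")
    ptt = baseline_ptt + _total_response(timeline.beat_times, events)
    if np.any(ptt <= 0):
        raise ParameterError("events produce non-positive PTT values")
    return ptt


@dataclass(frozen=True)
class PPGMorphology:
    """Two-lobe (systolic + dicrotic) Gaussian pulse template.

    ``onset_frac`` defines the pulse onset as the time where the rising
    edge first exceeds that fraction of the systolic peak amplitude.  The
    default geometry puts the systolic peak ~0.12 s after onset and the
    dicrotic peak ~0.40 s after onset, inside the canonical pulse-wave
    timing windows.
    """

    systolic_sigma: float = 0.040
    dicrotic_delay: float = 0.40   # onset -> dicrotic peak, s
    dicrotic_amp: float = 0.35     # relative to the systolic peak
    dicrotic_sigma: float = 0.055
    onset_frac: float = 0.01

    def __post_init__(self):
        if not 0 < self.onset_frac < 0.5:
            raise ParameterError("onset_frac must be in (0, 0.5)")
        if not 0 < self.dicrotic_amp < 1:
            raise ParameterError("dicrotic lobe must be smaller than the systolic lobe")
        if self.systolic_sigma <= 0 or self.dicrotic_sigma <= 0:
            raise ParameterError("lobe widths must be positive")

    @property
    def systolic_peak_delay(self) -> float:
        """Onset -> systolic peak delay implied by the onset threshold (s)."""
        return self.systolic_sigma * np.sqrt(-2.0 * np.log(self.onset_frac))

    def eval(self, u: np.ndarray) -> np.ndarray:
        """Template amplitude at time ``u`` after pulse onset."""
        u = np.asarray(u, dtype=float)
        c1 = self.systolic_peak_delay
        out = np.exp(-((u - c1) ** 2) / (2 * self.systolic_sigma**2))
        out += self.dicrotic_amp * np.exp(
            -((u - self.dicrotic_delay) ** 2) / (2 * self.dicrotic_sigma**2)
        )
        return out

    def inflection_delay(self, fs_refine: float = 100_000.0) -> float:
        """Onset -> maximum-upslope delay, located numerically (s)."""
        u = np.arange(0.0, self.systolic_peak_delay, 1.0 / fs_refine)
        d = np.gradient(self.eval(u), u)
        i = int(np.argmax(d))
        if 0 < i < u.size - 1:
            y0, y1, y2 = d[i - 1], d[i], d[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                return float(u[i] + 0.5 * (y0 - y2) / denom / fs_refine)
        return float(u[i])

    @property
    def support(self) -> float:
        """Pulse extent after onset beyond which the template is negligible."""
        return self.dicrotic_delay + 4 * self.dicrotic_sigma


def synthesize_ppg(
    timeline: CardiacTimeline,
    ptt: np.ndarray,
    fs: float = 1000.0,
    morphology: PPGMorphology | None = None,
    duration: float | None = None,
) -> np.ndarray:
    """Render the PPG sample array.

    Each beat contributes one pulse positioned so that its maximum-upslope
    (inflection) point falls exactly at ``beat_time + ptt``; overlapping
    pulses superpose additively.
    """
    morph = morphology or PPGMorphology()
    ptt = np.asarray(ptt, dtype=float)
    bt = timeline.beat_times
    if ptt.shape != bt.shape:
        raise ParameterError(
            f"ptt length {ptt.size} does not match timeline beat count {bt.size}"
        )
    if duration is None:
        duration = float(bt[-1] + ptt[-1]) + morph.support + 0.2 if bt.size else 0.0
    n = int(round(duration * fs))
    out = np.zeros(n)
    if bt.size == 0:
        return out

    u_inf = morph.inflection_delay()
    onsets = bt + ptt - u_inf
    for onset in onsets:
        i0 = max(0, int(np.floor(onset * fs)) - 1)
        i1 = min(n, int(np.ceil((onset + morph.support) * fs)) + 1)
        if i0 >= i1:
            continue
        u = np.arange(i0, i1) / fs - onset
        out[i0:i1] += morph.eval(u)
    return out


# ---------------------------------------------------------------------------
# Noise


@dataclass(frozen=True)
class NoiseSpec:
    """Additive disturbance model for one channel.

    Components: white Gaussian noise, mains interference at exactly 50 Hz,
    slow sinusoidal baseline wander, and Poisson-placed transient motion
    artifacts (Gaussian-windowed excursions of ~0.3 s width).  A zero spec
    is the identity.
    """

    white_sd: float = 0.0
    mains_amplitude: float = 0.0
    wander_amplitude: float = 0.0
    wander_freq: float = 0.25      # Hz, must stay below 0.5 Hz
    artifact_rate: float = 0.0     # events per minute
    artifact_amplitude: float = 0.0

    def __post_init__(self):
        for name in ("white_sd", "mains_amplitude", "wander_amplitude",
                     "artifact_rate", "artifact_amplitude"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not 0 < self.wander_freq < 0.5:
            raise ParameterError("wander_freq must be in (0, 0.5) Hz")

    @property
    def is_zero(self) -> bool:
        return (self.white_sd == 0 and self.mains_amplitude == 0
                and self.wander_amplitude == 0
                and (self.artifact_rate == 0 or self.artifact_amplitude == 0))


MAINS_HZ = 50.0
_ARTIFACT_SIGMA_S = 0.12


def add_noise(signal: np.ndarray, fs: float, spec: NoiseSpec, seed: int = 0) -> np.ndarray:
    """Return ``signal`` plus the disturbances described by ``spec``.

    Deterministic for a fixed seed; a zero spec returns an unchanged copy.
    """
    if fs <= 100:
        raise ParameterError(f"add_noise requires fs > 100 Hz, got {fs}")
    signal = np.asarray(signal, dtype=float)
    out = signal.copy()
    if spec.is_zero or signal.size == 0:
        return out

    rng = np.random.default_rng(seed)
    t = np.arange(signal.size) / fs
    if spec.white_sd > 0:
        out += rng.normal(0.0, spec.white_sd, signal.size)
    if spec.mains_amplitude > 0:
        out += spec.mains_amplitude * np.sin(2 * np.pi * MAINS_HZ * t + rng.uniform(0, 2 * np.pi))
    if spec.wander_amplitude > 0:
        out += spec.wander_amplitude * np.sin(
            2 * np.pi * spec.wander_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if spec.artifact_rate > 0 and spec.artifact_amplitude > 0:
        duration_min = signal.size / fs / 60.0
        n_art = rng.poisson(spec.artifact_rate * duration_min)
        for _ in range(n_art):
            t0 = rng.uniform(0, signal.size / fs)
            sign = rng.choice([-1.0, 1.0])
            i0 = max(0, int((t0 - 4 * _ARTIFACT_SIGMA_S) * fs))
            i1 = min(signal.size, int((t0 + 4 * _ARTIFACT_SIGMA_S) * fs))
            tw = np.arange(i0, i1) / fs
            out[i0:i1] += sign * spec.artifact_amplitude * np.exp(
                -((tw - t0) ** 2) / (2 * _ARTIFACT_SIGMA_S**2)
            )
    return out


# ---------------------------------------------------------------------------
# Therapy session profiles


@dataclass(frozen=True)
class SessionPhase:
    label: str
    start_min: float
    end_min: float
    pressure_ata: float  # chamber pressure at the end of the phase
    gas: str             # "air" or "oxygen"

    def __post_init__(self):
        if self.end_min <= self.start_min:
            raise ParameterError(f"phase '{self.label}' has non-positive duration")
        if self.pressure_ata < 1.0:
            raise ParameterError("pressure must be >= 1 ATA")
        if self.gas not in ("air", "oxygen"):
            raise ParameterError(f"unknown breathing gas '{self.gas}'")

    @property
    def duration_min(self) -> float:
        return self.end_min - self.start_min


@dataclass(frozen=True)
class SessionProfile:
    """Ordered, contiguous phases of one hyperbaric therapy session."""

    phases: tuple

    def __post_init__(self):
        phases = tuple(self.phases)
        object.__setattr__(self, "phases", phases)
        if not phases:
            raise ParameterError("profile needs at least one phase")
        for a, b in zip(phases, phases[1:]):
            if not np.isclose(a.end_min, b.start_min):
                raise ParameterError(
                    f"phases '{a.label}' and '{b.label}' are not contiguous"
                )

    @property
    def total_minutes(self) -> float:
        return self.phases[-1].end_min - self.phases[0].start_min

    @property
    def max_pressure_ata(self) -> float:
        return max(p.pressure_ata for p in self.phases)

    def phase_at(self, t_min: float) -> SessionPhase | None:
        for p in self.phases:
            if p.start_min <= t_min < p.end_min:
                return p
        return None

    def oxygen_isopressure_minutes(self) -> float:
        """Total time breathing pure oxygen at the full treatment pressure."""
        top = self.max_pressure_ata
        return sum(
            p.duration_min for p in self.phases
            if p.gas == "oxygen" and p.pressure_ata == top
        )

    def oxygen_duty_fraction(self, day_minutes: float = 1440.0) -> float:
        """Fraction of a day spent under hyperbaric oxygen at full pressure."""
        return self.oxygen_isopressure_minutes() / day_minutes


def generate_session_profile(
    scheme: str = "TS240-90",
    compression_min: float = 15.0,
    decompression_min: float = 15.0,
) -> SessionProfile:
    """Build the phase sequence of a named therapy scheme.

    ``TS240-90``: compression on air to 2.4 ATA, then three 30 min pure-
    oxygen periods at 2.4 ATA separated by two 10 min air breaks, then
    decompression back to 1 ATA with continued oxygen.  Total hyperbaric
    oxygen time at full pressure: 90 min.  Compression and decompression
    durations are configurable (they vary between chambers).
    """
    if scheme.replace("-", "").replace(" ", "").upper() != "TS24090":
        raise ParameterError(f"unknown therapy scheme '{scheme}'")
    if compression_min <= 0 or decompression_min <= 0:
        raise ParameterError("compression/decompression durations must be positive")
    t = 0.0
    phases = []

    def push(label, dur, pressure, gas):
        nonlocal t
        phases.append(SessionPhase(label, t, t + dur, pressure, gas))
        t += dur

    push("compression", compression_min, 2.4, "air")
    push("o2-1", 30.0, 2.4, "oxygen")
    push("air-break-1", 10.0, 2.4, "air")
    push("o2-2", 30.0, 2.4, "oxygen")
    push("air-break-2", 10.0, 2.4, "air")
    push("o2-3", 30.0, 2.4, "oxygen")
    push("decompression", decompression_min, 1.0, "oxygen")
    return SessionProfile(tuple(phases))


def nicotine_trial_timeline() -> list[tuple[str, float, float]]:
    """Phase labels of the nicotine provocation protocol (seconds).

    5 min rest, ~5 min of smoking three cigarettes in quick succession,
    10 min rest.
    """
    return [("rest", 0.0, 300.0), ("intake", 300.0, 600.0), ("rest", 600.0, 1200.0)]


# ---------------------------------------------------------------------------
# Full-recording convenience front end


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth emitted alongside a simulated recording."""

    beat_times: np.ndarray
    ptt: np.ndarray

    @property
    def rr_intervals(self) -> np.ndarray:
        return np.diff(self.beat_times)

    def to_frame(self):
        import pandas as pd

        rr = np.concatenate([[np.nan], self.rr_intervals])
        return pd.DataFrame(
            {"beat_time_s": self.beat_times, "rr_s": rr, "ptt_s": self.ptt}
        )


#: counts per signal unit used when quantizing float signals to 24-bit ADC
#: counts (pulse/R amplitudes of ~1 map to 1e5 counts, well inside +-2^23).
COUNTS_PER_UNIT = 100_000.0

# red and IR channels are scaled copies of the green PPG (no oximetry
# modelling), each with independently seeded noise
_RED_SCALE = 0.6
_IR_SCALE = 0.8


def simulate_recording(
    duration: float = 60.0,
    mean_hr: float = 70.0,
    rr_jitter_sd: float = 0.02,
    baseline_ptt: float = 0.25,
    ptt_events=(),
    rr_events=(),
    ecg_noise: NoiseSpec | None = None,
    ppg_noise: NoiseSpec | None = None,
    fs: float = 1000.0,
    seed: int = 0,
    device_id: str = "sim",
    events=(),
):
    """Simulate a full four-channel recording plus its ground truth.

    Returns ``(Recording, SimulationTruth)``.  All randomness flows from
    ``seed`` via deterministically spawned per-purpose substreams, so a
    fixed seed yields a bit-identical recording.
    """
    from .recordio import Recording

    ss = np.random.SeedSequence(seed)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]

    timeline = generate_beat_times(duration, mean_hr, rr_jitter_sd, rr_events, seed=sub[0])
    ptt = ptt_ground_truth(timeline, baseline_ptt, ptt_events)
    ecg = synthesize_ecg(timeline, fs=fs, duration=duration)
    green = synthesize_ppg(timeline, ptt, fs=fs, duration=duration)

    ecg_noise = ecg_noise or NoiseSpec()
    ppg_noise = ppg_noise or NoiseSpec()
    ecg_n = add_noise(ecg, fs, ecg_noise, seed=sub[1])
    green_n = add_noise(green, fs, ppg_noise, seed=sub[2])
    red_n = add_noise(green * _RED_SCALE, fs, ppg_noise, seed=sub[3])
    ir_n = add_noise(green * _IR_SCALE, fs, ppg_noise, seed=sub[4])

    def q(x):
        return np.round(x * COUNTS_PER_UNIT).astype(np.int32)

    rec = Recording(
        sample_rate=fs,
        ecg=q(ecg_n),
        ppg_green=q(green_n),
        ppg_red=q(red_n),
        ppg_ir=q(ir_n),
        events=tuple(events),
        device_id=device_id,
    )
    return rec, SimulationTruth(beat_times=timeline.beat_times, ptt=ptt)
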