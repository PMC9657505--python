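# Methods

`pttkit` models, stores and analyzes the signal chain of a wearable pulse-
transit-time (PTT) monitor: a synchronized 1 kHz four-channel recording
(one ECG lead plus green/red/infrared PPG), per-beat PTT measured from the
ECG R peak to the PPG upstroke inflection, heart rate and time-domain HRV,
and the fitting of vasoconstriction responses (nicotine, hyperbaric
oxygen) as exponential drop-and-recover transients. This note documents
the models, the defaults and why they hold, the numerical choices, and
what the synthetic data does and does not establish.

## Signal models

**Cardiac timeline.** Beats are generated sequentially: RR(i) =
60/HR + ε(i) + Σ events, with ε i.i.d. Gaussian (SD `rr_jitter_sd`,
default 0.02 s in the high-level simulator) and a hard floor of 0.3 s (the
physiological refractory limit). The first beat sits half a nominal RR
after t = 0, so a jitter-free minute at 60 BPM holds exactly 60 beats.
I.i.d. jitter is a deliberate simplification: it reproduces the SDNN a
detector must recover but has none of the autocorrelation (respiratory
sinus arrhythmia, Mayer waves) of real HRV. Tests built on it validate
detection and statistics, not HRV physiology.

**ECG.** One PQRST complex per beat as a sum of five Gaussians
(amplitude, center relative to R, width in seconds): P (0.12, −0.22,
0.025), Q (−0.10, −0.035, 0.010), R (1.0, 0, 0.012), S (−0.12, 0.045,
0.014), T (0.30, 0.30, 0.060). The R amplitude must strictly dominate, and
the summed template's true apex (pulled a few microseconds off center by
the Q/S/T neighbours) is located numerically on a dense grid and
subtracted, so the rendered maximum lands exactly on each beat time. At
short cycles the non-R lobe centers and widths compress proportionally to
local RR (relative to a nominal 0.8 s cycle), mimicking PQ/QT shortening;
with rate adaptation disabled, an RR shorter than the template support is
an error rather than a silent overlap.

**PPG.** Each pulse is two Gaussian lobes: a systolic lobe (unit
amplitude, σ = 40 ms) and a dicrotic lobe (relative amplitude 0.35,
σ = 55 ms) peaking 0.40 s after pulse onset. Pulse onset is defined as the
rising edge's crossing of 1% of the systolic peak; that convention fixes
the onset→systolic-peak delay at σ·√(−2 ln 0.01) ≈ 0.121 s. Both default
timings sit centrally inside the classic pulse-wave windows (systolic peak
0.10–0.15 s after onset; dicrotic wave 0.35–0.45 s after the initial
wave's start). The pulse is positioned so its maximum-upslope point —
located numerically on a 100 kHz grid with parabolic refinement — falls
exactly at beat time + PTT; overlapping pulses superpose additively. Red
and IR channels are scaled copies of green (0.6×, 0.8×) with independent
noise: no oximetry is modelled, they exist to exercise the four-channel
container.

**Vasoconstriction events.** A perturbation Δ·(1 − e^−(t−t_on)/τ_on)
between t_on and t_off, relaxing as an exponential with τ_recovery
afterwards; events sum linearly and the same structure applies to RR
intervals (heart-rate response). Δ < 0 is a PTT drop. Published relaxation
constants for nicotine-scale interventions are ambiguous in their units
(values quoted in ms against recoveries that visibly span minutes), so
the simulator treats τ as a free parameter; the nicotine-trial preset uses
τ_on = 40 s, τ_recovery = 60 s (PTT) and 90 s (RR) as plausible
minutes-scale dynamics, with a −30 ms PTT drop.

**Noise.** Additive white Gaussian noise, a 50 Hz mains sinusoid,
sinusoidal baseline wander (< 0.5 Hz) and Poisson-placed Gaussian-windowed
transients (σ = 0.12 s) standing in for motion artifacts. "Moderate noise"
throughout the tests means white SD = 5% of pulse amplitude plus mains
(0.2) and wander (0.5) interference. A zero spec is the identity. All
randomness in a simulated recording flows from one seed through
deterministically spawned substreams (timeline, then one per channel), so
recordings are bit-reproducible.

## Recording container

Frames are 12 bytes: four 24-bit little-endian two's-complement counts
(the native width of wearable analog front ends), at a shared sample rate
(default 1000 Hz). The header carries magic, version, sample rate, UTC
start time in integer milliseconds, a 16-byte device id, a reserved LED
time-slot metadata field (written as zero, preserved on read), and frame/
event counts. Event markers are (sample_index, code) pairs — tying markers
to samples rather than wall-clock times keeps them unambiguous relative to
the waveform. Round trips are bit-exact by construction and by
property-based test. The capacity helper is pure arithmetic:
flash_bits / (rate × frame_bits); 1 Gbit at 1 kHz and 96 bits/frame gives
10 416.7 s ≈ 2.89 h, comfortably covering a ~2 h therapy session.
Simulated float signals are quantized at 10⁵ counts per unit, keeping
unit-amplitude waveforms five orders of magnitude above quantization and
well inside the 24-bit range.

## Conditioning

All timing-critical stages are zero-phase (forward–backward) IIR filters,
because PTT is a timing measurement and phase delay would bias it
directly. Defaults: ECG 0.5–40 Hz plus a 50 Hz notch (Q = 30); PPG
0.3–14 Hz plus the same notch; optional z-score normalization (all
detectors are amplitude-scale invariant, so normalization is cosmetic).
Edges are reflect-padded by roughly three time constants of the slowest
characteristic frequency of each stage.

The PPG low-pass corner is the one default that was tuned against the
simulator's ground truth: a zero-phase 10 Hz corner visibly distorts the
upstroke and shifts the detected inflection early by ≈ 3.7 ms
(systematic), while 14 Hz leaves ≈ 0.7 ms of bias and still suppresses
enough in-band noise that per-beat errors at moderate noise stay around
1–4 ms. Narrower is not safer here.

The first-order RC low-pass (bilinear transform, DC gain 1, −3 dB at the
corner) emulates the analog anti-aliasing filter of an acquisition front
end. It is causal by design and deliberately not part of the default
digital chain.

**Artifact flagging.** The signal is centered by a block-wise (2 s)
running median; the amplitude scale is the median across blocks of each
block's 99.5th-percentile absolute deviation — a robust estimate of the
normal peak envelope. Samples deviating more than 3× that scale are
flagged and padded by 0.1 s. A plain MAD was rejected as the scale: for an
ECG the sample MAD sits far below the R amplitude, so no single MAD
multiplier can both pass R peaks and catch excursions a few times the beat
amplitude; the peak-envelope scale makes "several times the normal beat"
the natural unit.

## Fiducial detection

**R peaks** follow the Pan–Tompkins structure: 5–15 Hz band-pass emphasis
(zero-phase), derivative, squaring, 150 ms moving-window integration,
then adaptive dual thresholds with running signal/noise peak estimates,
a refractory period (default 0.2 s) and a search-back pass over long gaps
at half threshold. Every accepted detection is refined to the local
maximum of the conditioned ECG within ±50 ms, with parabolic
interpolation for sub-sample apex placement. Flat signals return zero
beats; signals under one second are rejected.

**PPG fiducials** per pulse: the systolic peak from a prominence-gated
local-maximum search (optionally restricted to within 1 s after a guide
R peak); the onset as the pulse foot — the last crossing of 1% relative
amplitude above the local pre-peak minimum, linearly interpolated; the
inflection as the maximum first derivative between onset and peak with
parabolic sub-sample refinement (PTT resolution should beat the 1 ms
grid); and the dicrotic wave as the most prominent local maximum within
0.5 s after the systolic peak, reported as absent when no candidate
exists. "Inflection point" is interpreted as the maximum-slope point of
the upstroke — the standard PTT fiducial; a pulse-foot convention would
shift every PTT by a constant and is a detector-level choice, not a
pipeline change. Unresolvable pulses are skipped, never fabricated. Ties
in discrete argmax break toward the earlier sample.

HR and HRV come from the R-peak annotation: a sliding-window (default
10 s) mean rate emitted once per second (matching a device that telemeters
heart rate at 1 Hz), and SDNN/RMSSD in milliseconds over RR intervals
gated to [0.3, 3.0] s.

## PTT analysis

**Pairing** walks both sorted lists once: each R peak takes the earliest
unconsumed inflection in (r + 0.1, r + 0.6] s. The window is essential —
"the next inflection" with no bound would mis-pair whenever a pulse is
dropped; the walk makes the pairing injective and order-preserving by
construction. **Cleaning** flags (never edits) beats deviating from a
31-beat running median by more than 5× the local MAD, with the MAD floored
at 0.1 ms so sub-resolution wiggle on near-perfect series cannot inflate
the flag rate.

**Intervention fitting** minimizes least squares of the drop-and-recover
model over (baseline, Δ, t_on, τ_on, τ_recovery, t_off), with both switch
times free within ±30 s of their hints. Freeing t_off matters: holding it
at a hint 10 s off the true value biases τ_recovery by tens of percent
for fast recoveries. Five deterministic (τ_on, τ_recovery) starts —
(10, 20), (30, 60), (60, 120), (20, 90), (45, 30) s — guard against local
minima; the lowest-RSS convergent fit wins, and total non-convergence
raises an error carrying per-start diagnostics rather than falling back
silently. Under the reference conditions (1 beat/s, 5 ms beat noise,
−30 ms drop over 300 s), the median relative error of τ_recovery across
20 seeded replicates stays within 10% for τ ∈ [20, 120] s.

**PWV utilities.** Moens–Korteweg, PWV = √(E·h/(ρ·D)), plus the
path-length conversion PWV = L/PTT. These are intentionally thin: no
blood-pressure estimation is attempted.

Internally PTT is carried in seconds; CSV export converts to milliseconds
in exactly one place (`PTTSeries.to_frame`).

## Session profiles

The hyperbaric scheme generator emits contiguous phases (label, start,
end, pressure, gas). The standard wound-care scheme: compression on air
to 2.4 ATA, three 30 min pure-oxygen periods separated by two 10 min air
breaks, decompression to 1 ATA under continued oxygen — 90 min of
hyperbaric oxygen at full pressure, i.e. exactly 6.25% of a 24 h day.
Compression/decompression durations are not standardized between chambers
and default to 15 min each, configurable. The duty-fraction helper counts
only oxygen phases at the maximum profile pressure, which excludes the
decompression phase automatically (its recorded pressure is the 1 ATA
endpoint).

## Problem sizes and what the tests show

The test suite's end-to-end chain runs 300 s recordings (~350 beats) at
1 kHz, clean and at moderate noise; parameter-recovery uses 20 × 900 s
beat-domain series; property-based round-trips use up to 300-frame random
recordings. Error metrics follow the per-beat mean absolute error (the
worst single beat under band-limited noise has unbounded tails, so a
hard per-beat maximum is only asserted for clean signals, where the
residual is purely systematic and ≈ 0.7 ms).

Passing these tests establishes that the pipeline recovers what the
generator encodes — timing to ~1 ms through quantization, storage,
filtering and detection, and intervention constants to ~5–10% under
honest noise. It does not establish performance on real skin-contact
data: the generator has no pulse-morphology variability between beats, no
sensor-coupling drift, no arrhythmia, and its artifacts are smooth
transients. The validation answers "is the measuring chain and its
arithmetic correct", not "is the detector clinically robust".

## Known limitations

- No autocorrelated HRV model; SDNN is reproduced, spectra are not.
- Red/IR channels carry no oximetry information (SpO₂ is out of scope).
- Artifact detection is amplitude-only; there is no accelerometer channel
  in the data model.
- The binary container has no compression and no per-frame LED metadata
  (a header field is reserved but unpopulated).
- The intervention model is single-exponential in and out; multi-phasic
  pharmacokinetics would need a richer model than the data here can
  constrain.
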