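"""Per-beat pulse-transit-time series, intervention fitting and PWV utilities.

PTT is the interval between an ECG R peak and the upstroke inflection of
the PPG pulse produced by the same cardiac cycle.  Pairing uses a
physiologic window (default 0.1–0.6 s after the R peak): an unbounded
"next inflection" rule would silently mis-pair beats whenever a pulse is
dropped.  Vasoconstriction episodes (e.g. nicotine, hyperbaric oxygen) are
quantified by fitting a saturating-exponential drop with exponential
recovery.  The Moens–Korteweg relation links pulse wave velocity to vessel
elasticity and geometry, PWV = sqrt(E h / (rho D)), connecting the timing
measurement to arterial mechanics.

PTT is carried in seconds internally; CSV export converts to milliseconds
(the conventional reporting unit) in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import AnalysisError, FitError, ParameterError
from .simulate import SessionProfile

__all__ = [
    "PTTSeries",
    "InterventionFit",
    "VesselParams",
    "pair_beats",
    "clean_series",
    "fit_intervention",
    "moens_korteweg_pwv",
    "pwv_from_ptt",
    "phase_summary",
]


@dataclass(frozen=True)
class PTTSeries:
    """Per-beat (time, PTT) pairs with a quality flag per beat."""

    beat_time: np.ndarray  # s, strictly increasing
    ptt: np.ndarray        # s
    quality: np.ndarray    # bool, True = usable

    def __post_init__(self):
        bt = np.asarray(self.beat_time, dtype=float)
        pt = np.asarray(self.ptt, dtype=float)
        q = np.asarray(self.quality, dtype=bool)
        if not bt.size == pt.size == q.size:
            raise ParameterError("beat_time, ptt and quality must have equal length")
        if bt.size > 1 and not np.all(np.diff(bt) > 0):
            raise ParameterError("beat times must be strictly increasing")
        object.__setattr__(self, "beat_time", bt)
        object.__setattr__(self, "ptt", pt)
        object.__setattr__(self, "quality", q)

    @property
    def n_beats(self) -> int:
        return int(self.beat_time.size)

    def usable(self) -> "PTTSeries":
        m = self.quality
        return PTTSeries(self.beat_time[m], self.ptt[m], self.quality[m])

    def to_frame(self) -> pd.DataFrame:
        """Interface representation: PTT in milliseconds."""
        return pd.DataFrame(
            {
                "beat_time_s": self.beat_time,
                "ptt_ms": self.ptt * 1000.0,
                "quality": self.quality.astype(int),
            }
        )


@dataclass(frozen=True)
class InterventionFit:
    """Fitted vasoconstriction response parameters (seconds)."""

    baseline_ptt: float
    delta: float
    t_on: float
    tau_on: float
    tau_recovery: float
    rss: float

    def __post_init__(self):
        if self.tau_on <= 0 or self.tau_recovery <= 0:
            raise ParameterError("fitted time constants must be positive")
        if self.rss < 0:
            raise ParameterError("residual sum of squares cannot be negative")


@dataclass(frozen=True)
class VesselParams:
    """Arterial segment parameters for the Moens–Korteweg relation (SI)."""

    E: float    # Young's modulus, Pa
    h: float    # wall thickness, m
    D: float    # lumen diameter, m
    rho: float  # blood density, kg/m^3

    def __post_init__(self):
        for name in ("E", "h", "D", "rho"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"vessel parameter {name} must be strictly positive")


def pair_beats(
    r_times,
    inflections,
    window: tuple[float, float] = (0.1, 0.6),
) -> PTTSeries:
    """Match each R peak to the earliest unused inflection in its window.

    The window is ``(r + window[0], r + window[1]]``.  R peaks without a
    candidate are dropped; each inflection is consumed at most once, so the
    pairing is injective and order-preserving.
    """
    r = np.asarray(r_times, dtype=float)
    infl = np.asarray(inflections, dtype=float)
    for name, arr in (("r_times", r), ("inflections", infl)):
        if arr.size > 1 and not np.all(np.diff(arr) > 0):
            raise ParameterError(f"{name} must be strictly increasing")
    lo, hi = window
    if not 0 <= lo < hi:
        raise ParameterError("pairing window must satisfy 0 <= min < max")

    times, ptts = [], []
    j = 0
    for rt in r:
        while j < infl.size and infl[j] <= rt + lo:
            j += 1
        if j < infl.size and infl[j] <= rt + hi:
            times.append(rt)
            ptts.append(infl[j] - rt)
            j += 1
    n = len(times)
    return PTTSeries(np.array(times), np.array(ptts), np.ones(n, dtype=bool))


def clean_series(series: PTTSeries, mad_k: float = 5.0, win_beats: int = 31) -> PTTSeries:
    """Flag outlier beats against a running median; values are never altered.

    A beat is marked ``quality=False`` when its PTT deviates from the
    centered running median by more than ``mad_k`` times the local median
    absolute deviation.  The local MAD is floored at 0.1 ms so that
    sub-resolution wiggle on near-perfect series cannot inflate the flag
    rate; a genuine outlier clears a 0.1 ms floor by orders of magnitude.
    """
    if series.n_beats == 0:
        raise ParameterError("cannot clean an empty series")
    if mad_k <= 0 or win_beats < 3:
        raise ParameterError("need mad_k > 0 and win_beats >= 3")
    s = pd.Series(series.ptt)
    med = s.rolling(win_beats, center=True, min_periods=1).median()
    dev = (s - med).abs()
    mad = dev.rolling(win_beats, center=True, min_periods=1).median()
    bad = dev.to_numpy() > mad_k * np.maximum(mad.to_numpy(), 1e-4)
    return PTTSeries(series.beat_time, series.ptt, series.quality & ~bad)


def _intervention_model(t, baseline, delta, t_on, tau_on, tau_rec, t_off):
    out = np.full_like(t, baseline, dtype=float)
    during = (t >= t_on) & (t <= t_off)
    out[during] += delta * (1.0 - np.exp(-(t[during] - t_on) / tau_on))
    after = t > t_off
    level = delta * (1.0 - np.exp(-(t_off - t_on) / tau_on))
    out[after] += level * np.exp(-(t[after] - t_off) / tau_rec)
    return out


# deterministic multi-start grid for (tau_on, tau_recovery), seconds
_TAU_STARTS = ((10.0, 20.0), (30.0, 60.0), (60.0, 120.0), (20.0, 90.0), (45.0, 30.0))


def fit_intervention(series: PTTSeries, t_on_hint: float, t_off_hint: float) -> InterventionFit:
    """Least-squares fit of the drop-and-recover response to a PTT series.

    Model: constant baseline, saturating-exponential drop of size ``delta``
    starting at ``t_on``, exponential return to baseline after ``t_off``.
    Both switch times are free within ±30 s of their hints (a mis-specified
    fixed ``t_off`` would bias the recovery constant by up to half a time
    constant).  Five deterministic starts span the plausible time-constant
    range; the lowest-RSS convergent fit wins.  Beats flagged
    ``quality=False`` are excluded.
    """
    use = series.usable()
    if use.n_beats < 30:
        raise AnalysisError(f"intervention fit needs >= 30 usable beats, got {use.n_beats}")
    t, y = use.beat_time, use.ptt
    if not (t[0] < t_on_hint < t_off_hint < t[-1]):
        raise ParameterError("series must span beyond both intervention hints")

    pre = y[t < t_on_hint]
    base0 = float(np.median(pre)) if pre.size else float(np.median(y))
    late = y[(t > t_on_hint + 0.66 * (t_off_hint - t_on_hint)) & (t <= t_off_hint)]
    delta0 = float(np.median(late) - base0) if late.size else 0.0

    span = y.max() - y.min() + 1e-6
    lb = [y.min() - span, -2 * span - 1e-3, t_on_hint - 30.0, 0.5, 0.5, t_off_hint - 30.0]
    ub = [y.max() + span, 2 * span + 1e-3, t_on_hint + 30.0, 5e3, 5e3, t_off_hint + 30.0]

    def resid(p):
        return _intervention_model(t, p[0], p[1], p[2], p[3], p[4], p[5]) - y

    best = None
    diagnostics = []
    for tau_on0, tau_rec0 in _TAU_STARTS:
        p0 = np.clip(
            [base0, delta0, t_on_hint, tau_on0, tau_rec0, t_off_hint], lb, ub
        )
        try:
            res = least_squares(resid, p0, bounds=(lb, ub), method="trf")
        except Exception as exc:  # pragma: no cover - scipy internal failure
            diagnostics.append({"start": (tau_on0, tau_rec0), "error": str(exc)})
            continue
        diagnostics.append(
            {"start": (tau_on0, tau_rec0), "status": res.status, "cost": float(res.cost)}
        )
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError(
            "intervention fit did not converge from any start",
            diagnostics={"starts": diagnostics},
        )
    p = best.x
    return InterventionFit(
        baseline_ptt=float(p[0]),
        delta=float(p[1]),
        t_on=float(p[2]),
        tau_on=float(p[3]),
        tau_recovery=float(p[4]),
        rss=float(2.0 * best.cost),
    )


def moens_korteweg_pwv(params: VesselParams) -> float:
    """Pulse wave velocity from vessel mechanics: sqrt(E h / (rho D)), m/s."""
    return float(np.sqrt(params.E * params.h / (params.rho * params.D)))


def pwv_from_ptt(ptt: float, path_length: float) -> float:
    """Average pulse wave velocity over an arterial path of known length."""
    if ptt <= 0 or path_length <= 0:
        raise ParameterError("ptt and path_length must both be positive")
    return path_length / ptt


def phase_summary(series: PTTSeries, profile: SessionProfile) -> pd.DataFrame:
    """Mean/SD PTT and usable beat count per therapy phase.

    Beats are assigned to the unique phase containing their beat time
    (series and profile share the t=0 origin).  Phases without beats are
    reported with ``n_beats=0`` and NaN statistics.
    """
    use = series.usable()
    t_min = use.beat_time / 60.0
    rows = []
    for ph in profile.phases:
        sel = use.ptt[(t_min >= ph.start_min) & (t_min < ph.end_min)]
        rows.append(
            {
                "phase": ph.label,
                "gas": ph.gas,
                "start_min": ph.start_min,
                "end_min": ph.end_min,
                "mean_ptt_s": float(sel.mean()) if sel.size else np.nan,
                "sd_ptt_s": float(sel.std(ddof=1)) if sel.size > 1 else (0.0 if sel.size == 1 else np.nan),
                "n_beats": int(sel.size),
            }
        )
    return pd.DataFrame(rows)
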