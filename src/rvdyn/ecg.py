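"""Paced surface-ECG delineation and hysteresis features.

Five landmarks are measured on each paced limb-lead complex, all relative
to the pacing stimulus: QRS onset (latency), QRS peak, end of QRS
(J-point), T-wave peak and T-wave end.  Repeats are aggregated by median
within lead and then across limb leads.  The diagnostic features are the
*changes* of the stimulus-to-landmark intervals between steady-state
pacing and the pre-ERP extrastimulus beat (hysteresis), which are robust
to the patient-specific pacing-electrode position.

The delineator is an algorithmic surrogate for on-screen caliper
measurement: signals are band-passed 0.1-50 Hz (zero phase), QRS onset and
offset are slope-threshold crossings relative to the maximum QRS slope,
and T-end uses the tangent method (intersection of the steepest post-peak
T slope with the pre-stimulus isoelectric baseline).  Thresholds are
configurable; defaults were chosen so that prescribed landmarks of the
synthetic morphology are recovered (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import SignalTrace
from .egm import smoothed_derivative

HYSTERESIS_INTERVALS = ("latency", "stim_to_qrs_peak", "stim_to_j",
                        "stim_to_tpeak", "stim_to_tend", "qrs_duration",
                        "tpeak_tend", "qt")


class LandmarkRejection(ValueError):
    """Raised when a paced complex cannot be delineated consistently."""


@dataclass
class EcgLandmarks:
    """Landmark times in ms from the pacing stimulus."""

    latency_ms: float
    qrs_peak_ms: float
    j_point_ms: float
    t_peak_ms: float
    t_end_ms: float
    lead: str = "?"
    state: str = "steady"
    repeat: int = 0

    def __post_init__(self) -> None:
        v = (self.latency_ms, self.qrs_peak_ms, self.j_point_ms,
             self.t_peak_ms, self.t_end_ms)
        if any(b <= a for a, b in zip(v, v[1:])):
            raise LandmarkRejection(f"landmarks out of order: {v}")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.latency_ms, self.qrs_peak_ms, self.j_point_ms,
                self.t_peak_ms, self.t_end_ms)


@dataclass
class EcgHysteresis:
    """Per-interval steady-state value, pre-ERP value and their difference."""

    steady: dict[str, float]
    pre_erp: dict[str, float]
    hysteresis: dict[str, float]


@dataclass
class EcgDetectorParams:
    band_hz: tuple[float, float] = (0.1, 50.0)
    blanking_ms: float = 10.0
    onset_frac: float = 0.10      # of max |dV/dt| in the QRS
    onset_dwell_ms: float = 4.0
    j_frac: float = 0.07          # of the QRS peak amplitude
    j_dwell_ms: float = 10.0
    qrs_search_end_ms: float = 200.0
    qrs_back_ms: float = 120.0
    tpeak_gap_ms: float = 40.0
    t_search_end_ms: float = 450.0
    t_tangent_span_ms: float = 160.0
    baseline_window_ms: tuple[float, float] = (-60.0, -10.0)
    derivative_kernel_ms: float = 14.0


def _filter_ecg(trace: SignalTrace, band: tuple[float, float]) -> np.ndarray:
    sos = butter(2, band, btype="bandpass", fs=trace.fs, output="sos")
    return sosfiltfilt(sos, trace.samples)


def detect_paced_ecg_landmarks(trace: SignalTrace, stimulus_t_ms: float,
                               params: EcgDetectorParams | None = None,
                               lead: str | None = None, state: str = "steady",
                               repeat: int = 0) -> EcgLandmarks:
    """Delineate one paced complex.  Raises LandmarkRejection on failure."""
    p = params or EcgDetectorParams()
    fs, dt = trace.fs, trace.dt_ms
    v = _filter_ecg(trace, p.band_hz)
    t = trace.times_ms

    def idx(ms: float) -> int:
        return int(np.clip(np.round((ms - trace.t0) / dt), 0,
                           v.size - 1))

    b0, b1 = idx(stimulus_t_ms + p.baseline_window_ms[0]), \
        idx(stimulus_t_ms + p.baseline_window_ms[1])
    baseline = float(np.median(v[b0:b1])) if b1 > b0 else 0.0
    v = v - baseline
    d = smoothed_derivative(v, fs, p.derivative_kernel_ms)

    # QRS peak: largest absolute excursion after blanking
    q0 = idx(stimulus_t_ms + p.blanking_ms + 5.0)
    q1 = idx(stimulus_t_ms + p.qrs_search_end_ms)
    if q1 <= q0 or not np.any(v[q0:q1]):
        raise LandmarkRejection("no QRS found (flat trace)")
    qrs_i = q0 + int(np.argmax(np.abs(v[q0:q1])))
    s0 = idx(t[qrs_i] - p.qrs_back_ms)
    max_slope = float(np.max(np.abs(d[s0:qrs_i + 2])))
    if max_slope <= 0:
        raise LandmarkRejection("no QRS slope")

    # latency: end of the last sustained sub-threshold run before QRS peak
    thr = p.onset_frac * max_slope
    dwell = max(1, int(round(p.onset_dwell_ms / dt)))
    lo = idx(stimulus_t_ms + p.blanking_ms)
    below = np.abs(d[lo:qrs_i]) < thr
    lat_i = None
    run = 0
    for k in range(below.size - 1, -1, -1):
        if below[k]:
            run += 1
            if run >= dwell:
                lat_i = lo + k + run  # first sample after the quiet run
                break
        else:
            run = 0
    if lat_i is None:
        raise LandmarkRejection("no QRS onset before peak")

    # J point: first sustained return to the isoelectric line after the
    # QRS peak.  An amplitude criterion is used because the slope of a
    # wide paced QRS is too shallow for a slope threshold to clear the
    # noise floor; the threshold is a fraction of the QRS peak amplitude,
    # so detection stays invariant to trace scaling.
    thr_j = p.j_frac * float(np.abs(v[qrs_i]))
    dwell_j = max(1, int(round(p.j_dwell_ms / dt)))
    below_j = np.abs(v[qrs_i:]) < thr_j
    j_i = None
    run = 0
    for k in range(below_j.size):
        if below_j[k]:
            run += 1
            if run >= dwell_j:
                j_i = qrs_i + k - run + 1
                break
        else:
            run = 0
    if j_i is None:
        raise LandmarkRejection("no J-point after QRS peak")

    # T peak
    t0_i = idx(t[j_i] + p.tpeak_gap_ms)
    t1_i = idx(stimulus_t_ms + p.t_search_end_ms)
    if t1_i <= t0_i:
        raise LandmarkRejection("no T-wave search window")
    tp_i = t0_i + int(np.argmax(np.abs(v[t0_i:t1_i])))
    sgn = np.sign(v[tp_i]) or 1.0

    # T end by the tangent method: a straight line is fitted to the
    # descending terminal limb (between 65% and 10% of the T amplitude,
    # which brackets its steepest sustained slope) and intersected with
    # the pre-stimulus isoelectric baseline.  Regressing the tangent
    # slope over the limb instead of taking the single steepest sample
    # keeps the intercept unbiased in noise.
    e1 = idx(t[tp_i] + p.t_tangent_span_ms)
    if e1 <= tp_i + 4:
        raise LandmarkRejection("no terminal T limb")
    rel = sgn * v[tp_i:e1] / max(sgn * v[tp_i], 1e-12)
    upper = np.flatnonzero(rel <= 0.65)
    lower = np.flatnonzero(rel <= 0.10)
    lo = tp_i + (int(upper[0]) if upper.size else 0)
    hi = tp_i + (int(lower[0]) if lower.size else rel.size - 1)
    if hi - lo < 4:
        raise LandmarkRejection("terminal T limb too short")
    slope, inter = np.polyfit(t[lo:hi + 1], v[lo:hi + 1], 1)
    if sgn * slope >= 0:
        raise LandmarkRejection("no descending T limb")
    t_end = -inter / slope

    return EcgLandmarks(
        latency_ms=float(t[lat_i] - stimulus_t_ms),
        qrs_peak_ms=float(t[qrs_i] - stimulus_t_ms),
        j_point_ms=float(t[j_i] - stimulus_t_ms),
        t_peak_ms=float(t[tp_i] - stimulus_t_ms),
        t_end_ms=float(t_end - stimulus_t_ms),
        lead=lead or trace.channel_id, state=state, repeat=repeat)


def _lower_median(values: Iterable[float]) -> float:
    """Median with the lower-median convention for even counts."""
    s = sorted(values)
    if not s:
        raise ValueError("no values to aggregate")
    return float(s[(len(s) - 1) // 2])


def aggregate_measurements(landmarks: Iterable[EcgLandmarks],
                           state: str | None = None) -> EcgLandmarks:
    """Patient-level landmarks: median over repeats within lead, then
    median across leads.  The lower-median convention is used for even
    counts so aggregated values are always observed values."""
    items = [lm for lm in landmarks
             if state is None or lm.state == state]
    if not items:
        raise ValueError("no landmarks to aggregate")
    by_lead: dict[str, list[EcgLandmarks]] = {}
    for lm in items:
        by_lead.setdefault(lm.lead, []).append(lm)
    per_lead = []
    for lead, reps in by_lead.items():
        per_lead.append(tuple(_lower_median(getattr(r, f) for r in reps)
                              for f in ("latency_ms", "qrs_peak_ms",
                                        "j_point_ms", "t_peak_ms",
                                        "t_end_ms")))
    agg = tuple(_lower_median(vals[k] for vals in per_lead)
                for k in range(5))
    return EcgLandmarks(*agg, lead="median",
                        state=state or items[0].state, repeat=0)


def _intervals(lm: EcgLandmarks) -> dict[str, float]:
    return {
        "latency": lm.latency_ms,
        "stim_to_qrs_peak": lm.qrs_peak_ms,
        "stim_to_j": lm.j_point_ms,
        "stim_to_tpeak": lm.t_peak_ms,
        "stim_to_tend": lm.t_end_ms,
        "qrs_duration": lm.j_point_ms - lm.latency_ms,
        "tpeak_tend": lm.t_end_ms - lm.t_peak_ms,
        "qt": lm.t_end_ms - lm.latency_ms,
    }


def hysteresis_features(steady: EcgLandmarks,
                        pre_erp: EcgLandmarks) -> EcgHysteresis:
    """All eight intervals and their pre-ERP minus steady differences."""
    s = _intervals(steady)
    p = _intervals(pre_erp)
    return EcgHysteresis(steady=s, pre_erp=p,
                         hysteresis={k: p[k] - s[k] for k in s})
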