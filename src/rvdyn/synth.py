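"""Synthetic electrogram and paced-ECG generator with prescribed truths.

Every downstream stage of the package is validated against this module:
it synthesises waveform-level datasets whose measurable features (local
activation and repolarization times, deflection counts, ECG landmarks) are
*prescribed*, so that the detectors and metrics can be checked end to end
without clinical recordings.

Waveform model
--------------
* pacing artifact: a 1 ms biphasic spike at t = 0;
* RS complex: a biphasic derivative-of-Gaussian wave whose steepest
  negative slope falls exactly at the prescribed activation time;
* T wave: a tanh upstroke with plateau and slow decay, whose steepest
  upstroke (rising-edge inflection for positive T waves, recovery-limb
  inflection for the time-mirrored negative ones) falls exactly at the
  prescribed repolarization time;
* fractionation: narrow (~5-10 ms) bumps inserted at separated offsets
  inside the activation complex, each contributing one supra-threshold
  downstroke to the deflection count;
* additive white Gaussian noise.

Restitution datasets realise a full S1S2 protocol against a capture oracle
``captures iff ci > true VERP``.  Activation delay curves are constructed
by inversion: either an exponential delay curve pinned to the prescribed
pre-VERP activation-time increase, or (when a mean-increase-in-delay value
is prescribed) per-step delay rates allocated over the realised fine scan
so the implemented MID formula evaluates exactly to the prescribed value.
Repolarization follows RT(ci) = AT(ci) + ARI(DI(ci)) with a mono-
exponential ARI restitution whose (signed) amplitude is solved from the
prescribed steady-state ARI and pre-VERP repolarization change.

Cohorts draw per-patient parameters from group-level distributions
(defaults in :mod:`rvdyn.calibration`), splitting each parameter's
variance between patients and electrodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import calibration
from .core import (GROUPS, LIMB_LEADS, ElectrodeMap,
                   PatientRecord, SignalTrace, StimulusProtocol,
                   build_electrode_map, generate_s2_schedule)
from .ecg import EcgDetectorParams, LandmarkRejection, \
    detect_paced_ecg_landmarks


class GeneratorError(ValueError):
    """Raised when a prescription cannot be realised as a waveform."""


# ---------------------------------------------------------------------------
# Single-beat unipolar electrogram


@dataclass
class EgmMorphologySpec:
    """Prescription for one unipolar electrogram beat."""

    at_true_ms: float
    rt_true_ms: float
    rs_amplitude_mv: float = 1.5
    t_amplitude_mv: float = 0.35
    t_polarity: int = 1                  # +1 or -1
    activation_width_ms: float = 4.0
    t_rise_ms: float = 5.0
    t_plateau_ms: float = 25.0
    t_width_ms: float = 35.0
    n_extra_deflections: int = 0
    deflection_amplitude_mv: float = 0.60
    deflection_width_ms: float = 2.2
    deflection_offsets_ms: tuple[float, ...] | None = None
    noise_sd_mv: float = 0.02
    stimulus_amplitude_mv: float = 2.0

    def __post_init__(self) -> None:
        if isinstance(self.t_polarity, str):
            self.t_polarity = 1 if self.t_polarity == "+" else -1
        if self.t_amplitude_mv > 0 \
                and self.rt_true_ms - self.at_true_ms < 40:
            raise GeneratorError("rt_true - at_true must be >= 40 ms")
        if self.activation_width_ms <= 0 or self.t_width_ms <= 0:
            raise GeneratorError("widths must be positive")
        if self.n_extra_deflections < 0:
            raise GeneratorError("n_extra_deflections must be >= 0")


# offsets (ms from activation) where extra deflections may be inserted;
# spaced 10 ms so neighbouring downstrokes never cancel, and >= 18 ms from
# the RS so its own derivative does not mask them
_DEFLECTION_SLOTS = (-38.0, -28.0, -18.0, 18.0, 28.0, 38.0)


def available_deflection_slots(at_true_ms: float,
                               blanking_ms: float = 10.0) -> list[float]:
    """Slots that stay clear of the stimulus artifact for this beat."""
    return [s for s in _DEFLECTION_SLOTS if at_true_ms + s >= blanking_ms]


def _deflection_offsets(spec: EgmMorphologySpec,
                        rng: np.random.Generator) -> tuple[float, ...]:
    if spec.deflection_offsets_ms is not None:
        return tuple(spec.deflection_offsets_ms[:spec.n_extra_deflections])
    avail = available_deflection_slots(spec.at_true_ms)
    n = min(spec.n_extra_deflections, len(avail))
    slots = rng.permutation(avail)[:n]
    return tuple(float(s + rng.uniform(-1.0, 1.0)) for s in slots)


def _add_beat(v: np.ndarray, t: np.ndarray, stim_ms: float,
              spec: EgmMorphologySpec, rng: np.random.Generator,
              stimulus: bool = True) -> None:
    """Add one beat (artifact + RS + T + deflections) in place."""
    if stimulus and spec.stimulus_amplitude_mv:
        a = spec.stimulus_amplitude_mv
        v += a * np.exp(-((t - stim_ms - 0.3) ** 2) / (2 * 0.3 ** 2))
        v -= a * np.exp(-((t - stim_ms - 1.0) ** 2) / (2 * 0.3 ** 2))
    at = stim_ms + spec.at_true_ms
    u = (t - at) / spec.activation_width_ms
    v += -spec.rs_amplitude_mv * u * np.exp(-0.5 * u * u)
    if spec.t_amplitude_mv > 0:
        rt = stim_ms + spec.rt_true_ms
        # T wave with a distinct intrinsic upstroke: a tanh rise whose
        # inflection (maximum dV/dt) sits exactly at rt, a short plateau,
        # and a slow Gaussian decay.  A negative T is the time mirror, so
        # its steepest *upstroke* (recovery limb) is still at rt.
        tau = spec.t_polarity * (t - rt)
        rise = 0.5 * (1.0 + np.tanh(tau / spec.t_rise_ms))
        decay = np.exp(-(np.maximum(tau - spec.t_plateau_ms, 0.0)
                         / spec.t_width_ms) ** 2)
        v += spec.t_polarity * spec.t_amplitude_mv * rise * decay
    for off in _deflection_offsets(spec, rng):
        v += spec.deflection_amplitude_mv * np.exp(
            -((t - at - off) ** 2) / (2 * spec.deflection_width_ms ** 2))


def synth_unipolar_egm(spec: EgmMorphologySpec, duration_ms: float,
                       fs: float = 1200.0,
                       rng: np.random.Generator | None = None,
                       t0: float = -120.0,
                       channel_id: str = "egm") -> SignalTrace:
    """Synthesise a single-beat unipolar electrogram (stimulus at t = 0)."""
    rng = rng or np.random.default_rng(0)
    if spec.t_amplitude_mv > 0 and spec.rt_true_ms + spec.t_plateau_ms \
            + 2 * spec.t_width_ms > t0 + duration_ms:
        raise GeneratorError("repolarization window outside trace duration")
    n = int(round(duration_ms * fs / 1000.0))
    t = t0 + np.arange(n) * 1000.0 / fs
    v = np.zeros(n)
    _add_beat(v, t, 0.0, spec, rng)
    if spec.noise_sd_mv > 0:
        v += rng.normal(0.0, spec.noise_sd_mv, n)
    return SignalTrace(channel_id, fs, t0, v)


# ---------------------------------------------------------------------------
# Paced surface ECG


def build_paced_ecg_complex(landmarks, fs: float = 1000.0,
                            pre_ms: float = 200.0, post_ms: float = 650.0,
                            qrs_amp: float = 1.0, t_amp: float = 0.5,
                            stim_amp: float = 1.0,
                            channel_id: str = "ecg") -> SignalTrace:
    """Noiseless paced limb-lead complex with the given internal landmarks.

    ``landmarks`` = (latency, qrs_peak, j_point, t_peak, t_end) in ms from
    the stimulus.  The QRS is a monophasic raised-cosine R wave; the ST
    segment is isoelectric.  The T wave peaks at a slope corner (so the
    peak stays localisable under noise) and its terminal limb runs into
    the baseline at t_end with a finite slope, so the tangent method
    recovers t_end by construction.
    """
    lat, qp, j, tp, te = (float(x) for x in landmarks)
    if not lat < qp < j < tp < te:
        raise GeneratorError(f"landmarks out of order: {landmarks}")
    n = int(round((pre_ms + post_ms) * fs / 1000.0))
    t = -pre_ms + np.arange(n) * 1000.0 / fs
    v = np.zeros(n)
    v += stim_amp * np.exp(-((t - 0.3) ** 2) / (2 * 0.4 ** 2))
    v -= stim_amp * np.exp(-((t - 1.3) ** 2) / (2 * 0.4 ** 2))
    m = (t >= lat) & (t < qp)
    v[m] = qrs_amp * 0.5 * (1 - np.cos(np.pi * (t[m] - lat) / (qp - lat)))
    m = (t >= qp) & (t < j)
    v[m] = qrs_amp * 0.5 * (1 + np.cos(np.pi * (t[m] - qp) / (j - qp)))
    t_on = max(j + 12.0, tp - 0.65 * (tp - j))
    m = (t >= t_on) & (t < tp)
    v[m] = t_amp * np.sin(0.3 * np.pi * (t[m] - t_on)
                          / (tp - t_on)) / np.sin(0.3 * np.pi)
    # linear T fall: the tangent-line baseline intercept equals t_end no
    # matter where on the limb the steepest-slope point is located
    m = (t >= tp) & (t < te)
    tau = (t[m] - tp) / (te - tp)
    v[m] = t_amp * (1 - tau)
    return SignalTrace(channel_id, fs, -pre_ms, v)


def calibrate_ecg_morphology(prescribed, fs: float = 1000.0,
                             detector_params: EcgDetectorParams | None = None,
                             n_iter: int = 3, **shape) -> tuple[float, ...]:
    """Internal landmark parameters whose *detected* landmarks equal the
    prescription.

    The slope-threshold onset/offset definitions have small shape-dependent
    offsets; a short fixed-point iteration against the package's own
    delineator absorbs them so that, at zero noise, detection recovers the
    prescription to within a sample.
    """
    target = np.asarray(prescribed, dtype=float)
    internal = target.copy()
    p = detector_params or EcgDetectorParams()
    for _ in range(n_iter):
        trace = build_paced_ecg_complex(internal, fs=fs, **shape)
        try:
            lm = detect_paced_ecg_landmarks(trace, 0.0, p)
        except LandmarkRejection:
            break
        err = np.array(lm.as_tuple()) - target
        internal = internal - err
        # keep the internal shape well ordered
        gaps = (12.0, 18.0, 45.0, 30.0)
        for k, g in enumerate(gaps):
            internal[k + 1] = max(internal[k + 1], internal[k] + g)
        if np.max(np.abs(err)) < 0.25:
            break
    return tuple(float(x) for x in internal)


def synth_paced_ecg(landmarks_by_state: dict[str, tuple],
                    leads=LIMB_LEADS, fs: float = 1000.0,
                    noise_sd_mv: float = 0.01, n_repeats: int = 3,
                    rng: np.random.Generator | None = None,
                    calibrate: bool = True,
                    detector_params: EcgDetectorParams | None = None,
                    **shape) -> dict[tuple, SignalTrace]:
    """Synthesise paced limb-lead complexes for each state.

    ``landmarks_by_state`` maps ``steady`` / ``pre_erp`` to prescribed
    (latency, qrs_peak, j_point, t_peak, t_end).  Per-lead amplitude
    scaling emulates projection differences; scaling does not move
    landmarks.  Returns ``{(lead, state, repeat): SignalTrace}``.
    """
    rng = rng or np.random.default_rng(0)
    out: dict[tuple, SignalTrace] = {}
    lead_scale = {lead: rng.uniform(0.75, 1.25) for lead in leads}
    for state, prescribed in landmarks_by_state.items():
        lat, qp, j, tp, te = prescribed
        if not lat < qp < j < tp < te:
            raise GeneratorError(
                f"unordered landmark prescription for {state}: {prescribed}")
        internal = calibrate_ecg_morphology(
            prescribed, fs, detector_params, **shape) if calibrate \
            else tuple(prescribed)
        base = build_paced_ecg_complex(internal, fs=fs, **shape)
        for lead in leads:
            for rep in range(1, n_repeats + 1):
                v = base.samples * lead_scale[lead]
                if noise_sd_mv > 0:
                    v = v + rng.normal(0.0, noise_sd_mv, v.size)
                out[(lead, state, rep)] = SignalTrace(lead, fs, base.t0, v)
    return out


# ---------------------------------------------------------------------------
# Patient kinetics and restitution datasets


@dataclass
class PatientKinetics:
    """Per-patient ground-truth parameters of the restitution dataset."""

    verp_true_ms: float = 205.0
    at_ss_ms: float = 75.0
    ari_ss_ms: float = 203.0
    delta_at_preverp_ms: float = 48.0
    delta_rt_preverp_ms: float = 15.0
    mid_true: float | None = None          # activates MID inversion
    frac_mean_ss: float = 3.1
    frac_mean_preverp: float = 3.0
    frac_mean_sinus: float = 2.8
    sinus_at_span_ms: float = 81.0
    sinus_rt_ms: float = 320.0
    sinus_base_at_ms: float = 12.0
    ecg_landmarks: dict[str, tuple] | None = None
    # curve shapes
    at_delay_tau_ms: float = 25.0
    ari_tau_ms: float = 60.0
    at_ss_span_ms: float = 30.0            # steady AT range across the RV
    # within-patient (per-electrode) spreads
    at_ss_within_sd: float = 3.0
    ari_ss_within_sd: float = 8.0
    delta_at_within_sd: float = 6.0
    delta_rt_within_sd: float = 8.0
    mid_within_sd: float = 0.0
    noise_sd_mv: float = 0.02
    t_polarity: int = 1

    def __post_init__(self) -> None:
        if not 150.0 <= self.verp_true_ms <= 320.0:
            raise GeneratorError("true VERP outside 150-320 ms")
        if self.mid_true is None and self.delta_at_preverp_ms < 0:
            raise GeneratorError("pre-VERP delay must be non-negative "
                                 "(monotone delay curve)")
        if self.mid_true is not None and self.mid_true < 0:
            raise GeneratorError("MID prescription must be non-negative")


@dataclass
class GroundTruth:
    kinetics: PatientKinetics
    per_electrode: pd.DataFrame
    per_beat: pd.DataFrame


def _fine_scan_points(protocol: StimulusProtocol,
                      fine_start: float = 300.0) -> np.ndarray:
    cis = [c for c in protocol.captured_intervals if c <= fine_start + 1e-9]
    return np.asarray(sorted(cis, reverse=True), dtype=float)


def invert_mid_delays(protocol: StimulusProtocol, mid_true: float,
                      fine_start: float = 300.0) -> dict[float, float]:
    """Delay at every captured fine-scan interval realising ``mid_true``.

    Per-step delay rates r_j are allocated proportionally to the inverse
    step width, so every step contributes equally to the cumulative delay
    and the mean of the per-step rates — the implemented MID formula —
    equals ``mid_true`` exactly.  Raises :class:`GeneratorError` when the
    fine scan has fewer than two steps.
    """
    ci = _fine_scan_points(protocol, fine_start)
    if ci.size < 3:
        raise GeneratorError(
            "MID inversion needs at least 3 capturing fine-scan points; "
            f"got {ci.size} (true VERP too close to the fine-scan floor?)")
    w = ci[:-1] - ci[1:]
    if np.any(w <= 0):
        raise GeneratorError("fine-scan intervals must be strictly "
                             "decreasing")
    m = w.size
    k = mid_true * m / np.sum(1.0 / w)
    rates = k / w
    delays = np.concatenate([[0.0], np.cumsum(rates * w)])
    return {float(c): float(d) for c, d in zip(ci, delays)}


def exponential_delay(ci: np.ndarray | float, pre_verp_ci: float,
                      delta_at: float, tau: float) -> np.ndarray | float:
    """Monotone activation-delay curve pinned to the pre-VERP increase."""
    return delta_at * np.exp(-(np.asarray(ci, dtype=float) - pre_verp_ci)
                             / tau)


def synth_restitution_dataset(kinetics: PatientKinetics,
                              electrode_map: ElectrodeMap | None = None,
                              protocol_kwargs: dict | None = None,
                              fs: float = 1200.0,
                              rng: np.random.Generator | None = None,
                              patient_id: str = "P000",
                              group: str = "definite_arvc",
                              include_waveforms: bool = True,
                              steady_repeats: int = 1,
                              sinus_beats: int = 2,
                              ecg_fs: float = 1000.0) -> PatientRecord:
    """Synthesise one patient's full S1S2 dataset with known ground truth."""
    rng = rng or np.random.default_rng(0)
    emap = electrode_map or build_electrode_map()
    kin = kinetics
    protocol = generate_s2_schedule(
        lambda ci: ci > kin.verp_true_ms, **(protocol_kwargs or {}))
    pre_ci = protocol.pre_verp_ci_ms

    z = emap.positions()[:, 2]
    z_norm = (z - z.min()) / max(z.max() - z.min(), 1e-9)

    # --- per-electrode true parameters -----------------------------------
    n_el = len(emap.electrodes)
    at_ss_e = (kin.at_ss_ms + kin.at_ss_span_ms * (z_norm - z_norm.mean())
               + rng.normal(0, kin.at_ss_within_sd, n_el))
    at_ss_e = np.clip(at_ss_e, 15.0, 195.0)
    ari_ss_e = np.clip(kin.ari_ss_ms
                       + rng.normal(0, kin.ari_ss_within_sd, n_el),
                       140.0, 300.0)

    if kin.mid_true is not None:
        mid_e = np.clip(kin.mid_true
                        + rng.normal(0, kin.mid_within_sd, n_el), 0.0, None)
        mid_e += kin.mid_true - mid_e.mean()   # patient mean exact
        delay_maps = [invert_mid_delays(protocol, m) for m in mid_e]
        delta_at_e = np.array([dm[min(dm)] for dm in delay_maps])
    else:
        delta_at_e = np.clip(kin.delta_at_preverp_ms
                             + rng.normal(0, kin.delta_at_within_sd, n_el),
                             0.5, None)
        delay_maps = None
    delta_rt_e = (kin.delta_rt_preverp_ms
                  + rng.normal(0, kin.delta_rt_within_sd, n_el))
    ari_pre_e = np.clip(ari_ss_e + (delta_rt_e - delta_at_e), 100.0, 320.0)
    delta_rt_e = ari_pre_e - ari_ss_e + delta_at_e

    def delay(ie: int, ci: float) -> float:
        if delay_maps is not None:
            return delay_maps[ie].get(round(ci, 3), 0.0) \
                if ci <= 300.0 + 1e-9 else 0.0
        return float(exponential_delay(ci, pre_ci, delta_at_e[ie],
                                       kin.at_delay_tau_ms))

    # ARI restitution ARI(DI) = ari_max - a * exp(-DI / tau); the (signed)
    # amplitude is solved from the steady and pre-VERP prescriptions.
    tau = kin.ari_tau_ms
    di_ss_e = 400.0 - ari_ss_e
    di_pre_e = np.maximum(pre_ci + delta_at_e - ari_ss_e, 10.0)
    denom = np.exp(-di_ss_e / tau) - np.exp(-di_pre_e / tau)
    a_e = np.where(np.abs(denom) > 1e-12,
                   (ari_pre_e - ari_ss_e) / denom, 0.0)
    ari_max_e = ari_ss_e + a_e * np.exp(-di_ss_e / tau)

    def ari_of(ie: int, ci: float) -> float:
        di = max(ci + delay(ie, ci) - ari_ss_e[ie], 10.0)
        return float(ari_max_e[ie] - a_e[ie] * math.exp(-di / tau))

    lam_ss = max(kin.frac_mean_ss - 1.0, 0.0)
    lam_pre = max(kin.frac_mean_preverp - 1.0, 0.0)
    lam_sin = max(kin.frac_mean_sinus - 1.0, 0.0)

    def lam_of(ci: float) -> float:
        if ci >= 400.0:
            return lam_ss
        span = max(400.0 - pre_ci, 1.0)
        f = np.clip((400.0 - ci) / span, 0.0, 1.0)
        return float(lam_ss + (lam_pre - lam_ss) * f)

    record = PatientRecord(patient_id=patient_id, group=group,
                           electrode_map=emap, protocol=protocol)
    per_beat_rows: list[dict] = []
    ids = emap.ids
    dt = 1000.0 / fs

    def make_spec(ie: int, at: float, rt: float, n_def: int,
                  t_pol: int | None = None) -> EgmMorphologySpec:
        return EgmMorphologySpec(
            at_true_ms=at, rt_true_ms=rt, n_extra_deflections=n_def,
            noise_sd_mv=kin.noise_sd_mv,
            t_polarity=t_pol if t_pol is not None else kin.t_polarity)

    def synth_trace(specs_by_stim: list[tuple[float, EgmMorphologySpec,
                                              bool]],
                    t0: float, duration: float, cid: str) -> SignalTrace:
        n = int(round(duration / dt))
        t = t0 + np.arange(n) * dt
        v = np.zeros(n)
        for stim_ms, spec, with_beat in specs_by_stim:
            if with_beat:
                _add_beat(v, t, stim_ms, spec, rng)
            elif spec.stimulus_amplitude_mv:
                a = spec.stimulus_amplitude_mv
                v += a * np.exp(-((t - stim_ms - 0.3) ** 2) / (2 * 0.3 ** 2))
                v -= a * np.exp(-((t - stim_ms - 1.0) ** 2) / (2 * 0.3 ** 2))
        if kin.noise_sd_mv > 0:
            v += rng.normal(0.0, kin.noise_sd_mv, n)
        return SignalTrace(cid, fs, t0, v)

    # --- steady-state epoch ----------------------------------------------
    for rep in range(1, steady_repeats + 1):
        for ie, eid in enumerate(ids):
            at, ari = float(at_ss_e[ie]), float(ari_ss_e[ie])
            n_def = min(int(rng.poisson(lam_ss)),
                        len(available_deflection_slots(at)))
            per_beat_rows.append(dict(state="steady", train=-rep,
                                      electrode_id=eid, coupling_ms=400.0,
                                      captured=True, at_true=at,
                                      rt_true=at + ari,
                                      n_deflections=1 + n_def))
            if include_waveforms:
                spec = make_spec(ie, at, at + ari, n_def)
                record.steady_traces[(rep, eid)] = synth_trace(
                    [(0.0, spec, True)], -120.0, 740.0, eid)

    # --- sinus epoch ------------------------------------------------------
    sinus_at_e = (kin.sinus_base_at_ms + kin.sinus_at_span_ms * z_norm
                  + rng.normal(0, 1.5, n_el))
    sinus_ari_e = np.clip(kin.sinus_rt_ms - float(np.mean(sinus_at_e))
                          + rng.normal(0, 8.0, n_el), 80.0, 420.0)
    for rep in range(1, sinus_beats + 1):
        jitter = rng.normal(0, 0.4, n_el)
        for ie, eid in enumerate(ids):
            at = float(sinus_at_e[ie] + jitter[ie])
            rt = at + float(sinus_ari_e[ie])
            n_def = min(int(rng.poisson(lam_sin)),
                        len(available_deflection_slots(at)))
            per_beat_rows.append(dict(state="sinus", train=-10 - rep,
                                      electrode_id=eid, coupling_ms=np.nan,
                                      captured=True, at_true=at, rt_true=rt,
                                      n_deflections=1 + n_def))
            if include_waveforms:
                spec = replace(make_spec(ie, at, rt, n_def),
                               stimulus_amplitude_mv=0.0)
                record.sinus_traces[(rep, eid)] = synth_trace(
                    [(0.0, spec, True)], -120.0, 740.0, eid)

    # --- S1S2 trains ------------------------------------------------------
    for ev in protocol.events:
        ci = ev.coupling_ms
        record.train_couplings[ev.train] = ci
        for ie, eid in enumerate(ids):
            at1 = float(at_ss_e[ie])
            s1_spec = make_spec(ie, at1, at1 + float(ari_ss_e[ie]), 0)
            at2 = at1 + delay(ie, ci)
            # floor keeps extreme restitution tails inside the detectable
            # repolarization window (ARI below ~100 ms is outside the
            # physiological range of this preparation)
            rt2 = at2 + max(ari_of(ie, ci), 100.0)
            n_def = min(int(rng.poisson(lam_of(ci))),
                        len(available_deflection_slots(at2)))
            per_beat_rows.append(dict(state="s1s2", train=ev.train,
                                      electrode_id=eid, coupling_ms=ci,
                                      captured=ev.captured, at_true=at2
                                      if ev.captured else np.nan,
                                      rt_true=rt2 if ev.captured else np.nan,
                                      n_deflections=(1 + n_def)
                                      if ev.captured else 0))
            if include_waveforms:
                s2_spec = make_spec(ie, at2, rt2, n_def)
                record.train_traces[(ev.train, eid)] = synth_trace(
                    [(-ci, s1_spec, True), (0.0, s2_spec, ev.captured)],
                    -ci - 120.0, ci + 740.0, eid)

    # --- paced surface ECG ------------------------------------------------
    if kin.ecg_landmarks:
        record.ecg_traces = synth_paced_ecg(
            kin.ecg_landmarks, fs=ecg_fs, noise_sd_mv=kin.noise_sd_mv,
            rng=rng)

    per_el = pd.DataFrame({
        "electrode_id": ids, "at_ss": at_ss_e, "ari_ss": ari_ss_e,
        "delta_at": delta_at_e, "delta_rt": delta_rt_e,
        "ari_amplitude": a_e,
        "mid": mid_e if kin.mid_true is not None else np.nan,
        "sinus_at": sinus_at_e,
    })
    record.truth = GroundTruth(kinetics=kin, per_electrode=per_el,
                               per_beat=pd.DataFrame(per_beat_rows))
    return record


def beat_table_from_truth(record: PatientRecord) -> pd.DataFrame:
    """Ground-truth beat table in the same layout as waveform extraction.

    Used for curve-level studies (and as the noiseless oracle in tests):
    activation/repolarization times are the generator's prescriptions, DI
    follows the same A1A2 - steady-ARI rule applied to the true values.
    """
    gt: GroundTruth = record.truth
    kin = gt.kinetics
    pb = gt.per_beat
    steady = pb[pb.state == "steady"].groupby("electrode_id").agg(
        at_true=("at_true", "mean"), rt_true=("rt_true", "mean"))
    rows = []
    for r in pb.itertuples():
        at = r.at_true
        rt = r.rt_true
        ari = rt - at if np.isfinite(rt) else np.nan
        di = np.nan
        if r.state == "s1s2" and r.captured and \
                r.electrode_id in steady.index:
            s = steady.loc[r.electrode_id]
            a1a2 = r.coupling_ms + at - s.at_true
            di = a1a2 - (s.rt_true - s.at_true)
        rows.append(dict(patient_id=record.patient_id,
                         electrode_id=r.electrode_id, train=r.train,
                         state=r.state, coupling_ms=r.coupling_ms,
                         captured=r.captured, at_ms=at, rt_ms=rt,
                         ari_ms=ari, di_ms=di, at_s1_ms=np.nan,
                         frac=float(r.n_deflections)
                         if r.n_deflections else np.nan,
                         qc_flags=""))
    df = pd.DataFrame(rows)
    df["group"] = record.group
    return df


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSpec:
    """Specification of one synthetic patient group.

    ``params`` follows the layout of :data:`rvdyn.calibration.GROUP_DEFAULTS`
    (``(mean, sd)`` tuples, lognormal blocks, nested ECG blocks); omitted
    entries fall back to the group defaults.  ``between_fraction`` is the
    share of each parameter's variance attributed to between-patient
    differences.  ``sampling`` is ``iid`` or ``stratified``
    (permuted-quantile draws — lower Monte-Carlo noise in cohort-level
    means, still marginally distributed as specified).
    """

    group: str = "definite_arvc"
    n_patients: int = 12
    params: dict = field(default_factory=dict)
    between_fraction: float = calibration.BETWEEN_PATIENT_VARIANCE_FRACTION
    sampling: str = "iid"
    prescribe_mid: bool = False
    noise_sd_mv: float = 0.02
    include_ecg: bool = True

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.sampling not in ("iid", "stratified"):
            raise ValueError("sampling must be 'iid' or 'stratified'")
        merged = {**calibration.GROUP_DEFAULTS[self.group], **self.params}
        for key, val in merged.items():
            if isinstance(val, tuple) and len(val) == 2 and val[1] < 0:
                raise ValueError(f"negative sd for {key}")
        self.params = merged


def _quantiles(n: int, rng: np.random.Generator,
               stratified: bool) -> np.ndarray:
    if not stratified:
        return rng.uniform(size=n)
    u = (rng.permutation(n) + rng.uniform(0.02, 0.98, n)) / n
    return u


def _draw_normal(mean_sd: tuple[float, float], n: int,
                 rng: np.random.Generator, lo: float = -np.inf,
                 hi: float = np.inf, stratified: bool = False) -> np.ndarray:
    mean, sd = mean_sd
    if sd == 0:
        return np.full(n, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = _quantiles(n, rng, stratified)
    return sstats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _draw_lognormal(block: dict, n: int, rng: np.random.Generator,
                    hi: float = np.inf,
                    stratified: bool = False) -> np.ndarray:
    mu, sigma = calibration.lognormal_params(block["median"],
                                             tuple(block["iqr"]))
    u = _quantiles(n, rng, stratified)
    if np.isfinite(hi):
        u = u * sstats.lognorm.cdf(hi, sigma, scale=math.exp(mu))
    return sstats.lognorm.ppf(u, sigma, scale=math.exp(mu))


def _ordered_landmarks(lm: dict[str, float],
                       fixed: str = "j_point") -> tuple[float, ...]:
    """Enforce detectability margins without moving the ``fixed`` landmark."""
    lat = max(lm["latency"], 16.0)
    j = max(lm["j_point"], lat + 35.0)
    if fixed == "j_point" and j != lm["j_point"]:
        lat = min(lat, lm["j_point"] - 35.0)
        j = lm["j_point"]
    qp = float(np.clip(lm["qrs_peak"], lat + 15.0, j - 18.0))
    te = max(lm["t_end"], j + 95.0)
    tp = float(np.clip(lm["t_peak"], j + 55.0, te - 35.0))
    return (lat, qp, j, tp, te)


def draw_patient_kinetics(spec: CohortSpec, n: int,
                          rng: np.random.Generator) -> list[PatientKinetics]:
    """Draw ``n`` patients' kinetics from the group-level distributions."""
    p = spec.params
    bf = math.sqrt(spec.between_fraction)
    wf = math.sqrt(max(1.0 - spec.between_fraction, 0.0))
    strat = spec.sampling == "stratified"

    def b(key):  # between-patient (mean, sd)
        mean, sd = p[key]
        return mean, sd * bf

    verp = _draw_normal(b("verp"), n, rng, 158.0, 302.0, strat)
    at_ss = _draw_normal(b("at_ss"), n, rng, 30.0, 140.0)
    ari_ss = _draw_normal(b("ari_ss"), n, rng, 150.0, 270.0)
    d_at = _draw_normal(b("delta_at_preverp"), n, rng, 1.0, 130.0, strat)
    d_rt = _draw_normal(b("delta_rt_preverp"), n, rng, -90.0, 90.0, strat)
    f_ss = _draw_normal(b("frac_ss"), n, rng, 1.0, 7.0, strat)
    f_pre = _draw_normal(b("frac_preverp"), n, rng, 1.0, 7.0)
    f_sin = _draw_normal(b("frac_sinus"), n, rng, 1.0, 7.0)
    span = _draw_normal(b("sinus_at_span"), n, rng, 20.0, 150.0)
    s_rt = _draw_normal(b("sinus_rt"), n, rng, 180.0, 460.0)
    mids = _draw_lognormal(p["mid"], n, rng, hi=60.0, stratified=strat) \
        if spec.prescribe_mid else [None] * n
    # headline ECG feature drawn as a vector so stratification applies
    hj = _draw_normal((p["ecg_hysteresis"]["j_point"][0],
                       p["ecg_hysteresis"]["j_point"][1] * bf),
                      n, rng, stratified=strat)

    kinetics = []
    for i in range(n):
        ecg = None
        if spec.include_ecg:
            st = {k: float(_draw_normal((m, s * bf), 1, rng)[0])
                  for k, (m, s) in p["ecg_steady"].items()}
            hy = {k: float(_draw_normal((m, s * bf), 1, rng)[0])
                  for k, (m, s) in p["ecg_hysteresis"].items()}
            hy["j_point"] = float(hj[i])
            pre = {k: st[k] + hy[k] for k in st}
            ecg = {"steady": _ordered_landmarks(st),
                   "pre_erp": _ordered_landmarks(pre)}
        sd = {k: p[k][1] * wf for k in
              ("at_ss", "ari_ss", "delta_at_preverp", "delta_rt_preverp")}
        kinetics.append(PatientKinetics(
            verp_true_ms=float(verp[i]), at_ss_ms=float(at_ss[i]),
            ari_ss_ms=float(ari_ss[i]),
            delta_at_preverp_ms=float(d_at[i]),
            delta_rt_preverp_ms=float(d_rt[i]),
            mid_true=None if mids[i] is None else float(mids[i]),
            frac_mean_ss=float(f_ss[i]), frac_mean_preverp=float(f_pre[i]),
            frac_mean_sinus=float(f_sin[i]),
            sinus_at_span_ms=float(span[i]), sinus_rt_ms=float(s_rt[i]),
            ecg_landmarks=ecg,
            # most steady-AT spread is the systematic base-to-apex gradient
            at_ss_within_sd=sd["at_ss"] * 0.3,
            ari_ss_within_sd=sd["ari_ss"],
            delta_at_within_sd=sd["delta_at_preverp"],
            delta_rt_within_sd=sd["delta_rt_preverp"],
            noise_sd_mv=spec.noise_sd_mv))
    return kinetics


def synth_cohort(spec: CohortSpec, rng: np.random.Generator | None = None,
                 include_waveforms: bool = True, fs: float = 1200.0,
                 protocol_kwargs: dict | None = None) -> list[PatientRecord]:
    """Generate a cohort of patient records (reproducible for a fixed rng)."""
    rng = rng or np.random.default_rng(0)
    emap = build_electrode_map()
    kins = draw_patient_kinetics(spec, spec.n_patients, rng)
    records = []
    for i, kin in enumerate(kins):
        records.append(synth_restitution_dataset(
            kin, emap, protocol_kwargs=protocol_kwargs, fs=fs, rng=rng,
            patient_id=f"{spec.group[:3].upper()}{i:03d}", group=spec.group,
            include_waveforms=include_waveforms))
    return records
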