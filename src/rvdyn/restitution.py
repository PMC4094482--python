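"""Restitution-curve assembly and dynamic conduction/repolarization metrics.

From the per-beat measurement table this module builds one restitution
curve per electrode (activation time, repolarization time, ARI and
diastolic interval against the S1S2 coupling interval, with steady-state
pacing references) and computes the study's dynamic metrics:

* pre-VERP changes in activation and repolarization time relative to
  steady-state pacing;
* the maximum ARI restitution slope (steepest least-squares line over a
  sliding window of points sorted by diastolic interval);
* the mean increase in delay (MID), the mean per-millisecond growth of
  activation delay over the fine scan of the extrastimulus protocol;
* sinus-rhythm RV activation time (latest minus earliest local AT);
* dispersion of repolarization (range of RT across electrodes);
* the activation-gradient statistics: slowest wavefront speed along
  adjacent electrode pairs, and the beat-to-beat consistency r^2 of the
  activation map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ElectrodeMap, RestitutionCurve, StimulusProtocol


@dataclass
class RestitutionMetrics:
    electrode_id: str
    max_ari_slope: float | None = None
    mid: float | None = None
    delta_at_preverp_ms: float | None = None
    delta_rt_preverp_ms: float | None = None
    at_preverp_ms: float | None = None
    rt_preverp_ms: float | None = None
    frac_ss: float | None = None
    frac_preverp: float | None = None


@dataclass
class ActivationMapStats:
    slowest_gradient_mm_per_ms: float
    r2: float
    rv_activation_time_ms: float | None = None
    rt_dispersion_ms: float | None = None


def assemble_curves(beat_table: pd.DataFrame,
                    protocol: StimulusProtocol,
                    min_points: int = 4) -> dict[str, RestitutionCurve]:
    """One restitution curve per electrode from the per-beat table.

    Repeated measurements at the same coupling interval are averaged.
    Steady-state references come from the 400 ms steady-pacing epoch.
    Electrodes with fewer than ``min_points`` valid capturing points are
    excluded.  Beats flagged ``EncroachingDI`` keep their AT/RT point but
    contribute no DI (they are excluded from ARI-restitution fitting).
    """
    curves: dict[str, RestitutionCurve] = {}
    steady = beat_table[beat_table.state == "steady"]
    s2 = beat_table[(beat_table.state == "s1s2") & beat_table.captured
                    & np.isfinite(beat_table.at_ms)]
    for eid, grp in s2.groupby("electrode_id", sort=True):
        ref = steady[steady.electrode_id == eid]
        if ref.empty or not np.isfinite(ref.at_ms).any():
            continue
        points = []
        for ci, sub in grp.groupby("coupling_ms"):
            di = sub.di_ms.where(sub.di_ms > 0)
            points.append({
                "coupling_ms": float(ci),
                "at_ms": float(np.nanmean(sub.at_ms)),
                "rt_ms": float(np.nanmean(sub.rt_ms))
                if np.isfinite(sub.rt_ms).any() else np.nan,
                "ari_ms": float(np.nanmean(sub.ari_ms))
                if np.isfinite(sub.ari_ms).any() else np.nan,
                "di_ms": float(np.nanmean(di)) if np.isfinite(di).any()
                else np.nan,
            })
        if len(points) < min_points:
            continue

        def ref_mean(col: pd.Series) -> float:
            vals = col[np.isfinite(col)]
            return float(vals.mean()) if len(vals) else np.nan

        curves[eid] = RestitutionCurve(
            electrode_id=eid, points=points,
            steady_at_ms=ref_mean(ref.at_ms),
            steady_rt_ms=ref_mean(ref.rt_ms),
            steady_ari_ms=ref_mean(ref.ari_ms))
    return curves


def max_ari_restitution_slope(curve: RestitutionCurve,
                              window: int = 5,
                              min_span_ms: float = 10.0) -> float | None:
    """Maximum least-squares ARI-restitution slope (dimensionless).

    Points are sorted by ascending diastolic interval; a straight line is
    fitted over every sliding window of ``window`` consecutive points whose
    DI span is at least ``min_span_ms``, and the maximum fitted slope is
    returned.  Returns None with fewer than ``window`` valid points or no
    window of sufficient span.
    """
    di = curve.column("di_ms")
    ari = curve.column("ari_ms")
    ok = np.isfinite(di) & np.isfinite(ari) & (di > 0)
    di, ari = di[ok], ari[ok]
    if di.size < window:
        return None
    order = np.argsort(di, kind="stable")
    di, ari = di[order], ari[order]
    best: float | None = None
    for i in range(di.size - window + 1):
        x = di[i:i + window]
        y = ari[i:i + window]
        if x[-1] - x[0] < min_span_ms:
            continue
        slope = np.polyfit(x, y, 1)[0]
        if best is None or slope > best:
            best = float(slope)
    return best


def mean_increase_in_delay(curve: RestitutionCurve,
                           fine_scan_start_ms: float = 300.0,
                           kappa: float = 1.0,
                           min_points: int = 3) -> float | None:
    """Mean increase in delay over the fine scan (ms of delay per ms of
    coupling-interval reduction, scaled by ``kappa``).

    With delay d(ci) = AT(ci) - steady AT, the per-step rate between
    successive capturing fine-scan points (ci <= ``fine_scan_start_ms``)
    is r_j = [d(c_{j+1}) - d(c_j)] / (c_j - c_{j+1}) for points sorted by
    descending ci; MID = kappa * mean(r_j).  Returns None with fewer than
    ``min_points`` capturing fine-scan points.

    ``kappa`` is exposed because published values of this metric have been
    printed in inconsistent units; the default of 1 reports plain ms/ms.
    """
    ci = curve.column("coupling_ms")
    at = curve.column("at_ms")
    ok = np.isfinite(at) & (ci <= fine_scan_start_ms + 1e-9)
    ci, at = ci[ok], at[ok]
    if ci.size < min_points:
        return None
    order = np.argsort(-ci, kind="stable")
    ci, at = ci[order], at[order]
    d = at - curve.steady_at_ms
    rates = (d[1:] - d[:-1]) / (ci[:-1] - ci[1:])
    return float(kappa * np.mean(rates))


def delta_pre_verp(curve: RestitutionCurve, protocol: StimulusProtocol,
                   tol_ms: float = 0.5):
    """(delta_at, delta_rt, at_preverp, rt_preverp) at the pre-VERP beat.

    Returns a 4-tuple of Nones when the curve has no point at the
    protocol's pre-VERP coupling interval.
    """
    ci = curve.column("coupling_ms")
    i = np.flatnonzero(np.abs(ci - protocol.pre_verp_ci_ms) <= tol_ms)
    if i.size == 0:
        return None, None, None, None
    p = curve.points[int(i[0])]
    at, rt = p["at_ms"], p["rt_ms"]
    delta_at = at - curve.steady_at_ms if np.isfinite(at) else None
    delta_rt = rt - curve.steady_rt_ms if np.isfinite(rt) else None
    return (delta_at, delta_rt,
            at if np.isfinite(at) else None,
            rt if np.isfinite(rt) else None)


def sinus_rv_activation_time(sinus_at_ms) -> float:
    """RV activation time in sinus rhythm: latest minus earliest local AT."""
    at = np.asarray([a for a in sinus_at_ms if np.isfinite(a)], dtype=float)
    if at.size < 2:
        raise ValueError("need sinus AT from at least 2 electrodes")
    return float(at.max() - at.min())


def repolarization_dispersion(rt_ms) -> float:
    """Dispersion of repolarization: range of RT across electrodes."""
    rt = np.asarray([r for r in rt_ms if np.isfinite(r)], dtype=float)
    if rt.size < 2:
        raise ValueError("need RT from at least 2 electrodes")
    return float(rt.max() - rt.min())


def activation_gradient_consistency(
        beat_at_maps: list[dict[str, float]],
        electrode_map: ElectrodeMap,
        min_dt_ms: float = 1.0) -> ActivationMapStats:
    """Slowest activation gradient and beat-to-beat consistency r^2.

    For each beat, the apparent wavefront speed along every adjacent
    electrode pair is distance / |dAT| (pairs with |dAT| below
    ``min_dt_ms`` or coincident electrodes are skipped); the slowest pair
    speed is averaged over beats.  r^2 is the squared Pearson correlation
    between the electrode-AT vectors of successive beats, averaged over
    beat pairs (1.0 for a single beat).

    This is a simplification of the published activation-gradient
    quantification algorithm; see docs/methods.md.
    """
    if not beat_at_maps:
        raise ValueError("need at least one activation map")
    pos = {e.electrode_id: np.asarray(e.position_mm)
           for e in electrode_map.electrodes}
    pairs = electrode_map.adjacent_pairs()
    slowest: list[float] = []
    for at_map in beat_at_maps:
        speeds = []
        for a, b in pairs:
            if a not in at_map or b not in at_map:
                continue
            dist = float(np.linalg.norm(pos[a] - pos[b]))
            dt = abs(at_map[a] - at_map[b])
            if dist <= 0 or dt < min_dt_ms:
                continue
            speeds.append(dist / dt)
        if speeds:
            slowest.append(min(speeds))
    ids = sorted(set.intersection(*(set(m) for m in beat_at_maps)))
    r2s = []
    for m1, m2 in zip(beat_at_maps, beat_at_maps[1:]):
        v1 = np.array([m1[i] for i in ids])
        v2 = np.array([m2[i] for i in ids])
        if np.std(v1) == 0 or np.std(v2) == 0:
            r2s.append(1.0 if np.allclose(v1, v2) else 0.0)
        else:
            r2s.append(float(np.corrcoef(v1, v2)[0, 1] ** 2))
    return ActivationMapStats(
        slowest_gradient_mm_per_ms=float(np.mean(slowest)) if slowest
        else np.nan,
        r2=float(np.mean(r2s)) if r2s else 1.0)


# ---------------------------------------------------------------------------
# Patient-level aggregation


def patient_metrics(beat_table: pd.DataFrame, protocol: StimulusProtocol,
                    electrode_map: ElectrodeMap | None = None,
                    kappa: float = 1.0) -> dict:
    """Aggregate one patient's beat table into scalar metrics.

    Electrode-level metrics are averaged globally and per region; the
    measured VERP is re-derived from the waveform-level capture outcomes
    (longest tested non-capturing interval).  RT dispersion is emitted for
    both the steady state and the pre-VERP beat.
    """
    curves = assemble_curves(beat_table, protocol)
    s2 = beat_table[beat_table.state == "s1s2"]
    per_ci = s2.groupby("coupling_ms").captured.any()
    failed = per_ci[~per_ci]
    verp_measured = float(failed.index.max()) if len(failed) else np.nan
    captured_ci = per_ci[per_ci]
    pre_verp_measured = (float(captured_ci.index.min())
                         if len(captured_ci) else np.nan)

    delta_at, delta_rt, at_pre, rt_pre, mids, slopes = [], [], [], [], [], []
    steady_rt, pre_rt = [], []
    for eid, curve in curves.items():
        da, dr, ap, rp = delta_pre_verp(curve, protocol)
        if da is not None:
            delta_at.append(da)
            at_pre.append(ap)
        if dr is not None:
            delta_rt.append(dr)
            pre_rt.append(rp)
        m = mean_increase_in_delay(curve, kappa=kappa)
        if m is not None:
            mids.append(m)
        s = max_ari_restitution_slope(curve)
        if s is not None:
            slopes.append(s)
        steady_rt.append(curve.steady_rt_ms)

    steady = beat_table[beat_table.state == "steady"]
    sinus = beat_table[beat_table.state == "sinus"]
    frac_ss = steady.frac.dropna()
    frac_pre = s2[np.isfinite(s2.frac)].frac
    frac_sinus = sinus.frac.dropna()

    out = {
        "patient_id": beat_table.patient_id.iloc[0],
        "group": beat_table.group.iloc[0] if "group" in beat_table else None,
        "verp_ms": verp_measured,
        "pre_verp_ci_ms": pre_verp_measured,
        "n_electrodes": len(curves),
        "delta_at_preverp_ms": float(np.mean(delta_at)) if delta_at else np.nan,
        "delta_rt_preverp_ms": float(np.mean(delta_rt)) if delta_rt else np.nan,
        "at_preverp_ms": float(np.mean(at_pre)) if at_pre else np.nan,
        "rt_preverp_ms": float(np.mean(pre_rt)) if pre_rt else np.nan,
        "steady_at_ms": float(np.nanmean(steady.at_ms)) if len(steady) else np.nan,
        "steady_rt_ms": float(np.nanmean(steady.rt_ms)) if len(steady) else np.nan,
        "steady_ari_ms": float(np.nanmean(steady.ari_ms)) if len(steady) else np.nan,
        "mid": float(np.mean(mids)) if mids else np.nan,
        "max_ari_slope": float(np.mean(slopes)) if slopes else np.nan,
        "frac_ss": float(frac_ss.mean()) if len(frac_ss) else np.nan,
        "frac_preverp": float(frac_pre.mean()) if len(frac_pre) else np.nan,
        "frac_sinus": float(frac_sinus.mean()) if len(frac_sinus) else np.nan,
    }

    # region-level means of the pre-VERP delay
    if electrode_map is not None:
        region_of = {e.electrode_id: e.region
                     for e in electrode_map.electrodes}
        by_region: dict[str, list[float]] = {}
        for eid, curve in curves.items():
            da, _, _, _ = delta_pre_verp(curve, protocol)
            if da is not None and eid in region_of:
                by_region.setdefault(region_of[eid], []).append(da)
        for region, vals in by_region.items():
            out[f"delta_at_preverp_{region}_ms"] = float(np.mean(vals))

    # sinus metrics
    if len(sinus):
        first_beat = sinus[sinus.train == sinus.train.min()]
        at_map = first_beat.set_index("electrode_id").at_ms
        if np.isfinite(at_map).sum() >= 2:
            out["sinus_activation_time_ms"] = sinus_rv_activation_time(at_map)
        rt_map = first_beat.set_index("electrode_id").rt_ms
        if np.isfinite(rt_map).sum() >= 2:
            out["sinus_rt_ms"] = float(np.nanmean(rt_map))
            out["sinus_rt_dispersion_ms"] = repolarization_dispersion(rt_map)
        if electrode_map is not None:
            maps = []
            for t, beat in sinus.groupby("train"):
                m = {r.electrode_id: r.at_ms for r in beat.itertuples()
                     if np.isfinite(r.at_ms)}
                if len(m) >= 4:
                    maps.append(m)
            if maps:
                stats = activation_gradient_consistency(maps, electrode_map)
                out["slowest_gradient_mm_per_ms"] = \
                    stats.slowest_gradient_mm_per_ms
                out["activation_r2"] = stats.r2

    # RT dispersion at steady state and pre-VERP
    if len(steady_rt) >= 2:
        out["rt_dispersion_steady_ms"] = repolarization_dispersion(steady_rt)
    if len(pre_rt) >= 2:
        out["rt_dispersion_preverp_ms"] = repolarization_dispersion(pre_rt)
    return out
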