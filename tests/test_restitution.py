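"""Restitution metrics: oracle equivalences and inversion checks."""

import numpy as np
import pandas as pd
import pytest

from rvdyn.core import RestitutionCurve, generate_s2_schedule
from rvdyn.restitution import (activation_gradient_consistency,
                               assemble_curves, delta_pre_verp,
                               max_ari_restitution_slope,
                               mean_increase_in_delay, patient_metrics,
                               repolarization_dispersion,
                               sinus_rv_activation_time)
from rvdyn.synth import (PatientKinetics, beat_table_from_truth,
                         invert_mid_delays, synth_restitution_dataset)


def curve_from_arrays(ci, at=None, ari=None, di=None, rt=None,
                      steady_at=75.0, steady_rt=278.0, steady_ari=203.0):
    n = len(ci)
    at = at if at is not None else [steady_at] * n
    ari = ari if ari is not None else [steady_ari] * n
    di = di if di is not None else [c - steady_ari for c in ci]
    rt = rt if rt is not None else [a + r for a, r in zip(at, ari)]
    points = [dict(coupling_ms=c, at_ms=a, rt_ms=r, ari_ms=x, di_ms=d)
              for c, a, r, x, d in zip(ci, at, rt, ari, di)]
    return RestitutionCurve("E", points, steady_at, steady_rt, steady_ari)


class TestAssembleCurves:
    def test_repeats_averaged(self):
        rows = []
        for at in (100.0, 101.0, 99.0, 100.0):
            rows.append(dict(patient_id="p", electrode_id="E1", train=1,
                             state="s1s2", coupling_ms=300.0, captured=True,
                             at_ms=at, rt_ms=at + 200, ari_ms=200.0,
                             di_ms=100.0, at_s1_ms=75.0, frac=np.nan,
                             qc_flags="", group="normal"))
        for ci in (400.0, 380.0, 360.0, 340.0):
            rows.append(dict(patient_id="p", electrode_id="E1", train=2,
                             state="s1s2", coupling_ms=ci, captured=True,
                             at_ms=100.0, rt_ms=300.0, ari_ms=200.0,
                             di_ms=ci - 200, at_s1_ms=75.0, frac=np.nan,
                             qc_flags="", group="normal"))
        rows.append(dict(patient_id="p", electrode_id="E1", train=-1,
                         state="steady", coupling_ms=400.0, captured=True,
                         at_ms=75.0, rt_ms=275.0, ari_ms=200.0,
                         di_ms=np.nan, at_s1_ms=np.nan, frac=np.nan,
                         qc_flags="", group="normal"))
        protocol = generate_s2_schedule(lambda ci: ci >= 280)
        curves = assemble_curves(pd.DataFrame(rows), protocol)
        pt = [p for p in curves["E1"].points if p["coupling_ms"] == 300.0]
        assert pt[0]["at_ms"] == pytest.approx(100.0)
        # sorted by descending coupling interval
        cis = curves["E1"].column("coupling_ms")
        assert list(cis) == sorted(cis, reverse=True)

    def test_sparse_electrode_excluded(self):
        rows = [dict(patient_id="p", electrode_id="E1", train=1,
                     state="s1s2", coupling_ms=300.0, captured=True,
                     at_ms=100.0, rt_ms=300.0, ari_ms=200.0, di_ms=100.0,
                     at_s1_ms=75.0, frac=np.nan, qc_flags="",
                     group="normal"),
                dict(patient_id="p", electrode_id="E1", train=-1,
                     state="steady", coupling_ms=400.0, captured=True,
                     at_ms=75.0, rt_ms=275.0, ari_ms=200.0, di_ms=np.nan,
                     at_s1_ms=np.nan, frac=np.nan, qc_flags="",
                     group="normal")]
        protocol = generate_s2_schedule(lambda ci: ci >= 280)
        assert assemble_curves(pd.DataFrame(rows), protocol) == {}


class TestAriSlope:
    def test_linear_curve(self):
        di = np.arange(40.0, 240.0, 10.0)
        ari = 150.0 + 0.8 * di
        c = curve_from_arrays(ci=di + 203.0, di=list(di), ari=list(ari))
        assert max_ari_restitution_slope(c) == pytest.approx(0.8, abs=0.01)

    def test_flat_curve(self):
        di = np.arange(40.0, 240.0, 10.0)
        c = curve_from_arrays(ci=di + 203.0, di=list(di),
                              ari=[200.0] * len(di))
        assert max_ari_restitution_slope(c) == pytest.approx(0.0, abs=1e-9)

    def test_exponential_matches_exhaustive_windows(self):
        """The sliding-window implementation equals brute-force window
        enumeration on an exponential restitution curve."""
        di = np.arange(40.0, 230.0, 10.0)
        ari = 250.0 - 100.0 * np.exp(-di / 60.0)
        c = curve_from_arrays(ci=di + 203.0, di=list(di), ari=list(ari))
        # independent oracle: enumerate every 5-point window directly
        best = -np.inf
        for i in range(len(di) - 4):
            x, y = di[i:i + 5], ari[i:i + 5]
            if x[-1] - x[0] < 10:
                continue
            xm, ym = x.mean(), y.mean()
            slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
            best = max(best, slope)
        assert max_ari_restitution_slope(c) == pytest.approx(best,
                                                             rel=1e-9)

    def test_insufficient_points(self):
        c = curve_from_arrays(ci=[300.0, 290.0, 280.0],
                              di=[97.0, 87.0, 77.0])
        assert max_ari_restitution_slope(c) is None


class TestMeanIncreaseInDelay:
    def test_constant_rate(self):
        """Delay linear in coupling interval with slope -0.5 ms/ms."""
        ci = list(np.arange(300.0, 210.0, -5.0))
        at = [75.0 + 0.5 * (300.0 - c) for c in ci]
        c = curve_from_arrays(ci=ci, at=at)
        assert mean_increase_in_delay(c) == pytest.approx(0.5, abs=1e-9)

    def test_zero_delay(self):
        ci = list(np.arange(300.0, 210.0, -5.0))
        c = curve_from_arrays(ci=ci)
        assert mean_increase_in_delay(c) == pytest.approx(0.0, abs=1e-12)

    def test_offset_invariance(self):
        """Adding a constant to every AT (including steady) leaves the
        metric unchanged."""
        ci = list(np.arange(300.0, 210.0, -5.0))
        at = [75.0 + 0.3 * (300.0 - c) ** 1.2 / 10 for c in ci]
        c1 = curve_from_arrays(ci=ci, at=at)
        c2 = curve_from_arrays(ci=ci, at=[a + 17.0 for a in at],
                               steady_at=75.0 + 17.0)
        assert mean_increase_in_delay(c1) == pytest.approx(
            mean_increase_in_delay(c2))

    def test_too_few_fine_points(self):
        c = curve_from_arrays(ci=[400.0, 380.0, 300.0, 295.0])
        assert mean_increase_in_delay(c) is None

    def test_inversion_round_trip(self):
        """Delay curves inverse-constructed for a prescribed MID value
        re-measure to that value through curve assembly."""
        kin = PatientKinetics(verp_true_ms=288.0, mid_true=7.0,
                              delta_rt_preverp_ms=0.0,
                              delta_rt_within_sd=0.0)
        rec = synth_restitution_dataset(kin, include_waveforms=False,
                                        rng=np.random.default_rng(5))
        m = patient_metrics(beat_table_from_truth(rec), rec.protocol,
                            rec.electrode_map)
        assert m["mid"] == pytest.approx(7.0, abs=0.2)

    def test_inversion_rejects_short_fine_scan(self):
        protocol = generate_s2_schedule(lambda ci: ci > 299)
        with pytest.raises(Exception, match="fine-scan"):
            invert_mid_delays(protocol, 7.0)


class TestDeltaPreVerp:
    def test_direct_subtraction(self):
        protocol = generate_s2_schedule(lambda ci: ci > 205)
        pre = protocol.pre_verp_ci_ms
        ci = [400.0, 300.0, 250.0, pre]
        c = curve_from_arrays(ci=ci, at=[75.0, 78.0, 90.0, 123.0],
                              rt=[278.0, 280.0, 285.0, 293.0])
        d_at, d_rt, at_p, rt_p = delta_pre_verp(c, protocol)
        assert d_at == pytest.approx(48.0)
        assert d_rt == pytest.approx(15.0)
        assert at_p == pytest.approx(123.0)

    def test_missing_pre_verp_point(self):
        protocol = generate_s2_schedule(lambda ci: ci > 205)
        c = curve_from_arrays(ci=[400.0, 300.0, 250.0])
        assert delta_pre_verp(c, protocol) == (None, None, None, None)


class TestMapMetrics:
    def test_sinus_activation_time(self):
        assert sinus_rv_activation_time([10.0, 40.0, 81.0]) == 71.0
        assert sinus_rv_activation_time([30.0, 30.0]) == 0.0
        with pytest.raises(ValueError):
            sinus_rv_activation_time([42.0])

    def test_repolarization_dispersion(self):
        assert repolarization_dispersion([200.0, 210.0, 250.0]) == 50.0
        assert repolarization_dispersion([200.0, 200.0]) == 0.0

    def test_plane_wave_gradient(self, default_map):
        """A plane wave along the long axis at 0.5 mm/ms: the slowest
        adjacent-pair speed is the true speed; duplicated beats give
        perfect consistency."""
        at_map = {e.electrode_id: e.position_mm[2] / 0.5
                  for e in default_map.electrodes}
        stats = activation_gradient_consistency([at_map, dict(at_map)],
                                                default_map)
        assert stats.slowest_gradient_mm_per_ms == pytest.approx(0.5,
                                                                 abs=0.05)
        assert stats.r2 == pytest.approx(1.0)

    def test_shuffled_maps_lose_consistency(self, default_map, rng):
        ids = [e.electrode_id for e in default_map.electrodes]
        base = rng.normal(50.0, 15.0, 24)
        r2s = []
        for _ in range(100):
            m1 = dict(zip(ids, rng.permutation(base)))
            m2 = dict(zip(ids, rng.permutation(base)))
            r2s.append(activation_gradient_consistency(
                [m1, m2], default_map).r2)
        assert np.mean(r2s) < 0.1

    def test_r2_bounds(self, default_map, rng):
        ids = [e.electrode_id for e in default_map.electrodes]
        for _ in range(10):
            maps = [dict(zip(ids, rng.normal(60, 20, 24)))
                    for _ in range(3)]
            r2 = activation_gradient_consistency(maps, default_map).r2
            assert 0.0 <= r2 <= 1.0


class TestPatientLevel:
    def test_measured_verp_matches_protocol(self, small_patient):
        rec, beats = small_patient
        m = patient_metrics(beats, rec.protocol, rec.electrode_map)
        assert m["verp_ms"] == rec.protocol.verp_ms
        assert m["pre_verp_ci_ms"] == rec.protocol.pre_verp_ci_ms

    def test_prescription_recovery(self, small_patient):
        """End-to-end waveform recovery of the prescribed patient-level
        pre-VERP changes within detector tolerance."""
        rec, beats = small_patient
        m = patient_metrics(beats, rec.protocol, rec.electrode_map)
        truth = rec.truth.per_electrode
        assert m["delta_at_preverp_ms"] == pytest.approx(
            truth.delta_at.mean(), abs=2.0)
        assert m["delta_rt_preverp_ms"] == pytest.approx(
            truth.delta_rt.mean(), abs=2.0)
        frac_true = rec.truth.per_beat.query(
            "state == 'steady'").n_deflections.mean()
        assert m["frac_ss"] == pytest.approx(frac_true, abs=0.25)
        assert m["sinus_activation_time_ms"] == pytest.approx(
            rec.truth.kinetics.sinus_at_span_ms, abs=8.0)
        assert m["activation_r2"] > 0.9
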