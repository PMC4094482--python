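"""Electrogram detectors against the waveform model and brute force."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rvdyn.egm import (FractionationParams,
                       NoActivationError, NoTWaveError,
                       TruncatedWindowError, compute_ari_di,
                       detect_activation_time, detect_repolarization_time,
                       fractionation_index)
from rvdyn.synth import EgmMorphologySpec, GeneratorError, synth_unipolar_egm


def make_beat(at=80.0, rt=280.0, fs=1200.0, noise=0.0, seed=0, **kw):
    spec = EgmMorphologySpec(at_true_ms=at, rt_true_ms=rt,
                             noise_sd_mv=noise, **kw)
    return synth_unipolar_egm(spec, 740.0, fs, np.random.default_rng(seed))


class TestActivationDetection:
    @pytest.mark.parametrize("at", [45.0, 80.0, 130.0])
    def test_noiseless_exact(self, at):
        tr = make_beat(at=at)
        assert detect_activation_time(tr, 0.0) == pytest.approx(at, abs=0.5)

    def test_matches_brute_force_argmin(self):
        """Smoothed-derivative timing equals the discrete-difference
        argmin on a noiseless trace (oracle equivalence)."""
        tr = make_beat(at=92.0, fs=2000.0)
        d = np.diff(tr.samples)
        i0, i1 = tr.index_of(5.0), tr.index_of(200.0)
        brute = tr.times_ms[i0 + int(np.argmin(d[i0:i1]))]
        det = detect_activation_time(tr, 0.0)
        assert abs(det - brute) <= 1000.0 / tr.fs

    def test_noise_monte_carlo_median_error(self):
        """With noise at 5% of the RS amplitude the median timing error
        stays below 1 ms over 1000 replicates."""
        errs = []
        for seed in range(1000):
            tr = make_beat(noise=0.075, seed=seed)
            errs.append(abs(detect_activation_time(tr, 0.0) - 80.0))
        assert np.median(errs) <= 1.0

    def test_flat_trace_flagged(self):
        from rvdyn.core import SignalTrace
        tr = SignalTrace("z", 1200.0, -120.0, np.zeros(900))
        with pytest.raises(NoActivationError):
            detect_activation_time(tr, 0.0)

    def test_noise_only_trace_flagged(self, rng):
        from rvdyn.core import SignalTrace
        tr = SignalTrace("z", 1200.0, -120.0, rng.normal(0, 0.02, 900))
        with pytest.raises(NoActivationError):
            detect_activation_time(tr, 0.0)


class TestRepolarizationDetection:
    @pytest.mark.parametrize("rt", [240.0, 280.0, 330.0])
    def test_noiseless_exact(self, rt):
        tr = make_beat(rt=rt)
        at = detect_activation_time(tr, 0.0)
        assert detect_repolarization_time(tr, 0.0, at) == \
            pytest.approx(rt, abs=1.0)

    def test_negative_t_wave_recovery_limb(self):
        """The classical method takes the maximum (signed) dV/dt, which
        for an inverted T wave sits on the recovery limb — still at the
        prescribed repolarization time."""
        tr = make_beat(rt=260.0, t_polarity="-")
        at = detect_activation_time(tr, 0.0)
        rt = detect_repolarization_time(tr, 0.0, at)
        assert rt == pytest.approx(260.0, abs=1.0)
        # brute force max-derivative inside the T window agrees
        d = np.diff(tr.samples) * tr.fs / 1000.0
        i0, i1 = tr.index_of(at + 80.0), tr.index_of(at + 450.0)
        brute = tr.times_ms[i0 + int(np.argmax(d[i0:i1]))]
        assert abs(rt - brute) <= 2 * 1000.0 / tr.fs

    def test_zero_amplitude_t_flagged(self):
        tr = make_beat(t_amplitude_mv=0.0, noise=0.02)
        with pytest.raises(NoTWaveError):
            detect_repolarization_time(tr, 0.0, 80.0)

    def test_truncated_window_rejected(self):
        tr = make_beat()
        with pytest.raises(TruncatedWindowError):
            detect_repolarization_time(tr, 0.0, 80.0,
                                       next_stimulus_t_ms=160.0)


class TestAriDi:
    def test_formulas(self):
        ari, di = compute_ari_di(100.0, 300.0, 420.0, 200.0)
        assert ari == 200.0
        assert di == 220.0

    def test_encroaching_di_is_negative(self):
        _, di = compute_ari_di(100.0, 300.0, 180.0, 200.0)
        assert di == -20.0

    def test_rt_before_at_rejected(self):
        with pytest.raises(ValueError):
            compute_ari_di(300.0, 100.0, 420.0, 200.0)


class TestFractionation:
    def test_clean_rs_counts_one(self):
        tr = make_beat()
        assert fractionation_index(tr, 0.0, (35.0, 125.0)) == 1

    @pytest.mark.parametrize("n_extra", [1, 2, 3, 4])
    def test_inserted_deflections_counted(self, n_extra):
        hits = 0
        for seed in range(10):
            tr = make_beat(noise=0.02, seed=seed,
                           n_extra_deflections=n_extra)
            if fractionation_index(tr, 0.0, (35.0, 125.0)) == 1 + n_extra:
                hits += 1
        assert hits >= 9

    def test_subthreshold_deflection_not_counted(self):
        """A deflection far below the counting threshold is invisible."""
        tr = make_beat(n_extra_deflections=1, deflection_amplitude_mv=0.02,
                       noise=0.01)
        assert fractionation_index(tr, 0.0, (35.0, 125.0)) == 1

    def test_band_validation(self):
        tr = make_beat()
        with pytest.raises(ValueError):
            fractionation_index(tr, 0.0, (35.0, 125.0),
                                FractionationParams(band_hz=(30.0, 900.0)))


class TestDetectorInvariances:
    @given(shift=st.integers(min_value=-20, max_value=40))
    def test_shift_equivariance(self, shift):
        """Shifting the trace by a whole number of samples shifts the
        detected times by exactly that amount."""
        tr = make_beat(noise=0.02, seed=3)
        delta = shift * tr.dt_ms
        shifted = tr.shifted(delta)
        at0 = detect_activation_time(tr, 0.0)
        at1 = detect_activation_time(shifted, delta)
        assert at1 == pytest.approx(at0, abs=1e-9)

    @given(k=st.floats(min_value=0.05, max_value=50.0))
    def test_amplitude_invariance(self, k):
        tr = make_beat(noise=0.02, seed=4, n_extra_deflections=2)
        at0 = detect_activation_time(tr, 0.0)
        rt0 = detect_repolarization_time(tr, 0.0, at0)
        f0 = fractionation_index(tr, 0.0, (35.0, 125.0))
        sc = tr.scaled(k)
        assert detect_activation_time(sc, 0.0) == at0
        assert detect_repolarization_time(sc, 0.0, at0) == rt0
        assert fractionation_index(sc, 0.0, (35.0, 125.0)) == f0

    def test_ari_identity(self, small_patient):
        _, beats = small_patient
        ok = beats[np.isfinite(beats.ari_ms)]
        assert np.allclose(ok.ari_ms, ok.rt_ms - ok.at_ms)


class TestMorphologySpec:
    def test_rt_too_close_to_at_rejected(self):
        with pytest.raises(GeneratorError):
            EgmMorphologySpec(at_true_ms=80.0, rt_true_ms=100.0)

    def test_duration_must_cover_t_wave(self):
        spec = EgmMorphologySpec(at_true_ms=80.0, rt_true_ms=700.0)
        with pytest.raises(GeneratorError):
            synth_unipolar_egm(spec, 500.0, 1200.0)
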