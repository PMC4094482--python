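"""Generator-level invariants: determinism, capture monotonicity,
cohort sampling and prescription feasibility."""

import numpy as np
import pytest

from rvdyn.calibration import GROUP_DEFAULTS, lognormal_params
from rvdyn.io import write_traces_csv
from rvdyn.synth import (CohortSpec, GeneratorError, PatientKinetics,
                         beat_table_from_truth, draw_patient_kinetics,
                         synth_cohort, synth_restitution_dataset)


def small_spec(**kw):
    defaults = dict(group="definite_arvc", n_patients=2,
                    include_ecg=False,
                    params={"verp": (255.0, 5.0)})
    defaults.update(kw)
    return CohortSpec(**defaults)


class TestSeedDeterminism:
    def test_byte_identical_csv(self, tmp_path):
        """Identical spec and seed produce byte-identical CSV output."""
        paths = []
        for run in (1, 2):
            rec = synth_cohort(small_spec(), np.random.default_rng(7))[0]
            traces = {eid: tr for (rep, eid), tr
                      in rec.steady_traces.items() if rep == 1}
            p = tmp_path / f"steady_{run}.csv"
            write_traces_csv(traces, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_distinct_seeds_differ(self):
        r1 = synth_cohort(small_spec(), np.random.default_rng(1))[0]
        r2 = synth_cohort(small_spec(), np.random.default_rng(2))[0]
        assert r1.truth.kinetics.verp_true_ms != \
            r2.truth.kinetics.verp_true_ms


class TestCaptureMonotonicity:
    def test_no_capture_below_verp(self):
        """No generated dataset captures at or below the true VERP while
        failing above it."""
        for seed in range(5):
            rec = synth_cohort(small_spec(),
                               np.random.default_rng(seed))[0]
            verp = rec.truth.kinetics.verp_true_ms
            for ev in rec.protocol.events:
                assert ev.captured == (ev.coupling_ms > verp)


class TestCohortSampling:
    def test_law_of_large_numbers(self):
        """Sample mean of the drawn pre-VERP delay stays within two
        standard errors of the configured group mean at n=50."""
        spec = CohortSpec(group="definite_arvc", n_patients=50,
                          include_ecg=False)
        kins = draw_patient_kinetics(spec, 50, np.random.default_rng(3))
        mu, sd = GROUP_DEFAULTS["definite_arvc"]["delta_at_preverp"]
        vals = [k.delta_at_preverp_ms for k in kins]
        assert abs(np.mean(vals) - mu) <= 2 * sd / np.sqrt(50) + 0.5

    def test_single_patient_cohort(self):
        recs = synth_cohort(small_spec(n_patients=1),
                            np.random.default_rng(0))
        assert len(recs) == 1
        assert len(recs[0].train_traces) > 0

    def test_zero_sd_gives_identical_patients(self):
        params = {k: ((v[0], 0.0) if isinstance(v, tuple) else v)
                  for k, v in GROUP_DEFAULTS["definite_arvc"].items()
                  if k not in ("ecg_steady", "ecg_hysteresis", "mid")}
        spec = CohortSpec(group="definite_arvc", n_patients=2,
                          include_ecg=False, params=params,
                          between_fraction=1.0)
        kins = draw_patient_kinetics(spec, 2, np.random.default_rng(0))
        assert kins[0].verp_true_ms == kins[1].verp_true_ms
        assert kins[0].delta_at_preverp_ms == kins[1].delta_at_preverp_ms

    def test_stratified_marginals_match(self):
        """Stratified draws keep the marginal distribution: mean/sd agree
        with iid draws at large n."""
        spec_i = CohortSpec(group="definite_arvc", n_patients=400,
                            include_ecg=False, sampling="iid")
        spec_s = CohortSpec(group="definite_arvc", n_patients=400,
                            include_ecg=False, sampling="stratified")
        ki = draw_patient_kinetics(spec_i, 400, np.random.default_rng(1))
        ks = draw_patient_kinetics(spec_s, 400, np.random.default_rng(1))
        vi = [k.delta_at_preverp_ms for k in ki]
        vs = [k.delta_at_preverp_ms for k in ks]
        assert np.mean(vs) == pytest.approx(np.mean(vi), abs=2.5)
        assert np.std(vs) == pytest.approx(np.std(vi), rel=0.15)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(group="normal", n_patients=2,
                       params={"verp": (210.0, -1.0)})

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(group="martians")


class TestKineticsValidation:
    def test_verp_bounds(self):
        with pytest.raises(GeneratorError):
            PatientKinetics(verp_true_ms=120.0)

    def test_negative_delay_rejected(self):
        with pytest.raises(GeneratorError):
            PatientKinetics(delta_at_preverp_ms=-5.0)


class TestTruthBookkeeping:
    def test_truth_beat_table_layout(self):
        rec = synth_cohort(small_spec(), np.random.default_rng(5))[0]
        bt = beat_table_from_truth(rec)
        assert set(bt.state) == {"steady", "sinus", "s1s2"}
        s2 = bt[(bt.state == "s1s2") & bt.captured]
        assert np.all(s2.ari_ms > 0)
        # DI follows the activation-interval-minus-steady-ARI rule
        steady = bt[bt.state == "steady"].groupby("electrode_id").agg(
            at=("at_ms", "mean"), ari=("ari_ms", "mean"))
        for row in s2.itertuples():
            a1a2 = row.coupling_ms + row.at_ms - steady.at[
                row.electrode_id, "at"]
            assert row.di_ms == pytest.approx(
                a1a2 - steady.at[row.electrode_id, "ari"], abs=1e-6)

    def test_lognormal_fit_honours_median(self):
        mu, sigma = lognormal_params(7.0, (3.6, 9.3))
        assert np.exp(mu) == pytest.approx(7.0)
        assert sigma == pytest.approx(np.log(9.3 / 3.6) / 1.349, abs=1e-3)

    def test_lognormal_zero_q1_falls_back(self):
        mu, sigma = lognormal_params(3.4, (0.0, 5.2))
        assert np.exp(mu) == pytest.approx(3.4)
        assert sigma > 0
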