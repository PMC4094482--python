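import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_map():
    from rvdyn.core import build_electrode_map
    return build_electrode_map()


@pytest.fixture(scope="session")
def small_patient():
    """One synthetic patient with full waveforms, measured once per session.

    Uses a raised pacing floor via a high true VERP so the fine scan stays
    short and the whole dataset synthesises in a few seconds.
    """
    from rvdyn.egm import measure_record
    from rvdyn.synth import PatientKinetics, synth_restitution_dataset

    kin = PatientKinetics(verp_true_ms=255.0, delta_at_preverp_ms=40.0,
                          delta_rt_preverp_ms=10.0)
    rec = synth_restitution_dataset(
        kin, rng=np.random.default_rng(99), patient_id="PTEST",
        group="definite_arvc")
    beats = measure_record(rec)
    return rec, beats
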