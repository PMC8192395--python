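import numpy as np
import pytest

from trainability.simulate import ParticipantTruth, StepProtocol


def make_participant(**overrides) -> ParticipantTruth:
    """A hand-built participant with round, analytically convenient truth."""
    defaults = dict(
        id="T01", sex="F", age=26.0, mass=65.0,
        true_baseline_vo2max=2200.0, true_delta=350.0,
        hr_rest=60.0, hr_max=190.0,
        hr_po_intercept=92.0, hr_po_slope=None,   # derived below
        ltp1_po=80.0, ltp2_po=130.0,
        nirs_true_slope=1.2, nirs_baseline=65.0,
        vo2_rest=377.5, vo2_po_slope=10.3,
        oues_a=2000.0, oues_b=-1622.5,
        lactate_basal=1.0, lactate_slopes=(0.002, 0.03, 0.15),
    )
    defaults.update(overrides)
    if defaults["hr_po_slope"] is None:
        po_peak = (defaults["true_baseline_vo2max"] - defaults["vo2_rest"]) \
            / defaults["vo2_po_slope"]
        defaults["hr_po_slope"] = (defaults["hr_max"] - defaults["hr_po_intercept"]) / po_peak
    p = ParticipantTruth(**defaults)
    p.validate()
    return p


NOISELESS = dict(vo2_noise_sd=0.0, hr_noise_sd=0.0, spike_rate=0.0,
                 lactate_noise_sd=0.0)


@pytest.fixture
def participant():
    return make_participant()


@pytest.fixture
def noiseless_protocol():
    return StepProtocol(**NOISELESS)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
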