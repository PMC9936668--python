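import numpy as np
import pytest

from vnsim.patterns import Condition, TrialProtocol, enumerate_design


@pytest.fixture(scope="session")
def short_protocol():
    """Scaled-down trial: 5 s baseline, 10 s VNS, analysis from 4 s in."""
    return TrialProtocol(
        baseline_s=5.0, stim_s=10.0, recovery_s=0.0, analysis_start_offset_s=4.0
    )


@pytest.fixture(scope="session")
def hr_protocol():
    """Scaled-down protocol for the slow SAN-network trials."""
    return TrialProtocol(
        baseline_s=4.0, stim_s=10.0, recovery_s=0.0, analysis_start_offset_s=4.0
    )


@pytest.fixture(scope="session")
def full_design():
    return enumerate_design()


def constant_condition(freq, amplitude=1.0):
    return Condition(
        amplitude=amplitude,
        intra_burst_frequency=float(freq),
        mean_pulse_rate=float(freq),
        pattern_kind="constant",
    )


@pytest.fixture(scope="session")
def make_constant_condition():
    return constant_condition
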