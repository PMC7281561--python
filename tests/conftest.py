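import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import seizurekit as sk

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def control_decay():
    """Control eIPSC kinetics (weighted tau exactly 41 ms)."""
    return sk.CONTROL_DECAY


@pytest.fixture
def simple_decay():
    """A well-separated reference decay used across recovery tests."""
    return sk.DecayComponents(a_fast=300.0, tau_fast=10.0, a_slow=100.0, tau_slow=80.0)


@pytest.fixture
def noiseless_spec(simple_decay):
    return sk.SweepSpec(decay=simple_decay, duration=1.0, baseline_noise_sd=0.0,
                        rise_tau_ms=0.0, stimulus_times=(0.1,))


@pytest.fixture
def noiseless_sweep(noiseless_spec):
    return sk.gen_eipsc(noiseless_spec, seed=0)
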