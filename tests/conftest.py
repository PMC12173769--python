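import pytest

from amygsim import make_config, run_session
from amygsim.params import IntegrationSpec, NoiseSpec


@pytest.fixture()
def fast_integration():
    """Short trials for mechanics tests where criterion values don't matter."""
    return IntegrationSpec(dt=0.015, steps_trial=200, steps_intertrial=100)


@pytest.fixture(scope="session")
def naive_session():
    """One full default naive session (noise on), shared across tests."""
    return run_session(make_config("naive", seed=7))


@pytest.fixture(scope="session")
def chronic_session():
    return run_session(make_config("chronic", seed=7))


@pytest.fixture(scope="session")
def deterministic_naive_session():
    """Noise-free (sd=0, tonic drift retained) naive session."""
    cfg = make_config("naive", seed=0).replace(noise=NoiseSpec(sd=0.0))
    return run_session(cfg)
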