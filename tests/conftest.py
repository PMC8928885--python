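import pytest

from ptarmigan.simdata import SimConfig, simulate_population


@pytest.fixture(scope="session")
def default_population():
    """One default-config synthetic population shared across the session."""
    cfg = SimConfig()
    fixes, birds, nests, truth = simulate_population(cfg)
    return cfg, fixes, birds, nests, truth
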