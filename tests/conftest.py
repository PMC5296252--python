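import pytest

from phosphocycle.simulate import SimulationConfig, generate_site_panel


@pytest.fixture(scope="session")
def fast_config() -> SimulationConfig:
    """Small seeded study used across tests (kept small for speed)."""
    return SimulationConfig(n_sites=300, seed=7)


@pytest.fixture(scope="session")
def fast_panel(fast_config):
    return generate_site_panel(fast_config)


@pytest.fixture(scope="session")
def fast_panel_with_proteins(fast_config):
    return generate_site_panel(fast_config, with_proteins=True)
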