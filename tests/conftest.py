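import pytest

from antquant import RunConfig, SimulationConfig, simulate


@pytest.fixture()
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated experiment shared by read-only tests."""
    cfg = SimulationConfig(n_proteins=40, seed=7)
    proteome, psms, truth = simulate(cfg)
    return cfg, proteome, psms, truth
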