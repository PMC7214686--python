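import pytest
from hypothesis import settings as hyp_settings

from promdens import SimulationConfig, simulate

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_landscape():
    """The default synthetic landscape: 2000 genes, seed 1."""
    return simulate(SimulationConfig())


@pytest.fixture(scope="session")
def small_landscape():
    """A small landscape for fast end-to-end checks."""
    return simulate(SimulationConfig(n_genes=200, seed=7))


@pytest.fixture(scope="session")
def small_landscape_files(tmp_path_factory):
    from promdens import generate_landscape

    outdir = tmp_path_factory.mktemp("sim")
    return generate_landscape(SimulationConfig(n_genes=200, seed=7), outdir)
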