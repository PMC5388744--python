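import pytest

from synfrac.pipeline import PipelineConfig, analyze
from synfrac.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition scenario: 3x200 ancestral genes, standard losses."""
    return simulate(SimConfig(seed=42))


@pytest.fixture(scope="session")
def default_run(default_sim):
    ref, derived, truth = default_sim
    return analyze(ref, derived, PipelineConfig()), truth


@pytest.fixture(scope="session")
def noloss_sim():
    """Default sizes with every loss probability zero."""
    cfg = SimConfig(seed=43, wgt_loss=0.0, wgd_loss=(0.0, 0.0))
    return simulate(cfg)


@pytest.fixture(scope="session")
def noloss_run(noloss_sim):
    ref, derived, truth = noloss_sim
    return analyze(ref, derived, PipelineConfig()), truth


@pytest.fixture(scope="session")
def small_sim():
    """Cheap scenario for structural tests: 2 chromosomes x 80 genes."""
    return simulate(SimConfig(seed=5, n_chromosomes=2,
                              genes_per_chromosome=80))


@pytest.fixture(scope="session")
def small_run(small_sim):
    ref, derived, truth = small_sim
    return analyze(ref, derived, PipelineConfig()), truth


@pytest.fixture(scope="session")
def tiny_sim():
    """One ancestral chromosome of 40 genes; fastest full scenario."""
    return simulate(SimConfig(seed=1, n_chromosomes=1,
                              genes_per_chromosome=40))
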