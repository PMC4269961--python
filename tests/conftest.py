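import pytest
from hypothesis import settings

from cytoprior.demo import sacral_locus_demo
from cytoprior.simulate import SimulationConfig, generate_all

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo():
    """Synthetic 45-gene terminal-7q locus with two planted candidates."""
    return sacral_locus_demo()


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated world shared by read-only tests."""
    config = SimulationConfig(
        seed=7,
        n_chrom=2,
        genes_per_chrom=20,
        n_tissues=8,
        n_planted=4,
        network_size=40,
        n_seeds=5,
        n_patients=30,
        benign_catalog_size=15,
    )
    return generate_all(config)
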