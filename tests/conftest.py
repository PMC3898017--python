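import numpy as np
import pytest

from chipregulon.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic dataset shared by the slower tests."""
    cfg = SimulationConfig(seed=1)
    genome, genes, truth, chip, input_lib = simulate_dataset(cfg)
    return {
        "config": cfg,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "chip": chip,
        "input": input_lib,
    }


@pytest.fixture(scope="session")
def small_dataset():
    """A 30-kb dataset for fast end-to-end tests."""
    cfg = SimulationConfig(
        genome_length=30_000, n_genes=10, n_sites=6, frac_intragenic_sites=0.5, seed=7
    )
    genome, genes, truth, chip, input_lib = simulate_dataset(cfg)
    return {
        "config": cfg,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "chip": chip,
        "input": input_lib,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
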