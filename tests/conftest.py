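import pytest

from archncc import SimulationParams, generate_dataset, plant_worked_example


@pytest.fixture(scope="session")
def worked_example():
    """Hand-built noise-free boundary dataset (matrix, design, truth)."""
    return plant_worked_example()


@pytest.fixture(scope="session")
def small_noise_free():
    """Small noise-free simulated dataset for fast recovery checks."""
    params = SimulationParams(n_genes=600, noise_sd=0.0, seed=7)
    return params, generate_dataset(params)
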