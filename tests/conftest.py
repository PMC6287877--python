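import numpy as np
import pytest

from tcrtail import (
    DiscreteGamma,
    DiscreteGPD,
    SplicedDistribution,
    SimulationDesign,
    generate_repertoire,
    fit_spliced,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def reference_model():
    """A representative spliced model (moderate tail) reused across tests."""
    return SplicedDistribution(
        bulk=DiscreteGamma(3.0, 0.15),
        tail=DiscreteGPD(20, 20.0, 0.5),
        phi=0.15,
    )


@pytest.fixture(scope="session")
def simulated_sample(reference_model):
    """20k clonotypes drawn from the reference model with a fixed seed."""
    return generate_repertoire(
        reference_model, 20_000, np.random.default_rng(1234), label="sim"
    )


@pytest.fixture(scope="session")
def simulated_fit(simulated_sample):
    """Profile-likelihood fit of the simulated sample (expensive; shared)."""
    return fit_spliced(simulated_sample)


@pytest.fixture(scope="session")
def design_cell_sample():
    """One factorial-design cell (alpha=3, xi=0.5, phi=0.15) sampled at n=20k."""
    design = SimulationDesign(seed=99)
    model = design.cell_model(3.0, 0.5, 0.15)
    return model, generate_repertoire(
        model, 20_000, np.random.default_rng(99), label="cell"
    )
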