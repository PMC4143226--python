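import numpy as np
import pytest

from laminarpop.experiments import recover_populations
from laminarpop.kcsd import KernelCSD
from laminarpop.synth import (
    PopulationSpec,
    Scenario,
    default_scenario,
    synthesize_dataset,
)


@pytest.fixture(scope="session")
def dataset():
    """Default three-population ground-truth dataset, noise-free."""
    return synthesize_dataset(default_scenario(), seed=1)


@pytest.fixture(scope="session")
def fitted_kcsd(dataset):
    """Kernel CSD estimator fitted to the default geometry (expensive)."""
    return KernelCSD(lam="cv").fit(dataset.total)


@pytest.fixture(scope="session")
def pipeline(dataset, fitted_kcsd):
    """Full noise-free pipeline result on the default scenario, K = 5."""
    assignment, info = recover_populations(
        dataset, k=5, ica_seed=0, kcsd=fitted_kcsd
    )
    return assignment, info


@pytest.fixture(scope="session")
def two_pop_scenario():
    """A small rank-1 two-population scenario for cheap end-to-end tests."""
    base = default_scenario()
    specs = [
        PopulationSpec(
            name="upper",
            depth_range=(450.0, 950.0),
            n_sources=200,
            rank=1,
            amplitude=1.0,
            dipole_extent=300.0,
            frequency=75.0,
            lag_ms=4.0,
        ),
        PopulationSpec(
            name="lower",
            depth_range=(1150.0, 1650.0),
            n_sources=200,
            rank=1,
            amplitude=1.0,
            dipole_extent=300.0,
            frequency=55.0,
            lag_ms=7.0,
        ),
    ]
    return Scenario(specs=specs, geometry=base.geometry, top_contact=base.top_contact)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
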