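import numpy as np
import pytest

from apeeg.ensemble import default_frequency_grid
from apeeg.geometry import CortexGeometry, LeadField, place_population
from apeeg.synthetic import make_kernel_bank, make_population, population_to_specs


@pytest.fixture(scope="session")
def population():
    return make_population(excitatory_fraction=0.85, class_count=8, seed=0)


@pytest.fixture(scope="session")
def kernel_bank(population):
    return make_kernel_bank(population_to_specs(population))


@pytest.fixture(scope="session")
def sphere_fixture():
    """Small cortical sphere + scalp electrode for pair-term tests."""
    geom = CortexGeometry.sphere(radius_mm=20.0)
    lf = LeadField.infinite_medium([0.0, 0.0, 30.0])
    return geom, lf


@pytest.fixture(scope="session")
def dense_fixture():
    """Tiny sphere where all neuron pairs sit within the synchrony range,
    so the pair term dominates the auto term (the whole-brain regime)."""
    geom = CortexGeometry.sphere(radius_mm=3.0, subdivisions=3)
    lf = LeadField.infinite_medium([0.0, 0.0, 30.0])
    return geom, lf


@pytest.fixture(scope="session")
def placed_50(population, sphere_fixture):
    geom, _ = sphere_fixture
    return place_population(geom, population, n_neurons=50, seed=1)


@pytest.fixture(scope="session")
def freq_grid():
    return default_frequency_grid(100)
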