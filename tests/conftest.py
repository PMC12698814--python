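import numpy as np
import pytest

from leafvar import (
    VarianceModel,
    generate_design,
    simulate_traits,
)


@pytest.fixture(scope="session")
def default_design():
    return generate_design(seed=0)


@pytest.fixture(scope="session")
def small_design():
    """4 species, levels {1,2,4}, 1 plot per species/level, 4 trees, no mortality."""
    return generate_design(
        seed=0,
        n_species=4,
        richness_levels=(1, 2, 4),
        plots_per_species_per_level=1,
        trees_per_population=4,
        mortality=None,
        central_trees_per_plot=8,
    )


@pytest.fixture(scope="session")
def small_traits(small_design):
    return simulate_traits(small_design, VarianceModel(), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
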