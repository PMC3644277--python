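import pytest

from minnut.fixtures import (
    RandomModelParams,
    crossfeed_model,
    example1_model,
    random_model,
)


@pytest.fixture
def example1():
    return example1_model()


@pytest.fixture
def example1_af():
    """Example network with only A and F offered as transportables."""
    return example1_model(transportables=("A", "F"))


@pytest.fixture
def crossfeed():
    return crossfeed_model()


@pytest.fixture
def make_random_model():
    def factory(seed, n_transportables=4, n_compounds=9, n_reactions=8, n_biomass=1,
                reversible_fraction=0.25):
        return random_model(
            RandomModelParams(
                n_compounds=n_compounds,
                n_reactions=n_reactions,
                n_transportables=n_transportables,
                n_biomass=n_biomass,
                reversible_fraction=reversible_fraction,
                seed=seed,
            )
        )

    return factory
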