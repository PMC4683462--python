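import pytest
from hypothesis import settings

from avigamut.simulate import AvifaunaConfig, OrderSpec, gen_avifauna
from avigamut.visual import (aggregate_species_sex, build_sensitivity_set,
                             model_set)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sens_u():
    return build_sensitivity_set("U")


@pytest.fixture(scope="session")
def sens_v():
    return build_sensitivity_set("V")


@pytest.fixture(scope="session")
def default_avifauna():
    """The default 60-species dichromatic synthetic avifauna, seed 1."""
    return gen_avifauna(AvifaunaConfig(seed=1))


@pytest.fixture(scope="session")
def default_points(default_avifauna, sens_u):
    """Species x sex x patch mean tetra points of the default avifauna."""
    sset, _ = default_avifauna
    return aggregate_species_sex(model_set(sset, sens_u))


def small_orders():
    """A compact avifauna design for fast pipeline-level tests."""
    return [
        OrderSpec("Passeriformes", 8, {
            "melanin": 0.6, "carotenoid": 0.15, "structural": 0.15,
            "carotenoid_structural": 0.10,
        }),
        OrderSpec("Psittaciformes", 4, {
            "melanin": 0.4, "carotenoid": 0.25, "structural": 0.15,
            "carotenoid_structural": 0.20,
        }, is_parrot_like=True),
    ]


@pytest.fixture
def small_avifauna_config():
    return AvifaunaConfig(orders=small_orders(), n_specimens_per_sex=2,
                          n_patches=8, seed=11)
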