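"""Shared fixtures: toy systems for every stage, plus the bundled E. coli model."""

import logging

import pytest

import crossfeed as cf

logging.getLogger("crossfeed").setLevel(logging.ERROR)
logging.getLogger("cobra").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_universe():
    return cf.make_toy_universe(cf.ToyUniverseSpec(seed=0))


@pytest.fixture(scope="session")
def protected_toy_universe(toy_universe):
    """Toy universe with its glucose-essential reactions protected."""
    ess = cf.essential_reactions(toy_universe.model, toy_universe.medium)
    return cf.Universe(
        model=toy_universe.model, medium=toy_universe.medium, protected=ess
    )


@pytest.fixture(scope="session")
def crossfeed_fixture():
    return cf.make_crossfeeding_fixture()


@pytest.fixture(scope="session")
def monod():
    model, ref = cf.make_monod_model(mu_max=0.5, km=0.05, yield_per_mmol=0.1)
    return model, ref


@pytest.fixture(scope="session")
def ecoli():
    """The bundled genome-scale E. coli model iJO1366 with its mineral medium."""
    model = cf.load_bigg_model("iJO1366")
    return model, cf.ecoli_mineral_medium(model)
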