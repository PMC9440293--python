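import numpy as np
import pytest

from hepatoflux import (
    MetabolicModel,
    Metabolite,
    Reaction,
    SimulationSpec,
    make_toy_model,
)


@pytest.fixture
def chain_model() -> MetabolicModel:
    """EX_A -> (R1) -> A -> (R2) -> B -> (R3) -> EX_B, all ub = 10."""
    mets = [
        Metabolite("A_e", compartment="e"),
        Metabolite("A", compartment="c"),
        Metabolite("B", compartment="c"),
        Metabolite("B_e", compartment="e"),
    ]
    rxns = [
        Reaction("EX_A", {"A_e": -1.0}, -10.0, 0.0, "exchange", is_exchange=True),
        Reaction("R1", {"A_e": -1.0, "A": 1.0}, 0.0, 10.0, "chain", gpr="g1"),
        Reaction("R2", {"A": -1.0, "B": 1.0}, 0.0, 10.0, "chain", gpr="g2 and g3"),
        Reaction("R3", {"B": -1.0, "B_e": 1.0}, 0.0, 10.0, "chain", gpr="g4 or g5"),
        Reaction("EX_B", {"B_e": -1.0}, 0.0, 10.0, "exchange", is_exchange=True),
    ]
    return MetabolicModel(mets, rxns, objective_reaction="EX_B", id="chain")


@pytest.fixture
def chain_with_deadend(chain_model) -> MetabolicModel:
    """Chain plus a dead-end branch B -> E with no consumer of E."""
    m = chain_model.copy()
    m.metabolites.append(Metabolite("E", compartment="c"))
    m.reactions.append(
        Reaction("RDEAD", {"B": -1.0, "E": 1.0}, 0.0, 10.0, "chain", gpr="g6")
    )
    m._validate()
    return m


@pytest.fixture
def toy_model():
    model, truth = make_toy_model(SimulationSpec(seed=0))
    return model


def toy(seed: int, **kw) -> tuple:
    return make_toy_model(SimulationSpec(seed=seed, **kw))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
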