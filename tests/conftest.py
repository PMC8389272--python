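import hypothesis
import pytest

import schemesim as ss
from schemesim import fixtures as fx

hypothesis.settings.register_profile(
    "suite", max_examples=30, deadline=None, derandomize=True)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def atp_toy():
    return fx.make_atp_toy()


@pytest.fixture(scope="session")
def butanol():
    return fx.make_butanol()


@pytest.fixture(scope="session")
def three_layer():
    return fx.make_three_layer_toy()


@pytest.fixture(scope="session")
def rule_event_toy():
    return fx.make_rule_event_toy()


@pytest.fixture(scope="session")
def chain3():
    return fx.make_linear_chain(n=3)


@pytest.fixture(scope="session")
def all_fixture_schemes(atp_toy, butanol, three_layer, rule_event_toy,
                        chain3):
    """Every named example scheme plus a random two-layer one."""
    return {
        "atp_toy": atp_toy,
        "butanol": butanol,
        "three_layer": three_layer,
        "rule_event_toy": rule_event_toy,
        "chain3": chain3,
        "random_two_layer": fx.make_random_scheme(
            n_species=6, n_reactions=6, seed=7, two_layers=True),
    }


@pytest.fixture()
def ab_toy():
    """Single mass-action reaction A -> B with rate constant k1."""
    s = ss.ReactionScheme(layers=["main"], name="ab")
    s.species.append(ss.SpeciesSymbol(id="A", initial_concentration=1.0))
    s.species.append(ss.SpeciesSymbol(id="B", initial_concentration=0.0))
    s.global_parameters["k1"] = 0.5
    s.reactions.append(ss.ReactionStep(
        id="r1",
        substrates=[ss.Participant("A")],
        products=[ss.Participant("B")],
        kinetic_law=ss.KineticLaw(kind="mass_action", rate_constant="k1")))
    return s
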