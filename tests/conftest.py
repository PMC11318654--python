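import pytest

from aacascade import (
    Compartment,
    Network,
    ReactionSpec,
    ReleaseProfile,
    SimulationProtocol,
    Species,
    build_aa_cascade,
    build_default_priors,
)


@pytest.fixture(scope="session")
def cascade_net():
    return build_aa_cascade()


@pytest.fixture(scope="session")
def cascade_priors(cascade_net):
    return build_default_priors(cascade_net)


@pytest.fixture(scope="session")
def stimulus_protocol():
    """Default 1 h equilibration + 6 h stimulated window with a fast release."""
    return SimulationProtocol(
        release=ReleaseProfile(max_conc_6h=0.1, doubling_time=0.25)
    )


def make_ab_network(k_f_name="k_f_r1"):
    """Closed single-compartment A <-> B network (one non-enzymatic reaction)."""
    comp = {"intracellular": Compartment("intracellular", 1e-12)}
    species = {}
    for sid, c0 in (("A", 1.0), ("B", 0.0)):
        sp = Species(sid, "intracellular", initial_concentration=c0)
        species[sp.ref] = sp
    rxn = ReactionSpec(
        number=1, rtype="non_enzymatic",
        substrates=(("A@intracellular", 1.0),),
        products=(("B@intracellular", 1.0),),
        parameters=("k_f", "k_r", "K_eq"),
    )
    return Network("ab", comp, species, {1: rxn})


def make_transport_network():
    """Closed two-compartment network: X moved out by a carrier, X <-> Y inside."""
    comps = {
        "intracellular": Compartment("intracellular", 1e-12),
        "extracellular": Compartment("extracellular", 1e-9),
    }
    species = {}
    for sid, comp, role, c0 in (
        ("X", "intracellular", "metabolite", 1.0),
        ("X", "extracellular", "metabolite", 0.0),
        ("Y", "intracellular", "metabolite", 0.0),
        ("T", "intracellular", "transporter", 0.0),
    ):
        sp = Species(sid, comp, role=role, initial_concentration=c0)
        species[sp.ref] = sp
    rxns = {
        1: ReactionSpec(
            number=1, rtype="transport",
            substrates=(("X@intracellular", 1.0),),
            products=(("X@extracellular", 1.0),),
            catalyst="T@intracellular",
            parameters=("K_ms",),
        ),
        2: ReactionSpec(
            number=2, rtype="non_enzymatic",
            substrates=(("X@intracellular", 1.0),),
            products=(("Y@intracellular", 1.0),),
            parameters=("k_f", "k_r", "K_eq"),
        ),
    }
    return Network("closed_transport", comps, species, rxns)


@pytest.fixture
def ab_network():
    return make_ab_network()


@pytest.fixture
def transport_network():
    return make_transport_network()
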