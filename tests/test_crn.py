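"""Reaction-network representation: summaries, RHS/Jacobian, conservation
laws, and serialization."""
import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from multiphos.crn import (ConfigurationError, MassActionSystem, Reaction,
                           ReactionNetwork, as_complex, conservation_laws,
                           jacobian, mass_action_rhs, network_summary,
                           read_reactions, to_sbml, write_reactions)
from multiphos.models import ModelConfig, build_network


def net_from_text(text):
    return read_reactions(text)


REVERSIBLE_PAIR = "# species: A B\nA -> B ; k1\nB -> A ; k2\n"
THREE_CYCLE = "# species: A B C\nA -> B ; k1\nB -> C ; k2\nC -> A ; k3\n"
BRANCHED = "# species: A B C D\nA + B -> C ; k1\nC -> A + B ; k2\nC -> A + D ; k3\n"


@pytest.mark.parametrize(
    "text, C, L, rank, deficiency, wr",
    [
        (REVERSIBLE_PAIR, 2, 1, 1, 0, True),
        (THREE_CYCLE, 3, 1, 2, 0, True),
        # complexes {A+B, C, A+D}; one linkage class; integer rank 2
        (BRANCHED, 3, 1, 2, 0, False),
    ],
)
def test_network_summary_examples(text, C, L, rank, deficiency, wr):
    s = network_summary(net_from_text(text))
    assert (s.n_complexes, s.n_linkage_classes, s.stoich_rank) == (C, L, rank)
    assert s.deficiency == deficiency
    assert s.weakly_reversible is wr


def test_empty_network_summary_is_all_zero_and_vacuously_reversible():
    s = network_summary(ReactionNetwork(("A",), ()))
    assert (s.n_complexes, s.n_linkage_classes, s.stoich_rank, s.deficiency) == (0, 0, 0, 0)
    assert s.weakly_reversible


def test_rate_names_must_be_unique_and_species_declared():
    with pytest.raises(ValueError, match="not declared"):
        ReactionNetwork(("A",), (Reaction(as_complex({"A": 1}), as_complex({"B": 1}), "k"),))
    r1 = Reaction(as_complex({"A": 1}), as_complex({"B": 1}), "k")
    r2 = Reaction(as_complex({"B": 1}), as_complex({"A": 1}), "k")
    with pytest.raises(ValueError, match="more than one reaction"):
        ReactionNetwork(("A", "B"), (r1, r2))
    with pytest.raises(ValueError, match="identical"):
        Reaction(as_complex({"A": 1}), as_complex({"A": 1}), "k")


def test_mass_action_rhs_examples():
    net = net_from_text("# species: A B\nA -> B ; k\n")
    rhs = mass_action_rhs(net, {"k": 2.0})
    out = rhs({"A": 3.0, "B": 0.0})
    assert out == {"A": -6.0, "B": 6.0}

    net2 = net_from_text("# species: A B C\nA + B -> C ; k\n")
    out2 = mass_action_rhs(net2, {"k": 1.0})({"A": 2.0, "B": 5.0, "C": 0.0})
    assert out2["C"] == 10.0 and out2["A"] == -10.0


def test_missing_rate_constant_is_a_named_configuration_error():
    net = net_from_text("# species: A B\nA -> B ; kfwd\n")
    with pytest.raises(ConfigurationError, match="kfwd"):
        mass_action_rhs(net, {})


def test_jacobian_examples():
    net = net_from_text("# species: A B\nA -> B ; k\n")
    J = jacobian(net, {"k": 2.0}, {"A": 1.0, "B": 1.0})
    assert np.allclose(J, [[-2.0, 0.0], [2.0, 0.0]])

    net2 = net_from_text("# species: A B C\nA + B -> C ; k\n")
    J2 = jacobian(net2, {"k": 1.0}, {"A": 2.0, "B": 5.0, "C": 0.0})
    assert J2[2, 0] == pytest.approx(5.0)   # d(dC/dt)/dA = B
    assert J2[2, 1] == pytest.approx(2.0)


def _random_network(rng, n_species=4, n_reactions=6):
    species = [f"X{i}" for i in range(n_species)]
    reactions = []
    for j in range(n_reactions):
        while True:
            lhs = {s: int(c) for s, c in zip(species, rng.integers(0, 3, n_species)) if c}
            rhs = {s: int(c) for s, c in zip(species, rng.integers(0, 3, n_species)) if c}
            if as_complex(lhs) != as_complex(rhs):
                break
        reactions.append(Reaction(as_complex(lhs), as_complex(rhs), f"k{j}"))
    return ReactionNetwork(tuple(species), tuple(reactions))


def test_jacobian_matches_central_differences_on_random_networks(rng):
    for _ in range(10):
        net = _random_network(rng)
        params = {name: float(v) for name, v in
                  zip(net.rate_names, rng.uniform(0.1, 5.0, len(net.reactions)))}
        system = MassActionSystem(net, params)
        x = rng.uniform(0.2, 3.0, net.n_species)
        J = system.jacobian(x)
        h = 1e-6
        for j in range(net.n_species):
            e = np.zeros(net.n_species)
            e[j] = h
            fd = (system.rhs(x + e) - system.rhs(x - e)) / (2 * h)
            assert np.allclose(J[:, j], fd, rtol=1e-5, atol=1e-8)


def test_rhs_is_orthogonal_to_every_conservation_law(rng):
    for _ in range(10):
        net = _random_network(rng)
        params = {name: float(v) for name, v in
                  zip(net.rate_names, rng.uniform(0.1, 5.0, len(net.reactions)))}
        laws = conservation_laws(net)
        for law in laws:
            assert np.all(law @ net.stoichiometry_matrix() == 0)
        x = rng.uniform(0.0, 3.0, net.n_species)
        dx = MassActionSystem(net, params).rhs(x)
        for law in laws:
            assert abs(law @ dx) < 1e-9 * max(1.0, np.max(np.abs(dx)))


def test_conservation_laws_examples():
    net = net_from_text(REVERSIBLE_PAIR)
    laws = conservation_laws(net)
    assert len(laws) == 1 and list(laws[0]) == [1, 1]
    # built families: LR-S has substrate + scaffold totals, MA-S adds enzymes
    assert len(conservation_laws(build_network(ModelConfig(2, "LR", scaffold=True)))) == 2
    assert len(conservation_laws(build_network(ModelConfig(2, "MA", scaffold=True)))) == 4


# --- brute-force oracle for the graph summary ------------------------------


def _summary_bruteforce(net):
    """Independent implementation: explicit complex list, reachability by
    repeated squaring of the adjacency relation, float rank."""
    complexes = []
    for rxn in net.reactions:
        for c in (rxn.reactants, rxn.products):
            if c not in complexes:
                complexes.append(c)
    n = len(complexes)
    adj = np.zeros((n, n), dtype=bool)
    und = np.zeros((n, n), dtype=bool)
    for rxn in net.reactions:
        i, j = complexes.index(rxn.reactants), complexes.index(rxn.products)
        adj[i, j] = True
        und[i, j] = und[j, i] = True
    reach = adj | np.eye(n, dtype=bool)
    reach_u = und | np.eye(n, dtype=bool)
    for _ in range(n):
        reach = reach | (reach @ reach)
        reach_u = reach_u | (reach_u @ reach_u)
    # weak components as equivalence classes of mutual undirected reachability
    weak = {frozenset(np.nonzero(reach_u[i])[0]) for i in range(n)}
    strong = {frozenset(np.nonzero(reach[i] & reach[:, i])[0]) for i in range(n)}
    rank = np.linalg.matrix_rank(net.stoichiometry_matrix().astype(float)) if net.reactions else 0
    return n, len(weak), int(rank), weak == strong


@pytest.mark.parametrize("builder", [
    lambda: net_from_text(BRANCHED),
    lambda: build_network(ModelConfig(2, "LR", scaffold=True)),
    lambda: build_network(ModelConfig(2, "MA", scaffold=True)),
    lambda: build_network(ModelConfig(3, "MA", scaffold=False)),
    lambda: build_network(ModelConfig(2, "LR", scaffold=True,
                                      phos_location="on_scaffold_only",
                                      dephos_location="on_scaffold_only")),
])
def test_summary_agrees_with_bruteforce(builder):
    net = builder()
    s = network_summary(net)
    C, L, rank, wr = _summary_bruteforce(net)
    assert (s.n_complexes, s.n_linkage_classes, s.stoich_rank, s.weakly_reversible) == (C, L, rank, wr)


def test_summary_invariant_under_reordering(rng):
    net = build_network(ModelConfig(2, "MA", scaffold=True))
    s0 = network_summary(net)
    perm = rng.permutation(net.n_species)
    rperm = rng.permutation(len(net.reactions))
    shuffled = ReactionNetwork(tuple(np.array(net.species)[perm]),
                               tuple(np.array(net.reactions, dtype=object)[rperm]))
    s1 = network_summary(shuffled)
    assert s0 == s1


@given(st.integers(1, 3), st.sampled_from(["LR", "MA"]), st.booleans())
def test_deficiency_is_nonnegative_and_consistent(n, kinetics, scaffold):
    net = build_network(ModelConfig(n, kinetics, scaffold=scaffold))
    s = network_summary(net)
    assert s.deficiency == s.n_complexes - s.n_linkage_classes - s.stoich_rank
    assert s.deficiency >= 0


# --- serialization ---------------------------------------------------------


def test_text_round_trip_is_exact():
    net = build_network(ModelConfig(2, "MA", scaffold=True))
    text = write_reactions(net)
    again = read_reactions(text)
    assert again == net
    assert write_reactions(again) == text


def test_text_round_trip_with_stoichiometry(tmp_path):
    net = net_from_text("# species: A B C\n2 A + B -> C ; k1\nC -> 2 A + B ; k2\n")
    path = tmp_path / "net.txt"
    write_reactions(net, path)
    assert read_reactions(str(path)) == net


def test_sbml_export_is_wellformed_and_complete():
    from xml.etree import ElementTree as ET

    net = build_network(ModelConfig(1, "MA", scaffold=True))
    doc = ET.fromstring(to_sbml(net))
    ns = "{http://www.sbml.org/sbml/level3/version2/core}"
    species = doc.findall(f".//{ns}species")
    rxns = doc.findall(f".//{ns}reaction")
    assert len(species) == net.n_species
    assert len(rxns) == len(net.reactions)
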