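"""Mass-action reaction networks.

A :class:`ReactionNetwork` is a list of species together with reactions
between *complexes* (multisets of species with non-negative integer
stoichiometry).  The module generates mass-action right-hand sides and
exact analytic Jacobians, extracts an integer basis of conservation laws,
and computes the graph-theoretic quantities of chemical reaction network
theory -- number of complexes C, linkage classes L, stoichiometric rank s,
deficiency delta = C - L - s, and weak reversibility -- that underpin the
Deficiency Zero Theorem's monostability guarantees.

Units convention (package-wide): concentrations in uM, time in seconds;
first-order rate constants in 1/s, second-order in 1/(uM*s).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence
from xml.etree import ElementTree as ET

import networkx as nx
import numpy as np
import sympy

__all__ = [
    "Complex",
    "Reaction",
    "ReactionNetwork",
    "NetworkSummary",
    "MassActionSystem",
    "ConfigurationError",
    "network_summary",
    "conservation_laws",
    "mass_action_rhs",
    "jacobian",
    "read_reactions",
    "write_reactions",
    "to_sbml",
]


class ConfigurationError(ValueError):
    """A model/parameter configuration is inconsistent or incomplete."""


# A complex is canonically a sorted tuple of (species, stoichiometry) pairs
# with strictly positive integer coefficients; () is the zero complex.
Complex = tuple[tuple[str, int], ...]


def as_complex(comp: Mapping[str, int] | Iterable[tuple[str, int]]) -> Complex:
    """Canonicalize a multiset of species into a Complex key."""
    items = dict(comp)
    for name, coeff in items.items():
        if not isinstance(coeff, (int, np.integer)) or coeff < 0:
            raise ValueError(f"stoichiometry for {name!r} must be a non-negative integer, got {coeff!r}")
    return tuple(sorted((s, int(c)) for s, c in items.items() if c > 0))


def format_complex(comp: Complex) -> str:
    if not comp:
        return "0"
    return " + ".join(f"{c} {s}" if c != 1 else s for s, c in comp)


@dataclass(frozen=True)
class Reaction:
    """A single irreversible reaction reactants -> products with a named rate constant."""

    reactants: Complex
    products: Complex
    rate: str

    def __post_init__(self):
        object.__setattr__(self, "reactants", as_complex(self.reactants))
        object.__setattr__(self, "products", as_complex(self.products))
        if self.reactants == self.products:
            raise ValueError(f"reaction {self.rate!r}: reactant and product complexes are identical")

    def __str__(self) -> str:
        return f"{format_complex(self.reactants)} -> {format_complex(self.products)} ; {self.rate}"


@dataclass(frozen=True)
class ReactionNetwork:
    """An ordered species list plus mass-action reactions between complexes."""

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        declared = set(self.species)
        if len(declared) != len(self.species):
            raise ValueError("duplicate species names")
        seen_rates: set[str] = set()
        for rxn in self.reactions:
            for comp in (rxn.reactants, rxn.products):
                for name, _ in comp:
                    if name not in declared:
                        raise ValueError(f"species {name!r} in reaction {rxn.rate!r} is not declared")
            if rxn.rate in seen_rates:
                raise ValueError(f"rate-constant name {rxn.rate!r} used by more than one reaction")
            seen_rates.add(rxn.rate)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def rate_names(self) -> tuple[str, ...]:
        return tuple(r.rate for r in self.reactions)

    def species_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.species)}

    def stoichiometry_matrix(self) -> np.ndarray:
        """Integer net-stoichiometry matrix N (n_species x n_reactions)."""
        idx = self.species_index()
        N = np.zeros((len(self.species), len(self.reactions)), dtype=int)
        for j, rxn in enumerate(self.reactions):
            for name, c in rxn.reactants:
                N[idx[name], j] -= c
            for name, c in rxn.products:
                N[idx[name], j] += c
        return N

    def reactant_order_matrix(self) -> np.ndarray:
        """Integer matrix of reactant stoichiometries (n_reactions x n_species)."""
        idx = self.species_index()
        R = np.zeros((len(self.reactions), len(self.species)), dtype=int)
        for j, rxn in enumerate(self.reactions):
            for name, c in rxn.reactants:
                R[j, idx[name]] = c
        return R

    def complexes(self) -> list[Complex]:
        out: list[Complex] = []
        seen: set[Complex] = set()
        for rxn in self.reactions:
            for comp in (rxn.reactants, rxn.products):
                if comp not in seen:
                    seen.add(comp)
                    out.append(comp)
        return out

    def complex_graph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.complexes())
        for rxn in self.reactions:
            g.add_edge(rxn.reactants, rxn.products, rate=rxn.rate)
        return g


@dataclass(frozen=True)
class NetworkSummary:
    """C, L, s, delta and weak reversibility of a reaction network."""

    n_complexes: int
    n_linkage_classes: int
    stoich_rank: int
    deficiency: int
    weakly_reversible: bool


def network_summary(net: ReactionNetwork) -> NetworkSummary:
    """Compute C, L, the exact integer stoichiometric rank, the deficiency
    delta = C - L - s, and weak reversibility (every connected component of
    the complex graph strongly connected).

    An empty network returns all zeros and is vacuously weakly reversible.
    """
    g = net.complex_graph()
    n_complexes = g.number_of_nodes()
    undirected = g.to_undirected(as_view=False)
    weak = [frozenset(c) for c in nx.connected_components(undirected)]
    strong = [frozenset(c) for c in nx.strongly_connected_components(g)]
    weakly_reversible = set(weak) == set(strong)
    if net.reactions:
        rank = int(sympy.Matrix(net.stoichiometry_matrix()).rank())
    else:
        rank = 0
    deficiency = n_complexes - len(weak) - rank
    return NetworkSummary(
        n_complexes=n_complexes,
        n_linkage_classes=len(weak),
        stoich_rank=rank,
        deficiency=deficiency,
        weakly_reversible=weakly_reversible,
    )


def conservation_laws(net: ReactionNetwork) -> list[np.ndarray]:
    """Integer basis of the left null space of the stoichiometry matrix.

    Each returned vector y (length n_species) satisfies y @ N == 0, i.e.
    y . x(t) is constant along every trajectory.  Vectors are scaled to
    coprime integers with positive leading entry, in a deterministic order.
    """
    if not net.reactions:
        return [np.eye(net.n_species, dtype=int)[i] for i in range(net.n_species)]
    N = sympy.Matrix(net.stoichiometry_matrix())
    basis = N.T.nullspace()
    out = []
    for vec in basis:
        denoms = [sympy.fraction(sympy.nsimplify(v))[1] for v in vec]
        scale = sympy.lcm([sympy.Integer(d) for d in denoms]) if denoms else 1
        ints = [int(v * scale) for v in vec]
        g = int(sympy.gcd(ints)) if any(ints) else 1
        arr = np.array([v // g for v in ints], dtype=int)
        lead = next((v for v in arr if v != 0), 1)
        if lead < 0:
            arr = -arr
        out.append(arr)
    out.sort(key=lambda a: tuple(a))
    return out


class MassActionSystem:
    """Array-backed mass-action ODE system for fast (batched) evaluation.

    Wraps a network plus numeric rate constants; `rhs` and `jacobian`
    accept a single state vector or a batch of states (..., n_species).
    """

    def __init__(self, net: ReactionNetwork, params: Mapping[str, float]):
        self.net = net
        self.species = list(net.species)
        missing = [r.rate for r in net.reactions if r.rate not in params]
        if missing:
            raise ConfigurationError(f"missing rate constant(s): {', '.join(missing)}")
        self.k = np.array([float(params[r.rate]) for r in net.reactions])
        if np.any(self.k <= 0):
            bad = [net.reactions[i].rate for i in np.nonzero(self.k <= 0)[0]]
            raise ConfigurationError(f"non-positive rate constant(s): {', '.join(bad)}")
        self.R = net.reactant_order_matrix()          # (nr, ns)
        self.N = net.stoichiometry_matrix()           # (ns, nr)
        self._NT = self.N.T.astype(float)

    def flux(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.k * np.prod(x[..., None, :] ** self.R, axis=-1)

    def rhs(self, x: np.ndarray) -> np.ndarray:
        return self.flux(x) @ self.N.T.astype(float)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """Exact analytic Jacobian d(rhs)/dx, batched over leading axes."""
        x = np.asarray(x, dtype=float)
        P = x[..., None, :] ** self.R                      # (..., nr, ns)
        tot = np.prod(P, axis=-1)                          # (..., nr)
        if np.all(x > 0):
            dflux = self.k[..., :, None] * self.R * tot[..., :, None] / x[..., None, :]
        else:
            # slow exact path for states touching zero
            dflux = np.zeros(P.shape)
            ns = len(self.species)
            for j in range(ns):
                Pj = P.copy()
                expo = np.where(self.R[:, j] > 0, self.R[:, j] - 1, 0)
                Pj[..., :, j] = x[..., j, None] ** expo
                excl = np.prod(Pj, axis=-1)
                dflux[..., :, j] = self.k * self.R[:, j] * excl
        return np.einsum("ir,...rj->...ij", self._NT.T, dflux)

    def conserved_quantities(self, x: np.ndarray, laws: Sequence[np.ndarray]) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.stack([x @ law.astype(float) for law in laws], axis=-1)


def mass_action_rhs(net: ReactionNetwork, params: Mapping[str, float]) -> Callable[[Mapping[str, float]], dict[str, float]]:
    """Dict-in/dict-out time derivative under mass-action kinetics.

    For a reaction with rate constant k and reactant complex sum a_i X_i the
    flux is k * prod x_i**a_i.  Raises :class:`ConfigurationError` naming any
    rate constant missing from ``params``.
    """
    system = MassActionSystem(net, params)

    def rhs(state: Mapping[str, float]) -> dict[str, float]:
        x = np.array([float(state[s]) for s in net.species])
        dx = system.rhs(x)
        return {s: float(dx[i]) for i, s in enumerate(net.species)}

    return rhs


def jacobian(net: ReactionNetwork, params: Mapping[str, float], state: Mapping[str, float] | np.ndarray) -> np.ndarray:
    """Exact Jacobian of the mass-action RHS at ``state`` (species order of ``net``)."""
    system = MassActionSystem(net, params)
    if isinstance(state, Mapping):
        x = np.array([float(state[s]) for s in net.species])
    else:
        x = np.asarray(state, dtype=float)
    return system.jacobian(x)


# ---------------------------------------------------------------------------
# plain-text reaction-list serialization:  "A + 2 B -> C ; k1"
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+)\s+)?(\S+)$")


def _parse_side(text: str) -> dict[str, int]:
    text = text.strip()
    if text == "0":
        return {}
    out: dict[str, int] = {}
    for term in text.split("+"):
        m = _TERM_RE.match(term.strip())
        if not m:
            raise ValueError(f"cannot parse complex term {term!r}")
        coeff = int(m.group(1)) if m.group(1) else 1
        name = m.group(2)
        out[name] = out.get(name, 0) + coeff
    return out


def write_reactions(net: ReactionNetwork, path=None) -> str:
    """Serialize to the one-reaction-per-line text format; round-trip exact."""
    lines = ["# species: " + " ".join(net.species)]
    lines.extend(str(r) for r in net.reactions)
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_reactions(source) -> ReactionNetwork:
    """Parse the text format written by :func:`write_reactions`.

    ``source`` is a path or a string containing the serialized network.
    """
    if isinstance(source, str) and "\n" not in source and not source.lstrip().startswith("#"):
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    species: list[str] | None = None
    reactions: list[Reaction] = []
    appearance: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("# species:"):
                species = line[len("# species:"):].split()
            continue
        body, _, rate = line.partition(";")
        rate = rate.strip()
        if not rate:
            raise ValueError(f"missing rate name in line {line!r}")
        lhs, arrow, rhs_txt = body.partition("->")
        if not arrow:
            raise ValueError(f"missing '->' in line {line!r}")
        reactants = _parse_side(lhs)
        products = _parse_side(rhs_txt)
        for name in list(reactants) + list(products):
            if name not in appearance:
                appearance.append(name)
        reactions.append(Reaction(as_complex(reactants), as_complex(products), rate))
    return ReactionNetwork(tuple(species if species is not None else appearance), tuple(reactions))


# ---------------------------------------------------------------------------
# SBML Level 3 export (mass-action kinetic laws); export only
# ---------------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _sbml_id(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "_", name)


def to_sbml(net: ReactionNetwork, params: Mapping[str, float] | None = None) -> str:
    """Serialize the network to an SBML Level 3 Version 2 document string.

    Every reaction carries an explicit mass-action kinetic law
    k * prod(reactant^stoich).  Rate constants default to 1 when ``params``
    is not given.
    """
    ET.register_namespace("", _SBML_NS)
    root = ET.Element(f"{{{_SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(root, f"{{{_SBML_NS}}}model", {"id": "multiphos_model"})
    comps = ET.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{_SBML_NS}}}compartment",
                  {"id": "cell", "constant": "true", "size": "1", "spatialDimensions": "3"})
    species_el = ET.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    for s in net.species:
        ET.SubElement(species_el, f"{{{_SBML_NS}}}species",
                      {"id": _sbml_id(s), "name": s, "compartment": "cell",
                       "hasOnlySubstanceUnits": "false", "boundaryCondition": "false",
                       "constant": "false", "initialConcentration": "0"})
    params_el = ET.SubElement(model, f"{{{_SBML_NS}}}listOfParameters")
    for r in net.reactions:
        value = 1.0 if params is None else float(params[r.rate]) if r.rate in params else 1.0
        ET.SubElement(params_el, f"{{{_SBML_NS}}}parameter",
                      {"id": _sbml_id(r.rate), "name": r.rate, "value": repr(value), "constant": "true"})
    rxns_el = ET.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")
    for r in net.reactions:
        rxn_el = ET.SubElement(rxns_el, f"{{{_SBML_NS}}}reaction",
                               {"id": f"r_{_sbml_id(r.rate)}", "reversible": "false"})
        if r.reactants:
            lhs = ET.SubElement(rxn_el, f"{{{_SBML_NS}}}listOfReactants")
            for name, c in r.reactants:
                ET.SubElement(lhs, f"{{{_SBML_NS}}}speciesReference",
                              {"species": _sbml_id(name), "stoichiometry": str(c), "constant": "true"})
        if r.products:
            rhs_el = ET.SubElement(rxn_el, f"{{{_SBML_NS}}}listOfProducts")
            for name, c in r.products:
                ET.SubElement(rhs_el, f"{{{_SBML_NS}}}speciesReference",
                              {"species": _sbml_id(name), "stoichiometry": str(c), "constant": "true"})
        kl = ET.SubElement(rxn_el, f"{{{_SBML_NS}}}kineticLaw")
        math = ET.SubElement(kl, f"{{{_MATHML_NS}}}math")
        apply_el = ET.SubElement(math, f"{{{_MATHML_NS}}}apply")
        ET.SubElement(apply_el, f"{{{_MATHML_NS}}}times")
        ci = ET.SubElement(apply_el, f"{{{_MATHML_NS}}}ci")
        ci.text = _sbml_id(r.rate)
        for name, c in r.reactants:
            for _ in range(c):
                ci = ET.SubElement(apply_el, f"{{{_MATHML_NS}}}ci")
                ci.text = _sbml_id(name)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)
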