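"""Deterministic toy models and randomized generators.

``TOY6`` is a six-metabolite, six-reaction model with a unique LP optimum,
an ATP/ADP cofactor pair and a linear uptake→biomass backbone:

    UPT: ∅ → A   [0, 10]
    R1:  A → B
    R2:  B + ATP → C + ADP
    R3:  B → D
    REG: ADP → ATP
    BIO: C + D → ∅   (objective)

Mass balance forces v_UPT = v_R1 = 10, v_R2 = v_R3 = v_REG = v_BIO = 5, so
the optimal growth is 5.  ``TOY6Z`` adds a dead-end uptake (UPT2: ∅ → E)
whose flux every steady state pins to zero, exercising the zero-flux
filter.  ``make_random_gem`` builds parallel uptake→…→biomass chains (which
guarantees a feasible, bounded, nonzero optimum) plus random cross
reactions; ``make_random_flux_graph`` builds connected random bipartite
flux graphs with deliberately tie-heavy weights for exercising the greedy
tree tie-breaks.  All generators are pure functions of their arguments.
"""

from __future__ import annotations

import numpy as np

from .flux_graph import CONSUMED_BY, PRODUCED_BY, FluxGraph, Node
from .gem_model import GEM, Metabolite, Reaction

__all__ = ["make_toy_gem", "make_random_gem", "make_random_flux_graph", "TOY_NAMES"]

TOY_NAMES = ("TOY6", "TOY6Z")


def make_toy_gem(name: str = "TOY6") -> GEM:
    name = name.upper()
    if name not in TOY_NAMES:
        raise ValueError(f"unknown toy model {name!r} (expected one of {TOY_NAMES})")
    mets = [
        Metabolite("A", "substrate A", "c", formula="C6H12O6"),
        Metabolite("B", "intermediate B", "c", formula="C3H4O3"),
        Metabolite("C", "precursor C", "c", formula="C4H6O4"),
        Metabolite("D", "precursor D", "c", formula="C2H4O2"),
        Metabolite("ATP", "ATP", "c", formula="C10H16N5O13P3"),
        Metabolite("ADP", "ADP", "c", formula="C10H15N5O10P2"),
    ]
    rxns = [
        Reaction("UPT", "uptake of A", {"A": 1.0}, 0.0, 10.0),
        Reaction("R1", "A to B", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
        Reaction("R2", "B to C (ATP-coupled)",
                 {"B": -1.0, "ATP": -1.0, "C": 1.0, "ADP": 1.0}, 0.0, 1000.0),
        Reaction("R3", "B to D", {"B": -1.0, "D": 1.0}, 0.0, 1000.0),
        Reaction("REG", "ATP regeneration", {"ADP": -1.0, "ATP": 1.0}, 0.0, 1000.0),
        Reaction("BIO", "biomass drain", {"C": -1.0, "D": -1.0}, 0.0, 1000.0,
                 objective_coefficient=1.0),
    ]
    if name == "TOY6Z":
        mets.append(Metabolite("E", "dead-end E", "c", formula="CH4"))
        rxns.append(Reaction("UPT2", "dead-end uptake", {"E": 1.0}, 0.0, 10.0))
    gem = GEM(model_id=name, compartments={"c": "cytosol"},
              metabolites=mets, reactions=rxns, objective_reaction_id="BIO")
    from .gem_model import molecular_weight
    for m in gem.metabolites:
        m.molecular_weight = molecular_weight(m.formula)
    gem.validate()
    return gem


def make_random_gem(n_pathways: int, pathway_length: int,
                    n_extra_edges: int = 0, seed: int = 0) -> GEM:
    """Random feasible GEM: parallel irreversible chains from uptake to a
    shared biomass drain, plus random cross-linking reactions."""
    if n_pathways < 1 or pathway_length < 1 or n_extra_edges < 0:
        raise ValueError("sizes must be positive (extras may be zero)")
    rng = np.random.default_rng(seed)
    gem = GEM(model_id=f"RAND_{seed}", compartments={"c": "cytosol"})
    chain_ends = []
    for p in range(n_pathways):
        ids = [f"M{p}_{i}" for i in range(pathway_length + 1)]
        for i, mid in enumerate(ids):
            k = int(rng.integers(1, 9))
            gem.metabolites.append(
                Metabolite(mid, mid, "c", formula=f"C{k}H{2 * k}O{k}")
            )
        uptake = float(np.round(rng.uniform(5.0, 15.0), 3))
        gem.reactions.append(
            Reaction(f"UPT{p}", f"uptake {p}", {ids[0]: 1.0}, 0.0, uptake)
        )
        for i in range(pathway_length):
            gem.reactions.append(
                Reaction(f"R{p}_{i}", f"step {p}.{i}",
                         {ids[i]: -1.0, ids[i + 1]: 1.0}, 0.0, 1000.0)
            )
        chain_ends.append(ids[-1])
    gem.reactions.append(
        Reaction("BIO", "biomass drain", {m: -1.0 for m in chain_ends},
                 0.0, 1000.0, objective_coefficient=1.0)
    )
    all_mets = [m.id for m in gem.metabolites]
    for j in range(n_extra_edges):
        a, b = rng.choice(len(all_mets), size=2, replace=False)
        gem.reactions.append(
            Reaction(f"X{j}", f"cross {j}",
                     {all_mets[int(a)]: -1.0, all_mets[int(b)]: 1.0}, 0.0, 1000.0)
        )
    gem.objective_reaction_id = "BIO"
    from .gem_model import molecular_weight
    for m in gem.metabolites:
        m.molecular_weight = molecular_weight(m.formula)
    gem.validate()
    return gem


def make_random_flux_graph(n_nodes: int, n_extra_edges: int = 5,
                           seed: int = 0) -> FluxGraph:
    """Connected random bipartite flux graph with tie-heavy weights.

    A random spanning structure guarantees connectivity; extra random
    metabolite–reaction edges (multi-edges allowed) add cycles.  Weights
    are drawn from a small set so greedy tie-breaking rules are exercised
    often.
    """
    if n_nodes < 2:
        raise ValueError("need at least two nodes")
    rng = np.random.default_rng(seed)
    n_mets = int(rng.integers(1, n_nodes))
    n_rxns = n_nodes - n_mets
    if n_rxns < 1:
        n_mets, n_rxns = n_nodes - 1, 1
    g = FluxGraph()
    mets = [f"M{i:02d}" for i in range(n_mets)]
    rxns = [f"R{i:02d}" for i in range(n_rxns)]
    for m in mets:
        g.add_node(Node(m, "metabolite", label=m))
    for r in rxns:
        g.add_node(Node(r, "reaction", label=r, flux=float(rng.uniform(0, 10))))

    weights = np.array([1.0, 1.0, 2.0, 3.0, 5.0])

    def random_edge(met: str, rxn: str) -> None:
        role = CONSUMED_BY if rng.random() < 0.5 else PRODUCED_BY
        g.add_edge(met, rxn, role, float(rng.choice([1.0, 2.0])),
                   float(rng.choice(weights)))

    # spanning skeleton over an interleaved node order
    order = mets[:1] + rxns[:1]
    random_edge(mets[0], rxns[0])
    rest = mets[1:] + rxns[1:]
    rng.shuffle(rest)
    for nid in rest:
        is_met = nid.startswith("M")
        partners = [p for p in order if p.startswith("R" if is_met else "M")]
        partner = partners[int(rng.integers(len(partners)))]
        if is_met:
            random_edge(nid, partner)
        else:
            random_edge(partner, nid)
        order.append(nid)
    for _ in range(n_extra_edges):
        random_edge(mets[int(rng.integers(n_mets))],
                    rxns[int(rng.integers(n_rxns))])
    return g
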