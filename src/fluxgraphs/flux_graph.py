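"""Weighted bipartite flux graphs and their tree decompositions.

The metabolic network is encoded as a bipartite graph: one node per
metabolite and per reaction, one edge per participation of a metabolite in
a reaction.  Edge direction follows the *net* flux: a reaction with
negative flux has its declared reactants and products swapped before the
``consumed-by`` / ``produced-by`` role is assigned, so arrows always follow
the material flow of the particular FBA solution.  Edge weights are the
product of a user-selectable combination of |reaction flux|, stoichiometric
coefficient and metabolite molecular weight; with nothing selected every
edge weighs exactly 1.

Two rooted decompositions are provided:

``spanning_tree``
    Greedy growth from the root: at every step the frontier edge ranked
    highest by (largest weight, then smallest prospective depth, then
    flux-toward-root before flux-from-root, then alphabetical node ids) is
    added.  Each node appears once.  With unit weights this reduces exactly
    to an alphabetically sorted breadth-first search, so tree depth equals
    BFS distance from the root.

``complete_tree``
    Breadth-first traversal with the same frontier ranking in which an edge
    that reaches an already-placed node spawns a *duplicate* leaf instance,
    so every edge of the graph is displayed exactly once.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Hashable, Iterable

from .fba_core import DEFAULT_ZERO_TOLERANCE, FluxState
from .gem_model import GEM, GEMError

__all__ = [
    "WeightOptions",
    "Node",
    "Edge",
    "FluxGraph",
    "SpanningTree",
    "NodeInstance",
    "DuplicatedTree",
    "TreeView",
    "edge_weight",
    "build_graph",
    "spanning_tree",
    "complete_tree",
]

CONSUMED_BY = "consumed-by"   # metabolite -> reaction
PRODUCED_BY = "produced-by"   # reaction -> metabolite


@dataclass(frozen=True)
class WeightOptions:
    """Which factors enter the edge weight product."""

    use_flux: bool = False
    use_stoichiometry: bool = False
    use_molecular_weight: bool = False

    @property
    def any(self) -> bool:
        return self.use_flux or self.use_stoichiometry or self.use_molecular_weight


@dataclass
class Node:
    id: str
    kind: str  # "metabolite" | "reaction"
    label: str = ""
    compartment: str | None = None
    flux: float | None = None  # reaction nodes only
    is_cofactor: bool = False


@dataclass
class Edge:
    metabolite: str
    reaction: str
    role: str  # CONSUMED_BY | PRODUCED_BY
    stoich: float
    weight: float
    index: int = -1

    @property
    def source(self) -> str:
        return self.metabolite if self.role == CONSUMED_BY else self.reaction

    @property
    def target(self) -> str:
        return self.reaction if self.role == CONSUMED_BY else self.metabolite

    def other(self, node_id: str) -> str:
        if node_id == self.metabolite:
            return self.reaction
        if node_id == self.reaction:
            return self.metabolite
        raise KeyError(f"{node_id!r} is not an endpoint of this edge")


class FluxGraph:
    """Directed weighted bipartite graph of metabolite and reaction nodes."""

    def __init__(self, options: WeightOptions | None = None):
        self.nodes: dict[str, Node] = {}
        self.edges: list[Edge] = []
        self.options = options or WeightOptions()
        self._adj: dict[str, list[int]] = {}

    # -- construction ----------------------------------------------------
    def add_node(self, node: Node) -> Node:
        existing = self.nodes.get(node.id)
        if existing is not None:
            if existing.kind != node.kind:
                raise GEMError(
                    f"node id {node.id!r} used for both a metabolite and a reaction"
                )
            return existing
        self.nodes[node.id] = node
        self._adj[node.id] = []
        return node

    def add_edge(self, metabolite: str, reaction: str, role: str,
                 stoich: float, weight: float) -> Edge:
        if metabolite not in self.nodes or reaction not in self.nodes:
            raise KeyError("both endpoints must be added before the edge")
        e = Edge(metabolite, reaction, role, stoich, weight, index=len(self.edges))
        self.edges.append(e)
        self._adj[metabolite].append(e.index)
        self._adj[reaction].append(e.index)
        return e

    # -- queries ---------------------------------------------------------
    def incident(self, node_id: str) -> list[Edge]:
        return [self.edges[i] for i in self._adj[node_id]]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    # -- mutation --------------------------------------------------------
    def prune_isolated(self) -> int:
        """Drop nodes with no incident edges; returns how many were removed."""
        lonely = [nid for nid, idx in self._adj.items() if not idx]
        for nid in lonely:
            del self.nodes[nid]
            del self._adj[nid]
        return len(lonely)


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

def edge_weight(flux: float | None, stoich: float, mw: float | None,
                opts: WeightOptions) -> float:
    """Product of the selected components; 1.0 when none are selected.

    ``flux`` enters as |flux| (the direction was already consumed by the
    role swap); an absent molecular weight contributes a factor of 1.
    """
    w = 1.0
    if opts.use_flux:
        w *= abs(flux) if flux is not None else 0.0
    if opts.use_stoichiometry:
        w *= stoich
    if opts.use_molecular_weight and mw is not None:
        w *= mw
    return w


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def build_graph(
    gem: GEM,
    flux: FluxState | None = None,
    opts: WeightOptions | None = None,
    exclude_zero_flux: bool = False,
    exclude_cofactors: bool = False,
    merge_compartments: bool = False,
) -> FluxGraph:
    """Bipartite flux graph of ``gem`` under the given display filters.

    ``exclude_zero_flux`` drops reactions whose |flux| is at or below the
    flux state's zero tolerance; ``exclude_cofactors`` drops metabolite
    nodes tagged as cofactors together with their edges;
    ``merge_compartments`` collapses metabolites sharing a base id into a
    single node.  Nodes left isolated by filtering are pruned.
    """
    opts = opts or WeightOptions()
    if flux is None and (opts.use_flux or exclude_zero_flux):
        raise ValueError(
            "flux-dependent options require a FluxState (run optimize first)"
        )
    tol = flux.zero_tolerance if flux is not None else DEFAULT_ZERO_TOLERANCE

    graph = FluxGraph(options=opts)
    for rxn in gem.reactions:
        f = flux.fluxes.get(rxn.id) if (flux is not None and flux.fluxes) else None
        if exclude_zero_flux and (f is None or abs(f) <= tol):
            continue
        participations = []
        for met_id in sorted(rxn.stoichiometry):
            coeff = rxn.stoichiometry[met_id]
            if coeff == 0:
                continue
            met = gem.metabolite(met_id)
            if exclude_cofactors and met.is_cofactor:
                continue
            participations.append((met, coeff))
        if not participations:
            continue
        rnode = graph.add_node(
            Node(rxn.id, "reaction", label=rxn.name or rxn.id, flux=f)
        )
        for met, coeff in participations:
            node_id = gem.base_id(met.id) if merge_compartments else met.id
            graph.add_node(
                Node(
                    node_id,
                    "metabolite",
                    label=met.name or node_id,
                    compartment=None if merge_compartments else met.compartment,
                    is_cofactor=met.is_cofactor,
                )
            )
            consumed = coeff < 0
            if f is not None and f < -tol:
                consumed = not consumed  # net flux runs backwards
            graph.add_edge(
                metabolite=node_id,
                reaction=rnode.id,
                role=CONSUMED_BY if consumed else PRODUCED_BY,
                stoich=abs(coeff),
                weight=edge_weight(f, abs(coeff), met.molecular_weight, opts),
            )
    graph.prune_isolated()
    return graph


# ---------------------------------------------------------------------------
# rooted trees
# ---------------------------------------------------------------------------

def frontier_key(edge: Edge, tree_node: str, new_node: str,
                 prospective_depth: int) -> tuple:
    """Ranking of a frontier edge; smaller sorts first.

    Order: larger weight, then smaller prospective depth, then edges whose
    flux-resolved direction points toward the root (new node feeding the
    tree), then alphabetical new-node id, then alphabetical tree-endpoint
    id.  The unit-weight special case degenerates to an alphabetically
    sorted BFS with producers placed first within each depth level.
    """
    toward = 0 if edge.target == tree_node else 1
    return (-edge.weight, prospective_depth, toward, new_node, tree_node)


@dataclass
class TreeView:
    """Uniform drawable-tree interface consumed by the layout algorithms."""

    root: Hashable
    children: dict[Hashable, list[Hashable]]
    depth: dict[Hashable, int]
    node_id: dict[Hashable, str]
    parent: dict[Hashable, Hashable] = field(default_factory=dict)
    via_edge: dict[Hashable, Edge] = field(default_factory=dict)

    @property
    def keys(self) -> list[Hashable]:
        return list(self.depth)


@dataclass
class SpanningTree:
    root: str
    parent: dict[str, tuple[str, Edge]]
    depth: dict[str, int]
    insertion_order: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.insertion_order)

    def edges(self) -> list[Edge]:
        return [e for (_, e) in self.parent.values()]

    def children(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {nid: [] for nid in self.insertion_order}
        for child in self.insertion_order:
            if child in self.parent:
                out[self.parent[child][0]].append(child)
        return out

    def tree_view(self) -> TreeView:
        return TreeView(
            root=self.root,
            children=self.children(),
            depth=dict(self.depth),
            node_id={nid: nid for nid in self.insertion_order},
            parent={c: p for c, (p, _) in self.parent.items()},
            via_edge={c: e for c, (_, e) in self.parent.items()},
        )


def spanning_tree(graph: FluxGraph, root: str) -> SpanningTree:
    """Greedy maximum-weight spanning tree rooted at ``root``.

    Nodes unreachable from the root are omitted.  Raises ``KeyError`` for an
    unknown root id.
    """
    if root not in graph:
        raise KeyError(f"root node {root!r} is not in the graph")
    depth = {root: 0}
    parent: dict[str, tuple[str, Edge]] = {}
    order = [root]
    heap: list[tuple] = []

    def push_frontier(u: str) -> None:
        for e in graph.incident(u):
            x = e.other(u)
            if x not in depth:
                heapq.heappush(heap, frontier_key(e, u, x, depth[u] + 1) + (e.index,))

    push_frontier(root)
    while heap:
        _w, d, _t, x, u, ei = heapq.heappop(heap)
        if x in depth:
            continue  # stale candidate
        depth[x] = d
        parent[x] = (u, graph.edges[ei])
        order.append(x)
        push_frontier(x)
    return SpanningTree(root=root, parent=parent, depth=depth, insertion_order=order)


@dataclass
class NodeInstance:
    node_id: str
    index: int
    is_duplicate: bool


@dataclass
class DuplicatedTree:
    root: str
    instances: list[NodeInstance]
    parent: dict[int, int]          # instance index -> parent instance index
    via_edge: dict[int, Edge]
    depth: dict[int, int]

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    @property
    def n_duplicates(self) -> int:
        return sum(inst.is_duplicate for inst in self.instances)

    def edges(self) -> list[tuple[int, int, Edge]]:
        return [(self.parent[i], i, e) for i, e in sorted(self.via_edge.items())]

    def tree_view(self) -> TreeView:
        children: dict[int, list[int]] = {inst.index: [] for inst in self.instances}
        for i in range(1, len(self.instances)):
            children[self.parent[i]].append(i)
        return TreeView(
            root=0,
            children=children,
            depth=dict(self.depth),
            node_id={inst.index: inst.node_id for inst in self.instances},
            parent=dict(self.parent),
            via_edge=dict(self.via_edge),
        )


def complete_tree(graph: FluxGraph, root: str) -> DuplicatedTree:
    """Breadth-first duplicated tree: every reachable graph edge appears
    exactly once; reaching an already-placed node spawns a duplicate leaf."""
    if root not in graph:
        raise KeyError(f"root node {root!r} is not in the graph")
    instances = [NodeInstance(root, 0, False)]
    placed: dict[str, int] = {root: 0}
    parent: dict[int, int] = {}
    via: dict[int, Edge] = {}
    depth = {0: 0}
    used: set[int] = set()
    heap: list[tuple] = []

    def push_frontier(inst_idx: int) -> None:
        u = instances[inst_idx].node_id
        for e in graph.incident(u):
            if e.index in used:
                continue
            x = e.other(u)
            heapq.heappush(
                heap, frontier_key(e, u, x, depth[inst_idx] + 1) + (e.index, inst_idx)
            )

    push_frontier(0)
    while heap:
        _w, d, _t, x, _u, ei, u_idx = heapq.heappop(heap)
        if ei in used:
            continue
        used.add(ei)
        idx = len(instances)
        dup = x in placed
        instances.append(NodeInstance(x, idx, dup))
        parent[idx] = u_idx
        via[idx] = graph.edges[ei]
        depth[idx] = d
        if not dup:
            placed[x] = idx
            push_frontier(idx)
    return DuplicatedTree(root=root, instances=instances, parent=parent,
                          via_edge=via, depth=depth)
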