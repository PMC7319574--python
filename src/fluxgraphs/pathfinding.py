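"""k-shortest loopless metabolic paths under flux-aware edge costs.

Paths run along the flux-resolved direction of the bipartite graph's edges
(metabolite → reaction for consumption, reaction → metabolite for
production), so a path is an alternating metabolite/reaction sequence that
material could actually follow in the particular FBA solution.

Two cost metrics are available.  Unweighted, every edge costs 1 and path
cost is simply the number of hops ("number of reactions as a metric").
Weighted, each edge costs the *reciprocal* of its weight, so heavy
(high-flux) edges are cheap and the shortest path is the highest-flux
route; a zero-weight edge costs +inf and is impassable.  The reciprocal is
this package's choice of monotone weight→cost transform (a −log transform
was rejected: it goes negative for weights below 1, breaking Dijkstra).

``k_shortest`` follows a single-edge-removal scheme: starting from the
shortest path, every edge of every path found so far is removed one at a
time and the shortest-path search repeated on the reduced graph.
``first_k`` stops as soon as k distinct paths exist and is a fast
heuristic; ``best_k`` exhausts all removals reachable through the growing
found-set and returns the k cheapest among everything found.  Unlike the
classic spur-node variant of Yen's algorithm there is no root-path
anchoring, so ``best_k`` can in rare topologies miss a true i-th shortest
path, but it never reports a path cheaper than one that exists.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field

from .flux_graph import Edge, FluxGraph

__all__ = ["Path", "PathSet", "edge_cost", "shortest_path", "k_shortest"]

INF = math.inf


def edge_cost(weight: float, weighted: bool) -> float:
    """Cost of traversing an edge: 1/weight if ``weighted`` (0 → +inf), else 1."""
    if not weighted:
        return 1.0
    return 1.0 / weight if weight > 0 else INF


@dataclass
class Path:
    """Loopless alternating metabolite/reaction walk with its total cost."""

    nodes: list[str]
    edges: list[Edge]
    cost: float
    rank: int = 0

    def key(self) -> tuple[str, ...]:
        return tuple(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class PathSet:
    source: str
    target: str
    k_requested: int
    mode: str  # "first_k" | "best_k"
    paths: list[Path] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self):
        return iter(self.paths)

    # -- reports ---------------------------------------------------------
    def to_text(self, graph: FluxGraph | None = None) -> str:
        lines = [
            f"# {len(self.paths)} path(s) {self.source} -> {self.target} "
            f"(k={self.k_requested}, mode={self.mode})"
        ]
        for p in self.paths:
            steps = []
            for nid in p.nodes:
                node = graph.nodes.get(nid) if graph is not None else None
                if node is not None and node.kind == "reaction" and node.flux is not None:
                    steps.append(f"{nid}[{node.flux:g}]")
                else:
                    steps.append(nid)
            lines.append(f"{p.rank}\tcost={p.cost:g}\t" + " -> ".join(steps))
        return "\n".join(lines) + "\n"

    def to_json(self, graph: FluxGraph | None = None) -> str:
        def flux_of(nid: str) -> float | None:
            if graph is None:
                return None
            node = graph.nodes.get(nid)
            return node.flux if node is not None and node.kind == "reaction" else None

        payload = {
            "source": self.source,
            "target": self.target,
            "k_requested": self.k_requested,
            "mode": self.mode,
            "paths": [
                {
                    "rank": p.rank,
                    "cost": p.cost,
                    "nodes": [
                        {"id": nid, "flux": flux_of(nid)} for nid in p.nodes
                    ],
                }
                for p in self.paths
            ],
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Dijkstra
# ---------------------------------------------------------------------------

def shortest_path(
    graph: FluxGraph,
    source: str,
    target: str,
    weighted: bool = False,
    excluded_edges: frozenset[int] | set[int] = frozenset(),
) -> Path | None:
    """Deterministic Dijkstra along directed edges; ``None`` if unreachable.

    Ties are broken by lexicographic node id in the priority queue and, for
    equal-cost predecessors, by the smaller predecessor id.
    """
    for nid in (source, target):
        if nid not in graph:
            raise KeyError(f"unknown node id {nid!r}")
    dist: dict[str, float] = {source: 0.0}
    pred: dict[str, tuple[str, Edge]] = {}
    done: set[str] = set()
    heap: list[tuple[float, str]] = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        if u == target:
            break
        for e in graph.incident(u):
            if e.index in excluded_edges or e.source != u:
                continue
            cost = edge_cost(e.weight, weighted)
            if cost == INF:
                continue
            x = e.target
            nd = d + cost
            old = dist.get(x, INF)
            if nd < old or (nd == old and x not in done and u < pred[x][0]):
                dist[x] = nd
                pred[x] = (u, e)
                heapq.heappush(heap, (nd, x))
    if target not in dist or (target != source and target not in pred):
        return None if target != source else Path([source], [], 0.0)
    nodes = [target]
    edges: list[Edge] = []
    while nodes[-1] != source:
        u, e = pred[nodes[-1]]
        nodes.append(u)
        edges.append(e)
    return Path(nodes[::-1], edges[::-1], dist[target])


# ---------------------------------------------------------------------------
# k-shortest (single-edge-removal scheme)
# ---------------------------------------------------------------------------

def k_shortest(
    graph: FluxGraph,
    source: str,
    target: str,
    k: int,
    weighted: bool = False,
    mode: str = "best_k",
) -> PathSet:
    """The k cheapest distinct loopless paths found by single-edge removal.

    The found-set starts with the plain shortest path; for each path found
    so far (discovery order) and each of its edges (path order), the
    shortest path with that single edge removed is computed and added if
    new.  ``first_k`` stops when k distinct paths exist; ``best_k``
    exhausts every removal before keeping the k cheapest.  Output is sorted
    by (cost, lexicographic node sequence) and ranked from 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("first_k", "best_k"):
        raise ValueError(f"unknown mode {mode!r}")
    result = PathSet(source=source, target=target, k_requested=k, mode=mode)
    first = shortest_path(graph, source, target, weighted)
    if first is None:
        return result
    found: list[Path] = [first]
    seen = {first.key()}
    if not (mode == "first_k" and k == 1):
        i = 0
        while i < len(found):
            for e in found[i].edges:
                p = shortest_path(graph, source, target, weighted,
                                  excluded_edges={e.index})
                if p is not None and p.key() not in seen:
                    seen.add(p.key())
                    found.append(p)
                    if mode == "first_k" and len(found) >= k:
                        break
            if mode == "first_k" and len(found) >= k:
                break
            i += 1
    found.sort(key=lambda p: (p.cost, p.key()))
    result.paths = found[:k]
    for rank, p in enumerate(result.paths, start=1):
        p.rank = rank
    return result
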