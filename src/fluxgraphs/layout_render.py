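"""2-D layouts and renderers for flux trees, path DAGs and full graphs.

Layout families:

* ``tidy_layout`` — Reingold–Tilford-style tidy tree: depth on the
  horizontal axis with the root at the right (x = −depth), sibling subtrees
  packed by contour merging with ≥ 1 unit separation, parents centered on
  the midpoint of their children's extent.
* ``dendrogram_layout`` — all leaves on a common leftmost column, equally
  spaced; internal nodes centered over their children.
* ``radial_transform`` — wraps either tree layout onto concentric circles
  (radius = depth, angle = normalized breadth); root at the origin.
* ``layered_layout`` — Sugiyama-style layered drawing for DAGs:
  longest-path layering, dummy nodes for long edges, iterative barycenter
  sweeps for crossing reduction (the best ordering seen is kept, so the
  final crossing count never exceeds the initial one).
* ``force_layout`` — a particle simulation integrated with the velocity
  Verlet scheme: pairwise 1/d² repulsion, Hookean springs along edges,
  weak centering, velocity decay.  Deterministic for a fixed seed.

Rendering emits SVG 1.1 (metabolites yellow, reactions green; edges blue
when directed toward the tree root and red away from it, per-path colors
for path sets with overlaps resolved in favor of the lower rank).
``export_graph`` writes GraphML (round-trip exact via ``import_graphml``),
a node-link JSON schema (documented in docs/json_schema.md) and Graphviz
DOT.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path as _P
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np

from .flux_graph import (
    CONSUMED_BY,
    DuplicatedTree,
    Edge,
    FluxGraph,
    Node,
    SpanningTree,
    TreeView,
    WeightOptions,
)
from .pathfinding import PathSet

__all__ = [
    "LayoutResult",
    "RenderStyle",
    "ForceParams",
    "tidy_layout",
    "dendrogram_layout",
    "radial_transform",
    "layered_layout",
    "force_layout",
    "count_crossings",
    "render_svg",
    "export_graph",
    "import_graphml",
]

MIN_SEPARATION = 1.0


@dataclass
class LayoutResult:
    coordinates: dict[Hashable, tuple[float, float]]
    layout_kind: str
    #: (xmin, ymin, xmax, ymax)
    bounds: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    #: algorithm diagnostics (e.g. crossing counts for layered layouts)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coordinates and self.bounds == (0.0, 0.0, 0.0, 0.0):
            xs = [p[0] for p in self.coordinates.values()]
            ys = [p[1] for p in self.coordinates.values()]
            self.bounds = (min(xs), min(ys), max(xs), max(ys))


@dataclass
class RenderStyle:
    metabolite_color: str = "#f3d34a"   # yellow
    reaction_color: str = "#58b368"     # green
    toward_root_edge_color: str = "#3b6fd4"  # blue
    from_root_edge_color: str = "#d43b3b"    # red
    edge_emphasis: str | None = None    # None | "width" | "opacity"
    label_mode: str = "id"              # id | name | flux | localization | none
    scale: float = 60.0
    node_radius: float = 7.0


def _as_tree_view(tree) -> TreeView:
    if isinstance(tree, TreeView):
        return tree
    if isinstance(tree, (SpanningTree, DuplicatedTree)):
        return tree.tree_view()
    raise TypeError(f"not a tree: {type(tree).__name__}")


# ---------------------------------------------------------------------------
# tidy tree (contour packing)
# ---------------------------------------------------------------------------

def tidy_layout(tree) -> LayoutResult:
    """Tidy tree drawing: x = −depth (root right), breadth on y.

    Sibling subtrees are packed left-to-right in child order so that at
    every shared depth they stay ≥ 1 unit apart; each parent sits on the
    midpoint of its first and last child.
    """
    view = _as_tree_view(tree)
    order = sorted(view.depth, key=lambda k: view.depth[k], reverse=True)

    # Per-subtree contour: relative depth -> (min_y, max_y) in the node's
    # own frame, where the node itself sits at y = 0.
    contour: dict[Hashable, dict[int, tuple[float, float]]] = {}
    offset: dict[Hashable, float] = {}  # child y relative to its parent

    for key in order:  # children strictly before parents
        kids = view.children.get(key, [])
        if not kids:
            contour[key] = {0: (0.0, 0.0)}
            continue
        merged: dict[int, tuple[float, float]] = {}
        roots: list[float] = []
        for child in kids:
            sub = contour.pop(child)
            shift = 0.0
            if merged:
                for d, (lo, _hi) in sub.items():
                    if d in merged:
                        shift = max(shift, merged[d][1] + MIN_SEPARATION - lo)
            roots.append(shift)
            for d, (lo, hi) in sub.items():
                if d in merged:
                    mlo, mhi = merged[d]
                    merged[d] = (min(mlo, lo + shift), max(mhi, hi + shift))
                else:
                    merged[d] = (lo + shift, hi + shift)
        center = (roots[0] + roots[-1]) / 2.0
        for child, r in zip(kids, roots):
            offset[child] = r - center
        own = {d + 1: (lo - center, hi - center) for d, (lo, hi) in merged.items()}
        own[0] = (0.0, 0.0)
        contour[key] = own

    coords: dict[Hashable, tuple[float, float]] = {}
    stack: list[tuple[Hashable, float]] = [(view.root, 0.0)]
    while stack:
        key, y = stack.pop()
        coords[key] = (-float(view.depth[key]), y)
        for child in view.children.get(key, []):
            stack.append((child, y + offset[child]))
    return LayoutResult(coords, "tidy")


def dendrogram_layout(tree) -> LayoutResult:
    """All leaves on one leftmost column, equally spaced; parents centered."""
    view = _as_tree_view(tree)
    max_depth = max(view.depth.values(), default=0)
    ys: dict[Hashable, float] = {}
    next_leaf = [0.0]

    def assign(key: Hashable) -> float:
        kids = view.children.get(key, [])
        if not kids:
            ys[key] = next_leaf[0]
            next_leaf[0] += MIN_SEPARATION
        else:
            child_ys = [assign(c) for c in kids]
            ys[key] = (child_ys[0] + child_ys[-1]) / 2.0
        return ys[key]

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 2 * len(view.depth) + 100))
    try:
        assign(view.root)
    finally:
        sys.setrecursionlimit(old)

    coords = {}
    for key, d in view.depth.items():
        kids = view.children.get(key, [])
        x = -float(max_depth) if not kids else -float(d)
        coords[key] = (x, ys[key])
    return LayoutResult(coords, "dendrogram")


def radial_transform(layout: LayoutResult, step: float = 1.0) -> LayoutResult:
    """Polar remapping of a tree layout: radius = depth·step, angle from
    normalized breadth; the root (depth 0) lands at the origin."""
    if layout.layout_kind not in ("tidy", "dendrogram"):
        raise ValueError("radial_transform applies to tidy or dendrogram layouts")
    ys = [p[1] for p in layout.coordinates.values()]
    ymin, ymax = (min(ys), max(ys)) if ys else (0.0, 0.0)
    span = (ymax - ymin) + MIN_SEPARATION
    coords = {}
    for key, (x, y) in layout.coordinates.items():
        r = -x * step
        theta = 2.0 * math.pi * (y - ymin) / span
        coords[key] = (r * math.cos(theta), r * math.sin(theta))
    return LayoutResult(coords, f"radial_{layout.layout_kind}")


# ---------------------------------------------------------------------------
# layered (Sugiyama) layout
# ---------------------------------------------------------------------------

def _directed_edges(obj) -> tuple[list[str], list[tuple[str, str]]]:
    if isinstance(obj, tuple) and len(obj) == 2:
        nodes, pairs = obj
        return list(nodes), list(pairs)
    if isinstance(obj, PathSet):
        nodes: list[str] = []
        seen: set[str] = set()
        pairs: list[tuple[str, str]] = []
        epairs: set[tuple[str, str]] = set()
        for p in obj.paths:
            for nid in p.nodes:
                if nid not in seen:
                    seen.add(nid)
                    nodes.append(nid)
            for e in p.edges:
                pair = (e.source, e.target)
                if pair not in epairs:
                    epairs.add(pair)
                    pairs.append(pair)
        return nodes, pairs
    if isinstance(obj, FluxGraph):
        pairs = []
        epairs = set()
        for e in obj.edges:
            pair = (e.source, e.target)
            if pair not in epairs:
                epairs.add(pair)
                pairs.append(pair)
        return list(obj.nodes), pairs
    raise TypeError(f"cannot derive a DAG from {type(obj).__name__}")


def count_crossings(layers: Sequence[Sequence[str]],
                    edges: Iterable[tuple[str, str]]) -> int:
    """Straight-line crossings between consecutive layers (edges must join
    adjacent layers; use the dummy-node expansion for longer spans)."""
    pos = {}
    layer_of = {}
    for li, layer in enumerate(layers):
        for xi, nid in enumerate(layer):
            pos[nid] = xi
            layer_of[nid] = li
    per_gap: dict[int, list[tuple[int, int]]] = {}
    for u, v in edges:
        lu, lv = layer_of[u], layer_of[v]
        if abs(lu - lv) != 1:
            raise ValueError("count_crossings expects adjacent-layer edges")
        a, b = (u, v) if lu < lv else (v, u)
        per_gap.setdefault(layer_of[a], []).append((pos[a], pos[b]))
    total = 0
    for segs in per_gap.values():
        for i in range(len(segs)):
            for j in range(i + 1, len(segs)):
                (a1, b1), (a2, b2) = segs[i], segs[j]
                if (a1 - a2) * (b1 - b2) < 0:
                    total += 1
    return total


def layered_layout(obj, sweeps: int = 8) -> LayoutResult:
    """Layered DAG drawing: y = layer (sources at the top), x = within-layer
    position after barycenter crossing reduction.  Raises ``ValueError``
    naming an offending node if the input contains a cycle."""
    nodes, pairs = _directed_edges(obj)
    succ: dict[str, list[str]] = {n: [] for n in nodes}
    indeg: dict[str, int] = {n: 0 for n in nodes}
    for u, v in pairs:
        succ[u].append(v)
        indeg[v] += 1

    # Kahn toposort; leftover nodes are on a cycle
    queue = sorted(n for n in nodes if indeg[n] == 0)
    topo: list[str] = []
    indeg_work = dict(indeg)
    while queue:
        u = queue.pop(0)
        topo.append(u)
        for v in succ[u]:
            indeg_work[v] -= 1
            if indeg_work[v] == 0:
                queue.append(v)
        queue.sort()
    if len(topo) != len(nodes):
        offender = sorted(set(nodes) - set(topo))[0]
        raise ValueError(f"input is not acyclic: node {offender!r} lies on a cycle")

    layer: dict[str, int] = {n: 0 for n in nodes}
    for u in topo:
        for v in succ[u]:
            layer[v] = max(layer[v], layer[u] + 1)

    # dummy-node expansion of long edges
    exp_edges: list[tuple[str, str]] = []
    dummies: list[str] = []
    for ei, (u, v) in enumerate(pairs):
        span = layer[v] - layer[u]
        prev = u
        for step in range(1, span):
            d = f"__dummy_{ei}_{step}"
            layer[d] = layer[u] + step
            dummies.append(d)
            exp_edges.append((prev, d))
            prev = d
        exp_edges.append((prev, v))

    n_layers = max(layer.values(), default=0) + 1
    layers: list[list[str]] = [[] for _ in range(n_layers)]
    for n in sorted(layer):
        layers[layer[n]].append(n)

    up: dict[str, list[str]] = {n: [] for n in layer}
    down: dict[str, list[str]] = {n: [] for n in layer}
    for u, v in exp_edges:
        down[u].append(v)
        up[v].append(u)

    def barycenter_pass(downward: bool) -> None:
        rng = range(1, n_layers) if downward else range(n_layers - 2, -1, -1)
        neigh = up if downward else down
        for li in rng:
            ref = {n: i for i, n in enumerate(layers[li - 1] if downward
                                              else layers[li + 1])}
            def bary(n: str) -> float:
                ns = [ref[m] for m in neigh[n] if m in ref]
                return sum(ns) / len(ns) if ns else float(layers[li].index(n))
            layers[li] = sorted(layers[li], key=lambda n: (bary(n), n))

    best = [list(l) for l in layers]
    initial_x = best_x = count_crossings(layers, exp_edges)
    for s in range(sweeps):
        barycenter_pass(downward=(s % 2 == 0))
        x = count_crossings(layers, exp_edges)
        if x < best_x:
            best_x, best = x, [list(l) for l in layers]
    layers = best

    coords: dict[Hashable, tuple[float, float]] = {}
    for li, row in enumerate(layers):
        for xi, n in enumerate(row):
            if not n.startswith("__dummy_"):
                coords[n] = (xi - (len(row) - 1) / 2.0, float(li))
    return LayoutResult(coords, "layered",
                        meta={"crossings_initial": initial_x,
                              "crossings_final": best_x})


# ---------------------------------------------------------------------------
# force layout (velocity Verlet)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForceParams:
    """Simulation constants.  Distances are in layout units; the defaults
    put the two-body spring/repulsion equilibrium within a few percent of
    the rest length."""

    repulsion: float = 50.0     # pairwise k/d² strength
    spring: float = 0.08        # Hooke constant along edges
    rest_length: float = 30.0   # spring rest length
    centering: float = 0.001    # pull toward the origin
    decay: float = 0.9          # velocity retained per step
    dt: float = 1.0


def _nodes_and_pairs(obj) -> tuple[list[Hashable], list[tuple[int, int]]]:
    if isinstance(obj, FluxGraph):
        ids = list(obj.nodes)
        index = {n: i for i, n in enumerate(ids)}
        return ids, [(index[e.metabolite], index[e.reaction]) for e in obj.edges]
    if isinstance(obj, (SpanningTree, DuplicatedTree, TreeView)):
        view = _as_tree_view(obj)
        ids = view.keys
        index = {n: i for i, n in enumerate(ids)}
        return ids, [(index[c], index[p]) for c, p in view.parent.items()]
    raise TypeError(f"cannot run a force simulation on {type(obj).__name__}")


def force_layout(obj, iterations: int = 300, seed: int = 0,
                 params: ForceParams | None = None,
                 return_energy: bool = False):
    """Velocity-Verlet particle simulation; deterministic for a fixed seed.

    Nodes repel pairwise with a 1/d² force, edges act as Hookean springs
    toward their rest length, and a weak force pulls everything toward the
    origin; velocities decay geometrically so the system settles.  With
    ``return_energy`` the per-step total kinetic energy trace is returned
    alongside the layout.
    """
    params = params or ForceParams()
    ids, pairs = _nodes_and_pairs(obj)
    n = len(ids)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-params.rest_length, params.rest_length, size=(n, 2))
    vel = np.zeros((n, 2))
    e_u = np.array([p[0] for p in pairs], dtype=int)
    e_v = np.array([p[1] for p in pairs], dtype=int)

    def accel(p: np.ndarray) -> np.ndarray:
        a = -params.centering * p
        if n > 1:
            diff = p[:, None, :] - p[None, :, :]
            d2 = (diff ** 2).sum(axis=2)
            np.fill_diagonal(d2, 1.0)
            d = np.sqrt(d2)
            np.clip(d, 1e-6, None, out=d)
            rep = params.repulsion * diff / (d ** 3)[:, :, None]
            idx = np.arange(n)
            rep[idx, idx, :] = 0.0
            a = a + rep.sum(axis=1)
        if len(e_u):
            dvec = p[e_v] - p[e_u]
            dist = np.linalg.norm(dvec, axis=1)
            np.clip(dist, 1e-6, None, out=dist)
            f = params.spring * (dist - params.rest_length)
            fvec = (f / dist)[:, None] * dvec
            np.add.at(a, e_u, fvec)
            np.add.at(a, e_v, -fvec)
        return a

    energies = []
    a = accel(pos)
    for _ in range(iterations):
        pos = pos + vel * params.dt + 0.5 * a * params.dt ** 2
        a_new = accel(pos)
        vel = (vel + 0.5 * (a + a_new) * params.dt) * params.decay
        a = a_new
        energies.append(float(0.5 * (vel ** 2).sum()))

    coords = {nid: (float(x), float(y)) for nid, (x, y) in zip(ids, pos)}
    result = LayoutResult(coords, "force")
    return (result, energies) if return_energy else result


# ---------------------------------------------------------------------------
# SVG rendering
# ---------------------------------------------------------------------------

_PATH_PALETTE = [
    "#d43b3b", "#3b6fd4", "#58b368", "#e08b2e", "#8e44ad",
    "#16a085", "#c2185b", "#7f8c00", "#00838f", "#5d4037",
]


def _instance_kinds(view: TreeView, graph: FluxGraph | None) -> dict[Hashable, str]:
    kinds: dict[Hashable, str] = {}
    for key, nid in view.node_id.items():
        if graph is not None and nid in graph.nodes:
            kinds[key] = graph.nodes[nid].kind
            continue
        e = view.via_edge.get(key)
        if e is None:  # root: infer from any child's edge
            for child in view.children.get(key, []):
                e = view.via_edge.get(child)
                if e is not None:
                    break
        if e is not None:
            kinds[key] = "metabolite" if nid == e.metabolite else "reaction"
        else:
            kinds[key] = "reaction"
    return kinds


def render_svg(obj, layout: LayoutResult, style: RenderStyle | None = None,
               out: str | _P | None = None, graph: FluxGraph | None = None) -> str:
    """Render a FluxGraph, tree or PathSet with the given layout to SVG 1.1.

    Trees color edges by flux direction relative to the root (blue toward,
    red away); path sets use one color per path, with overlapping segments
    painted in the color of the lower-rank (shorter) path.  Passing the
    source ``graph`` enriches labels (names, fluxes, localizations).
    """
    style = style or RenderStyle()
    s = style.scale
    xmin, ymin, xmax, ymax = layout.bounds
    pad = 3.0 * style.node_radius + 40.0
    width = (xmax - xmin) * s + 2 * pad
    height = (ymax - ymin) * s + 2 * pad

    def pt(key) -> tuple[float, float]:
        x, y = layout.coordinates[key]
        return ((x - xmin) * s + pad, (y - ymin) * s + pad)

    svg = ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg",
        "version": "1.1",
        "width": f"{width:.1f}",
        "height": f"{height:.1f}",
        "viewBox": f"0 0 {width:.1f} {height:.1f}",
    })

    edges_el = ET.SubElement(svg, "g", {"class": "edges", "stroke-width": "1.5"})
    nodes_el = ET.SubElement(svg, "g", {"class": "nodes"})
    labels_el = ET.SubElement(svg, "g", {
        "class": "labels", "font-size": "9", "font-family": "sans-serif",
        "text-anchor": "middle",
    })

    # -- collect drawables ----------------------------------------------
    node_items: list[tuple[Hashable, str, str]] = []  # key, node_id, kind
    edge_items: list[tuple[Hashable, Hashable, str, float]] = []  # a, b, color, weight

    if isinstance(obj, (SpanningTree, DuplicatedTree, TreeView)):
        view = _as_tree_view(obj)
        kinds = _instance_kinds(view, graph)
        node_items = [(k, view.node_id[k], kinds[k]) for k in view.keys]
        for child, par in view.parent.items():
            e = view.via_edge[child]
            toward = e.target == view.node_id[par]
            color = (style.toward_root_edge_color if toward
                     else style.from_root_edge_color)
            edge_items.append((par, child, color, e.weight))
    elif isinstance(obj, PathSet):
        seen: set[str] = set()
        for p in obj.paths:
            for i, nid in enumerate(p.nodes):
                if nid not in seen:
                    seen.add(nid)
                    kind = "metabolite" if i % 2 == (0 if _starts_with_metabolite(p) else 1) else "reaction"
                    if graph is not None and nid in graph.nodes:
                        kind = graph.nodes[nid].kind
                    node_items.append((nid, nid, kind))
        for p in sorted(obj.paths, key=lambda q: -q.rank):  # low rank paints last
            color = _PATH_PALETTE[(p.rank - 1) % len(_PATH_PALETTE)]
            for e in p.edges:
                edge_items.append((e.source, e.target, color, e.weight))
    elif isinstance(obj, FluxGraph):
        node_items = [(nid, nid, node.kind) for nid, node in obj.nodes.items()]
        for e in obj.edges:
            color = (style.toward_root_edge_color if e.role == CONSUMED_BY
                     else style.from_root_edge_color)
            edge_items.append((e.source, e.target, color, e.weight))
    else:
        raise TypeError(f"cannot render {type(obj).__name__}")

    wmax = max((w for (_, _, _, w) in edge_items), default=1.0) or 1.0
    for a, b, color, w in edge_items:
        if a not in layout.coordinates or b not in layout.coordinates:
            continue
        x1, y1 = pt(a)
        x2, y2 = pt(b)
        attrs = {"x1": f"{x1:.2f}", "y1": f"{y1:.2f}",
                 "x2": f"{x2:.2f}", "y2": f"{y2:.2f}", "stroke": color}
        if style.edge_emphasis == "width":
            attrs["stroke-width"] = f"{0.5 + 3.0 * w / wmax:.2f}"
        elif style.edge_emphasis == "opacity":
            attrs["stroke-opacity"] = f"{0.2 + 0.8 * w / wmax:.2f}"
        ET.SubElement(edges_el, "line", attrs)

    for key, nid, kind in node_items:
        if key not in layout.coordinates:
            continue
        x, y = pt(key)
        color = style.metabolite_color if kind == "metabolite" else style.reaction_color
        ET.SubElement(nodes_el, "circle", {
            "cx": f"{x:.2f}", "cy": f"{y:.2f}", "r": f"{style.node_radius:.1f}",
            "fill": color, "stroke": "#333333",
        })
        label = _node_label(nid, kind, style.label_mode, graph)
        if label:
            ET.SubElement(labels_el, "text", {
                "x": f"{x:.2f}",
                "y": f"{y + style.node_radius + 10:.2f}",
            }).text = label

    ET.indent(svg)
    text = ET.tostring(svg, encoding="unicode", xml_declaration=True)
    if out is not None:
        _P(out).write_text(text)
    return text


def _starts_with_metabolite(p) -> bool:
    return bool(p.edges) and p.nodes[0] == p.edges[0].metabolite


def _node_label(nid: str, kind: str, mode: str,
                graph: FluxGraph | None) -> str | None:
    if mode == "none":
        return None
    node = graph.nodes.get(nid) if graph is not None else None
    if mode == "name" and node is not None:
        return node.label or nid
    if mode == "flux":
        if kind == "reaction" and node is not None and node.flux is not None:
            return f"{nid} ({node.flux:.3g})"
        return nid
    if mode == "localization":
        comp = node.compartment if node is not None else None
        return f"{nid} [{comp}]" if comp else nid
    return nid


# ---------------------------------------------------------------------------
# graph exchange formats
# ---------------------------------------------------------------------------

def _to_nx(obj, graph: FluxGraph | None = None) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    if isinstance(obj, FluxGraph):
        for nid, node in obj.nodes.items():
            attrs = {"kind": node.kind, "label": node.label or nid}
            if node.compartment:
                attrs["compartment"] = node.compartment
            if node.flux is not None:
                attrs["flux"] = float(node.flux)
            g.add_node(nid, **attrs)
        for e in obj.edges:
            g.add_edge(e.source, e.target, role=e.role,
                       stoich=float(e.stoich), weight=float(e.weight))
        return g
    if isinstance(obj, (SpanningTree, DuplicatedTree, TreeView)):
        view = _as_tree_view(obj)
        kinds = _instance_kinds(view, graph)
        names = {}
        counts: dict[str, int] = {}
        for key in view.keys:
            nid = view.node_id[key]
            k = counts.get(nid, 0)
            counts[nid] = k + 1
            names[key] = nid if k == 0 else f"{nid}#{k}"
        for key in view.keys:
            g.add_node(names[key], kind=kinds[key], depth=int(view.depth[key]))
        for child, par in view.parent.items():
            e = view.via_edge[child]
            g.add_edge(names[par], names[child], role=e.role,
                       stoich=float(e.stoich), weight=float(e.weight))
        return g
    if isinstance(obj, PathSet):
        for p in obj.paths:
            for nid in p.nodes:
                if nid not in g:
                    kind = "unknown"
                    if graph is not None and nid in graph.nodes:
                        kind = graph.nodes[nid].kind
                    g.add_node(nid, kind=kind)
            for e in p.edges:
                if not g.has_edge(e.source, e.target):
                    g.add_edge(e.source, e.target, role=e.role,
                               stoich=float(e.stoich), weight=float(e.weight))
        return g
    raise TypeError(f"cannot export {type(obj).__name__}")


def export_graph(obj, format: str, out: str | _P,
                 graph: FluxGraph | None = None) -> None:
    """Write GraphML, node-link JSON or Graphviz DOT for a graph or tree."""
    out = _P(out)
    g = _to_nx(obj, graph)
    if format == "graphml":
        nx.write_graphml(g, out)
    elif format == "json":
        payload = {
            "directed": True,
            "nodes": [dict(id=n, **attrs) for n, attrs in g.nodes(data=True)],
            "edges": [dict(source=u, target=v, **attrs)
                      for u, v, attrs in g.edges(data=True)],
        }
        out.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "dot":
        lines = ["digraph fluxgraph {", "  rankdir=LR;"]
        for n, attrs in g.nodes(data=True):
            shape = "ellipse" if attrs.get("kind") == "metabolite" else "box"
            lines.append(f'  "{n}" [shape={shape}, label="{n}"];')
        for u, v, attrs in g.edges(data=True):
            w = attrs.get("weight", 1.0)
            lines.append(f'  "{u}" -> "{v}" [weight={w:g}];')
        lines.append("}")
        out.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_graphml(path: str | _P) -> FluxGraph:
    """Rebuild a FluxGraph from a GraphML file written by ``export_graph``."""
    g = nx.read_graphml(path, force_multigraph=True)
    fg = FluxGraph()
    for nid, attrs in g.nodes(data=True):
        fg.add_node(Node(
            id=nid,
            kind=attrs.get("kind", "metabolite"),
            label=attrs.get("label", nid),
            compartment=attrs.get("compartment"),
            flux=attrs.get("flux"),
        ))
    for u, v, attrs in g.edges(data=True):
        role = attrs.get("role", CONSUMED_BY)
        met, rxn = (u, v) if role == CONSUMED_BY else (v, u)
        fg.add_edge(met, rxn, role, float(attrs.get("stoich", 1.0)),
                    float(attrs.get("weight", 1.0)))
    return fg
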