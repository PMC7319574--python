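"""Layout invariants and SVG / GraphML / JSON / DOT exporters."""

import json
import math
import xml.etree.ElementTree as ET

import numpy as np
import pytest

from fluxgraphs import (
    dendrogram_layout,
    export_graph,
    force_layout,
    import_graphml,
    k_shortest,
    layered_layout,
    make_random_flux_graph,
    radial_transform,
    render_svg,
    spanning_tree,
    tidy_layout,
)
from fluxgraphs.flux_graph import CONSUMED_BY, FluxGraph, Node, TreeView


def chain_view(n):
    keys = list(range(n))
    return TreeView(root=0,
                    children={i: ([i + 1] if i + 1 < n else []) for i in keys},
                    depth={i: i for i in keys},
                    node_id={i: f"n{i}" for i in keys},
                    parent={i: i - 1 for i in keys[1:]})


def star_view(n_leaves):
    keys = list(range(n_leaves + 1))
    return TreeView(root=0,
                    children={0: keys[1:], **{k: [] for k in keys[1:]}},
                    depth={0: 0, **{k: 1 for k in keys[1:]}},
                    node_id={k: f"n{k}" for k in keys},
                    parent={k: 0 for k in keys[1:]})


def balanced_binary(depth):
    children, depths, parent = {0: []}, {0: 0}, {}
    nxt = [0]
    idx = 0
    for d in range(depth):
        cur, nxt = nxt, []
        for p in cur:
            for _ in range(2):
                idx += 1
                children[idx] = []
                children[p].append(idx)
                depths[idx] = d + 1
                parent[idx] = p
                nxt.append(idx)
    return TreeView(root=0, children=children, depth=depths,
                    node_id={k: f"n{k}" for k in children}, parent=parent)


# ---------------------------------------------------------------------------
# tidy
# ---------------------------------------------------------------------------

def test_single_node_sits_at_origin():
    lay = tidy_layout(chain_view(1))
    assert lay.coordinates[0] == (0.0, 0.0)


def test_root_with_two_leaves_is_centered():
    lay = tidy_layout(star_view(2))
    ys = [lay.coordinates[k][1] for k in (1, 2)]
    assert lay.coordinates[0][1] == pytest.approx(sum(ys) / 2, abs=1e-9)


def test_chain_is_collinear_and_equally_spaced():
    lay = tidy_layout(chain_view(5))
    xs = [lay.coordinates[i][0] for i in range(5)]
    ys = [lay.coordinates[i][1] for i in range(5)]
    assert ys == [0.0] * 5
    assert xs == [0.0, -1.0, -2.0, -3.0, -4.0]  # root at max x


@pytest.mark.parametrize("seed", range(10))
def test_tidy_separation_and_parent_centering_on_random_trees(seed):
    g = make_random_flux_graph(n_nodes=12 + seed, n_extra_edges=5, seed=seed)
    tree = spanning_tree(g, sorted(g.nodes)[0])
    lay = tidy_layout(tree)
    by_depth = {}
    for nid, d in tree.depth.items():
        by_depth.setdefault(d, []).append(lay.coordinates[nid][1])
    for ys in by_depth.values():
        ys = sorted(ys)
        for a, b in zip(ys, ys[1:]):
            assert b - a >= 1.0 - 1e-9
    for parent, kids in tree.children().items():
        if kids:
            y = lay.coordinates[parent][1]
            lo = lay.coordinates[kids[0]][1]
            hi = lay.coordinates[kids[-1]][1]
            assert y == pytest.approx((lo + hi) / 2, abs=1e-9)
        # depth maps to the horizontal axis, root at maximum x
        assert lay.coordinates[parent][0] == -float(tree.depth[parent])


# ---------------------------------------------------------------------------
# dendrogram
# ---------------------------------------------------------------------------

def test_dendrogram_leaves_share_x_and_are_equally_spaced():
    view = balanced_binary(2)
    lay = dendrogram_layout(view)
    leaves = [k for k, kids in view.children.items() if not kids]
    xs = {lay.coordinates[k][0] for k in leaves}
    assert len(xs) == 1
    ys = sorted(lay.coordinates[k][1] for k in leaves)
    assert len(ys) == 4
    steps = {round(b - a, 9) for a, b in zip(ys, ys[1:])}
    assert steps == {1.0}


@pytest.mark.parametrize("seed", range(6))
def test_dendrogram_leaf_colinearity_on_random_trees(seed):
    g = make_random_flux_graph(n_nodes=10 + seed, n_extra_edges=4, seed=30 + seed)
    tree = spanning_tree(g, sorted(g.nodes)[0])
    lay = dendrogram_layout(tree)
    kids = tree.children()
    leaf_xs = [lay.coordinates[k][0] for k, c in kids.items() if not c]
    assert max(leaf_xs) - min(leaf_xs) <= 1e-9


# ---------------------------------------------------------------------------
# radial
# ---------------------------------------------------------------------------

def test_radial_root_at_origin_and_rings_by_depth():
    view = balanced_binary(2)
    lay = radial_transform(tidy_layout(view))
    assert lay.coordinates[0] == (0.0, 0.0)
    for k, d in view.depth.items():
        r = math.hypot(*lay.coordinates[k])
        assert r == pytest.approx(float(d), abs=1e-9)


def test_radial_angles_increase_with_breadth():
    base = tidy_layout(star_view(4))
    lay = radial_transform(base)
    order = sorted(range(1, 5), key=lambda k: base.coordinates[k][1])
    angles = [math.atan2(*reversed(lay.coordinates[k])) % (2 * math.pi)
              for k in order]
    assert angles == sorted(angles)
    assert all(a < 2 * math.pi for a in angles)


def test_radial_rejects_non_tree_layouts(toy6_core):
    lay = force_layout(toy6_core, iterations=10, seed=0)
    with pytest.raises(ValueError):
        radial_transform(lay)


# ---------------------------------------------------------------------------
# layered
# ---------------------------------------------------------------------------

def test_single_path_layers_one_node_each_and_no_crossings(toy6_core):
    pset = k_shortest(toy6_core, "A", "BIO", k=1)
    lay = layered_layout(pset)
    layers = {}
    for nid, (x, y) in lay.coordinates.items():
        layers.setdefault(y, []).append(nid)
    assert all(len(v) == 1 for v in layers.values())
    assert lay.meta["crossings_final"] == 0


def test_two_disjoint_paths_have_zero_crossings():
    nodes = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
    edges = [(f"a{i}", f"a{i+1}") for i in range(3)] + \
            [(f"b{i}", f"b{i+1}") for i in range(3)]
    lay = layered_layout((nodes, edges))
    assert lay.meta["crossings_final"] == 0
    # tracks stay separated: consistent x ordering per layer
    for i in range(3):
        xa = lay.coordinates[f"a{i}"][0]
        xb = lay.coordinates[f"b{i}"][0]
        assert (xa < xb) == (lay.coordinates["a0"][0] < lay.coordinates["b0"][0])


def test_edges_always_point_to_deeper_layers(toy6_core):
    pset = k_shortest(toy6_core, "A", "BIO", k=2)
    lay = layered_layout(pset)
    for p in pset.paths:
        for e in p.edges:
            assert lay.coordinates[e.source][1] < lay.coordinates[e.target][1]


def test_cycle_is_rejected_with_offending_node():
    with pytest.raises(ValueError, match="x1"):
        layered_layout((["x1", "x2"], [("x1", "x2"), ("x2", "x1")]))


@pytest.mark.parametrize("seed", range(25))
def test_barycenter_sweeps_never_increase_crossings(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 16))
    nodes = [f"v{i:02d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.25:
                edges.append((nodes[i], nodes[j]))
    lay = layered_layout((nodes, edges))
    assert lay.meta["crossings_final"] <= lay.meta["crossings_initial"]


# ---------------------------------------------------------------------------
# force
# ---------------------------------------------------------------------------

def test_force_layout_is_seed_deterministic(toy6_core):
    a = force_layout(toy6_core, seed=5)
    b = force_layout(toy6_core, seed=5)
    c = force_layout(toy6_core, seed=6)
    assert a.coordinates == b.coordinates
    assert a.coordinates != c.coordinates


def test_two_connected_nodes_settle_near_rest_length():
    g = FluxGraph()
    g.add_node(Node("m", "metabolite"))
    g.add_node(Node("r", "reaction"))
    g.add_edge("m", "r", CONSUMED_BY, 1, 1.0)
    lay = force_layout(g, iterations=300, seed=2)
    d = math.dist(lay.coordinates["m"], lay.coordinates["r"])
    assert abs(d - 30.0) / 30.0 < 0.05


def test_disconnected_cliques_separate():
    g = FluxGraph()
    for c in ("a", "b"):
        for i in range(3):
            g.add_node(Node(f"{c}m{i}", "metabolite"))
            g.add_node(Node(f"{c}r{i}", "reaction"))
        for i in range(3):
            for j in range(3):
                g.add_edge(f"{c}m{i}", f"{c}r{j}", CONSUMED_BY, 1, 1.0)
    lay = force_layout(g, seed=11)
    pa = np.array([xy for k, xy in lay.coordinates.items() if k.startswith("a")])
    pb = np.array([xy for k, xy in lay.coordinates.items() if k.startswith("b")])
    inter = np.linalg.norm(pa.mean(0) - pb.mean(0))
    intra = np.mean([np.linalg.norm(p[i] - p[j])
                     for p in (pa, pb)
                     for i in range(len(p)) for j in range(i + 1, len(p))])
    assert inter > intra


def test_kinetic_energy_settles(toy6_core):
    _, energy = force_layout(toy6_core, seed=3, return_energy=True)
    tail = energy[-len(energy) // 10:]
    assert all(b <= a * (1 + 1e-9) for a, b in zip(tail, tail[1:]))


# ---------------------------------------------------------------------------
# SVG
# ---------------------------------------------------------------------------

def test_tree_svg_has_expected_shape_and_edge_counts(toy6_core, tmp_path):
    tree = spanning_tree(toy6_core, "BIO")
    out = tmp_path / "tree.svg"
    render_svg(tree, tidy_layout(tree), out=out, graph=toy6_core)
    root = ET.parse(out).getroot()  # well-formed XML
    assert root.tag.endswith("svg")
    ns = "{http://www.w3.org/2000/svg}"
    assert len(root.findall(f".//{ns}circle")) == 9
    assert len(root.findall(f".//{ns}line")) == 8
    # tree edges colored by direction relative to the root
    strokes = {el.get("stroke") for el in root.findall(f".//{ns}line")}
    assert strokes <= {"#3b6fd4", "#d43b3b"}


def test_empty_graph_renders_valid_svg(tmp_path):
    from fluxgraphs import LayoutResult
    g = FluxGraph()
    text = render_svg(g, LayoutResult({}, "force"))
    root = ET.fromstring(text)
    assert not root.findall(".//{http://www.w3.org/2000/svg}circle")


def test_pathset_svg_uses_one_color_per_path(toy6_core, tmp_path):
    pset = k_shortest(toy6_core, "A", "BIO", k=2)
    text = render_svg(pset, layered_layout(pset), graph=toy6_core)
    root = ET.fromstring(text)
    strokes = {el.get("stroke")
               for el in root.iter("{http://www.w3.org/2000/svg}line")}
    assert len(strokes) == 2


def test_flux_labels_appear_under_reaction_nodes(toy6_core):
    from fluxgraphs import RenderStyle
    tree = spanning_tree(toy6_core, "BIO")
    text = render_svg(tree, tidy_layout(tree),
                      RenderStyle(label_mode="flux"), graph=toy6_core)
    assert "R1 (10)" in text


def test_edge_emphasis_scales_width_with_weight(toy6_core):
    from fluxgraphs import RenderStyle
    tree = spanning_tree(toy6_core, "BIO")
    text = render_svg(tree, tidy_layout(tree),
                      RenderStyle(edge_emphasis="width"), graph=toy6_core)
    root = ET.fromstring(text)
    widths = {float(el.get("stroke-width"))
              for el in root.iter("{http://www.w3.org/2000/svg}line")}
    assert len(widths) > 1  # weight-10 edges thicker than weight-5 edges


# ---------------------------------------------------------------------------
# graph exchange
# ---------------------------------------------------------------------------

def test_graphml_round_trip_is_exact(toy6_graph, tmp_path):
    out = tmp_path / "g.graphml"
    export_graph(toy6_graph, "graphml", out)
    back = import_graphml(out)
    assert back.n_nodes == 12 and back.n_edges == 13
    key = lambda g: sorted((e.metabolite, e.reaction, e.role, e.stoich, e.weight)
                           for e in g.edges)
    assert key(back) == key(toy6_graph)
    assert {n.id: n.kind for n in back.nodes.values()} == \
           {n.id: n.kind for n in toy6_graph.nodes.values()}


def test_json_export_schema(toy6_graph, tmp_path):
    out = tmp_path / "g.json"
    export_graph(toy6_graph, "json", out)
    payload = json.loads(out.read_text())
    assert payload["directed"] is True
    assert len(payload["nodes"]) == 12 and len(payload["edges"]) == 13
    assert {"id", "kind", "label"} <= set(payload["nodes"][0])
    assert {"source", "target", "weight", "role", "stoich"} <= set(payload["edges"][0])


def test_dot_export_structure(toy6_graph, tmp_path):
    import re
    out = tmp_path / "g.dot"
    export_graph(toy6_graph, "dot", out)
    text = out.read_text()
    assert text.startswith("digraph") and text.rstrip().endswith("}")
    assert len(re.findall(r'"\S+" -> "\S+"', text)) == 13
    assert 'shape=ellipse' in text and 'shape=box' in text


def test_duplicated_tree_export_disambiguates_instances(toy6_core, tmp_path):
    from fluxgraphs import complete_tree
    dup = complete_tree(toy6_core, "BIO")
    out = tmp_path / "dup.graphml"
    export_graph(dup, "graphml", out, graph=toy6_core)
    import networkx as nx
    g = nx.read_graphml(out, force_multigraph=True)
    assert g.number_of_nodes() == 10 and g.number_of_edges() == 9
    assert "B#1" in g.nodes
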