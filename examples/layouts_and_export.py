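"""One tree, five layouts, three exchange formats.

Tidy and dendrogram layouts place the root at the right; their radial
variants wrap depth onto concentric rings; the force layout relaxes a
particle simulation (deterministic for a fixed seed).  GraphML re-imports
exactly; the JSON schema is documented in docs/json_schema.md.
"""

from fluxgraphs import (
    WeightOptions, build_graph, dendrogram_layout, export_graph, force_layout,
    import_graphml, make_toy_gem, optimize, radial_transform, render_svg,
    spanning_tree, tag_cofactors, tidy_layout,
)

gem = make_toy_gem("TOY6")
tag_cofactors(gem)
state = optimize(gem)
graph = build_graph(gem, state, WeightOptions(True, True), exclude_cofactors=True)
tree = spanning_tree(graph, "BIO")

layouts = {
    "tidy": tidy_layout(tree),
    "dendrogram": dendrogram_layout(tree),
    "radial_tidy": radial_transform(tidy_layout(tree)),
    "force": force_layout(tree, seed=0),
}
for name, lay in layouts.items():
    render_svg(tree, lay, out=f"toy6_{name}.svg", graph=graph)
    print(f"{name:>12s}: bounds {tuple(round(b, 2) for b in lay.bounds)}")

export_graph(graph, "graphml", "toy6.graphml")
export_graph(graph, "json", "toy6.json")
export_graph(graph, "dot", "toy6.dot")
back = import_graphml("toy6.graphml")
print(f"GraphML round-trip: {back.n_nodes} nodes, {back.n_edges} edges "
      f"(exact match: {back.n_edges == graph.n_edges})")
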