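# fluxgraphs

Headless computation, analysis and layout of genome-scale metabolic flux
graphs.  Point it at any SBML constraint-based model (Level 3 + `fbc`, or
the legacy COBRA dialect) and it will run flux balance analysis, build the
flux-weighted bipartite metabolite–reaction graph, and derive the three
classic views for exploring where the flux goes:

- a **flux spanning tree** rooted at the biomass reaction (or any node),
  grown greedily by edge weight so the pathways contributing most to the
  root are attached first;
- the ***k*-shortest loopless paths** between any two metabolites or
  reactions, under a hop-count or highest-flux metric;
- the **complete duplicated tree**, a breadth-first unfolding in which
  repeated nodes are duplicated so every edge of the model is visible.

It is written for metabolic modelers and metabolic-engineering work:
finding the main routes from a substrate to a product, checking how
knockouts reroute flux, and producing publication-ready SVG (plus GraphML
/ JSON / DOT for Cytoscape-style tools) without a web service.

## The mathematics in brief

FBA solves the LP `max c·v s.t. S·v = 0, lb ≤ v ≤ ub` (HiGHS via scipy);
knockouts clamp bounds to zero.  Each metabolite–reaction participation
becomes an edge directed along the *net* flux, weighted by a selectable
product of |v|, the stoichiometric coefficient and the metabolite's
molecular weight (computed from its formula; weight 1 when nothing is
selected).  The spanning tree picks, at every step, the frontier edge with
the largest weight — ties broken by smaller depth, flux-toward-root
precedence, then alphabetical ids — so with unit weights it reduces
exactly to an alphabetically sorted BFS.  Path costs are 1 per hop or
1/weight, making high-flux routes short and zero-flux edges impassable;
the k-shortest search removes the edges of already-found paths one at a
time and re-runs Dijkstra, either stopping at the first *k* distinct paths
or exhausting all removals and keeping the *k* best.  Trees can be drawn
with tidy, dendrogram, radial or force (velocity-Verlet) layouts, path
DAGs with a layered barycenter layout.

## Worked example

```
$ python examples/spanning_tree_walkthrough.py
growth (objective flux): 5
flux graph: 9 nodes, 9 edges
spanning tree: 8 edges
insertion order (most important first): BIO C D R2 R3 B R1 A UPT
     C -> BIO  via weight 5
     D -> BIO  via weight 5
    R2 -> C    via weight 5
    R3 -> D    via weight 5
     B -> R2   via weight 5
    R1 -> B    via weight 10
     A -> R1   via weight 10
   UPT -> A    via weight 10
wrote toy6_tree.svg (root right, leaves left; blue = toward root)
```

The toy model imports substrate A (≤ 10 flux units), splits it through an
ATP-coupled branch (R2) and a plain branch (R3), and drains both products
into biomass; the unique optimum is growth 5.  With cofactors excluded the
graph is the 9-node backbone; the tree attaches biomass's two precursors
first (C before D — equal weight, equal depth, alphabetical), then walks
upstream to the uptake, with the weight-10 edges of the trunk taking
priority as soon as they enter the frontier.  The same pipeline from the
shell:

```
$ fluxgraphs fixture TOY6 -o toy6.xml
$ fluxgraphs fba toy6.xml --knockout R1        # objective value: 0
$ fluxgraphs tree toy6.xml --root BIO --weights flux,stoich \
      --exclude-cofactors --svg tree.svg --export graphml --out tree.graphml
$ fluxgraphs paths toy6.xml --from A --to BIO -k 2
# 2 path(s) A -> BIO (k=2, mode=best_k)
1	cost=5	A -> R1[10] -> B -> R2[5] -> C -> BIO[5]
2	cost=5	A -> R1[10] -> B -> R3[5] -> D -> BIO[5]
```

Real models work the same way: `fluxgraphs tree iB21_1397.xml
--exclude-zero-flux --exclude-cofactors --svg bl21.svg` reads the BiGG
*E. coli* BL21(DE3) reconstruction, reports its growth rate and renders
the biomass-rooted flux tree.

See `docs/methods.md` for the algorithms, parameter defaults and
limitations, and `examples/` for one narrative script per capability.

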