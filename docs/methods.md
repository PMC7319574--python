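# Methods

## The model and its assumptions

A genome-scale metabolic model (GEM) is read into a normalized form:
compartments, metabolites (with Hill-notation formula, charge and boundary
flag), and reactions with signed stoichiometry, flux bounds
(mmol·gDW⁻¹·h⁻¹) and objective coefficients.  Flux balance analysis (FBA)
solves

    max  c·v   subject to   S·v = 0,   lb ≤ v ≤ ub,

where S is the stoichiometric matrix over non-boundary metabolites.
Boundary-condition species are excluded from the mass-balance rows (the
standard treatment of exchanges) but kept for display.  Knockouts force a
reaction's bounds to [0, 0].  The LP is solved with HiGHS dual simplex via
`scipy.optimize.linprog`, which is deterministic and seed-free; repeated
solves return the same optimal vertex.  When alternative optima exist the
objective value is unique but the flux vector is one particular vertex,
and every downstream graph is a function of that vertex.  No
post-processing (loop removal, pFBA) is applied.  Fluxes with magnitude at
or below `zero_tolerance` (default 1e-9, the solver noise floor) are
treated as zero by the zero-flux filter.

Molecular weights are computed from each metabolite's own chemical formula
using IUPAC standard atomic weights, rather than pooled from external
databases; this keeps the package fully offline at the cost of returning
no weight for polymeric or otherwise unparseable formulas (those
contribute a neutral factor of 1 to edge weights).  The shipped cofactor
list (ATP/ADP/AMP, NAD(P)(H), FAD(H₂), CoA, water, protons, CO₂, O₂, NH₄,
Pi/PPi, sulfate, quinones, glutathione) is a pragmatic default for the
usual currency metabolites and is user-overridable everywhere; matching is
case-insensitive on the compartment-stripped base id (`atp_c`, `atp[m]`
and `ATP` all match `atp`).

## The flux graph

The network is bipartite: a node per metabolite and per reaction, an edge
per participation.  Edge direction follows net flux — a reaction running
backwards (negative flux) has reactants and products swapped before the
consumed-by/produced-by role is assigned, so arrows always track material
flow; zero-flux reversible reactions keep their declared direction.  Edge
weight is the product of any combination of |flux|, stoichiometric
coefficient and molecular weight; with nothing selected every edge weighs
exactly 1.  Filters (zero-flux reactions, cofactor metabolites,
compartment merging by base id) are applied during construction, and nodes
left isolated are pruned so the drawn graph never contains floating nodes.
Reaction nodes are never merged across compartments.

## Greedy spanning tree and the frontier ranking

The spanning tree grows from a chosen root (default: the objective
reaction) by repeatedly taking the best frontier edge — an edge joining a
tree node to a node not yet placed.  The ranking, applied lexicographically:

1. larger edge weight;
2. smaller prospective depth (tree endpoint's depth + 1);
3. edges whose flux direction points toward the root (the new node feeds
   the tree) before edges pointing away;
4. alphabetically smaller new-node id;
5. alphabetically smaller tree-endpoint id.

Placing weight above all else keeps the construction a maximum-weight
greedy; putting depth ahead of flux-direction precedence is the one
ordering under which the unit-weight case degenerates *exactly* to an
alphabetically sorted breadth-first search (tree depth = BFS distance),
which we treat as a defining property of the algorithm.  Ranking
toward-root precedence above weight or depth breaks that equivalence on
graphs where a node's only producing edges sit deep while a consuming edge
sits shallow, so producers-first is applied within a depth level, not
globally.  Ties beyond rule 5 (parallel edges identical in every respect)
fall back to edge insertion index.  "Prospective depth" is the depth the
new node would receive, computable online while the tree is still under
construction; it is not a global shortest-path distance.

The complete (duplicated) tree uses the same frontier ranking in a
breadth-first traversal, but an edge reaching an already-placed node
spawns a duplicate leaf instance instead of being discarded; every
reachable graph edge therefore appears exactly once, and the number of
instances equals unique nodes + (graph edges − spanning-tree edges).

## Pathfinding

Paths follow directed edges, so they are alternating
metabolite/reaction sequences realizable by the flux solution.  Costs are
1 per edge (hop metric) or 1/weight (weighted); the reciprocal is the
package's monotone weight→cost transform — it makes heavy edges cheap and
zero-weight edges impassable (+inf).  A −log transform was rejected
because weights below 1 would give negative costs and break Dijkstra.
Dijkstra tie-breaks are deterministic: lexicographic node id in the
priority queue, smaller predecessor id at equal cost.

`k_shortest` uses a single-edge-removal scheme: starting from the shortest
path, each edge of each found path is removed one at a time (discovery
order, then edge position) and the search repeated; `first_k` stops at k
distinct paths (fast, heuristic — paths may be found out of true rank
order), `best_k` exhausts all removals reachable through the growing
found-set and keeps the k cheapest.  Without spur-node anchoring (the
classic Yen variant) `best_k` can miss a true i-th shortest path on some
topologies, but it can never report a cost *below* the true i-th
shortest; the test suite asserts exactly that bound against exhaustive
enumeration, with equality on the toy fixtures.  Duplicate paths are
detected by node-id sequence; output is sorted by (cost, lexicographic
node sequence) and ranked from 1.

## Layouts

*Tidy tree*: depth on the horizontal axis, root at maximum x (flux flows
left → right into the root).  Subtrees are packed by contour merging with
a minimum sibling separation of 1 unit at every shared depth; each parent
is centered on the midpoint of its first and last child.  *Dendrogram*:
leaves share the leftmost column at unit spacing, internal nodes centered
over their children.  *Radial*: radius = depth, angle = breadth normalized
to [0, 2π) with a one-unit guard so first and last branches do not
coincide; root at the origin.  *Layered* (for path DAGs): longest-path
layering from the sources, dummy nodes for multi-layer edges, 8 barycenter
sweeps alternating direction; the best ordering encountered is kept, so
the final crossing count never exceeds the initial one.  Cyclic input is
rejected with the offending node named.  *Force*: velocity-Verlet
integration of pairwise 1/d² repulsion (strength 50), Hookean springs on
edges (k = 0.08, rest length 30), a weak centering force (0.001) and
geometric velocity decay (0.9 per step, dt = 1, 300 iterations).  The
constants are fixed package defaults chosen so that an isolated connected
pair settles within a few percent of the rest length and kinetic energy
decays monotonically in the simulation tail; they are overridable via
`ForceParams` / the YAML config.  Initial positions come from a seeded
generator, so layouts are reproducible bit-for-bit for a fixed seed.
Disconnected components interact only through repulsion and centering, so
they drift apart into separate clusters — asserted in the tests as
inter-cluster centroid distance exceeding mean intra-cluster distance,
not as any specific picture.

## Rendering and exchange formats

SVG 1.1 is emitted directly (metabolites yellow circles, reactions green;
tree edges blue toward the root, red away; full-graph edges blue for
consumption, red for production).  Path sets get one palette color per
path, drawn in decreasing rank order so overlapping segments show the
lower-rank path's color.  Edge width or opacity can be scaled to weight.
Raster output is out of scope; vector SVG suffices.  GraphML (exact
round-trip via `import_graphml`), node-link JSON (schema in
`json_schema.md`) and Graphviz DOT are written for downstream tools.

## Synthetic data: what it does and does not emulate

`make_toy_gem` provides a six-reaction model with a hand-solvable unique
LP optimum (growth 5), an ATP/ADP currency pair and a variant with a
dead-end uptake forced to zero flux — enough to pin down every algorithm's
expected output exactly.  `make_random_gem` builds parallel
uptake→…→biomass chains (guaranteeing feasible, bounded, nonzero optima)
with random cross-reactions; `make_random_flux_graph` builds connected
random bipartite graphs whose weights are drawn from a small set so greedy
tie-breaks fire often.  These fixtures exercise correctness, determinism
and the oracle equivalences at desk scale (tens of nodes); they do not
reproduce the statistical structure of real reconstructions — thousands of
reactions, highly skewed cofactor connectivity, blocked-reaction clusters,
multi-compartment transport chains — so passing tests demonstrate
algorithmic correctness, not genome-scale performance or the biological
salience of particular trees.  Real BiGG models are supported through the
same SBML reader, and an optional test validates the published growth rate
and model size for *E. coli* BL21(DE3) and RECON3D when those files are
provided locally.

## Problem sizes and numerical choices

Default test and acceptance runs use 100–200 random instances of ≤ 30
nodes (trees), ≤ 12 nodes (path enumeration, which is exponential) and
100 random DAGs for the layered-layout invariant — sizes chosen so the
exhaustive oracles stay trivially cheap while still covering the
tie-break space.  Mass-balance residuals are accepted to 1e-6, bound
violations to 1e-9, parent-centering and leaf colinearity to 1e-9.
Degenerate inputs are defined: empty weight selection → unit weights;
absent molecular weight → neutral factor; source = target → a zero-cost
single-node path; k larger than the number of simple paths → all of them;
an unreachable target → an empty path set; a model without an objective →
an explicit `no_objective` status until one is supplied.

## Known limitations

- Individual fluxes of degenerate LPs are vertex-dependent (though
  deterministic); graphs on such models are one valid view among many.
- `first_k` is a heuristic; only `best_k` carries the optimality bound,
  and even it inherits the single-edge-removal scheme's incompleteness.
- Gene–protein–reaction rules are stored verbatim, never evaluated.
- No flux-variability analysis, pFBA, media editing, extreme pathways,
  elementary flux modes or MinSpan decompositions.
- The tidy/dendrogram algorithms assume trees; general DAGs go through
  the layered layout, general graphs through the force layout.
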