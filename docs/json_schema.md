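# Node-link JSON export schema

`export_graph(obj, "json", path)` writes a single JSON object:

```json
{
  "directed": true,
  "nodes": [
    {"id": "B",  "kind": "metabolite", "label": "intermediate B",
     "compartment": "c"},
    {"id": "R2", "kind": "reaction",   "label": "B to C (ATP-coupled)",
     "flux": 5.0}
  ],
  "edges": [
    {"source": "B", "target": "R2", "role": "consumed-by",
     "stoich": 1.0, "weight": 5.0}
  ]
}
```

Field notes

- `nodes[].kind` is `"metabolite"` or `"reaction"`; tree exports carry a
  `depth` attribute instead of `compartment`/`flux`, and duplicate node
  instances of a complete tree are disambiguated as `"<id>#<n>"`.
- `edges[].role` records the flux-resolved direction: `consumed-by` means
  metabolite → reaction, `produced-by` means reaction → metabolite; the
  `source`/`target` pair is already oriented accordingly.
- `stoich` is the positive stoichiometric coefficient; `weight` is the
  edge weight under the options the graph was built with (1.0 when no
  weight metric was selected).
- Optional attributes (`compartment`, `flux`) are omitted where absent,
  never null.
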