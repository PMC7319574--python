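"""Simulate single-reaction gene deletions and their growth phenotypes.

Each reaction's bounds are forced to [0, 0] in turn and the FBA LP re-run.
Essential steps (every reaction on the only route to biomass) drop growth
to zero; knockouts can never increase the optimum.
"""

from fluxgraphs import make_toy_gem, optimize

gem = make_toy_gem("TOY6")
wild_type = optimize(gem).objective_value
print(f"wild-type growth: {wild_type:g}")
for rxn in gem.reactions:
    mutant = optimize(gem, {rxn.id}).objective_value
    tag = "essential" if mutant < 1e-9 else "dispensable"
    print(f"  d{rxn.id:<4s} growth {mutant:6g}  ({tag})")
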