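import pytest

from fluxgraphs import (
    WeightOptions,
    build_graph,
    make_toy_gem,
    optimize,
    tag_cofactors,
)


@pytest.fixture()
def toy6():
    gem = make_toy_gem("TOY6")
    tag_cofactors(gem)
    return gem


@pytest.fixture()
def toy6z():
    gem = make_toy_gem("TOY6Z")
    tag_cofactors(gem)
    return gem


@pytest.fixture()
def toy6_flux(toy6):
    return optimize(toy6)


@pytest.fixture()
def toy6_graph(toy6, toy6_flux):
    """Full TOY6 bipartite graph, flux*stoich weights, no filters."""
    return build_graph(toy6, toy6_flux, WeightOptions(use_flux=True, use_stoichiometry=True))


@pytest.fixture()
def toy6_core(toy6, toy6_flux):
    """TOY6 with cofactors excluded: the 9-node / 9-edge backbone."""
    return build_graph(
        toy6, toy6_flux, WeightOptions(use_flux=True, use_stoichiometry=True),
        exclude_cofactors=True,
    )
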