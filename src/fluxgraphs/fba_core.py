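"""Flux balance analysis: the steady-state LP behind every flux graph.

FBA maximizes the objective flux subject to mass balance S·v = 0 over the
non-boundary metabolites and the per-reaction bounds lb ≤ v ≤ ub.  Reaction
knockouts force bounds to [0, 0], emulating enzyme gene deletions.  The LP
is solved with the HiGHS dual simplex via :func:`scipy.optimize.linprog`,
which is deterministic: repeated solves of the same model return the same
vertex.  When alternative optima exist the objective value is unique but
the flux vector is one particular optimal vertex; downstream graphs are a
function of that vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .gem_model import GEM

__all__ = ["FluxStatus", "FluxState", "optimize", "knockout"]

#: |flux| at or below this is treated as zero by zero-flux filtering
DEFAULT_ZERO_TOLERANCE = 1e-9


class FluxStatus(str, Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"
    NO_OBJECTIVE = "no_objective"


@dataclass
class FluxState:
    """Per-reaction fluxes (mmol·gDW⁻¹·h⁻¹; the objective conventionally
    h⁻¹) plus the optimum and solver status."""

    fluxes: dict[str, float] = field(default_factory=dict)
    objective_value: float = float("nan")
    status: FluxStatus = FluxStatus.NO_OBJECTIVE
    knocked_out: frozenset[str] = frozenset()
    zero_tolerance: float = DEFAULT_ZERO_TOLERANCE

    @property
    def ok(self) -> bool:
        return self.status is FluxStatus.OPTIMAL

    def flux(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def is_zero(self, rxn_id: str) -> bool:
        return abs(self.fluxes.get(rxn_id, 0.0)) <= self.zero_tolerance


def optimize(
    gem: GEM,
    knockouts: frozenset[str] | set[str] = frozenset(),
    objective: str | None = None,
    zero_tolerance: float = DEFAULT_ZERO_TOLERANCE,
) -> FluxState:
    """Solve the FBA LP, maximizing the model objective (or ``objective``).

    Unknown knockout ids raise ``KeyError`` naming the id.  A model without
    an objective (and no ``objective`` argument) yields status
    ``no_objective``.  Infeasible or unbounded programs yield a FluxState
    with that status and no fluxes.
    """
    rxn_ids = [r.id for r in gem.reactions]
    known = set(rxn_ids)
    for rid in knockouts:
        if rid not in known:
            raise KeyError(f"unknown knockout reaction id {rid!r}")
    obj_id = objective or gem.objective_reaction_id
    if obj_id is None:
        return FluxState(status=FluxStatus.NO_OBJECTIVE, knocked_out=frozenset(knockouts))
    if obj_id not in known:
        raise KeyError(f"unknown objective reaction id {obj_id!r}")

    c = np.zeros(len(rxn_ids))
    if objective is not None:
        c[rxn_ids.index(obj_id)] = -1.0
        obj_coeff = 1.0
    else:
        for j, r in enumerate(gem.reactions):
            c[j] = -r.objective_coefficient
        obj_coeff = gem.reaction(obj_id).objective_coefficient

    S, _, _ = gem.stoichiometric_matrix()
    A_eq = sparse.csr_matrix(S)
    bounds = []
    for r in gem.reactions:
        if r.id in knockouts:
            bounds.append((0.0, 0.0))
        else:
            bounds.append((r.lower_bound, r.upper_bound))

    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs-ds",
    )
    if res.status == 0:
        # + 0.0 folds IEEE negative zeros into plain zeros
        fluxes = {rid: float(v) + 0.0 for rid, v in zip(rxn_ids, res.x)}
        return FluxState(
            fluxes=fluxes,
            objective_value=float(fluxes[obj_id] * obj_coeff),
            status=FluxStatus.OPTIMAL,
            knocked_out=frozenset(knockouts),
            zero_tolerance=zero_tolerance,
        )
    status = FluxStatus.INFEASIBLE if res.status == 2 else FluxStatus.UNBOUNDED
    return FluxState(
        status=status,
        knocked_out=frozenset(knockouts),
        zero_tolerance=zero_tolerance,
    )


def knockout(gem: GEM, ids: frozenset[str] | set[str]) -> GEM:
    """Copy of ``gem`` with the given reactions' bounds forced to [0, 0]."""
    known = {r.id for r in gem.reactions}
    for rid in ids:
        if rid not in known:
            raise KeyError(f"unknown reaction id {rid!r}")
    out = gem.copy()
    for r in out.reactions:
        if r.id in ids:
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return out
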