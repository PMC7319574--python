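"""Genome-scale metabolic models: SBML I/O, molecular weights, cofactors.

A :class:`GEM` is the normalized in-memory form of a constraint-based
metabolic reconstruction: compartments, metabolites, reactions with signed
stoichiometry (negative = consumed, positive = produced), flux bounds in
mmol·gDW⁻¹·h⁻¹ and a single objective reaction (usually biomass growth).
The implicit stoichiometric matrix S over non-boundary metabolites is
recoverable exactly from the reactions' stoichiometry.

Reading supports SBML Level 3 with the ``fbc`` (v2) extension natively and
falls back to the legacy COBRA dialect (bounds in kinetic-law parameters,
``FORMULA:`` / ``CHARGE:`` / ``GENE_ASSOCIATION:`` in species/reaction
notes).  Files may be plain or gzip-compressed.  Molecular weights are
computed from each metabolite's chemical formula rather than pooled from
external databases, so the package works fully offline.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import libsbml
import numpy as np

from ._elements import ATOMIC_WEIGHTS

__all__ = [
    "Metabolite",
    "Reaction",
    "GEM",
    "GEMError",
    "read_sbml",
    "write_sbml",
    "molecular_weight",
    "tag_cofactors",
    "default_cofactor_ids",
]

DEFAULT_LOWER_BOUND = -1000.0
DEFAULT_UPPER_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_FORMULA_FULL = re.compile(r"(?:[A-Z][a-z]?\d*)+\Z")


class GEMError(ValueError):
    """Raised for malformed or unusable model files."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None
    charge: int | None = None
    molecular_weight: float | None = None
    is_cofactor: bool = False
    is_boundary: bool = False


@dataclass
class Reaction:
    id: str
    name: str = ""
    #: metabolite id -> signed coefficient (negative consumed, positive produced)
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = DEFAULT_LOWER_BOUND
    upper_bound: float = DEFAULT_UPPER_BOUND
    objective_coefficient: float = 0.0
    gene_association: str | None = None

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise GEMError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} "
                f"exceeds upper bound {self.upper_bound}"
            )


@dataclass
class GEM:
    model_id: str
    compartments: dict[str, str] = field(default_factory=dict)
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_reaction_id: str | None = None

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except (AttributeError, KeyError):
            self._rebuild_index()
            if met_id not in self._met_index:
                raise KeyError(f"unknown metabolite id {met_id!r}") from None
            return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except (AttributeError, KeyError):
            self._rebuild_index()
            if rxn_id not in self._rxn_index:
                raise KeyError(f"unknown reaction id {rxn_id!r}") from None
            return self._rxn_index[rxn_id]

    def _rebuild_index(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    # -- derived structure ----------------------------------------------
    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S over non-boundary metabolites (rows) x reactions (cols)."""
        mets = [m.id for m in self.metabolites if not m.is_boundary]
        row = {m: i for i, m in enumerate(mets)}
        rxns = [r.id for r in self.reactions]
        S = np.zeros((len(mets), len(rxns)))
        for j, r in enumerate(self.reactions):
            for met_id, coeff in r.stoichiometry.items():
                i = row.get(met_id)
                if i is not None:
                    S[i, j] += coeff
        return S, mets, rxns

    def base_id(self, met_id: str) -> str:
        """Metabolite id with a trailing ``_<comp>`` or ``[<comp>]`` suffix
        removed when the suffix names a declared compartment."""
        for comp in self.compartments:
            if met_id.endswith(f"_{comp}"):
                return met_id[: -len(comp) - 1]
            if met_id.endswith(f"[{comp}]"):
                return met_id[: -len(comp) - 2]
        return met_id

    def copy(self) -> "GEM":
        g = _copy.deepcopy(self)
        g.__dict__.pop("_met_index", None)
        g.__dict__.pop("_rxn_index", None)
        return g

    def validate(self) -> None:
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            raise GEMError("duplicate metabolite ids")
        known = set(ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise GEMError(
                    f"reaction {r.id!r} references unknown metabolites "
                    f"{sorted(missing)}"
                )


# ---------------------------------------------------------------------------
# molecular weights
# ---------------------------------------------------------------------------

def molecular_weight(formula: str | None) -> float | None:
    """Molecular weight in g/mol from a Hill-notation formula.

    Returns ``None`` for an absent, empty or unparseable formula — including
    polymeric ``R``/``X`` groups, ``*`` repeats and parenthesised units.
    Never raises.
    """
    if not formula or not isinstance(formula, str):
        return None
    if not _FORMULA_FULL.match(formula):
        return None
    total = 0.0
    for element, count in _FORMULA_TOKEN.findall(formula):
        if not element:
            continue
        weight = ATOMIC_WEIGHTS.get(element)
        if weight is None:
            return None
        total += weight * (int(count) if count else 1)
    return total if total > 0 else None


# ---------------------------------------------------------------------------
# cofactors
# ---------------------------------------------------------------------------

def default_cofactor_ids() -> frozenset[str]:
    """Shipped base-id list of currency metabolites (ATP/ADP, NAD(P)(H),
    water, protons, Pi, ...).  User-overridable everywhere it is consumed."""
    text = resources.files("fluxgraphs").joinpath("data/cofactors.txt").read_text()
    ids = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line.lower())
    return frozenset(ids)


def tag_cofactors(gem: GEM, cofactor_base_ids: frozenset[str] | set[str] | None = None) -> int:
    """Flag metabolites whose compartment-stripped base id is in the list.

    Matching is case-insensitive (BiGG ids are lowercase; hand-built models
    often are not).  Returns the number of metabolites tagged.  Idempotent;
    metabolites not in the list are untagged.
    """
    if cofactor_base_ids is None:
        cofactor_base_ids = default_cofactor_ids()
    wanted = {c.lower() for c in cofactor_base_ids}
    count = 0
    for met in gem.metabolites:
        met.is_cofactor = gem.base_id(met.id).lower() in wanted
        count += met.is_cofactor
    return count


# ---------------------------------------------------------------------------
# SBML reading
# ---------------------------------------------------------------------------

def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _notes_field(notes: str | None, key: str) -> str | None:
    if not notes:
        return None
    m = re.search(rf"{key}\s*:\s*([^<\n]*)", notes)
    if m:
        value = m.group(1).strip()
        return value or None
    return None


def _species_formula_charge(sp: libsbml.Species) -> tuple[str | None, int | None]:
    formula: str | None = None
    charge: int | None = None
    fbc = sp.getPlugin("fbc")
    if fbc is not None:
        if fbc.isSetChemicalFormula():
            formula = fbc.getChemicalFormula() or None
        if fbc.isSetCharge():
            charge = fbc.getCharge()
    notes = sp.getNotesString() if sp.isSetNotes() else None
    if formula is None:
        formula = _notes_field(notes, "FORMULA")
    if charge is None:
        raw = _notes_field(notes, "CHARGE")
        if raw is not None:
            try:
                charge = int(float(raw))
            except ValueError:
                charge = None
    # SBML Level 2 species had a (deprecated) charge attribute
    if charge is None and sp.isSetCharge():
        charge = sp.getCharge()
    return formula, charge


def _reaction_bounds(rxn: libsbml.Reaction, model: libsbml.Model) -> tuple[float, float]:
    lb = DEFAULT_LOWER_BOUND if rxn.getReversible() else 0.0
    ub = DEFAULT_UPPER_BOUND
    fbc = rxn.getPlugin("fbc")
    if fbc is not None and fbc.isSetLowerFluxBound():
        p = model.getParameter(fbc.getLowerFluxBound())
        if p is not None:
            lb = p.getValue()
    if fbc is not None and fbc.isSetUpperFluxBound():
        p = model.getParameter(fbc.getUpperFluxBound())
        if p is not None:
            ub = p.getValue()
    kl = rxn.getKineticLaw()
    if kl is not None:
        for getter in (kl.getParameter, kl.getLocalParameter):
            try:
                plo, pup = getter("LOWER_BOUND"), getter("UPPER_BOUND")
            except Exception:  # pragma: no cover - older bindings
                continue
            if plo is not None:
                lb = plo.getValue()
            if pup is not None:
                ub = pup.getValue()
            if plo is not None or pup is not None:
                break
    return lb, ub


def _gene_association(rxn: libsbml.Reaction) -> str | None:
    fbc = rxn.getPlugin("fbc")
    if fbc is not None and fbc.isSetGeneProductAssociation():
        assoc = fbc.getGeneProductAssociation().getAssociation()
        if assoc is not None:
            try:
                return assoc.toInfix() or None
            except Exception:  # pragma: no cover
                return None
    notes = rxn.getNotesString() if rxn.isSetNotes() else None
    return _notes_field(notes, "GENE_ASSOCIATION")


def read_sbml(path: str | Path) -> GEM:
    """Parse an SBML model file (L3+fbc or legacy COBRA dialect; .gz ok).

    Species and reaction ids keep document order; BiGG-convention ``M_`` /
    ``R_`` SId prefixes are stripped.  Boundary-condition species are
    flagged and later dropped from mass-balance rows but kept for display.
    A missing objective is tolerated (``objective_reaction_id`` stays
    ``None``); flux optimization will then require an explicit objective.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise GEMError(f"SBML parse error in {path.name}: {err.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise GEMError(f"{path.name}: no <model> element")
    if model.getNumReactions() == 0:
        raise GEMError(f"{path.name}: model contains no reactions")

    gem = GEM(model_id=model.getId() or path.stem)
    for i in range(model.getNumCompartments()):
        comp = model.getCompartment(i)
        gem.compartments[comp.getId()] = comp.getName() or comp.getId()

    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        sid = _strip_prefix(sp.getId(), "M_")
        formula, charge = _species_formula_charge(sp)
        gem.metabolites.append(
            Metabolite(
                id=sid,
                name=sp.getName() or sid,
                compartment=sp.getCompartment(),
                formula=formula,
                charge=charge,
                molecular_weight=molecular_weight(formula),
                is_boundary=bool(sp.getBoundaryCondition()),
            )
        )

    objective_id: str | None = None
    objective_coeffs: dict[str, float] = {}
    mplug = model.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        if obj is not None:
            for j in range(obj.getNumFluxObjectives()):
                fo = obj.getFluxObjective(j)
                rid = _strip_prefix(fo.getReaction(), "R_")
                if fo.getCoefficient() != 0:
                    objective_coeffs[rid] = fo.getCoefficient()

    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        rid = _strip_prefix(rxn.getId(), "R_")
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            sr = rxn.getReactant(j)
            met = _strip_prefix(sr.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) - sr.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            sr = rxn.getProduct(j)
            met = _strip_prefix(sr.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) + sr.getStoichiometry()
        # legacy notes: objective coefficient
        coeff = objective_coeffs.get(rid, 0.0)
        if not objective_coeffs:
            raw = _notes_field(
                rxn.getNotesString() if rxn.isSetNotes() else None,
                "OBJECTIVE_COEFFICIENT",
            )
            if raw:
                try:
                    coeff = float(raw)
                except ValueError:
                    coeff = 0.0
        lb, ub = _reaction_bounds(rxn, model)
        gem.reactions.append(
            Reaction(
                id=rid,
                name=rxn.getName() or rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                objective_coefficient=coeff,
                gene_association=_gene_association(rxn),
            )
        )
        if coeff != 0 and objective_id is None:
            objective_id = rid

    gem.objective_reaction_id = objective_id
    gem.validate()
    return gem


# ---------------------------------------------------------------------------
# SBML writing (fixture writer: Level 3 Version 1 + fbc v2)
# ---------------------------------------------------------------------------

def write_sbml(gem: GEM, path: str | Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(gem.model_id)
    mplug = model.getPlugin("fbc")
    mplug.setStrict(True)

    for cid, cname in (gem.compartments or {"c": "cytosol"}).items():
        comp = model.createCompartment()
        comp.setId(cid)
        comp.setName(cname)
        comp.setConstant(True)
        comp.setSize(1.0)

    for met in gem.metabolites:
        sp = model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment or next(iter(gem.compartments), "c"))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(met.is_boundary)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        if met.formula:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(int(met.charge))

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in gem.reactions:
        r = model.createReaction()
        r.setId(rxn.id)
        r.setName(rxn.name)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff < 0:
                sr = r.createReactant()
            elif coeff > 0:
                sr = r.createProduct()
            else:
                continue
            sr.setSpecies(met_id)
            sr.setStoichiometry(abs(coeff))
            sr.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))

    objective_rxns = [r for r in gem.reactions if r.objective_coefficient != 0]
    if objective_rxns:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        for r in objective_rxns:
            fo = obj.createFluxObjective()
            fo.setReaction(r.id)
            fo.setCoefficient(r.objective_coefficient)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")
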