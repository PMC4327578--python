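"""SBML import/export for mass-action count models.

Reads SBML Level 2 / Level 3 documents whose reactions are irreversible
mass-action channels of order 0-2, with species held as substance amounts
(integer molecule counts).  Kinetic laws are matched symbolically against the
supported propensity forms (c, c*S, c*S1*S2, c*S*(S-1)/2), so algebraically
equivalent arrangements are accepted.  Writes Level 3 Version 1 documents
that round-trip exactly through the reader.

Units declared in the SBML are ignored: rate constants are taken verbatim as
stochastic rate constants on the molecule-count scale.  This is reported
loudly in the import warnings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import libsbml
import sympy
from sympy.parsing.sympy_parser import parse_expr

from .model import ModelSpec, ReactionSpec

__all__ = ["SBMLImportOptions", "SBMLImportError", "load_sbml", "write_sbml", "import_report"]

_AMOUNT_TOL = 1e-9


class SBMLImportError(ValueError):
    """Import failure; ``element`` names the offending SBML element id."""

    def __init__(self, message: str, element: str | None = None):
        self.element = element
        super().__init__(message if element is None else f"{message} (element {element!r})")


@dataclass(frozen=True)
class SBMLImportOptions:
    """Import policy.

    strict_mass_action
        Reject kinetic laws that do not reduce to a supported mass-action
        form.  When False, the single (local preferred) parameter of the
        kinetic law is taken as the rate constant without checking the form.
    amount_interpretation
        Fixed: initial amounts are substance amounts read as integer counts.
    """

    strict_mass_action: bool = True
    amount_interpretation: str = "substance amounts as integer counts"


def _expected_mass_action(reactants, symbols):
    """Propensity polynomial for the reactant multiset (combinatorial form)."""
    expr = sympy.Integer(1)
    for idx, coeff in reactants:
        s = symbols[idx]
        if coeff == 1:
            expr *= s
        elif coeff == 2:
            expr *= s * (s - 1) / 2
    return expr


def _rate_constant_from_law(reaction, reactants, species_ids, global_params, options):
    law = reaction.getKineticLaw()
    rid = reaction.getId() or reaction.getIdAttribute()
    if law is None:
        raise SBMLImportError("reaction has no kinetic law", rid)

    local_params: dict[str, float] = {}
    for i in range(law.getNumLocalParameters()):
        p = law.getLocalParameter(i)
        local_params[p.getId()] = p.getValue()
    for i in range(law.getNumParameters()):  # L2 "parameter" children
        p = law.getParameter(i)
        local_params.setdefault(p.getId(), p.getValue())

    def lookup(name: str) -> float:
        if name in local_params:  # local wins on collision
            return local_params[name]
        if name in global_params:
            return global_params[name]
        raise SBMLImportError(f"kinetic-law parameter {name!r} is undefined", rid)

    formula = libsbml.formulaToL3String(law.getMath()) if law.getMath() else None
    if formula is None:
        raise SBMLImportError("kinetic law has no math", rid)

    names = set(species_ids) | set(local_params) | set(global_params)
    local_dict = {name: sympy.Symbol(name) for name in names}
    try:
        expr = parse_expr(formula.replace("^", "**"), local_dict=local_dict)
    except Exception as exc:
        raise SBMLImportError(f"cannot parse kinetic law {formula!r}: {exc}", rid)

    sp_symbols = {i: local_dict[sid] for i, sid in enumerate(species_ids)}
    expected = _expected_mass_action(reactants, sp_symbols)
    ratio = sympy.simplify(sympy.cancel(expr / expected))
    if ratio.is_number:
        return float(ratio)
    if len(ratio.free_symbols) == 1:
        # c, 0.5*c (homodimer written without the /2), etc.
        p = next(iter(ratio.free_symbols))
        coeff = sympy.simplify(ratio / p)
        if coeff.is_number:
            return float(coeff) * lookup(str(p))
    if options.strict_mass_action:
        raise SBMLImportError(
            f"kinetic law {formula!r} is not mass-action for its reactants", rid
        )
    if len(local_params) == 1:
        return next(iter(local_params.values()))
    free = [s for s in expr.free_symbols if str(s) not in species_ids]
    if len(free) == 1:
        return lookup(str(free[0]))
    raise SBMLImportError("cannot identify a single rate constant", rid)


def load_sbml(path: str, options: SBMLImportOptions | None = None) -> ModelSpec:
    """Read an SBML file into a :class:`ModelSpec`.

    Species follow document order; initial amounts must be integral within
    1e-9.  Each reaction must be irreversible with reactant-coefficient sum
    (the reaction order) at most 2.
    """
    options = options or SBMLImportOptions()
    doc = libsbml.readSBMLFromFile(path)
    log = doc.getErrorLog()
    if log.getNumFailsWithSeverity(libsbml.LIBSBML_SEV_ERROR) > 0:
        first = next(
            log.getError(i)
            for i in range(log.getNumErrors())
            if log.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        )
        raise SBMLImportError(f"SBML parse error: {first.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLImportError(f"no model element in {path!r}")

    species_ids: list[str] = []
    initial_counts: list[int] = []
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        sid = s.getId()
        amount = s.getInitialAmount() if s.isSetInitialAmount() else 0.0
        if math.isnan(amount):
            amount = 0.0
        rounded = round(amount)
        if abs(amount - rounded) > _AMOUNT_TOL:
            raise SBMLImportError(
                f"initial amount {amount} is not an integer count", sid
            )
        species_ids.append(sid)
        initial_counts.append(int(rounded))
    index = {sid: i for i, sid in enumerate(species_ids)}

    global_params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    reactions: list[ReactionSpec] = []
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        rid = rxn.getId()
        if rxn.getReversible():
            raise SBMLImportError(
                "reversible reaction: split it into two irreversible channels", rid
            )

        def side(refs):
            out = []
            for ref in refs:
                stoich = ref.getStoichiometry()
                if math.isnan(stoich):
                    stoich = 1.0
                k = round(stoich)
                if abs(stoich - k) > _AMOUNT_TOL or k < 1:
                    raise SBMLImportError(
                        f"non-integer stoichiometry {stoich}", rid
                    )
                sp = ref.getSpecies()
                if sp not in index:
                    raise SBMLImportError(f"unknown species {sp!r}", rid)
                out.append((index[sp], int(k)))
            return tuple(out)

        reactants = side(rxn.getReactant(j) for j in range(rxn.getNumReactants()))
        products = side(rxn.getProduct(j) for j in range(rxn.getNumProducts()))
        order = sum(k for _, k in reactants)
        if order > 2:
            raise SBMLImportError(
                f"reaction order {order} > 2: rewrite as a combination of 0th-2nd order channels",
                rid,
            )
        c = _rate_constant_from_law(rxn, reactants, species_ids, global_params, options)
        reactions.append(ReactionSpec(rid, c, reactants=reactants, products=products))

    return ModelSpec(tuple(species_ids), tuple(initial_counts), tuple(reactions))


def _kinetic_formula(r: ReactionSpec, species: tuple[str, ...]) -> str:
    parts = ["c"]
    for idx, coeff in r.reactants:
        s = species[idx]
        if coeff == 1:
            parts.append(s)
        else:
            return f"c * {s} * ({s} - 1) / 2"
    return " * ".join(parts)


def write_sbml(model: ModelSpec, path: str) -> None:
    """Write a model as SBML Level 3 Version 1; load_sbml inverts it exactly."""
    from .model import require_valid

    require_valid(model)
    doc = libsbml.SBMLDocument(3, 1)
    m = doc.createModel()
    m.setId("model")
    comp = m.createCompartment()
    comp.setId("cell")
    comp.setSize(1.0)
    comp.setConstant(True)
    comp.setSpatialDimensions(3)
    for sid, x0 in zip(model.species, model.initial_counts):
        s = m.createSpecies()
        s.setId(sid)
        s.setCompartment("cell")
        s.setInitialAmount(float(x0))
        s.setHasOnlySubstanceUnits(True)
        s.setBoundaryCondition(False)
        s.setConstant(False)
    for r in model.reactions:
        rxn = m.createReaction()
        rxn.setId(r.id)
        rxn.setReversible(False)
        rxn.setFast(False)
        for idx, coeff in r.reactants:
            ref = rxn.createReactant()
            ref.setSpecies(model.species[idx])
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        for idx, coeff in r.products:
            ref = rxn.createProduct()
            ref.setSpecies(model.species[idx])
            ref.setStoichiometry(float(coeff))
            ref.setConstant(True)
        law = rxn.createKineticLaw()
        p = law.createLocalParameter()
        p.setId("c")
        p.setValue(r.rate_constant)
        law.setMath(libsbml.parseL3Formula(_kinetic_formula(r, model.species)))
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise OSError(f"could not write SBML to {path!r}")


def import_report(path: str, options: SBMLImportOptions | None = None) -> dict:
    """Import an SBML file and return a structured JSON-able report."""
    options = options or SBMLImportOptions()
    try:
        model = load_sbml(path, options)
    except SBMLImportError as exc:
        return {"path": str(path), "ok": False, "error": str(exc), "element": exc.element}
    return {
        "path": str(path),
        "ok": True,
        "species": model.m_species,
        "reactions": model.n,
        "total_initial_molecules": int(sum(model.initial_counts)),
        "warnings": [
            "SBML unit definitions are ignored: rate constants are used verbatim "
            "as stochastic rate constants on the molecule-count scale"
        ],
    }
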