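"""SBML Level 3 + FBC v2 subset I/O backed by libsbml.

Covered: compartments, species (formula/charge via the FBC plugin),
reactions with bounds expressed as FBC parameters, gene-product
associations, and a single maximisation objective.  Anything outside
this subset (kinetic laws, rules, events) raises instead of being
dropped silently.
"""

from __future__ import annotations

import libsbml

from .errors import ValidationError
from .model import (
    GPRTree,
    MetabolicModel,
    Metabolite,
    Reaction,
    gene,
    gpr_and,
    gpr_or,
)

_MET_PREFIX = "M_"
_RXN_PREFIX = "R_"
_GENE_PREFIX = "G_"


def _sanitize(sid: str) -> str:
    out = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in sid)
    return out


def _fbc_assoc_to_gpr(assoc) -> GPRTree:
    if assoc.isGeneProductRef():
        gid = assoc.getGeneProduct()
        if gid.startswith(_GENE_PREFIX):
            gid = gid[len(_GENE_PREFIX):]
        return gene(gid)
    children = [_fbc_assoc_to_gpr(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())]
    if assoc.isFbcAnd():
        return gpr_and(*children)
    if assoc.isFbcOr():
        return gpr_or(*children)
    raise ValidationError("unsupported gene association node in SBML")


def _gpr_to_fbc_assoc(tree: GPRTree, parent) -> None:
    if tree.kind == "GENE":
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(_GENE_PREFIX + _sanitize(tree.gene_id))
        return
    node = parent.createAnd() if tree.kind == "AND" else parent.createOr()
    for ch in tree.children:
        _gpr_to_fbc_assoc(ch, node)


def read_sbml_model(path: str) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ValidationError(f"SBML parse error: {err.getMessage() if err else 'unknown'}")
    sm = doc.getModel()
    if sm is None:
        raise ValidationError("SBML file contains no model")
    if sm.getNumRules() or sm.getNumEvents() or sm.getNumConstraints():
        raise ValidationError("SBML rules/events/constraints are not supported")

    comp_code = {}
    for i in range(sm.getNumCompartments()):
        comp = sm.getCompartment(i)
        cid = comp.getId()
        code = cid[-1] if cid else "c"
        comp_code[cid] = code

    mets = []
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        fbc = sp.getPlugin("fbc")
        mid = sp.getId()
        if mid.startswith(_MET_PREFIX):
            mid = mid[len(_MET_PREFIX):]
        charge = None
        formula = ""
        if fbc is not None:
            if fbc.isSetCharge():
                charge = fbc.getCharge()
            if fbc.isSetChemicalFormula():
                formula = fbc.getChemicalFormula() or ""
        mets.append(
            Metabolite(
                id=mid,
                name=sp.getName() or "",
                compartment=comp_code.get(sp.getCompartment(), "c"),
                formula=formula,
                charge=charge,
            )
        )

    def bound_value(pid: str) -> float:
        p = sm.getParameter(pid)
        if p is None or not p.isSetValue():
            raise ValidationError(f"reaction bound parameter {pid!r} missing a value")
        return p.getValue()

    rxns = []
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        if sr.isSetKineticLaw():
            raise ValidationError(f"kinetic law on reaction {sr.getId()!r} not supported")
        rid = sr.getId()
        if rid.startswith(_RXN_PREFIX):
            rid = rid[len(_RXN_PREFIX):]
        stoich: dict[str, float] = {}
        boundary_only = True
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            sid = ref.getSpecies()
            sp = sm.getSpecies(sid)
            if sp is not None and sp.getBoundaryCondition():
                continue
            boundary_only = False
            if sid.startswith(_MET_PREFIX):
                sid = sid[len(_MET_PREFIX):]
            stoich[sid] = stoich.get(sid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            sid = ref.getSpecies()
            sp = sm.getSpecies(sid)
            if sp is not None and sp.getBoundaryCondition():
                continue
            boundary_only = False
            if sid.startswith(_MET_PREFIX):
                sid = sid[len(_MET_PREFIX):]
            stoich[sid] = stoich.get(sid, 0.0) + ref.getStoichiometry()
        del boundary_only
        fbc = sr.getPlugin("fbc")
        if fbc is None or not fbc.isSetLowerFluxBound() or not fbc.isSetUpperFluxBound():
            raise ValidationError(f"reaction {rid!r} is missing FBC flux bounds")
        lb = bound_value(fbc.getLowerFluxBound())
        ub = bound_value(fbc.getUpperFluxBound())
        gpr = None
        if fbc.isSetGeneProductAssociation():
            gpa = fbc.getGeneProductAssociation()
            gpr = _fbc_assoc_to_gpr(gpa.getAssociation())
        rxns.append(
            Reaction(
                id=rid,
                name=sr.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                is_exchange=len(stoich) == 1,
                subsystem="",
            )
        )

    objective_id = ""
    mplug = sm.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            oid = obj.getFluxObjective(0).getReaction()
            if oid.startswith(_RXN_PREFIX):
                oid = oid[len(_RXN_PREFIX):]
            objective_id = oid

    model = MetabolicModel(
        metabolites=mets, reactions=rxns, objective_id=objective_id, id=sm.getId() or "model"
    )
    model.validate()
    return model


def write_sbml_model(model: MetabolicModel, path: str) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sanitize(model.id))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    used_comps = sorted({m.compartment for m in model.metabolites})
    for code in used_comps:
        comp = sm.createCompartment()
        comp.setId(code)
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(_MET_PREFIX + _sanitize(m.id))
        sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        fbc = sp.getPlugin("fbc")
        if m.formula:
            fbc.setChemicalFormula(m.formula)
        if m.charge is not None:
            fbc.setCharge(int(m.charge))

    genes: set[str] = set()
    for r in model.reactions:
        if r.gpr is not None:
            genes |= r.gpr.genes()
    for g in sorted(genes):
        gp = mplug.createGeneProduct()
        gp.setId(_GENE_PREFIX + _sanitize(g))
        gp.setLabel(g)

    def make_param(pid: str, value: float) -> str:
        p = sm.createParameter()
        p.setId(pid)
        p.setValue(float(value))
        p.setConstant(True)
        return pid

    for r in model.reactions:
        sr = sm.createReaction()
        rid = _RXN_PREFIX + _sanitize(r.id)
        sr.setId(rid)
        sr.setName(r.name)
        sr.setReversible(r.lower_bound < 0)
        sr.setFast(False)
        for mid, coef in r.stoichiometry.items():
            if coef < 0:
                ref = sr.createReactant()
                ref.setStoichiometry(-coef)
            else:
                ref = sr.createProduct()
                ref.setStoichiometry(coef)
            ref.setSpecies(_MET_PREFIX + _sanitize(mid))
            ref.setConstant(True)
        fbc = sr.getPlugin("fbc")
        fbc.setLowerFluxBound(make_param(rid + "_lb", r.lower_bound))
        fbc.setUpperFluxBound(make_param(rid + "_ub", r.upper_bound))
        if r.gpr is not None:
            gpa = fbc.createGeneProductAssociation()
            if r.gpr.kind == "GENE":
                ref = gpa.createGeneProductRef()
                ref.setGeneProduct(_GENE_PREFIX + _sanitize(r.gpr.gene_id))
            else:
                _gpr_to_fbc_assoc(r.gpr, gpa)

    if model.objective_id:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize" if model.objective_sense == "max" else "minimize")
        fo = obj.createFluxObjective()
        fo.setReaction(_RXN_PREFIX + _sanitize(model.objective_id))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise ValidationError(f"failed to write SBML to {path!r}")
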