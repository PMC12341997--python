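"""Metabolic-model data structures, GPR parsing, matrices, and JSON I/O.

The in-memory representation follows the COBRA convention: a model is a
list of metabolites and a list of reactions, each reaction holding a
sparse stoichiometry (negative coefficients = substrates), flux bounds in
mmol gDW^-1 h^-1, and an optional boolean gene association.  Exchange
reactions are single-metabolite boundary reactions written ``M ->`` so
that uptake is a negative flux.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    FormulaError,
    GPRParseError,
    UnknownCompositionError,
    ValidationError,
)

#: Valid one-letter compartment codes: cytosol, extracellular, Golgi,
#: inner mitochondrial space, lysosome, mitochondria, nucleus,
#: endoplasmic reticulum, peroxisome.
COMPARTMENTS = frozenset("cegilmnrx")

CHARGE_ELEMENT = "charge"


# ---------------------------------------------------------------------------
# GPR trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPRTree:
    """Boolean gene association: AND/OR internal nodes, GENE leaves."""

    kind: str  # "AND" | "OR" | "GENE"
    children: tuple["GPRTree", ...] = ()
    gene_id: str = ""

    def __post_init__(self):
        if self.kind == "GENE":
            if self.children or not self.gene_id:
                raise ValidationError("GENE node must carry a gene id and no children")
        elif self.kind in ("AND", "OR"):
            if len(self.children) < 2:
                raise ValidationError(f"{self.kind} node needs >=2 children")
        else:
            raise ValidationError(f"unknown GPR node kind {self.kind!r}")

    def genes(self) -> set[str]:
        if self.kind == "GENE":
            return {self.gene_id}
        out: set[str] = set()
        for ch in self.children:
            out |= ch.genes()
        return out

    def to_string(self) -> str:
        return _gpr_to_string(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def gene(gid: str) -> GPRTree:
    return GPRTree("GENE", gene_id=gid)


def gpr_and(*children: GPRTree) -> GPRTree:
    return GPRTree("AND", children=tuple(children))


def gpr_or(*children: GPRTree) -> GPRTree:
    return GPRTree("OR", children=tuple(children))


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize_gpr(text: str):
    tokens = []
    for m in _TOKEN_RE.finditer(text):
        tok = m.group(0)
        up = tok.upper()
        if tok == "(":
            kind = "LPAR"
        elif tok == ")":
            kind = "RPAR"
        elif up == "AND":
            kind = "AND"
        elif up == "OR":
            kind = "OR"
        else:
            kind = "GENE"
        tokens.append((kind, tok, m.start()))
    return tokens


class _GPRParser:
    """Recursive-descent parser; OR binds looser than AND."""

    def __init__(self, tokens, text):
        self.tokens = tokens
        self.pos = 0
        self.text = text

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        if tok is None:
            raise GPRParseError("unexpected end of rule", len(self.text))
        self.pos += 1
        return tok

    def parse(self) -> GPRTree:
        tree = self.expr()
        if self.peek() is not None:
            kind, tok, at = self.peek()
            raise GPRParseError(f"unexpected token {tok!r}", at)
        return tree

    def expr(self) -> GPRTree:
        terms = [self.term()]
        while self.peek() and self.peek()[0] == "OR":
            self.take()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else _flatten("OR", terms)

    def term(self) -> GPRTree:
        factors = [self.factor()]
        while self.peek() and self.peek()[0] == "AND":
            self.take()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else _flatten("AND", factors)

    def factor(self) -> GPRTree:
        kind, tok, at = self.take()
        if kind == "GENE":
            return gene(tok)
        if kind == "LPAR":
            inner = self.expr()
            nxt = self.peek()
            if nxt is None or nxt[0] != "RPAR":
                raise GPRParseError("unbalanced parentheses: missing ')'", at)
            self.take()
            return inner
        if kind in ("AND", "OR"):
            raise GPRParseError(f"dangling operator {tok!r}", at)
        raise GPRParseError(f"unexpected token {tok!r}", at)


def _flatten(kind: str, nodes: list[GPRTree]) -> GPRTree:
    """Associativity: collapse nested nodes of the same kind into one n-ary node."""
    flat: list[GPRTree] = []
    for n in nodes:
        if n.kind == kind:
            flat.extend(n.children)
        else:
            flat.append(n)
    return GPRTree(kind, children=tuple(flat))


def parse_gpr(text: str) -> GPRTree | None:
    """Parse a boolean gene-association rule; empty/blank text -> ``None``.

    Grammar: ``expr := term (OR term)*``, ``term := factor (AND factor)*``,
    ``factor := GENE | '(' expr ')'`` with case-insensitive operators.
    """
    if text is None or not text.strip():
        return None
    tokens = _tokenize_gpr(text)
    return _GPRParser(tokens, text).parse()


def _gpr_to_string(tree: GPRTree) -> str:
    if tree.kind == "GENE":
        return tree.gene_id
    parts = []
    for ch in tree.children:
        s = _gpr_to_string(ch)
        # OR inside AND needs parentheses; anything else does not.
        if tree.kind == "AND" and ch.kind == "OR":
            s = f"({s})"
        parts.append(s)
    sep = " and " if tree.kind == "AND" else " or "
    return sep.join(parts)


# ---------------------------------------------------------------------------
# Formulas
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a flat elemental composition string like ``C6H12O6``.

    Repeated element blocks are summed; parenthesised groups are rejected
    (genome-scale reconstructions store formulas flat).
    """
    if any(ch in formula for ch in "()[]{}"):
        raise FormulaError(f"parenthesised formula not supported: {formula!r}")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula):
        raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


# ---------------------------------------------------------------------------
# Metabolites, reactions, models
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str = ""
    charge: int | None = None

    def element_counts(self) -> dict[str, int]:
        if not self.formula:
            raise UnknownCompositionError(f"metabolite {self.id!r} has no formula")
        return parse_formula(self.formula)


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr: GPRTree | None = None
    is_exchange: bool = False
    subsystem: str = ""
    name: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str = ""
    objective_sense: str = "max"
    id: str = "model"

    # -- lookup helpers ----------------------------------------------------
    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def get_metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    @property
    def objective(self) -> Reaction:
        return self.get_reaction(self.objective_id)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            objective_id=self.objective_id,
            objective_sense=self.objective_sense,
            id=self.id,
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ValidationError` listing every violated invariant."""
        problems: list[str] = []
        mids = [m.id for m in self.metabolites]
        if len(set(mids)) != len(mids):
            dups = sorted({i for i in mids if mids.count(i) > 1})
            problems.append(f"duplicate metabolite ids: {dups}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dups = sorted({i for i in rids if rids.count(i) > 1})
            problems.append(f"duplicate reaction ids: {dups}")
        for m in self.metabolites:
            if m.compartment not in COMPARTMENTS:
                problems.append(
                    f"metabolite {m.id!r}: unknown compartment {m.compartment!r}"
                )
        known = set(mids)
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                problems.append(f"reaction {r.id!r}: lower_bound > upper_bound")
            for mid in r.stoichiometry:
                if mid not in known:
                    problems.append(f"reaction {r.id!r}: unknown metabolite {mid!r}")
        if self.objective_id and self.objective_id not in set(rids):
            problems.append(f"objective reaction {self.objective_id!r} not in model")
        if problems:
            raise ValidationError("; ".join(problems))


def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense stoichiometric matrix S (metabolites x reactions).

    Column order follows the model's reaction order; entry (m, r) is the
    signed coefficient of metabolite m in reaction r.
    """
    midx = model.metabolite_index()
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for mid, coef in rxn.stoichiometry.items():
            S[midx[mid], j] = coef
    return S


# ---------------------------------------------------------------------------
# Element matrix and mass balance
# ---------------------------------------------------------------------------

@dataclass
class ElementMatrix:
    """Element x metabolite count matrix with a charge pseudo-element row.

    Metabolites with an empty formula are flagged ``unknown`` rather than
    silently zeroed.
    """

    elements: list[str]
    metabolite_ids: list[str]
    counts: np.ndarray  # elements x metabolites
    unknown: set[str]

    def column(self, mid: str) -> np.ndarray:
        if mid in self.unknown:
            raise UnknownCompositionError(f"metabolite {mid!r} has unknown composition")
        return self.counts[:, self.metabolite_ids.index(mid)]


def element_matrix(model: MetabolicModel, include_charge: bool = True) -> ElementMatrix:
    per_met: list[dict[str, int]] = []
    unknown: set[str] = set()
    elements: list[str] = []
    seen: set[str] = set()
    for m in model.metabolites:
        if not m.formula:
            unknown.add(m.id)
            per_met.append({})
            continue
        counts = parse_formula(m.formula)
        per_met.append(counts)
        for e in counts:
            if e not in seen:
                seen.add(e)
                elements.append(e)
    if include_charge:
        elements = elements + [CHARGE_ELEMENT]
    mat = np.zeros((len(elements), len(model.metabolites)))
    for j, (m, counts) in enumerate(zip(model.metabolites, per_met)):
        for e, c in counts.items():
            mat[elements.index(e), j] = c
        if include_charge and m.charge is not None:
            mat[elements.index(CHARGE_ELEMENT), j] = m.charge
    return ElementMatrix(
        elements=elements,
        metabolite_ids=[m.id for m in model.metabolites],
        counts=mat,
        unknown=unknown,
    )


def check_mass_balance(
    model: MetabolicModel, reaction: Reaction | str, include_charge: bool = True
) -> dict[str, float]:
    """Per-element residual of a reaction: sum of coeff * element count.

    An all-zero residual means balanced.  Exchange reactions are boundary
    pseudo-reactions and return an empty residual by design.  A participating
    metabolite without a formula raises :class:`UnknownCompositionError`.
    """
    if isinstance(reaction, str):
        reaction = model.get_reaction(reaction)
    if reaction.is_exchange:
        return {}
    mets = {m.id: m for m in model.metabolites}
    residual: dict[str, float] = {}
    for mid, coef in reaction.stoichiometry.items():
        met = mets[mid]
        counts = met.element_counts()  # raises UnknownCompositionError when empty
        for e, c in counts.items():
            residual[e] = residual.get(e, 0.0) + coef * c
        if include_charge and met.charge is not None:
            residual[CHARGE_ELEMENT] = residual.get(CHARGE_ELEMENT, 0.0) + coef * met.charge
    return {e: v for e, v in residual.items() if abs(v) > 1e-9}


# ---------------------------------------------------------------------------
# JSON dialect I/O
# ---------------------------------------------------------------------------

JSON_SCHEMA_VERSION = 1


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "schema_version": JSON_SCHEMA_VERSION,
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string() if r.gpr is not None else "",
                "is_exchange": r.is_exchange,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "objective": {"reaction": model.objective_id, "sense": model.objective_sense},
    }


def model_from_dict(data: dict) -> MetabolicModel:
    for key in ("metabolites", "reactions"):
        if key not in data:
            raise ValidationError(f"model JSON missing {key!r}")
    mets = []
    for d in data["metabolites"]:
        mets.append(
            Metabolite(
                id=d["id"],
                name=d.get("name", ""),
                compartment=d.get("compartment", "c"),
                formula=d.get("formula", "") or "",
                charge=d.get("charge"),
            )
        )
    rxns = []
    for d in data["reactions"]:
        if "lower_bound" not in d or "upper_bound" not in d:
            raise ValidationError(f"reaction {d.get('id')!r} is missing bounds")
        rxns.append(
            Reaction(
                id=d["id"],
                name=d.get("name", ""),
                stoichiometry={k: float(v) for k, v in d["stoichiometry"].items()},
                lower_bound=float(d["lower_bound"]),
                upper_bound=float(d["upper_bound"]),
                gpr=parse_gpr(d.get("gpr", "")),
                is_exchange=bool(d.get("is_exchange", False)),
                subsystem=d.get("subsystem", ""),
            )
        )
    obj = data.get("objective", {}) or {}
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_id=obj.get("reaction", ""),
        objective_sense=obj.get("sense", "max"),
        id=data.get("id", "model"),
    )
    model.validate()
    return model


def read_model(path: str, format: str | None = None) -> MetabolicModel:
    """Read a model from JSON (native dialect) or SBML L3+FBC."""
    fmt = format or ("sbml" if str(path).endswith((".xml", ".sbml")) else "json")
    if fmt == "json":
        with open(path) as fh:
            return model_from_dict(json.load(fh))
    if fmt == "sbml":
        from .sbml import read_sbml_model

        return read_sbml_model(path)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path: str, format: str | None = None) -> None:
    fmt = format or ("sbml" if str(path).endswith((".xml", ".sbml")) else "json")
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif fmt == "sbml":
        from .sbml import write_sbml_model

        write_sbml_model(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def export_stoichiometry_tsv(model: MetabolicModel, path: str) -> None:
    """Write the stoichiometric matrix as TSV (rows metabolites, cols reactions)."""
    S = stoichiometric_matrix(model)
    with open(path, "w") as fh:
        fh.write("metabolite\t" + "\t".join(r.id for r in model.reactions) + "\n")
        for i, m in enumerate(model.metabolites):
            fh.write(m.id + "\t" + "\t".join(f"{v:g}" for v in S[i]) + "\n")
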