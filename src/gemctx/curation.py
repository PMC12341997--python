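"""Model curation: dead-end detection, gap filling against a universal
reaction database, leak/siphon detection, minimal leakage modes, and
element-matrix reaction balancing.

Leaks are metabolites still producible with every exchange closed
(created "from nothing"); siphons are consumable into nothing.  Either is
a certificate of broken mass conservation.  Detection runs one LP per
metabolite; minimal leakage modes and gap filling are small MILPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._opt import MilpProblem, solve_lp
from .errors import InfeasibleError, ValidationError
from .model import (
    ElementMatrix,
    MetabolicModel,
    Reaction,
    check_mass_balance,
    stoichiometric_matrix,
)

_BIG_M = 1000.0


@dataclass
class CurationReport:
    dead_ends: dict[str, set[str]] = field(default_factory=dict)  # met -> tags
    added_reactions: dict[str, float] = field(default_factory=dict)  # rxn -> weight
    unfillable: set[str] = field(default_factory=set)
    leaks: set[str] = field(default_factory=set)
    siphons: set[str] = field(default_factory=set)
    balanced_pairs: list[dict] = field(default_factory=list)


def find_dead_end_metabolites(model: MetabolicModel) -> dict[str, set[str]]:
    """Metabolites that cannot be produced, consumed, or either, given the
    current bounds; returns met-id -> subset of {no-production, no-consumption}.

    A reaction produces m when it has coeff > 0 and can run forward
    (ub > 0), or coeff < 0 and can run backward (lb < 0); consumption is
    symmetric.  Exchanges count like any other reaction.
    """
    producible: set[str] = set()
    consumable: set[str] = set()
    for rxn in model.reactions:
        fwd = rxn.upper_bound > 0
        bwd = rxn.lower_bound < 0
        for mid, coef in rxn.stoichiometry.items():
            if (coef > 0 and fwd) or (coef < 0 and bwd):
                producible.add(mid)
            if (coef < 0 and fwd) or (coef > 0 and bwd):
                consumable.add(mid)
    out: dict[str, set[str]] = {}
    for m in model.metabolites:
        tags = set()
        if m.id not in producible:
            tags.add("no-production")
        if m.id not in consumable:
            tags.add("no-consumption")
        if tags:
            out[m.id] = tags
    return out


def _reaction_kind(rxn: Reaction, model: MetabolicModel) -> str:
    if rxn.is_exchange:
        return "exchange"
    comp = {model.get_metabolite(m).compartment for m in rxn.stoichiometry}
    return "transport" if len(comp) > 1 else "metabolic"


DEFAULT_GAP_WEIGHTS = {"metabolic": 1.0, "transport": 10.0, "exchange": 100.0}


def gap_fill(
    model: MetabolicModel,
    universal_db: MetabolicModel,
    weights: dict[str, float] | None = None,
    epsilon: float = 1.0,
) -> CurationReport:
    """Choose a minimum-weight set of database reactions whose addition
    lets every currently dead-end metabolite carry steady-state flux.

    One joint MILP: per dead-end metabolite a separate flux scenario over
    the extended network (split into forward/backward parts with direction
    binaries so a reversible reaction cannot fake turnover by running both
    ways at once); database reactions are gated by shared binary
    use-indicators whose weighted sum is minimised.  Metabolites whose gap
    no candidate can fill are reported as unfillable, not fatal.
    """
    weights = dict(DEFAULT_GAP_WEIGHTS, **(weights or {}))
    dead = find_dead_end_metabolites(model)
    report = CurationReport(dead_ends=dead)
    if not dead:
        return report

    existing = {r.id for r in model.reactions}
    db_rxns = [r for r in universal_db.reactions if r.id not in existing]
    model_met_ids = {m.id for m in model.metabolites}
    for r in db_rxns:
        unknown = set(r.stoichiometry) - model_met_ids - {m.id for m in universal_db.metabolites}
        if unknown:
            raise ValidationError(f"database reaction {r.id!r} uses unknown metabolites {unknown}")

    all_rxns = list(model.reactions) + db_rxns
    all_mets = list(model_met_ids) + [
        m.id for m in universal_db.metabolites if m.id not in model_met_ids
    ]
    met_pos = {m: i for i, m in enumerate(all_mets)}

    def fillable(targets: list[str], minimize: bool) -> tuple[bool, dict[str, float]]:
        prob = MilpProblem()
        use = {
            r.id: prob.add_var(
                cost=weights.get(_reaction_kind(r, universal_db), 1.0) if minimize else 0.0,
                lb=0, ub=1, integer=True,
            )
            for r in db_rxns
        }
        for target in targets:
            f = {}
            b = {}
            for r in all_rxns:
                f[r.id] = prob.add_var(lb=0.0, ub=max(r.upper_bound, 0.0))
                b[r.id] = prob.add_var(lb=0.0, ub=max(-r.lower_bound, 0.0))
                if r.lower_bound < 0 < r.upper_bound:
                    d = prob.add_var(lb=0, ub=1, integer=True)
                    prob.add_constraint({f[r.id]: 1.0, d: -r.upper_bound}, hi=0.0)
                    prob.add_constraint({b[r.id]: 1.0, d: -r.lower_bound}, hi=-r.lower_bound)
            for r in db_rxns:
                prob.add_constraint({f[r.id]: 1.0, use[r.id]: -_BIG_M}, hi=0.0)
                prob.add_constraint({b[r.id]: 1.0, use[r.id]: -_BIG_M}, hi=0.0)
            # steady state per metabolite of the extended network
            rows: dict[int, dict[int, float]] = {}
            for r in all_rxns:
                for mid, coef in r.stoichiometry.items():
                    row = rows.setdefault(met_pos[mid], {})
                    row[f[r.id]] = row.get(f[r.id], 0.0) + coef
                    row[b[r.id]] = row.get(b[r.id], 0.0) - coef
            for row in rows.values():
                prob.add_constraint(row, 0.0, 0.0)
            # genuine turnover of the target: production >= epsilon
            prod: dict[int, float] = {}
            for r in all_rxns:
                coef = r.stoichiometry.get(target)
                if coef is None:
                    continue
                if coef > 0:
                    prod[f[r.id]] = prod.get(f[r.id], 0.0) + coef
                else:
                    prod[b[r.id]] = prod.get(b[r.id], 0.0) - coef
            if not prod:
                return False, {}
            prob.add_constraint(prod, lo=epsilon)
        try:
            res = prob.solve(sense="min")
        except InfeasibleError:
            return False, {}
        chosen = {
            r.id: weights.get(_reaction_kind(r, universal_db), 1.0)
            for r in db_rxns
            if res.x[use[r.id]] > 0.5
        }
        return True, chosen

    fillable_targets = []
    for mid in sorted(dead):
        ok, _ = fillable([mid], minimize=False)
        if ok:
            fillable_targets.append(mid)
        else:
            report.unfillable.add(mid)
    if fillable_targets:
        ok, chosen = fillable(fillable_targets, minimize=True)
        assert ok, "jointly infeasible despite individually fillable targets"
        report.added_reactions = chosen
    return report


def apply_gap_fill(
    model: MetabolicModel, universal_db: MetabolicModel, report: CurationReport
) -> MetabolicModel:
    """Materialise a gap-fill report: model + chosen database reactions."""
    out = model.copy()
    have_mets = {m.id for m in out.metabolites}
    for rid in sorted(report.added_reactions):
        rxn = universal_db.get_reaction(rid).copy()
        for mid in rxn.stoichiometry:
            if mid not in have_mets:
                out.metabolites.append(universal_db.get_metabolite(mid))
                have_mets.add(mid)
        out.reactions.append(rxn)
    out.validate()
    return out


def _closed_exchange_bounds(model: MetabolicModel) -> list[tuple[float, float]]:
    return [
        (0.0, 0.0) if r.is_exchange else (r.lower_bound, r.upper_bound)
        for r in model.reactions
    ]


def find_leaks_siphons(
    model: MetabolicModel, tolerance: float = 1e-6
) -> tuple[set[str], set[str]]:
    """Leak/siphon scan with all exchanges closed to [0, 0].

    For each metabolite, one LP maximises the flux of a temporary drain
    (leak test) or source (siphon test); positive optimum beyond
    ``tolerance`` flags the metabolite.
    """
    S = stoichiometric_matrix(model)
    bounds = _closed_exchange_bounds(model)
    n = S.shape[1]
    leaks: set[str] = set()
    siphons: set[str] = set()
    c = np.zeros(n + 1)
    c[-1] = 1.0
    for i, met in enumerate(model.metabolites):
        for sign, bucket in ((-1.0, leaks), (1.0, siphons)):
            col = np.zeros((S.shape[0], 1))
            col[i, 0] = sign  # drain: S v - d e_i = 0 ; source: S v + d e_i = 0
            A = np.hstack([S, col])
            res = solve_lp(
                c,
                A_eq=A,
                b_eq=np.zeros(S.shape[0]),
                bounds=bounds + [(0.0, _BIG_M)],
                sense="max",
                allow_nonoptimal=True,
            )
            if res.status == "optimal" and res.objective > tolerance:
                bucket.add(met.id)
    return leaks, siphons


def minimal_leakage_mode(
    model: MetabolicModel,
    metabolite: str,
    kind: str | None = None,
    min_rate: float = 0.1,
    tolerance: float = 1e-6,
) -> set[str]:
    """Minimum-cardinality reaction set sustaining a leak (or siphon) of
    ``metabolite`` with exchanges closed.

    MILP: binary support indicators b_r with |v_r| <= M b_r, the temporary
    drain/source forced to at least ``min_rate``, minimising sum b_r.
    Raises if the metabolite does not actually leak/siphon.
    """
    leaks, siphons = find_leaks_siphons(model, tolerance)
    if kind is None:
        kind = "leak" if metabolite in leaks else ("siphon" if metabolite in siphons else None)
    if kind == "leak" and metabolite not in leaks:
        raise ValidationError(f"{metabolite!r} is not a leak")
    if kind == "siphon" and metabolite not in siphons:
        raise ValidationError(f"{metabolite!r} is not a siphon")
    if kind is None:
        raise ValidationError(f"{metabolite!r} is neither a leak nor a siphon")

    sign = -1.0 if kind == "leak" else 1.0
    midx = model.metabolite_index()[metabolite]
    S = stoichiometric_matrix(model)
    bounds = _closed_exchange_bounds(model)
    prob = MilpProblem()
    v_idx = [prob.add_var(lb=lo, ub=hi) for lo, hi in bounds]
    d = prob.add_var(lb=min_rate, ub=_BIG_M)
    for i in range(S.shape[0]):
        coeffs = {v_idx[j]: S[i, j] for j in range(S.shape[1]) if S[i, j] != 0.0}
        if i == midx:
            coeffs[d] = sign
        if coeffs:
            prob.add_constraint(coeffs, 0.0, 0.0)
    b_idx = []
    for j, (lo, hi) in enumerate(bounds):
        b = prob.add_var(cost=1.0, lb=0, ub=1, integer=True)
        b_idx.append(b)
        prob.add_constraint({v_idx[j]: 1.0, b: -max(hi, 0.0)}, hi=0.0)
        prob.add_constraint({v_idx[j]: 1.0, b: -min(lo, 0.0)}, lo=0.0)
    res = prob.solve(sense="min")
    return {
        model.reactions[j].id
        for j in range(len(bounds))
        if res.x[b_idx[j]] > 0.5 and abs(res.x[v_idx[j]]) > tolerance
    }


@dataclass
class BalanceResult:
    adjusted: dict[str, dict[str, float]]  # rxn id -> new stoichiometry
    added: dict[str, dict[str, float]]  # rxn id -> candidate -> coefficient
    balanced: dict[str, bool]


def _balance_one(
    residual: dict[str, float],
    element_matrix: ElementMatrix,
    candidates: list[str],
    max_coeff: int,
) -> dict[str, float] | None:
    """Integer coefficients x over candidates with E x = -residual, found
    by MILP minimising sum |x|; None when no combination balances."""
    if not residual:
        return {}
    E = np.array(
        [[element_matrix.column(c)[element_matrix.elements.index(e)] for c in candidates]
         for e in element_matrix.elements],
        dtype=float,
    )
    r = np.array([residual.get(e, 0.0) for e in element_matrix.elements])
    prob = MilpProblem()
    pos = [prob.add_var(cost=1.0, lb=0, ub=max_coeff, integer=True) for _ in candidates]
    neg = [prob.add_var(cost=1.0, lb=0, ub=max_coeff, integer=True) for _ in candidates]
    for i in range(E.shape[0]):
        coeffs: dict[int, float] = {}
        for j in range(len(candidates)):
            if E[i, j] != 0.0:
                coeffs[pos[j]] = E[i, j]
                coeffs[neg[j]] = -E[i, j]
        prob.add_constraint(coeffs, -r[i], -r[i])
    try:
        res = prob.solve(sense="min")
    except InfeasibleError:
        return None
    out = {}
    for j, c in enumerate(candidates):
        x = round(res.x[pos[j]]) - round(res.x[neg[j]])
        if x != 0:
            out[c] = float(x)
    return out


DEFAULT_BALANCE_CANDIDATES = ("h", "h2o", "e")  # proton, water, electron


def balance_reaction_pair(
    model: MetabolicModel,
    rxn_a: Reaction | str,
    rxn_b: Reaction | str,
    element_matrix: ElementMatrix,
    candidates: list[str] | None = None,
    max_coeff: int = 10,
) -> BalanceResult:
    """Add candidate species (protons/water/... by default, when present in
    the model) to each reaction of a sharing pair so both element residuals
    vanish.

    The pair must share at least one metabolite with opposite roles.  Each
    reaction is balanced independently by an exact integer solve of
    E_candidates x = -residual; reactions no candidate combination can fix
    are reported with ``balanced = False`` rather than raising.
    """
    if isinstance(rxn_a, str):
        rxn_a = model.get_reaction(rxn_a)
    if isinstance(rxn_b, str):
        rxn_b = model.get_reaction(rxn_b)
    shared_opposite = any(
        mid in rxn_b.stoichiometry
        and rxn_a.stoichiometry[mid] * rxn_b.stoichiometry[mid] < 0
        for mid in rxn_a.stoichiometry
    )
    if not shared_opposite:
        raise ValidationError(
            f"reactions {rxn_a.id!r} and {rxn_b.id!r} share no metabolite "
            "with opposite roles"
        )
    if candidates is None:
        known = set(element_matrix.metabolite_ids) - element_matrix.unknown
        candidates = [c for c in DEFAULT_BALANCE_CANDIDATES if c in known]
    if not candidates:
        raise ValidationError("no usable balancing candidates")
    for c in candidates:
        if c in element_matrix.unknown:
            raise ValidationError(f"candidate {c!r} has unknown composition")

    result = BalanceResult(adjusted={}, added={}, balanced={})
    for rxn in (rxn_a, rxn_b):
        residual = check_mass_balance(model, rxn)
        fix = _balance_one(residual, element_matrix, list(candidates), max_coeff)
        stoich = dict(rxn.stoichiometry)
        if fix is None:
            result.balanced[rxn.id] = False
            result.adjusted[rxn.id] = stoich
            result.added[rxn.id] = {}
            continue
        for mid, coef in fix.items():
            stoich[mid] = stoich.get(mid, 0.0) + coef
            if stoich[mid] == 0.0:
                del stoich[mid]
        result.balanced[rxn.id] = True
        result.adjusted[rxn.id] = stoich
        result.added[rxn.id] = fix
    return result
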