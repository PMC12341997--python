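"""Reaction classification, the iMAT MILP, context-model extraction, and
activity-derived flux bounds.

The iMAT program maximises the number of satisfied indicators: a HIGH
reaction scores when it carries at least epsilon flux in either direction,
a LOW reaction when its flux is forced to zero.  Reactions the data does
not cover count as MODERATE inside the program (neither rewarded nor
penalised).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from ._opt import MilpProblem
from .errors import SolverError, ValidationError
from .integration import ActivityVector
from .model import MetabolicModel, stoichiometric_matrix


class ReactionState(str, Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    UNCOVERED = "UNCOVERED"


@dataclass
class ReactionClassification:
    states: dict[str, ReactionState]

    def of(self, rid: str) -> ReactionState:
        return self.states[rid]

    def by_state(self, state: ReactionState) -> list[str]:
        return [r for r, s in self.states.items() if s == state]


@dataclass
class IMATSolution:
    fluxes: dict[str, float]
    indicators: dict[str, bool]  # per HIGH/LOW reaction: indicator satisfied?
    objective_value: int
    status: str


def classify_reactions(
    av: ActivityVector,
    model: MetabolicModel,
    low_threshold: float = -500.0,
    high_threshold: float = 500.0,
) -> ReactionClassification:
    """score > high -> HIGH, score < low -> LOW, otherwise MODERATE
    (strict inequalities: boundary scores are MODERATE); reactions absent
    from the activity vector's coverage are UNCOVERED."""
    if low_threshold >= high_threshold:
        raise ValidationError("low_threshold must be < high_threshold")
    states: dict[str, ReactionState] = {}
    for rxn in model.reactions:
        if rxn.id not in av.scores:
            states[rxn.id] = ReactionState.UNCOVERED
            continue
        s = av.scores[rxn.id]
        if s > high_threshold:
            states[rxn.id] = ReactionState.HIGH
        elif s < low_threshold:
            states[rxn.id] = ReactionState.LOW
        else:
            states[rxn.id] = ReactionState.MODERATE
    return ReactionClassification(states=states)


def imat(
    model: MetabolicModel,
    classification: ReactionClassification,
    epsilon: float = 1.0,
    integer_tolerance: float = 1e-6,
) -> IMATSolution:
    """Solve the iMAT MILP.

    maximise  sum_{i in HIGH} (y+_i + y-_i) + sum_{i in LOW} z_i
    s.t.      S v = 0,  lb <= v <= ub,
              y+_i = 1  =>  v_i >= epsilon
              y-_i = 1  =>  v_i <= -epsilon   (reversible HIGH only)
              z_i  = 1  =>  v_i  = 0

    Ties among optima are broken by re-solving with the binaries fixed
    and minimising sum |v|, so extraction is reproducible.
    """
    model.validate()
    S = stoichiometric_matrix(model)
    n = len(model.reactions)
    prob = MilpProblem()
    v_idx = [
        prob.add_var(lb=r.lower_bound, ub=r.upper_bound) for r in model.reactions
    ]
    for i in range(S.shape[0]):
        coeffs = {v_idx[j]: S[i, j] for j in range(n) if S[i, j] != 0.0}
        prob.add_constraint(coeffs, 0.0, 0.0)

    high = [j for j, r in enumerate(model.reactions)
            if classification.of(r.id) == ReactionState.HIGH]
    low = [j for j, r in enumerate(model.reactions)
           if classification.of(r.id) == ReactionState.LOW]

    yp: dict[int, int] = {}
    ym: dict[int, int] = {}
    z: dict[int, int] = {}
    for j in high:
        r = model.reactions[j]
        yj = prob.add_var(cost=1.0, lb=0, ub=1, integer=True)
        yp[j] = yj
        # v_j + y+_j (lb_j - eps) >= lb_j  -> y=1 forces v_j >= eps
        prob.add_constraint({v_idx[j]: 1.0, yj: r.lower_bound - epsilon}, lo=r.lower_bound)
        if r.lower_bound < 0:
            yj2 = prob.add_var(cost=1.0, lb=0, ub=1, integer=True)
            ym[j] = yj2
            # v_j + y-_j (ub_j + eps) <= ub_j  -> y=1 forces v_j <= -eps
            prob.add_constraint({v_idx[j]: 1.0, yj2: r.upper_bound + epsilon}, hi=r.upper_bound)
            prob.add_constraint({yj: 1.0, yj2: 1.0}, hi=1.0)
    for j in low:
        r = model.reactions[j]
        zj = prob.add_var(cost=1.0, lb=0, ub=1, integer=True)
        z[j] = zj
        # z=1 forces lb(1-z) <= v <= ub(1-z), i.e. v = 0
        prob.add_constraint({v_idx[j]: 1.0, zj: r.lower_bound}, lo=r.lower_bound)
        prob.add_constraint({v_idx[j]: 1.0, zj: r.upper_bound}, hi=r.upper_bound)

    res = prob.solve(sense="max")
    objective = int(round(res.objective))

    # secondary pass: binaries pinned, minimise sum |v| for determinism
    for idxs in (yp, ym, z):
        for bidx in idxs.values():
            val = float(round(res.x[bidx]))
            prob.lb[bidx] = val
            prob.ub[bidx] = val
    t_idx = []
    for j in range(n):
        t = prob.add_var(cost=0.0, lb=0.0)
        t_idx.append(t)
        prob.add_constraint({t: 1.0, v_idx[j]: -1.0}, lo=0.0)
        prob.add_constraint({t: 1.0, v_idx[j]: 1.0}, lo=0.0)
    prob.c = [0.0] * len(prob.c)
    for t in t_idx:
        prob.c[t] = 1.0
    res2 = prob.solve(sense="min")
    x = res2.x

    fluxes = {r.id: float(x[v_idx[j]]) for j, r in enumerate(model.reactions)}
    indicators: dict[str, bool] = {}
    for j in high:
        rid = model.reactions[j].id
        on = x[yp[j]] > 1 - integer_tolerance
        if j in ym:
            on = on or x[ym[j]] > 1 - integer_tolerance
        indicators[rid] = bool(on)
    for j in low:
        indicators[model.reactions[j].id] = bool(x[z[j]] > 1 - integer_tolerance)

    resid = S @ np.array([x[i] for i in v_idx])
    if np.abs(resid).max(initial=0.0) > 1e-6:
        raise SolverError("iMAT solution violates steady state beyond tolerance")
    return IMATSolution(
        fluxes=fluxes,
        indicators=indicators,
        objective_value=objective,
        status="optimal",
    )


def extract_context_model(
    model: MetabolicModel,
    solution: IMATSolution,
    classification: ReactionClassification | None = None,
    flux_tolerance: float = 1e-6,
) -> MetabolicModel:
    """Keep reactions carrying flux in the iMAT solution, plus every
    exchange and the objective reaction; drop orphaned metabolites."""
    keep: set[str] = set()
    for rxn in model.reactions:
        if rxn.is_exchange or rxn.id == model.objective_id:
            keep.add(rxn.id)
        elif abs(solution.fluxes.get(rxn.id, 0.0)) > flux_tolerance:
            keep.add(rxn.id)
    if model.objective_id and model.objective_id not in keep:  # pragma: no cover
        raise ValidationError("objective reaction was pruned")
    reactions = [r.copy() for r in model.reactions if r.id in keep]
    used_mets = {m for r in reactions for m in r.stoichiometry}
    metabolites = [m for m in model.metabolites if m.id in used_mets]
    sub = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_id=model.objective_id,
        objective_sense=model.objective_sense,
        id=model.id + "_context",
    )
    sub.validate()
    return sub


def activity_to_bounds(
    model: MetabolicModel, av: ActivityVector, v_max: float = 1000.0
) -> MetabolicModel:
    """exp2flux-style bounds: scale each covered reaction's capacity by its
    min-max-normalised activity score; uncovered reactions are untouched."""
    covered = [r for r in model.reactions if r.id in av.scores]
    if not covered:
        raise ValidationError("activity vector covers no model reaction")
    vals = np.array([av.scores[r.id] for r in covered])
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < 1e-12:
        raise ValidationError("constant activity vector cannot set bounds")
    out = model.copy()
    for rxn in out.reactions:
        if rxn.id not in av.scores:
            continue
        cap = v_max * (av.scores[rxn.id] - lo) / (hi - lo)
        was_reversible = rxn.lower_bound < 0
        rxn.upper_bound = cap
        rxn.lower_bound = -cap if was_reversible else 0.0
    return out
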