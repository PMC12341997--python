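"""Medium application, FBA / loopless FBA, FVA at a fixed objective, the
four metabolic scenarios, and the prediction-accuracy statistic.

Concentrations in mM convert to exchange fluxes via flux = C * V / (X * t)
with culture volume V (L), biomass X (gDW), and duration t (h).  Uptake is
a negative exchange flux, so a medium component sets the exchange lower
bound to minus its converted flux.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from ._opt import MilpProblem, solve_lp
from .errors import InfeasibleError, ScenarioError, ValidationError
from .model import MetabolicModel, stoichiometric_matrix


@dataclass
class Medium:
    """mM concentrations plus the culture parameters of the conversion."""

    concentrations: dict[str, float]
    volume_L: float = 1.0
    biomass_gDW: float = 1.0
    duration_h: float = 1.0

    def __post_init__(self):
        bad = {m: c for m, c in self.concentrations.items() if c < 0}
        if bad:
            raise ValidationError(f"negative medium concentrations: {bad}")
        if min(self.volume_L, self.biomass_gDW, self.duration_h) <= 0:
            raise ValidationError("volume, biomass, and duration must be positive")


#: Scenario constants: palmitate challenge 0.208 mM/g, tibolone 70 uM/g
#: (0.07 mM/g), ischemia ramp from 2.5 down to 0 mmol gDW^-1 h^-1.
PA_UPTAKE = 0.208
TB_UPTAKE = 70e-3
ISCHEMIA_START = 2.5
ISCHEMIA_END = 0.0
ISCHEMIA_STEPS = 11

SCENARIO_NAMES = ("basal", "ischemia", "PA", "Tb_PA")


@dataclass
class Scenario:
    name: str
    exchange_overrides: dict[str, float] = field(default_factory=dict)
    ramp_start: float = ISCHEMIA_START
    ramp_end: float = ISCHEMIA_END
    ramp_steps: int = ISCHEMIA_STEPS

    def __post_init__(self):
        if self.name not in SCENARIO_NAMES:
            raise ValidationError(f"unknown scenario {self.name!r}; expected one of {SCENARIO_NAMES}")

    @classmethod
    def basal(cls) -> "Scenario":
        return cls("basal")

    @classmethod
    def ischemia(cls, steps: int = ISCHEMIA_STEPS) -> "Scenario":
        return cls("ischemia", ramp_steps=steps)

    @classmethod
    def pa(cls) -> "Scenario":
        return cls("PA")

    @classmethod
    def tb_pa(cls) -> "Scenario":
        return cls("Tb_PA")


@dataclass
class FluxResult:
    fluxes: dict[str, float]
    objective_value: float
    status: str
    loopless: bool = False


@dataclass
class FVAResult:
    ranges: dict[str, tuple[float, float]]
    fixed_objective_value: float


def concentration_to_flux(
    concentration_mM: float,
    volume_L: float = 1.0,
    biomass_gDW: float = 1.0,
    duration_h: float = 1.0,
) -> float:
    """flux (mmol gDW^-1 h^-1) = concentration * volume / (biomass * duration)."""
    if concentration_mM < 0:
        raise ValidationError("concentration must be >= 0")
    if biomass_gDW <= 0 or duration_h <= 0 or volume_L <= 0:
        raise ValidationError("volume, biomass, and duration must be positive")
    return concentration_mM * volume_L / (biomass_gDW * duration_h)


def _exchange_by_metabolite(model: MetabolicModel) -> dict[str, str]:
    out = {}
    for r in model.exchanges():
        if len(r.stoichiometry) == 1:
            (mid,) = r.stoichiometry
            out[mid] = r.id
    return out


def resolve_exchange(model: MetabolicModel, species: str) -> str:
    """Find the exchange reaction for a species given as an exchange id, a
    metabolite id, or a metabolite id without its compartment suffix."""
    rids = {r.id for r in model.exchanges()}
    if species in rids:
        return species
    ex = _exchange_by_metabolite(model)
    if species in ex:
        return ex[species]
    matches = [rid for mid, rid in ex.items() if mid.rsplit("_", 1)[0] == species]
    if len(matches) == 1:
        return matches[0]
    raise ScenarioError(f"no exchange reaction found for species {species!r}")


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Open uptake for medium components, close it for everything else.

    Each medium metabolite's exchange lower bound becomes minus its
    converted flux; exchanges of absent metabolites get lower bound 0.
    Secretion (upper) bounds are untouched.  Medium metabolites with no
    exchange in the model produce a warning, not an error.
    """
    out = model.copy()
    ex = _exchange_by_metabolite(out)
    by_base: dict[str, list[str]] = {}
    for mid in ex:
        by_base.setdefault(mid.rsplit("_", 1)[0], []).append(mid)
    resolved: dict[str, float] = {}
    unmatched = []
    for species, conc in medium.concentrations.items():
        mid = None
        if species in ex:
            mid = species
        elif species in by_base and len(by_base[species]) == 1:
            mid = by_base[species][0]
        if mid is None:
            unmatched.append(species)
            continue
        resolved[ex[mid]] = concentration_to_flux(
            conc, medium.volume_L, medium.biomass_gDW, medium.duration_h
        )
    if unmatched:
        warnings.warn(f"medium metabolites without exchange: {unmatched}", stacklevel=2)
    for rxn in out.reactions:
        if not rxn.is_exchange:
            continue
        if rxn.id in resolved:
            rxn.lower_bound = -resolved[rxn.id]
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return out


def fba(model: MetabolicModel, loopless: bool = False, big_m: float = 1000.0) -> FluxResult:
    """Maximise the model objective at steady state.

    With ``loopless`` the standard loop-law MILP is used: each internal
    reaction gets a direction binary and a potential-like variable G_i of
    the opposite sign, with G constrained to the row space orthogonal to
    internal cycles (null-space basis of the internal stoichiometry), so
    no thermodynamically infeasible circulation can carry flux.
    """
    model.validate()
    if not model.objective_id:
        raise ValidationError("model has no objective reaction")
    S = stoichiometric_matrix(model)
    n = len(model.reactions)
    obj_j = model.reaction_index()[model.objective_id]
    sense = model.objective_sense

    if not loopless:
        c = np.zeros(n)
        c[obj_j] = 1.0
        bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
        res = solve_lp(
            c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
            sense=sense, allow_nonoptimal=True,
        )
        if res.status != "optimal":
            return FluxResult(fluxes={}, objective_value=math.nan, status=res.status)
        return FluxResult(
            fluxes={r.id: float(res.x[j]) for j, r in enumerate(model.reactions)},
            objective_value=float(res.objective),
            status="optimal",
        )

    internal = [j for j, r in enumerate(model.reactions) if not r.is_exchange]
    prob = MilpProblem()
    v_idx = [prob.add_var(lb=r.lower_bound, ub=r.upper_bound) for r in model.reactions]
    prob.c[v_idx[obj_j]] = 1.0
    for i in range(S.shape[0]):
        coeffs = {v_idx[j]: S[i, j] for j in range(n) if S[i, j] != 0.0}
        prob.add_constraint(coeffs, 0.0, 0.0)
    if internal:
        N = null_space(S[:, internal])
        a_idx, g_idx = {}, {}
        for j in internal:
            a = prob.add_var(lb=0, ub=1, integer=True)
            g = prob.add_var(lb=-big_m, ub=big_m)
            a_idx[j], g_idx[j] = a, g
            # a=1 -> v_j in [0, M], G_j in [-M, -1]; a=0 -> mirrored
            prob.add_constraint({v_idx[j]: 1.0, a: -big_m}, hi=0.0)
            prob.add_constraint({v_idx[j]: 1.0, a: -big_m}, lo=-big_m)
            prob.add_constraint({g_idx[j]: 1.0, a: big_m + 1.0}, hi=big_m)
            prob.add_constraint({g_idx[j]: 1.0, a: big_m + 1.0}, lo=1.0)
        # G orthogonal to every internal cycle
        for k in range(N.shape[1]):
            coeffs = {
                g_idx[j]: N[t, k]
                for t, j in enumerate(internal)
                if abs(N[t, k]) > 1e-12
            }
            if coeffs:
                prob.add_constraint(coeffs, 0.0, 0.0)
    try:
        res = prob.solve(sense=sense)
    except InfeasibleError:
        return FluxResult(fluxes={}, objective_value=math.nan, status="infeasible", loopless=True)
    return FluxResult(
        fluxes={r.id: float(res.x[v_idx[j]]) for j, r in enumerate(model.reactions)},
        objective_value=float(res.objective),
        status=res.status,
        loopless=True,
    )


def fva(
    model: MetabolicModel,
    fixed_objective_value: float,
    fraction: bool = False,
    reactions: list[str] | None = None,
) -> FVAResult:
    """Per-reaction (min, max) flux with the objective pinned.

    ``fraction`` interprets ``fixed_objective_value`` as a fraction of the
    FBA optimum instead of an absolute value.  Raises when the pinned
    value is infeasible.
    """
    model.validate()
    S = stoichiometric_matrix(model)
    n = len(model.reactions)
    obj_j = model.reaction_index()[model.objective_id]
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    if fraction:
        base = fba(model)
        if base.status != "optimal":
            raise InfeasibleError("cannot compute FBA optimum for fractional FVA")
        fixed = fixed_objective_value * base.objective_value
    else:
        fixed = fixed_objective_value
    row = np.zeros((1, n))
    row[0, obj_j] = 1.0
    A_eq = np.vstack([S, row])
    b_eq = np.concatenate([np.zeros(S.shape[0]), [fixed]])
    # feasibility probe before the per-reaction sweeps
    solve_lp(np.zeros(n), A_eq=A_eq, b_eq=b_eq, bounds=bounds, sense="min")
    targets = reactions if reactions is not None else [r.id for r in model.reactions]
    ridx = model.reaction_index()
    ranges: dict[str, tuple[float, float]] = {}
    for rid in targets:
        j = ridx[rid]
        c = np.zeros(n)
        c[j] = 1.0
        lo = solve_lp(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, sense="min").objective
        hi = solve_lp(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, sense="max").objective
        ranges[rid] = (float(lo), float(hi))
    return FVAResult(ranges=ranges, fixed_objective_value=float(fixed))


#: Default species aliases used by the named scenarios; override per model.
DEFAULT_SPECIES_ALIASES = {
    "glucose": "glc",
    "oxygen": "o2",
    "palmitate": "pal",
    "tibolone": "tib",
}


def run_scenario(
    model: MetabolicModel,
    scenario: Scenario,
    medium: Medium,
    species_aliases: dict[str, str] | None = None,
    loopless: bool = False,
) -> list[FluxResult]:
    """Apply the medium, impose the scenario's uptake overrides, and run
    FBA — once per ramp step for ischemia, once otherwise."""
    aliases = dict(DEFAULT_SPECIES_ALIASES, **(species_aliases or {}))
    base = apply_medium(model, medium)

    def uptake(m: MetabolicModel, species_key: str, rate: float) -> None:
        try:
            rid = resolve_exchange(m, aliases[species_key])
        except ScenarioError:
            raise ScenarioError(
                f"scenario {scenario.name!r} needs an exchange for "
                f"{species_key!r} (alias {aliases[species_key]!r})"
            ) from None
        m.get_reaction(rid).lower_bound = -rate

    for rid, val in scenario.exchange_overrides.items():
        base.get_reaction(resolve_exchange(base, rid)).lower_bound = val

    if scenario.name == "basal":
        return [fba(base, loopless=loopless)]
    if scenario.name == "ischemia":
        results = []
        for rate in np.linspace(scenario.ramp_start, scenario.ramp_end, scenario.ramp_steps):
            step = base.copy()
            uptake(step, "glucose", float(rate))
            uptake(step, "oxygen", float(rate))
            results.append(fba(step, loopless=loopless))
        return results
    if scenario.name == "PA":
        uptake(base, "palmitate", PA_UPTAKE)
        return [fba(base, loopless=loopless)]
    if scenario.name == "Tb_PA":
        uptake(base, "palmitate", PA_UPTAKE)
        uptake(base, "tibolone", TB_UPTAKE)
        return [fba(base, loopless=loopless)]
    raise ValidationError(f"unhandled scenario {scenario.name!r}")  # pragma: no cover


def _round_half_up(x: float, ndigits: int) -> float:
    factor = 10.0 ** ndigits
    return math.floor(x * factor + 0.5) / factor


def prediction_accuracy(predicted_flux: float, experimental_flux: float) -> float:
    """Percentage agreement: (1 - |predicted - experimental| / experimental) * 100,
    reported to two decimals."""
    if experimental_flux == 0:
        raise ValidationError("experimental flux must be nonzero")
    acc = (1.0 - abs(predicted_flux - experimental_flux) / experimental_flux) * 100.0
    return _round_half_up(acc, 2)


def flux_fraction_percent(part_flux: float, total_flux: float, ndigits: int = 1) -> float:
    """100 * part / total, rounded half-up — e.g. the share of glucose
    uptake leaving as lactate."""
    if total_flux == 0:
        raise ValidationError("total flux must be nonzero")
    return _round_half_up(100.0 * part_flux / total_flux, ndigits)
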