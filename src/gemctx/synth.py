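"""Synthetic fixtures: toy metabolic models with GPRs and paired
transcript/protein tables with a planted ground truth.

Everything is deterministic given the spec's seed, so test expectations
can be frozen.  Toy metabolites carry a single-element pseudo-formula
("C") which keeps every 1:1 conversion elementally balanced by
construction; the astrocyte-mini model uses real formulas for the
metabolites whose flux ratios are biologically meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .model import MetabolicModel, Metabolite, Reaction, parse_gpr
from .preprocess import OmicsTable

TOPOLOGIES = ("chain", "diamond", "cycle-trap", "random")
GROUPS = ("basal", "PA", "TbPA")


@dataclass
class FixtureSpec:
    topology: str = "random"
    n_reactions: int = 12
    gpr_fraction: float = 1.0
    capacities: list[float] | None = None
    noise_sd: float = 0.5
    rho: float = 0.6  # transcript-protein correlation on the log scale
    replicates: int = 6
    # 2% keeps the 70%-per-group protein validity filter from voiding
    # whole features at 6 replicates per group
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise ValidationError(f"unknown topology {self.topology!r}")
        if not (0 <= self.rho <= 1):
            raise ValidationError("rho must lie in [0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must lie in [0, 1)")


def _met(mid: str, compartment: str = "c") -> Metabolite:
    return Metabolite(id=mid, compartment=compartment, formula="C")


def _maybe_gpr(rng: np.random.Generator, fraction: float, counter: list[int]):
    if rng.random() >= fraction:
        return None
    counter[0] += 1
    g1 = f"g{counter[0]:04d}"
    style = rng.integers(0, 3)
    if style == 0:
        return parse_gpr(g1)
    counter[0] += 1
    g2 = f"g{counter[0]:04d}"
    op = "and" if style == 1 else "or"
    return parse_gpr(f"{g1} {op} {g2}")


def make_toy_model(spec: FixtureSpec) -> MetabolicModel:
    """Build a small valid model for the requested topology.

    chain/diamond have analytic FBA optima (bottleneck / sum of branch
    capacities); cycle-trap adds a free-running 3-reaction internal cycle
    for loopless tests; random plants an exchanged trunk chain (the active
    subnetwork) plus inactive side branches.  The planted reaction ids are
    stored on the model as ``planted_active``.
    """
    rng = np.random.default_rng(spec.seed)
    counter = [0]
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    planted: list[str] = []

    def add_exchange(mid: str, lb: float, ub: float = 1000.0) -> Reaction:
        r = Reaction(
            id=f"EX_{mid}", stoichiometry={mid: -1.0},
            lower_bound=lb, upper_bound=ub, is_exchange=True,
        )
        rxns.append(r)
        return r

    if spec.topology in ("chain", "cycle-trap"):
        caps = spec.capacities or [float(rng.integers(2, 10)) for _ in range(max(spec.n_reactions - 2, 2))]
        k = len(caps) + 1
        for i in range(k):
            mets.append(_met(f"X{i + 1}"))
        add_exchange("X1", -1000.0)
        for i, cap in enumerate(caps):
            r = Reaction(
                id=f"R{i + 1}",
                stoichiometry={f"X{i + 1}": -1.0, f"X{i + 2}": 1.0},
                lower_bound=0.0, upper_bound=cap,
                gpr=_maybe_gpr(rng, spec.gpr_fraction, counter),
            )
            rxns.append(r)
            planted.append(r.id)
        add_exchange(f"X{k}", 0.0)
        objective = f"R{len(caps)}"
        if spec.topology == "cycle-trap":
            for mid in ("P", "Q", "W"):
                mets.append(_met(mid))
            for rid, (a, b) in zip(
                ("CYC1", "CYC2", "CYC3"), (("P", "Q"), ("Q", "W"), ("W", "P"))
            ):
                rxns.append(
                    Reaction(
                        id=rid, stoichiometry={a: -1.0, b: 1.0},
                        lower_bound=-1000.0, upper_bound=1000.0,
                        gpr=_maybe_gpr(rng, spec.gpr_fraction, counter),
                    )
                )
    elif spec.topology == "diamond":
        caps = spec.capacities or [3.0, 7.0]
        for mid in ("A", "B", "C", "D"):
            mets.append(_met(mid))
        add_exchange("A", -1000.0)
        rxns.append(Reaction(id="R_AB", stoichiometry={"A": -1.0, "B": 1.0},
                             lower_bound=0.0, upper_bound=caps[0],
                             gpr=_maybe_gpr(rng, spec.gpr_fraction, counter)))
        rxns.append(Reaction(id="R_AC", stoichiometry={"A": -1.0, "C": 1.0},
                             lower_bound=0.0, upper_bound=caps[1],
                             gpr=_maybe_gpr(rng, spec.gpr_fraction, counter)))
        rxns.append(Reaction(id="R_BD", stoichiometry={"B": -1.0, "D": 1.0},
                             lower_bound=0.0, upper_bound=1000.0,
                             gpr=_maybe_gpr(rng, spec.gpr_fraction, counter)))
        rxns.append(Reaction(id="R_CD", stoichiometry={"C": -1.0, "D": 1.0},
                             lower_bound=0.0, upper_bound=1000.0,
                             gpr=_maybe_gpr(rng, spec.gpr_fraction, counter)))
        planted = ["R_AB", "R_AC", "R_BD", "R_CD"]
        add_exchange("D", 0.0)
        objective = "EX_D"
    else:  # random: exchanged trunk (planted) + inactive side branches
        # trunk is ~1/4 of the network so the active score cluster sits
        # entirely above the upper-quartile threshold anchor downstream
        n_trunk = max(spec.n_reactions // 4, 3)
        n_branch = max(spec.n_reactions - n_trunk, 1)
        for i in range(n_trunk + 1):
            mets.append(_met(f"T{i + 1}"))
        add_exchange("T1", -1000.0)
        for i in range(n_trunk):
            r = Reaction(
                id=f"TRK{i + 1}",
                stoichiometry={f"T{i + 1}": -1.0, f"T{i + 2}": 1.0},
                lower_bound=0.0, upper_bound=1000.0,
                gpr=_maybe_gpr(rng, spec.gpr_fraction, counter),
            )
            rxns.append(r)
            planted.append(r.id)
        add_exchange(f"T{n_trunk + 1}", 0.0)
        for b in range(n_branch):
            src = f"T{int(rng.integers(1, n_trunk + 1))}"
            side = f"S{b + 1}"
            mets.append(_met(side))
            rxns.append(
                Reaction(
                    id=f"BRN{b + 1}",
                    stoichiometry={src: -1.0, side: 1.0},
                    lower_bound=0.0, upper_bound=1000.0,
                    gpr=_maybe_gpr(rng, spec.gpr_fraction, counter),
                )
            )
            add_exchange(side, 0.0)
        objective = f"TRK{n_trunk}"

    model = MetabolicModel(metabolites=mets, reactions=rxns, objective_id=objective,
                           id=f"toy_{spec.topology}_{spec.seed}")
    model.validate()
    model.planted_active = planted  # type: ignore[attr-defined]
    return model


# ---------------------------------------------------------------------------
# Astrocyte-mini
# ---------------------------------------------------------------------------

def make_astrocyte_mini() -> MetabolicModel:
    """~40-reaction astrocyte cartoon: glycolysis to lactate, lumped
    oxidative metabolism, glutamate->glutamine, glutathione synthesis,
    palmitate beta-oxidation, a tibolone sink, and a maintenance-biomass
    objective.  Feasible with positive optimum under the DMEM-like medium
    from :func:`dmem_like_medium`."""
    M = Metabolite
    mets = [
        M("glc_e", "glucose", "e", "C6H12O6"), M("glc_c", "glucose", "c", "C6H12O6"),
        M("o2_e", "oxygen", "e", "O2"), M("o2_c", "oxygen", "c", "O2"),
        M("pyr_c", "pyruvate", "c", "C3H4O3"), M("pyr_m", "pyruvate", "m", "C3H4O3"),
        M("lac_c", "lactate", "c", "C3H6O3"), M("lac_e", "lactate", "e", "C3H6O3"),
        M("co2_c", "CO2", "c", "CO2"), M("co2_e", "CO2", "e", "CO2"),
        M("h2o_c", "water", "c", "H2O"), M("h2o_e", "water", "e", "H2O"),
        M("glu_e", "glutamate", "e", "C5H9NO4"), M("glu_c", "glutamate", "c", "C5H9NO4"),
        M("gln_c", "glutamine", "c", "C5H10N2O3"), M("gln_e", "glutamine", "e", "C5H10N2O3"),
        M("nh4_e", "ammonium", "e", "H4N"), M("nh4_c", "ammonium", "c", "H4N"),
        M("cys_e", "cysteine", "e", "C3H7NO2S"), M("cys_c", "cysteine", "c", "C3H7NO2S"),
        M("gly_e", "glycine", "e", "C2H5NO2"), M("gly_c", "glycine", "c", "C2H5NO2"),
        M("gsh_c", "glutathione", "c", "C10H17N3O6S"), M("gsh_e", "glutathione", "e", "C10H17N3O6S"),
        M("pal_e", "palmitate", "e", "C16H32O2"), M("pal_c", "palmitate", "c", "C16H32O2"),
        M("pal_m", "palmitate", "m", "C16H32O2"),
        M("tib_e", "tibolone", "e", "C21H28O2"), M("tib_c", "tibolone", "c", "C21H28O2"),
    ]

    def rxn(rid, stoich, lb=0.0, ub=1000.0, gpr="", sub="", exchange=False):
        return Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                        gpr=parse_gpr(gpr), subsystem=sub, is_exchange=exchange)

    rxns = [
        # exchanges: uptake closed by default except core nutrients
        rxn("EX_glc_e", {"glc_e": -1.0}, lb=-10.0, exchange=True),
        rxn("EX_o2_e", {"o2_e": -1.0}, lb=-10.0, exchange=True),
        rxn("EX_lac_e", {"lac_e": -1.0}, exchange=True),
        rxn("EX_co2_e", {"co2_e": -1.0}, exchange=True),
        rxn("EX_h2o_e", {"h2o_e": -1.0}, exchange=True),
        rxn("EX_glu_e", {"glu_e": -1.0}, lb=-1.0, exchange=True),
        rxn("EX_gln_e", {"gln_e": -1.0}, exchange=True),
        rxn("EX_nh4_e", {"nh4_e": -1.0}, lb=-5.0, exchange=True),
        rxn("EX_cys_e", {"cys_e": -1.0}, lb=-1.0, exchange=True),
        rxn("EX_gly_e", {"gly_e": -1.0}, lb=-1.0, exchange=True),
        rxn("EX_gsh_e", {"gsh_e": -1.0}, exchange=True),
        rxn("EX_pal_e", {"pal_e": -1.0}, exchange=True),
        rxn("EX_tib_e", {"tib_e": -1.0}, exchange=True),
        # transports
        rxn("GLCt", {"glc_e": -1.0, "glc_c": 1.0}, gpr="SLC2A1", sub="transport"),
        rxn("O2t", {"o2_e": -1.0, "o2_c": 1.0}, lb=-1000.0, sub="transport"),
        rxn("LACt", {"lac_c": -1.0, "lac_e": 1.0}, gpr="SLC16A1 or SLC16A3", sub="transport"),
        rxn("CO2t", {"co2_c": -1.0, "co2_e": 1.0}, lb=-1000.0, sub="transport"),
        rxn("H2Ot", {"h2o_c": -1.0, "h2o_e": 1.0}, lb=-1000.0, sub="transport"),
        rxn("GLUt", {"glu_e": -1.0, "glu_c": 1.0}, gpr="SLC1A2 or SLC1A3", sub="transport"),
        rxn("GLNt", {"gln_c": -1.0, "gln_e": 1.0}, gpr="SLC38A3", sub="transport"),
        rxn("NH4t", {"nh4_e": -1.0, "nh4_c": 1.0}, lb=-1000.0, sub="transport"),
        rxn("CYSt", {"cys_e": -1.0, "cys_c": 1.0}, gpr="SLC7A11", sub="transport"),
        rxn("GLYt", {"gly_e": -1.0, "gly_c": 1.0}, gpr="SLC6A9", sub="transport"),
        rxn("GSHt", {"gsh_c": -1.0, "gsh_e": 1.0}, sub="transport"),
        rxn("PALt", {"pal_e": -1.0, "pal_c": 1.0}, gpr="CD36", sub="transport"),
        rxn("PALtm", {"pal_c": -1.0, "pal_m": 1.0}, gpr="CPT1A and CPT2", sub="transport"),
        rxn("TIBt", {"tib_e": -1.0, "tib_c": 1.0}, sub="transport"),
        rxn("PYRtm", {"pyr_c": -1.0, "pyr_m": 1.0}, gpr="MPC1 and MPC2", sub="transport"),
        # core metabolism (lumped)
        rxn("GLYC", {"glc_c": -1.0, "pyr_c": 2.0}, gpr="HK1 and GAPDH and PKM",
            sub="glycolysis"),
        rxn("LDH", {"pyr_c": -1.0, "lac_c": 1.0}, lb=-1000.0, gpr="LDHA or LDHB",
            sub="glycolysis"),
        rxn("PDHTCA", {"pyr_m": -1.0, "o2_c": -2.5, "co2_c": 3.0, "h2o_c": 2.0},
            gpr="PDHA1 and CS and SDHA", sub="oxidative"),
        rxn("GS", {"glu_c": -1.0, "nh4_c": -1.0, "gln_c": 1.0, "h2o_c": 1.0},
            gpr="GLUL", sub="glutamate-glutamine"),
        rxn("GSHS", {"glu_c": -1.0, "cys_c": -1.0, "gly_c": -1.0, "gsh_c": 1.0,
                     "h2o_c": 2.0},
            gpr="GCLC and GCLM and GSS", sub="glutathione"),
        rxn("BOX", {"pal_m": -1.0, "o2_c": -23.0, "co2_c": 16.0, "h2o_c": 16.0},
            gpr="ACADVL and HADHA and HADHB", sub="beta-oxidation"),
        rxn("TIBDEG", {"tib_c": -1.0, "o2_c": -27.5, "co2_c": 21.0, "h2o_c": 14.0},
            gpr="CYP3A4", sub="xenobiotic"),
        rxn("BIOMASS_astro",
            {"pyr_c": -1.0, "o2_c": -1.0, "gln_c": -0.1, "gsh_c": -0.01},
            sub="biomass"),
    ]
    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           objective_id="BIOMASS_astro", id="astrocyte_mini")
    model.validate()
    return model


def dmem_like_medium() -> "Medium":
    """DMEM+FBS-flavoured fixture medium for the astrocyte-mini model
    (mM, unit culture parameters so concentration == flux)."""
    from .simulate import Medium

    return Medium(
        concentrations={
            "glc": 25.0,
            "o2": 10.0,
            "glu": 0.5,
            "nh4": 2.0,
            "cys": 0.4,
            "gly": 0.4,
            "h2o": 100.0,
        }
    )


# ---------------------------------------------------------------------------
# Paired omics simulation
# ---------------------------------------------------------------------------

def simulate_omics(
    model: MetabolicModel, spec: FixtureSpec, planted: list[str] | None = None
) -> tuple[OmicsTable, OmicsTable, set[str]]:
    """Draw paired transcript/protein tables whose genes follow the model's
    GPRs: genes of planted-active reactions come from a high log-normal
    component, all others from a low one; protein log-values correlate
    with transcript log-values at rho; missing cells are injected at the
    spec's rate (never a whole row).

    Returns (transcript counts table, protein intensity table, planted set).
    """
    if planted is None:
        planted = getattr(model, "planted_active", None)
    if planted is None:
        raise ValidationError("no planted reaction set available")
    rng = np.random.default_rng(spec.seed + 1)
    active_genes: set[str] = set()
    all_genes: list[str] = []
    seen: set[str] = set()
    for rxn in model.reactions:
        if rxn.gpr is None:
            continue
        gs = sorted(rxn.gpr.genes())
        for g in gs:
            if g not in seen:
                seen.add(g)
                all_genes.append(g)
        if rxn.id in set(planted):
            active_genes |= set(gs)
    if not all_genes:
        raise ValidationError("model has no GPRs to simulate omics for")

    n_samples = spec.replicates * len(GROUPS)
    samples = [f"{g}_{i + 1}" for g in GROUPS for i in range(spec.replicates)]
    groups = [g for g in GROUPS for _ in range(spec.replicates)]

    mu_hi, mu_lo = 7.0, 2.0  # log2-scale means of the two components
    t_log = np.empty((len(all_genes), n_samples))
    p_log = np.empty_like(t_log)
    for i, g in enumerate(all_genes):
        mu = mu_hi if g in active_genes else mu_lo
        eps_t = rng.normal(0.0, spec.noise_sd, size=n_samples)
        eps_p = rng.normal(0.0, spec.noise_sd, size=n_samples)
        t_log[i] = mu + eps_t
        p_log[i] = mu + spec.rho * eps_t + np.sqrt(1.0 - spec.rho**2) * eps_p

    t_vals = np.rint(np.exp2(t_log))  # raw-count flavour
    p_vals = np.exp2(p_log) * 1e4  # intensity flavour

    def inject_missing(vals: np.ndarray) -> np.ndarray:
        if spec.missing_rate == 0:
            return vals
        mask = rng.random(vals.shape) < spec.missing_rate
        # never blank out a full row: keep each row's first observed cell
        full = mask.all(axis=1)
        mask[full, 0] = False
        out = vals.astype(float)
        out[mask] = np.nan
        return out

    transcript = OmicsTable(
        features=list(all_genes), samples=list(samples), groups=list(groups),
        values=inject_missing(t_vals), kind="transcript",
    )
    protein = OmicsTable(
        features=list(all_genes), samples=list(samples), groups=list(groups),
        values=inject_missing(p_vals), kind="protein",
    )
    return transcript, protein, set(planted)
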