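"""curation: dead ends, gap filling, leaks/siphons, minimal leakage modes,
element balancing."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linprog

from gemctx.curation import (
    apply_gap_fill,
    balance_reaction_pair,
    find_dead_end_metabolites,
    find_leaks_siphons,
    gap_fill,
    minimal_leakage_mode,
)
from gemctx.errors import ValidationError
from gemctx.model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    check_mass_balance,
    element_matrix,
    stoichiometric_matrix,
)
from gemctx.synth import FixtureSpec, make_toy_model


def _ex(mid, lb=0.0, ub=1000.0):
    return Reaction(id=f"EX_{mid}", stoichiometry={mid: -1.0},
                    lower_bound=lb, upper_bound=ub, is_exchange=True)


def _rxn(rid, stoich, lb=0.0, ub=1000.0):
    return Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub)


class TestDeadEnds:
    def test_unconsumed_product(self):
        m = MetabolicModel(
            metabolites=[Metabolite("A", formula="C"), Metabolite("B", formula="C")],
            reactions=[_ex("A", lb=-10.0), _rxn("R", {"A": -1.0, "B": 1.0})],
            objective_id="R",
        )
        dead = find_dead_end_metabolites(m)
        assert dead == {"B": {"no-consumption"}}

    def test_fully_exchanged_chain_clean(self, balanced_model):
        assert find_dead_end_metabolites(balanced_model) == {}

    def test_random_fixture_matches_directional_scan_oracle(self):
        m = make_toy_model(FixtureSpec(topology="random", n_reactions=20, seed=9))
        # strip some exchanges to create dead ends
        m.reactions = [r for r in m.reactions if r.id not in ("EX_S1", "EX_S2")]
        m.validate()
        S = stoichiometric_matrix(m)
        expected = {}
        for i, met in enumerate(m.metabolites):
            can_prod = can_cons = False
            for j, r in enumerate(m.reactions):
                coef = S[i, j]
                if coef > 0 and r.upper_bound > 0 or coef < 0 and r.lower_bound < 0:
                    can_prod = True
                if coef < 0 and r.upper_bound > 0 or coef > 0 and r.lower_bound < 0:
                    can_cons = True
            tags = set()
            if not can_prod:
                tags.add("no-production")
            if not can_cons:
                tags.add("no-consumption")
            if tags:
                expected[met.id] = tags
        assert find_dead_end_metabolites(m) == expected


def broken_chain_model():
    """X1 -> X2   [gap]   X3 -> X4, with exchanges at both ends; X2 and X3
    are dead ends.  Z is a producible-only metabolite no database fixes."""
    mets = [Metabolite(x, formula="C") for x in ("X1", "X2", "X3", "X4", "Z")]
    rxns = [
        _ex("X1", lb=-10.0),
        _rxn("R1", {"X1": -1.0, "X2": 1.0}),
        _rxn("R3", {"X3": -1.0, "X4": 1.0}),
        _ex("X4"),
        _rxn("RZ", {"X1": -1.0, "Z": 1.0}),
    ]
    m = MetabolicModel(metabolites=mets, reactions=rxns, objective_id="R3")
    m.validate()
    return m


def universal_db(extra=()):
    mets = [Metabolite(x, formula="C") for x in ("X1", "X2", "X3", "X4", "Y")]
    rxns = [
        _rxn("FIX", {"X2": -1.0, "X3": 1.0}),
        _rxn("ALT1", {"X2": -1.0, "Y": 1.0}),
        _rxn("ALT2", {"Y": -1.0, "X3": 1.0}),
    ]
    rxns.extend(extra)
    return MetabolicModel(metabolites=mets, reactions=rxns, objective_id="")


def oracle_gap_fill_weight(model, db, weights, epsilon=1.0):
    """Power-set search: smallest total weight of a database subset whose
    addition lets every dead-end metabolite carry steady-state flux.
    All fixture reactions are irreversible so plain LPs suffice."""
    dead = sorted(find_dead_end_metabolites(model))
    best = None
    db_rxns = db.reactions
    for mask in itertools.product((0, 1), repeat=len(db_rxns)):
        chosen = [r for r, used in zip(db_rxns, mask) if used]
        rxns = list(model.reactions) + chosen
        met_ids = sorted({m for r in rxns for m in r.stoichiometry})
        pos = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxns)))
        for j, r in enumerate(rxns):
            for mid, coef in r.stoichiometry.items():
                S[pos[mid], j] = coef
        ok = True
        for target in dead:
            prod = np.array([max(r.stoichiometry.get(target, 0.0), 0.0) for r in rxns])
            if not prod.any():
                ok = False
                break
            res = linprog(
                np.zeros(len(rxns)),
                A_eq=S, b_eq=np.zeros(len(met_ids)),
                A_ub=-prod[None, :], b_ub=[-epsilon],
                bounds=[(r.lower_bound, r.upper_bound) for r in rxns],
                method="highs",
            )
            if res.status != 0:
                ok = False
                break
        if ok:
            w = sum(weights.get("metabolic", 1.0) for _ in chosen)
            if best is None or w < best:
                best = w
    return best


class TestGapFill:
    def test_single_missing_link_added(self):
        m = broken_chain_model()
        report = gap_fill(m, universal_db())
        assert set(report.added_reactions) == {"FIX"}
        assert report.unfillable == {"Z"}

    def test_cheaper_fix_wins(self):
        # direct FIX (total weight 1) beats the ALT1+ALT2 route (total 2)
        m = broken_chain_model()
        report = gap_fill(m, universal_db(), weights={"metabolic": 1.0})
        assert set(report.added_reactions) == {"FIX"}

    def test_weight_equals_powerset_oracle(self):
        m = broken_chain_model()
        # drop the deliberately unfillable Z so every dead end is coverable
        m.reactions = [r for r in m.reactions if r.id != "RZ"]
        m.metabolites = [x for x in m.metabolites if x.id != "Z"]
        m.validate()
        db = universal_db()
        weights = {"metabolic": 1.0, "transport": 10.0, "exchange": 100.0}
        report = gap_fill(m, db, weights=weights)
        got = sum(report.added_reactions.values())
        assert got == oracle_gap_fill_weight(m, db, weights)

    def test_dead_ends_resolved_after_application(self):
        m = broken_chain_model()
        db = universal_db()
        report = gap_fill(m, db)
        filled = apply_gap_fill(m, db, report)
        remaining = set(find_dead_end_metabolites(filled))
        assert remaining == report.unfillable

    def test_no_dead_ends_no_op(self, balanced_model):
        report = gap_fill(balanced_model, universal_db())
        assert report.added_reactions == {}
        assert report.dead_ends == {}

    def test_reversible_reaction_cannot_fake_turnover(self):
        """A reversible db reaction touching only the dead end must not count
        as a fix by running forward and backward simultaneously."""
        mets = [Metabolite("A", formula="C"), Metabolite("B", formula="C")]
        m = MetabolicModel(
            metabolites=mets,
            reactions=[_ex("A", lb=-10.0), _rxn("R", {"A": -1.0, "B": 1.0})],
            objective_id="R",
        )
        db = MetabolicModel(
            metabolites=[Metabolite("B", formula="C"), Metabolite("W", formula="C")],
            reactions=[Reaction(id="SPIN", stoichiometry={"B": -1.0, "W": 1.0},
                                lower_bound=-1000.0, upper_bound=1000.0)],
            objective_id="",
        )
        report = gap_fill(m, db)
        # SPIN alone leads to W being a new dead end; B->W->nothing cannot
        # sustain steady-state turnover, so B stays unfillable.
        assert report.unfillable == {"B"}
        assert report.added_reactions == {}


class TestLeaksSiphons:
    def test_internal_creation_is_leak(self):
        m = MetabolicModel(
            metabolites=[Metabolite("A", formula="C")],
            reactions=[_rxn("MAKE", {"A": 1.0}), _ex("A")],
            objective_id="MAKE",
        )
        leaks, siphons = find_leaks_siphons(m)
        assert "A" in leaks and "A" not in siphons

    def test_internal_destruction_is_siphon(self):
        m = MetabolicModel(
            metabolites=[Metabolite("A", formula="C")],
            reactions=[_rxn("EAT", {"A": -1.0}), _ex("A", lb=-10.0)],
            objective_id="EAT",
        )
        leaks, siphons = find_leaks_siphons(m)
        assert "A" in siphons and "A" not in leaks

    def test_balanced_fixture_clean(self, balanced_model):
        assert find_leaks_siphons(balanced_model) == (set(), set())

    def test_unbalanced_reaction_creates_leak_or_siphon(self, balanced_model):
        """Planting a mass-creating shortcut (lac -> glc doubles carbon via
        the fermentation cycle) must be caught."""
        rng = np.random.default_rng(17)
        for _ in range(5):
            k = float(rng.integers(1, 4))
            reversible = bool(rng.integers(2))
            m = balanced_model.copy()
            # lac -> k glc amplifies carbon through the fermentation loop
            m.reactions.append(
                Reaction(id="BAD", stoichiometry={"lac": -1.0, "glc": k},
                         lower_bound=-1000.0 if reversible else 0.0,
                         upper_bound=1000.0)
            )
            m.validate()
            leaks, siphons = find_leaks_siphons(m)
            assert leaks or siphons


def leaky_fixture():
    """<= 8 reactions; A appears from nothing, then converts to B."""
    mets = [Metabolite(x, formula="C") for x in ("A", "B", "C")]
    rxns = [
        _rxn("IMB", {"A": 1.0}),
        _rxn("RAB", {"A": -1.0, "B": 1.0}),
        _rxn("RBC", {"B": -1.0, "C": 1.0}),
        _ex("C"),
    ]
    m = MetabolicModel(metabolites=mets, reactions=rxns, objective_id="RAB")
    m.validate()
    return m


def oracle_min_support(model, metabolite, min_rate=0.1):
    """Smallest reaction subset that still sustains the leak, by exhaustive
    subset enumeration with all other reactions clamped to zero."""
    S = stoichiometric_matrix(model)
    midx = model.metabolite_index()[metabolite]
    n = len(model.reactions)
    drain = np.zeros((S.shape[0], 1))
    drain[midx, 0] = -1.0
    A = np.hstack([S, drain])
    for size in range(n + 1):
        for subset in itertools.combinations(range(n), size):
            bounds = []
            for j, r in enumerate(model.reactions):
                if j in subset and not r.is_exchange:
                    bounds.append((r.lower_bound, r.upper_bound))
                else:
                    bounds.append((0.0, 0.0))
            bounds.append((min_rate, 1000.0))
            res = linprog(np.zeros(n + 1), A_eq=A, b_eq=np.zeros(S.shape[0]),
                          bounds=bounds, method="highs")
            if res.status == 0:
                return size
    return None


class TestMinimalLeakageMode:
    def test_single_offender(self):
        m = leaky_fixture()
        assert minimal_leakage_mode(m, "A") == {"IMB"}

    def test_cardinality_matches_subset_enumeration(self):
        m = leaky_fixture()
        mode = minimal_leakage_mode(m, "B")
        assert len(mode) == oracle_min_support(m, "B")

    def test_certificate_property(self):
        """The induced submodel still exhibits the leak."""
        m = leaky_fixture()
        mode = minimal_leakage_mode(m, "B")
        sub = m.copy()
        for r in sub.reactions:
            if r.id not in mode and not r.is_exchange:
                r.lower_bound = r.upper_bound = 0.0
        leaks, _ = find_leaks_siphons(sub)
        assert "B" in leaks

    def test_non_leaking_metabolite_rejected(self, balanced_model):
        with pytest.raises(ValidationError, match="neither"):
            minimal_leakage_mode(balanced_model, "glc")


def balancing_model():
    mets = [
        Metabolite("glc", "glucose", "c", "C6H12O6", 0),
        Metabolite("dext", "anhydroglucose", "c", "C6H10O5", 0),
        Metabolite("h2o", "water", "c", "H2O", 0),
        Metabolite("h", "proton", "c", "H", 1),
        Metabolite("lac", "lactate", "c", "C3H6O3", 0),
    ]
    rxns = [
        # short one water on the right: C6H12O6 -> C6H10O5 (+ H2O missing)
        _rxn("DEHYD", {"glc": -1.0, "dext": 1.0}),
        # balanced partner consuming dext
        _rxn("REHYD", {"dext": -1.0, "h2o": -1.0, "glc": 1.0}),
        _rxn("FERM", {"glc": -1.0, "lac": 2.0}),
    ]
    m = MetabolicModel(metabolites=mets, reactions=rxns, objective_id="FERM")
    m.validate()
    return m


def oracle_balance(model, rid, candidates, span=3):
    """Exhaustive small-coefficient search for E x = -residual, min sum |x|."""
    em = element_matrix(model)
    res = check_mass_balance(model, rid)
    best = None
    cols = [em.column(c) for c in candidates]
    target = -np.array([res.get(e, 0.0) for e in em.elements])
    for combo in itertools.product(range(-span, span + 1), repeat=len(candidates)):
        tot = sum(x * col for x, col in zip(combo, cols))
        if np.allclose(tot, target):
            cost = sum(abs(x) for x in combo)
            if best is None or cost < best[0]:
                best = (cost, dict(zip(candidates, combo)))
    return best


class TestBalanceReactionPair:
    def test_missing_water_added(self):
        m = balancing_model()
        em = element_matrix(m)
        out = balance_reaction_pair(m, "DEHYD", "REHYD", em, candidates=["h", "h2o"])
        assert out.balanced["DEHYD"]
        assert out.added["DEHYD"] == {"h2o": 1.0}
        m.get_reaction("DEHYD").stoichiometry = out.adjusted["DEHYD"]
        assert check_mass_balance(m, "DEHYD") == {}

    def test_already_balanced_unchanged(self):
        m = balancing_model()
        em = element_matrix(m)
        out = balance_reaction_pair(m, "DEHYD", "REHYD", em, candidates=["h", "h2o"])
        assert out.added["REHYD"] == {}
        assert out.adjusted["REHYD"] == m.get_reaction("REHYD").stoichiometry

    def test_random_imbalances_match_integer_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            m = balancing_model()
            rxn = m.get_reaction("REHYD")
            dh = int(rng.integers(-2, 3))
            dw = int(rng.integers(-2, 3))
            if dh:
                rxn.stoichiometry["h"] = rxn.stoichiometry.get("h", 0.0) + dh
            if dw:
                rxn.stoichiometry["h2o"] = rxn.stoichiometry.get("h2o", 0.0) + dw
                if rxn.stoichiometry["h2o"] == 0:
                    del rxn.stoichiometry["h2o"]
            em = element_matrix(m)
            out = balance_reaction_pair(m, "REHYD", "DEHYD", em, candidates=["h", "h2o"])
            oracle = oracle_balance(m, "REHYD", ["h", "h2o"])
            assert out.balanced["REHYD"]
            assert oracle is not None
            got_cost = sum(abs(v) for v in out.added["REHYD"].values())
            assert got_cost == oracle[0]
            m.get_reaction("REHYD").stoichiometry = out.adjusted["REHYD"]
            assert check_mass_balance(m, "REHYD") == {}

    def test_unbalanceable_reported_not_fatal(self):
        m = balancing_model()
        # nitrogen imbalance cannot be fixed with {h, h2o}
        m.metabolites.append(Metabolite("gln", "glutamine", "c", "C5H10N2O3", 0))
        m.get_reaction("DEHYD").stoichiometry["gln"] = 1.0
        em = element_matrix(m)
        out = balance_reaction_pair(m, "DEHYD", "REHYD", em, candidates=["h", "h2o"])
        assert out.balanced["DEHYD"] is False

    def test_disjoint_pair_rejected(self):
        m = balancing_model()
        em = element_matrix(m)
        with pytest.raises(ValidationError, match="share"):
            balance_reaction_pair(m, "DEHYD", "FERM", em, candidates=["h2o"])
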