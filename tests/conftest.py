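"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from gemctx.model import (
    GPRTree,
    MetabolicModel,
    Metabolite,
    Reaction,
    gene,
    gpr_and,
    gpr_or,
)


# ---------------------------------------------------------------------------
# Oracles (kept independent of the package implementations they check)
# ---------------------------------------------------------------------------

def oracle_gpr_eval(tree: GPRTree, values: dict[str, float]):
    """Brute-force recursive min/max evaluation (ignore-missing policy)."""
    if tree.kind == "GENE":
        return values.get(tree.gene_id)
    evaluated = [oracle_gpr_eval(ch, values) for ch in tree.children]
    if tree.kind == "AND":
        if any(v is None for v in evaluated):
            return None
        return min(evaluated)
    present = [v for v in evaluated if v is not None]
    return max(present) if present else None


def random_gpr_tree(rng: np.random.Generator, max_depth: int, n_genes: int = 12) -> GPRTree:
    if max_depth == 0 or rng.random() < 0.35:
        return gene(f"g{int(rng.integers(n_genes))}")
    make = gpr_and if rng.random() < 0.5 else gpr_or
    n_children = int(rng.integers(2, 4))
    return make(*[random_gpr_tree(rng, max_depth - 1, n_genes) for _ in range(n_children)])


# ---------------------------------------------------------------------------
# Model fixtures
# ---------------------------------------------------------------------------

def _ex(mid: str, lb: float = 0.0, ub: float = 1000.0) -> Reaction:
    return Reaction(id=f"EX_{mid}", stoichiometry={mid: -1.0},
                    lower_bound=lb, upper_bound=ub, is_exchange=True)


@pytest.fixture
def balanced_model() -> MetabolicModel:
    """Mass-consistent mini model: glucose oxidation and fermentation with
    real formulas; every internal reaction is elementally balanced."""
    mets = [
        Metabolite("glc", "glucose", "c", "C6H12O6", 0),
        Metabolite("o2", "oxygen", "c", "O2", 0),
        Metabolite("co2", "carbon dioxide", "c", "CO2", 0),
        Metabolite("h2o", "water", "c", "H2O", 0),
        Metabolite("lac", "lactate", "c", "C3H6O3", 0),
    ]
    rxns = [
        _ex("glc", lb=-10.0),
        _ex("o2", lb=-20.0),
        _ex("co2"),
        _ex("h2o"),
        _ex("lac"),
        Reaction(id="OXID",
                 stoichiometry={"glc": -1.0, "o2": -6.0, "co2": 6.0, "h2o": 6.0},
                 lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="FERM", stoichiometry={"glc": -1.0, "lac": 2.0},
                 lower_bound=0.0, upper_bound=1000.0),
    ]
    m = MetabolicModel(metabolites=mets, reactions=rxns, objective_id="OXID",
                       id="balanced_mini")
    m.validate()
    return m


@pytest.fixture
def three_reaction_model() -> MetabolicModel:
    """A -> B -> C open chain with GPRs, used for mapping and I/O tests."""
    mets = [Metabolite(x, compartment="c", formula="C") for x in "ABC"]
    rxns = [
        _ex("A", lb=-1000.0),
        Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0},
                 lower_bound=0.0, upper_bound=5.0, gpr=gpr_and(gene("P4"), gene("P5"))),
        Reaction(id="R2", stoichiometry={"B": -1.0, "C": 1.0},
                 lower_bound=0.0, upper_bound=1000.0, gpr=gpr_or(gene("P2"), gene("P3"))),
        _ex("C"),
    ]
    m = MetabolicModel(metabolites=mets, reactions=rxns, objective_id="R2")
    m.validate()
    return m
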