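"""Shared fixtures and independent oracles.

The oracles deliberately avoid the code paths they check: GPR rules are
evaluated by Python ``eval`` on the rule text, flux consistency by one
flux-maximization LP per reaction (scipy, direct formulation), and knockout
growth ratios by cobrapy (GLPK solver) on an independently constructed model.
"""

from __future__ import annotations

import re

import numpy as np
import pytest
from scipy.optimize import linprog

from fluxscreen.model_core import (
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_gpr,
    render_gpr,
)

UB = 1000.0


def make_reaction(rid, stoich, lb=0.0, ub=UB, gpr=""):
    return Reaction(
        reaction_id=rid,
        stoichiometry=stoich,
        lower_bound=lb,
        upper_bound=ub,
        gpr=parse_gpr(gpr),
        is_exchange=len(stoich) == 1,
    )


def make_model(model_id, mets, reactions, biomass=None, atpm=None):
    genes = sorted(set().union(*(r.gpr.genes() for r in reactions)) if reactions else set())
    return MetabolicModel(
        model_id=model_id,
        metabolites=[Metabolite(m) for m in mets],
        reactions=reactions,
        genes=genes,
        biomass_reaction=biomass,
        atp_maintenance_reaction=atpm,
    )


# ---------------------------------------------------------------------------
# Oracle: GPR evaluation via Python eval on the rule text
# ---------------------------------------------------------------------------

_IDENT = re.compile(r"[A-Za-z0-9_]+")


def eval_rule_text(rule_text: str, inactive: set[str]) -> bool:
    """Truth of a GPR rule under a knockout set, via Python boolean eval."""
    if not rule_text.strip():
        return True

    def sub(m):
        word = m.group()
        if word.lower() in ("and", "or"):
            return word.lower()
        return "False" if word in inactive else "True"

    return bool(eval(_IDENT.sub(sub, rule_text)))


# ---------------------------------------------------------------------------
# Oracle: per-reaction flux maximization (flux consistency)
# ---------------------------------------------------------------------------

def consistent_reactions_oracle(model: MetabolicModel, epsilon: float) -> set[str]:
    """{r : max |v_r| >= epsilon subject to S·v = 0 and bounds}, one or two
    LPs per reaction."""
    mets = {m: i for i, m in enumerate(model.metabolite_ids)}
    n = len(model.reactions)
    S = np.zeros((len(mets), n))
    bounds = []
    for j, rxn in enumerate(model.reactions):
        for met, coeff in rxn.stoichiometry.items():
            S[mets[met], j] = coeff
        bounds.append((rxn.lower_bound, rxn.upper_bound))
    consistent = set()
    for j, rxn in enumerate(model.reactions):
        c = np.zeros(n)
        c[j] = -1.0  # maximize v_j
        res = linprog(c, A_eq=S, b_eq=np.zeros(len(mets)), bounds=bounds, method="highs")
        if res.success and -res.fun >= epsilon * (1 - 1e-6):
            consistent.add(rxn.reaction_id)
            continue
        c[j] = 1.0  # minimize v_j
        res = linprog(c, A_eq=S, b_eq=np.zeros(len(mets)), bounds=bounds, method="highs")
        if res.success and res.fun <= -epsilon * (1 - 1e-6):
            consistent.add(rxn.reaction_id)
    return consistent


# ---------------------------------------------------------------------------
# Oracle: cobrapy knockout ratios
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.model_id)
    cmets = {m.metabolite_id: cobra.Metabolite(m.metabolite_id, compartment=m.compartment)
             for m in model.metabolites}
    crxns = []
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.reaction_id)
        cr.lower_bound = rxn.lower_bound
        cr.upper_bound = rxn.upper_bound
        crxns.append(cr)
    cm.add_reactions(crxns)
    for rxn, cr in zip(model.reactions, crxns):
        cr.add_metabolites({cmets[m]: v for m, v in rxn.stoichiometry.items()})
        rule = render_gpr(rxn.gpr)
        if rule:
            cr.gene_reaction_rule = rule
    return cm


def cobra_knockout_ratio(model: MetabolicModel, objective: str, genes: set[str]) -> float:
    """Growth ratio for a (multi-)gene knockout, computed entirely in cobrapy."""
    cm = to_cobra(model)
    cm.objective = objective
    wt = cm.slim_optimize(error_value=0.0)
    if not np.isfinite(wt):
        wt = 0.0
    with cm:
        for g in genes:
            if g in {g.id for g in cm.genes}:
                cm.genes.get_by_id(g).knock_out()
        ko = cm.slim_optimize(error_value=0.0)
    if not np.isfinite(ko):
        ko = 0.0
    return min(max(ko / wt, 0.0), 1.0) if wt > 1e-9 else float("nan")


# ---------------------------------------------------------------------------
# Common fixture models
# ---------------------------------------------------------------------------

@pytest.fixture
def chain_model():
    """EX_A (uptake 10) -> A, R1: A -> B (g1), BIOMASS: B -> (drain)."""
    return make_model(
        "chain",
        ["A", "B"],
        [
            make_reaction("EX_A", {"A": -1}, lb=-10.0),
            make_reaction("R1", {"A": -1, "B": 1}, gpr="g1"),
            make_reaction("BIOMASS", {"B": -1}),
        ],
        biomass="BIOMASS",
    )


@pytest.fixture
def isozyme_model():
    """Single biomass route through an isozyme reaction (g1 or g2)."""
    return make_model(
        "isozyme",
        ["A", "B"],
        [
            make_reaction("EX_A", {"A": -1}, lb=-10.0),
            make_reaction("R_iso", {"A": -1, "B": 1}, gpr="g1 or g2"),
            make_reaction("BIOMASS", {"B": -1}),
        ],
        biomass="BIOMASS",
    )


@pytest.fixture
def two_path_model():
    """Long (3-reaction) and short (1-reaction) routes from A to biomass."""
    return make_model(
        "two_path",
        ["A", "L1", "L2", "B"],
        [
            make_reaction("EX_A", {"A": -1}, lb=-10.0),
            make_reaction("P_long_1", {"A": -1, "L1": 1}, gpr="gl1"),
            make_reaction("P_long_2", {"L1": -1, "L2": 1}, gpr="gl2"),
            make_reaction("P_long_3", {"L2": -1, "B": 1}, gpr="gl3"),
            make_reaction("P_short", {"A": -1, "B": 1}, gpr="gs"),
            make_reaction("BIOMASS", {"B": -1}),
        ],
        biomass="BIOMASS",
    )
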