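"""Synthetic fixtures with planted ground truth.

Generates a toy metabolic network, an FPKM-like expression matrix, a medium
and a drug catalogue that together emulate the shape of a real screening
study — tumour and control RNA-seq cohorts over a genome-scale
reconstruction plus a drug–target table — at desk scale, with every truth
label known by construction so the whole pipeline can be validated without
external downloads.

The network couples a glucose uptake to two objectives:

* a **biomass** drain fed by a cancer-specific pathway (genes expressed only
  in tumour samples), containing one planted essential gene on each branch
  and one isozyme pair (``g_iso1 or g_iso2``) whose reaction only a
  multi-target drug can shut;
* an **ATP maintenance** hydrolysis fed by a housekeeping ATP-producing
  reaction (expressed everywhere) — knocking its gene out harms the control
  models, which is what the planted toxic drug does.

It also carries a GPR-free transport scaffold, a planted dead-end reaction
(blocked, removed by the consistency check), and ``n_pathways`` housekeeping
chains of non-essential gene-associated reactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deletion import DrugRecord
from .fba import Medium
from .model_core import MetabolicModel, Metabolite, Reaction, parse_gpr

__all__ = [
    "SyntheticSpec",
    "generate_network",
    "generate_expression",
    "generate_drug_table",
    "default_medium",
    "generate_fixture",
    "random_screen_network",
]

UB = 1000.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study.

    Cohort sizes default to 28 tumour and 3 control samples (a realistic
    small patient cohort with few healthy references). Expression is drawn
    as FPKM = 2^N(mean, sd) with expressed and silent log2 modes at +5 and
    −5 (sd 1): a ≥ 4·sd mode separation, enforced here, guarantees the
    mixture discretization recovers the planted labels exactly.
    """

    n_pathways: int = 3
    pathway_length: int = 3
    n_samples_cancer: int = 28
    n_samples_control: int = 3
    expressed_log2_mean: float = 5.0
    silent_log2_mean: float = -5.0
    log2_sd: float = 1.0
    n_silent_genes: int = 45
    seed: int = 20230417

    def __post_init__(self) -> None:
        if abs(self.expressed_log2_mean - self.silent_log2_mean) < 4 * self.log2_sd:
            raise ValueError(
                "expressed and silent log2 modes must be separated by >= 4 sd "
                "for guaranteed-recovery fixtures"
            )
        if self.seed is None:
            raise ValueError("seed is mandatory")

    # -- planted truth ------------------------------------------------------
    @property
    def cancer_pathway_genes(self) -> tuple[str, ...]:
        return ("g_c1", "g_iso1", "g_iso2", "g_c3")

    @property
    def planted_essential_genes(self) -> tuple[str, ...]:
        """Selectively essential in cancer: kill biomass, spare ATP maintenance."""
        return ("g_c1", "g_c3")

    @property
    def planted_selective_drugs(self) -> tuple[str, ...]:
        return ("D_sel_direct", "D_sel_branch", "D_iso_pair")

    @property
    def planted_toxic_drugs(self) -> tuple[str, ...]:
        return ("D_tox",)

    @property
    def planted_inert_drugs(self) -> tuple[str, ...]:
        return ("D_iso_single", "D_hk", "D_decoy")

    @property
    def isozyme_pair_drug(self) -> str:
        return "D_iso_pair"

    def housekeeping_genes(self) -> list[str]:
        return [
            f"g_hk_{i}_{j}"
            for i in range(1, self.n_pathways + 1)
            for j in range(1, self.pathway_length + 1)
        ]


def generate_network(spec: SyntheticSpec = SyntheticSpec()) -> MetabolicModel:
    """Toy network with biomass and ATP-maintenance objectives.

    Deterministic for a given spec (topology depends only on the counts, not
    on the seed). Deleting a planted essential gene zeroes biomass but not
    ATP maintenance; the planted dead-end reaction ``R_dead`` is the only
    flux-inconsistent reaction.
    """
    mets = ["glc_e", "glc_c", "atp_c", "waste_c", "waste_e", "pre1_c", "pre2_c",
            "pre3_c", "dead_c"]
    compartment = {m: ("e" if m.endswith("_e") else "c") for m in mets}

    def rxn(rid, stoich, lb=0.0, ub=UB, gpr=""):
        return Reaction(
            reaction_id=rid,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=parse_gpr(gpr),
            is_exchange=len(stoich) == 1,
        )

    reactions = [
        rxn("EX_glc", {"glc_e": -1}, lb=-10.0),
        rxn("EX_waste", {"waste_e": -1}, lb=0.0),
        rxn("T_glc", {"glc_e": -1, "glc_c": 1}),            # GPR-free scaffold
        rxn("T_waste", {"waste_c": -1, "waste_e": 1}),      # GPR-free scaffold
        # housekeeping energy branch (needed by both objectives)
        rxn("R_atp", {"glc_c": -1, "atp_c": 2}, gpr="g_atp1"),
        rxn("ATPM", {"atp_c": -1, "waste_c": 1}),           # control objective
        # cancer-only biomass pathway: serial + isozyme + parallel branch
        rxn("R_c1", {"glc_c": -1, "pre1_c": 1}, gpr="g_c1"),
        rxn("R_iso", {"pre1_c": -1, "pre2_c": 1}, gpr="g_iso1 or g_iso2"),
        rxn("R_c3", {"glc_c": -1, "pre3_c": 1}, gpr="g_c3"),
        rxn("BIOMASS", {"pre2_c": -1, "pre3_c": -1, "atp_c": -1, "waste_c": 1}),
        # planted dead end: nothing consumes dead_c
        rxn("R_dead", {"glc_c": -1, "dead_c": 1}, gpr="g_dead"),
    ]
    # housekeeping chains: glc_c -> hk_i_1 -> ... -> hk_i_L -> waste_c
    for i in range(1, spec.n_pathways + 1):
        prev = "glc_c"
        for j in range(1, spec.pathway_length + 1):
            met = f"hk{i}_{j}_c"
            mets.append(met)
            compartment[met] = "c"
            reactions.append(
                rxn(f"H_{i}_{j}", {prev: -1, met: 1}, gpr=f"g_hk_{i}_{j}")
            )
            prev = met
        reactions.append(rxn(f"T_hk_{i}", {prev: -1, "waste_c": 1}))

    genes = sorted(set().union(*(r.gpr.genes() for r in reactions)))
    return MetabolicModel(
        model_id="synthetic_tumour_network",
        metabolites=[Metabolite(m, compartment[m]) for m in mets],
        reactions=reactions,
        genes=genes,
        biomass_reaction="BIOMASS",
        atp_maintenance_reaction="ATPM",
    )


def default_medium(spec: SyntheticSpec = SyntheticSpec()) -> Medium:
    """Minimal glucose medium (uptake 10 mmol·gDW⁻¹·h⁻¹)."""
    return Medium({"glc_e": 10.0})


def generate_expression(
    spec: SyntheticSpec, model: MetabolicModel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM-like matrix plus boolean truth labels (True = expressed).

    Cancer samples express the cancer pathway genes; control samples silence
    them; housekeeping genes (including the ATP branch and the dead-end gene)
    are expressed everywhere; ``n_silent_genes`` decoy genes, absent from the
    model, are silent everywhere so every sample is bimodal. Values are
    2^N(mode_mean, sd) draws, bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    cancer_samples = [f"cancer_{i:02d}" for i in range(1, spec.n_samples_cancer + 1)]
    control_samples = [f"control_{i:02d}" for i in range(1, spec.n_samples_control + 1)]
    samples = cancer_samples + control_samples
    silent_genes = [f"g_off_{i}" for i in range(1, spec.n_silent_genes + 1)]
    genes = list(model.genes) + silent_genes
    cancer_only = set(spec.cancer_pathway_genes)

    truth = pd.DataFrame(False, index=genes, columns=samples)
    for gene in genes:
        if gene in silent_genes:
            continue
        for sample in samples:
            is_cancer = sample.startswith("cancer")
            truth.loc[gene, sample] = (gene not in cancer_only) or is_cancer

    means = np.where(
        truth.values, spec.expressed_log2_mean, spec.silent_log2_mean
    )
    values = np.exp2(rng.normal(loc=means, scale=spec.log2_sd))
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    matrix.index.name = "gene"
    return matrix, truth


def generate_drug_table(
    spec: SyntheticSpec, model: MetabolicModel
) -> tuple[list[DrugRecord], dict[str, list[str]]]:
    """Drug catalogue with planted selective, toxic and inert drugs.

    * ``D_sel_direct`` / ``D_sel_branch`` hit one planted essential gene each;
    * ``D_iso_pair`` hits both isozymes of ``R_iso`` — lethal although each
      single target is non-essential (``D_iso_single`` is the inert control);
    * ``D_tox`` hits the ATP branch gene, harming the control models;
    * ``D_hk`` hits a housekeeping chain gene (safe, ineffective);
    * ``D_decoy`` targets a gene absent from the model.

    Anticancer annotations cover the selective drugs only, so the planted
    prediction set is enriched for the annotation. Returns the records plus a
    truth dict {selective, toxic, inert, isozyme_pair}.
    """
    hk_gene = spec.housekeeping_genes()[0] if spec.n_pathways else "g_dead"
    drugs = [
        DrugRecord("D_sel_direct", frozenset({"g_c1"}), is_anticancer=True),
        DrugRecord("D_sel_branch", frozenset({"g_c3"}), is_anticancer=True),
        DrugRecord("D_iso_pair", frozenset({"g_iso1", "g_iso2"}), is_anticancer=True),
        DrugRecord("D_iso_single", frozenset({"g_iso1"}), is_anticancer=False),
        DrugRecord("D_tox", frozenset({"g_atp1"}), is_anticancer=False),
        DrugRecord("D_hk", frozenset({hk_gene}), is_anticancer=False),
        DrugRecord("D_decoy", frozenset({"g_absent_1"}), is_anticancer=False),
    ]
    truth = {
        "selective": list(spec.planted_selective_drugs),
        "toxic": list(spec.planted_toxic_drugs),
        "inert": list(spec.planted_inert_drugs),
        "isozyme_pair": [spec.isozyme_pair_drug],
    }
    return drugs, truth


def generate_fixture(spec: SyntheticSpec = SyntheticSpec()):
    """Convenience bundle: (model, medium, expression, truth, drugs, drug_truth)."""
    model = generate_network(spec)
    medium = default_medium(spec)
    matrix, truth = generate_expression(spec, model)
    drugs, drug_truth = generate_drug_table(spec, model)
    return model, medium, matrix, truth, drugs, drug_truth


# ---------------------------------------------------------------------------
# Random networks for oracle-equivalence testing
# ---------------------------------------------------------------------------

def random_screen_network(
    seed: int,
    n_extra_reactions: int = 8,
    n_genes: int = 6,
) -> MetabolicModel:
    """Random small network with a guaranteed-viable biomass backbone.

    A linear uptake → backbone → secretion chain keeps the biomass objective
    feasible; on top of it random branch, shortcut, dead-end and reversible
    reactions with random GPR rules (single genes, OR pairs, AND pairs,
    nested) are added. Total size stays ≤ ~20 reactions — the scale at which
    brute-force oracles are exact.
    """
    rng = np.random.default_rng(seed)
    backbone_len = int(rng.integers(3, 5))
    mets = [f"m{i}" for i in range(backbone_len + 1)]
    genes = [f"g{i}" for i in range(1, n_genes + 1)]

    def random_gpr() -> str:
        kind = rng.integers(0, 5)
        g = lambda: genes[rng.integers(0, n_genes)]
        if kind == 0:
            return ""
        if kind == 1:
            return g()
        if kind == 2:
            return f"{g()} or {g()}"
        if kind == 3:
            return f"{g()} and {g()}"
        return f"({g()} and {g()}) or {g()}"

    reactions = [
        Reaction("EX_in", {"m0": -1}, -10.0, UB, parse_gpr(""), True),
        Reaction(f"EX_out", {mets[-1]: -1}, 0.0, UB, parse_gpr(""), True),
    ]
    for i in range(backbone_len):
        reactions.append(
            Reaction(
                f"B{i}", {mets[i]: -1, mets[i + 1]: 1}, 0.0, UB,
                parse_gpr(random_gpr()), False,
            )
        )
    biomass = f"B{backbone_len - 1}"

    n_mets = len(mets)
    for k in range(n_extra_reactions):
        choice = rng.integers(0, 4)
        if choice == 0:  # dead end
            new = f"x{k}"
            mets.append(new)
            src = mets[rng.integers(0, n_mets)]
            stoich = {src: -1, new: 1}
            lb = 0.0
        elif choice == 1:  # shortcut / parallel edge
            i, j = sorted(rng.choice(n_mets, size=2, replace=False))
            stoich = {mets[i]: -1, mets[j]: 1}
            lb = 0.0
        elif choice == 2:  # reversible internal edge
            i, j = sorted(rng.choice(n_mets, size=2, replace=False))
            stoich = {mets[i]: -1, mets[j]: 1}
            lb = -UB
        else:  # converging reaction (two substrates)
            i, j, t = rng.choice(n_mets, size=3, replace=False)
            stoich = {mets[i]: -1, mets[j]: -1, mets[t]: 2}
            lb = 0.0
        reactions.append(
            Reaction(f"R{k}", stoich, lb, UB, parse_gpr(random_gpr()), False)
        )

    used_genes = sorted(set().union(*(r.gpr.genes() for r in reactions)))
    return MetabolicModel(
        model_id=f"random_{seed}",
        metabolites=[Metabolite(m, "c") for m in mets],
        reactions=reactions,
        genes=used_genes,
        biomass_reaction=biomass,
        atp_maintenance_reaction=None,
    )
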