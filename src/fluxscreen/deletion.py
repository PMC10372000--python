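"""In silico single-gene and multi-target drug deletion screening.

A deletion is simulated through the GPR rules: the knocked-out genes are set
to False, every reaction whose GPR then evaluates False has its bounds closed
to [0, 0], and the context model is re-optimized for its objective (biomass
for cancer contexts, ATP maintenance for controls). The outcome is the growth
ratio knockout/wild-type.

Drug deletion knocks out *all* mapped targets of a drug simultaneously, which
captures multi-target effects single-gene deletion cannot: a drug inhibiting
both isozymes of an OR rule shuts the reaction although neither single
knockout does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .context import ContextModel
from .fba import fba_optimize
from .model_core import inactivate_for_genes

__all__ = [
    "DeletionOutcome",
    "DrugRecord",
    "ScreeningError",
    "single_gene_deletion",
    "drug_deletion",
    "screen_dataset",
    "read_drug_table",
    "write_drug_table",
]

_RATIO_TOL = 1e-6


class ScreeningError(RuntimeError):
    """Raised when a context cannot be screened (non-viable wild type)."""


@dataclass(frozen=True)
class DeletionOutcome:
    """Effect of one knockout on one context model's objective."""

    entity_id: str
    entity_kind: str  # "gene" | "drug"
    context_id: str
    condition: str
    objective_kind: str  # "biomass" | "atp_maintenance"
    wt_objective: float
    ko_objective: float
    ratio: float
    no_target: bool = False  # drug with no mapped target in the context


@dataclass(frozen=True)
class DrugRecord:
    """A drug with its (inhibited) metabolic target genes."""

    drug_id: str
    target_genes: frozenset[str]
    is_anticancer: bool = False


def _objective_kind(context: ContextModel) -> str:
    return "biomass" if context.condition == "cancer" else "atp_maintenance"


def _check_screenable(context: ContextModel) -> float:
    if context.objective_reaction is None or not context.viable:
        raise ScreeningError(
            f"context {context.context_id!r} is not viable for its "
            f"{_objective_kind(context)} objective and cannot be screened"
        )
    return context.objective_flux


def _ratio(ko: float, wt: float) -> float:
    ratio = ko / wt
    if ratio > 1.0 + 1e-4:
        raise AssertionError(
            f"knockout objective {ko} exceeds wild type {wt}: solver inconsistency"
        )
    return min(max(ratio, 0.0), 1.0)


def _knockout(context: ContextModel, inactive_genes: Iterable[str], wt: float) -> tuple[float, float]:
    shut = inactivate_for_genes(context.model, inactive_genes)
    if not shut:
        return wt, 1.0
    sol = fba_optimize(context.model, context.objective_reaction, disabled_reactions=shut)
    ko = sol.objective_value
    return ko, _ratio(ko, wt)


def single_gene_deletion(
    context: ContextModel,
    genes: Sequence[str] | None = None,
) -> list[DeletionOutcome]:
    """Knock out each gene of the context model in turn.

    The wild-type optimum is computed once per context. Genes absent from
    every GPR of the context (including genes not in the model at all) leave
    the network untouched and score ratio 1. Raises :class:`ScreeningError`
    on a non-viable context.
    """
    wt = _check_screenable(context)
    kind = _objective_kind(context)
    gene_list = sorted(genes) if genes is not None else sorted(context.model.genes)
    outcomes = []
    for gene in gene_list:
        ko, ratio = _knockout(context, {gene}, wt)
        outcomes.append(
            DeletionOutcome(
                entity_id=gene,
                entity_kind="gene",
                context_id=context.context_id,
                condition=context.condition,
                objective_kind=kind,
                wt_objective=wt,
                ko_objective=ko,
                ratio=ratio,
            )
        )
    return outcomes


def drug_deletion(context: ContextModel, drug: DrugRecord) -> DeletionOutcome:
    """Knock out all of a drug's mapped targets simultaneously.

    Targets are intersected with the context model's genes; a drug with no
    mapped target gets ratio 1 and the ``no_target`` flag.
    """
    wt = _check_screenable(context)
    kind = _objective_kind(context)
    mapped = drug.target_genes & set(context.model.genes)
    if not mapped:
        return DeletionOutcome(
            entity_id=drug.drug_id,
            entity_kind="drug",
            context_id=context.context_id,
            condition=context.condition,
            objective_kind=kind,
            wt_objective=wt,
            ko_objective=wt,
            ratio=1.0,
            no_target=True,
        )
    ko, ratio = _knockout(context, mapped, wt)
    return DeletionOutcome(
        entity_id=drug.drug_id,
        entity_kind="drug",
        context_id=context.context_id,
        condition=context.condition,
        objective_kind=kind,
        wt_objective=wt,
        ko_objective=ko,
        ratio=ratio,
    )


def screen_dataset(
    contexts: Sequence[ContextModel],
    drugs: Sequence[DrugRecord] = (),
    genes: bool | Sequence[str] = True,
) -> pd.DataFrame:
    """Cross product of contexts × (genes ∪ drugs) deletion outcomes.

    Cancer contexts are scored on biomass, control contexts on ATP
    maintenance. Non-viable contexts are skipped with a warning (they are
    excluded from all scoring denominators). ``genes`` may be True (screen
    the union of all context genes), False (drugs only) or an explicit list.

    Returns a tidy DataFrame with one row per (context, entity), sorted by
    context then entity for deterministic output.
    """
    screenable = []
    for context in contexts:
        if context.objective_reaction is None or not context.viable:
            warnings.warn(
                f"context {context.context_id!r} is not screenable; skipping",
                stacklevel=2,
            )
            continue
        screenable.append(context)

    if genes is True:
        gene_union: set[str] = set()
        for context in screenable:
            gene_union |= set(context.model.genes)
        gene_list: list[str] = sorted(gene_union)
    elif genes is False:
        gene_list = []
    else:
        gene_list = sorted(genes)

    rows: list[DeletionOutcome] = []
    for context in screenable:
        rows.extend(single_gene_deletion(context, genes=gene_list) if gene_list else [])
        for drug in drugs:
            rows.append(drug_deletion(context, drug))
    df = pd.DataFrame([vars(r) | {} for r in rows] if rows else [],
                      columns=["entity_id", "entity_kind", "context_id", "condition",
                               "objective_kind", "wt_objective", "ko_objective",
                               "ratio", "no_target"])
    if len(df):
        df = df.sort_values(["context_id", "entity_kind", "entity_id"]).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Drug table IO (TSV: drug_id, target_genes semicolon-separated, is_anticancer)
# ---------------------------------------------------------------------------

def read_drug_table(path) -> list[DrugRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"drug_id", "target_genes", "is_anticancer"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: drug table missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        targets = frozenset(t for t in str(row["target_genes"]).split(";") if t)
        records.append(
            DrugRecord(
                drug_id=row["drug_id"],
                target_genes=targets,
                is_anticancer=str(row["is_anticancer"]).strip() in ("1", "true", "True"),
            )
        )
    return records


def write_drug_table(drugs: Sequence[DrugRecord], path) -> None:
    df = pd.DataFrame(
        {
            "drug_id": [d.drug_id for d in drugs],
            "target_genes": [";".join(sorted(d.target_genes)) for d in drugs],
            "is_anticancer": [int(d.is_anticancer) for d in drugs],
        }
    )
    df.to_csv(path, sep="\t", index=False)
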