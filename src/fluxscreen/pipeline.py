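"""End-to-end orchestration: read → discretize → extract → screen → score.

A :class:`RunConfig` (one YAML or JSON file) names the parent model, the
expression datasets (each tagged cancer or control), the drug table and the
medium. :func:`run_pipeline` executes every stage and writes plain-text
reports:

* ``calls_<dataset>.tsv`` — ternary expression calls ({1, 0, -1});
* ``outcomes_<dataset>.tsv`` — tidy knockout outcome table (sample models);
* ``efficacy_matrix_<dataset>.tsv`` — entity × sample growth-ratio matrix;
* ``essential_genes_<dataset>.tsv`` — consensus-model essentiality calls;
* ``essential_genes_shared.tsv`` — genes essential in every cancer dataset;
* ``drug_ranking_<dataset>.tsv`` — per-entity efficacy/harm fractions,
  drug essentiality scores and NNT;
* ``candidates_shared.tsv`` — drugs predicted in every cancer dataset;
* ``run_log.json`` — versions, seed, tolerances, model sizes, enrichment.

Outputs are a pure function of (inputs, config): every table is sorted and
every random element (the synthetic generators, the mixture fit) is seeded,
so a rerun with the same config is byte-identical.

Each cancer dataset is screened independently and only intersected at the
candidate level; control datasets are pooled into a single safety arm.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .context import (
    ContextModel,
    build_consensus_model,
    build_sample_models,
    discretize_expression,
    read_expression_tsv,
    write_calls_tsv,
)
from .deletion import read_drug_table, screen_dataset
from .fba import DEFAULT_EPSILON, Medium
from .model_core import read_model, write_model
from .scoring import (
    Thresholds,
    call_essential_consensus,
    enrichment_score,
    intersect_candidates,
    score_entities,
)

__all__ = ["DatasetConfig", "RunConfig", "load_config", "run_pipeline", "PipelineResult"]


@dataclass(frozen=True)
class DatasetConfig:
    expression: str
    condition: str  # "cancer" | "control"

    def __post_init__(self) -> None:
        if self.condition not in ("cancer", "control"):
            raise ValueError(f"dataset condition must be cancer or control, got {self.condition!r}")


@dataclass(frozen=True)
class RunConfig:
    model: str
    datasets: Mapping[str, DatasetConfig]
    drugs: str
    medium: Mapping[str, float]
    outdir: str
    thresholds: Thresholds = Thresholds()
    epsilon: float = DEFAULT_EPSILON
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("config names no datasets")


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML or JSON."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    datasets = {
        name: DatasetConfig(**entry) for name, entry in raw["datasets"].items()
    }
    thresholds = Thresholds(**raw.get("thresholds", {}))
    return RunConfig(
        model=raw["model"],
        datasets=datasets,
        drugs=raw["drugs"],
        medium={k: float(v) for k, v in raw.get("medium", {}).items()},
        outdir=raw["outdir"],
        thresholds=thresholds,
        epsilon=float(raw.get("epsilon", DEFAULT_EPSILON)),
        seed=int(raw.get("seed", 0)),
    )


@dataclass
class PipelineResult:
    outdir: Path
    sample_contexts: dict[str, list[ContextModel]]
    consensus_contexts: dict[str, ContextModel]
    outcomes: dict[str, pd.DataFrame]
    consensus_outcomes: dict[str, pd.DataFrame]
    reports: dict[str, pd.DataFrame]
    essential_genes: dict[str, pd.DataFrame]
    shared_essential_genes: list[str]
    predicted_drugs: dict[str, list[str]]
    shared_drugs: list[str]
    run_log: dict


def _tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage of the screening workflow and write the report files."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    log: dict = {
        "fluxscreen_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "epsilon": config.epsilon,
        "thresholds": asdict(th),
        "stages": [],
    }

    def stage(name: str, **info) -> None:
        log["stages"].append({"stage": name, **info})

    model = read_model(config.model)
    medium = Medium(config.medium) if config.medium else None
    drugs = read_drug_table(config.drugs)
    stage("read", model=model.model_id, n_reactions=len(model.reactions),
          n_genes=len(model.genes), n_drugs=len(drugs))

    cancer_names = [n for n, d in config.datasets.items() if d.condition == "cancer"]
    control_names = [n for n, d in config.datasets.items() if d.condition == "control"]
    no_safety_filter = not control_names
    if no_safety_filter:
        log["no_safety_filter"] = True

    sample_contexts: dict[str, list[ContextModel]] = {}
    consensus_contexts: dict[str, ContextModel] = {}
    outcomes: dict[str, pd.DataFrame] = {}
    consensus_outcomes: dict[str, pd.DataFrame] = {}

    for name in sorted(config.datasets):
        ds = config.datasets[name]
        matrix = read_expression_tsv(ds.expression)
        calls = discretize_expression(matrix)
        write_calls_tsv(calls, outdir / f"calls_{name}.tsv")
        contexts = build_sample_models(model, calls, medium, ds.condition, epsilon=config.epsilon)
        consensus = build_consensus_model(
            model, calls, medium, ds.condition,
            activity_fraction=th.consensus_activity_fraction,
            epsilon=config.epsilon, dataset_id=name,
        )
        write_model(consensus.model, outdir / f"consensus_model_{name}.json")
        sample_contexts[name] = contexts
        consensus_contexts[name] = consensus
        stage("build_models", dataset=name, condition=ds.condition,
              n_samples=len(contexts), n_viable=sum(c.viable for c in contexts),
              consensus_reactions=len(consensus.kept_reactions))

    # one gene universe across all arms: a predicted target must also be
    # testable in the control models, where its deletion may be a no-op
    gene_universe: set[str] = set()
    for contexts in sample_contexts.values():
        for ctx in contexts:
            gene_universe |= set(ctx.model.genes)
    for cons in consensus_contexts.values():
        gene_universe |= set(cons.model.genes)
    gene_list = sorted(gene_universe)

    for name in sorted(config.datasets):
        df = screen_dataset(sample_contexts[name], drugs=drugs, genes=gene_list)
        outcomes[name] = df
        _tsv(df, outdir / f"outcomes_{name}.tsv")
        matrix_view = df.pivot_table(index=["entity_kind", "entity_id"],
                                     columns="context_id", values="ratio")
        _tsv(matrix_view.reset_index(), outdir / f"efficacy_matrix_{name}.tsv")
        consensus_outcomes[name] = screen_dataset(
            [consensus_contexts[name]], drugs=drugs, genes=gene_list
        )
        stage("screen", dataset=name, n_outcomes=len(df))

    # pooled control arm (sample-specific and consensus)
    control_pool = (
        pd.concat([outcomes[n] for n in control_names], ignore_index=True)
        if control_names else None
    )
    control_consensus_pool = (
        pd.concat([consensus_outcomes[n] for n in control_names], ignore_index=True)
        if control_names else None
    )

    reports: dict[str, pd.DataFrame] = {}
    essential_tables: dict[str, pd.DataFrame] = {}
    predicted_drugs: dict[str, list[str]] = {}
    essential_sets: dict[str, set[str]] = {}

    for name in sorted(cancer_names):
        report = score_entities(outcomes[name], control_pool, th)
        reports[name] = report
        _tsv(report, outdir / f"drug_ranking_{name}.tsv")

        # consensus-model essentiality (genes and drugs)
        cons = consensus_outcomes[name]
        rows = []
        for _, row in cons.iterrows():
            if control_consensus_pool is not None and len(control_consensus_pool):
                ctrl = control_consensus_pool[
                    (control_consensus_pool.entity_id == row.entity_id)
                    & (control_consensus_pool.entity_kind == row.entity_kind)
                ]
                healthy_ratio = float(ctrl.ratio.min()) if len(ctrl) else None
            else:
                healthy_ratio = None
            essential = call_essential_consensus(
                row.ratio, healthy_ratio, th,
                missing_healthy_passes=no_safety_filter,
            )
            rows.append({
                "entity_id": row.entity_id,
                "entity_kind": row.entity_kind,
                "cancer_ratio": row.ratio,
                "healthy_ratio": healthy_ratio,
                "consensus_essential": essential,
                "no_safety_filter": no_safety_filter,
            })
        table = pd.DataFrame(rows).sort_values(["entity_kind", "entity_id"]).reset_index(drop=True)
        essential_tables[name] = table
        _tsv(table, outdir / f"essential_genes_{name}.tsv")
        essential_sets[name] = set(
            table[(table.entity_kind == "gene") & table.consensus_essential].entity_id
        )

        # sample-level drug prediction
        drug_rows = report[(report.entity_kind == "drug") & (report.essential_samples == True)]  # noqa: E712
        predicted_drugs[name] = sorted(drug_rows.entity_id)
        stage("score", dataset=name,
              n_consensus_essential_genes=len(essential_sets[name]),
              n_predicted_drugs=len(predicted_drugs[name]))

    shared_genes = sorted(set.intersection(*essential_sets.values())) if essential_sets else []
    pd.DataFrame({"gene": shared_genes}).to_csv(
        outdir / "essential_genes_shared.tsv", sep="\t", index=False
    )

    shared_drugs_set, venn = intersect_candidates(predicted_drugs) if predicted_drugs else (set(), pd.DataFrame())
    shared_drugs = sorted(shared_drugs_set)
    if len(venn):
        _tsv(venn.reset_index(), outdir / "candidates_shared.tsv")
    else:
        (outdir / "candidates_shared.tsv").write_text("drug_id\tn_datasets\n")

    universe = [d.drug_id for d in drugs]
    annotated = [d.drug_id for d in drugs if d.is_anticancer]
    union_predicted = sorted(set().union(*predicted_drugs.values())) if predicted_drugs else []
    k, p = enrichment_score(union_predicted, annotated, universe)
    log["enrichment"] = {
        "predicted": len(union_predicted),
        "annotated_in_predicted": k,
        "universe": len(universe),
        "annotated": len(annotated),
        "p_value": p,
    }
    log["shared_essential_genes"] = shared_genes
    log["shared_candidate_drugs"] = shared_drugs
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True) + "\n")

    return PipelineResult(
        outdir=outdir,
        sample_contexts=sample_contexts,
        consensus_contexts=consensus_contexts,
        outcomes=outcomes,
        consensus_outcomes=consensus_outcomes,
        reports=reports,
        essential_genes=essential_tables,
        shared_essential_genes=shared_genes,
        predicted_drugs=predicted_drugs,
        shared_drugs=shared_drugs,
        run_log=log,
    )


# ---------------------------------------------------------------------------
# Synthetic study convenience
# ---------------------------------------------------------------------------

def write_synthetic_inputs(spec, directory) -> RunConfig:
    """Materialise the synthetic fixture as pipeline input files + config."""
    from .deletion import write_drug_table
    from .synthetic import generate_fixture

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model, medium, matrix, _truth, drugs, _drug_truth = generate_fixture(spec)
    write_model(model, directory / "model.json")
    cancer = matrix[[c for c in matrix.columns if c.startswith("cancer")]]
    control = matrix[[c for c in matrix.columns if c.startswith("control")]]
    cancer.to_csv(directory / "expression_cancer.tsv", sep="\t")
    control.to_csv(directory / "expression_control.tsv", sep="\t")
    write_drug_table(drugs, directory / "drugs.tsv")
    datasets = {"tumour": DatasetConfig(str(directory / "expression_cancer.tsv"), "cancer")}
    if len(control.columns):
        datasets["control"] = DatasetConfig(str(directory / "expression_control.tsv"), "control")
    return RunConfig(
        model=str(directory / "model.json"),
        datasets=datasets,
        drugs=str(directory / "drugs.tsv"),
        medium=dict(medium.uptakes),
        outdir=str(directory / "results"),
        seed=spec.seed,
    )
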