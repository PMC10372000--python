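#!/usr/bin/env python
"""Screen every context model for gene and drug knockouts.

Loads the serialized context models, simulates single-gene deletions and
multi-target drug deletions (all targets of a drug inactivated at once
through the GPR rules), and writes one tidy outcome table per dataset with
the growth ratio knockout/wild-type — biomass for tumour models, ATP
maintenance for controls. A single gene universe spanning all datasets is
used so that safety can be assessed for every candidate target.
"""

from pathlib import Path

from fluxscreen.context import context_from_model
from fluxscreen.deletion import read_drug_table, screen_dataset
from fluxscreen.model_core import read_model
from fluxscreen.pipeline import load_config

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"
MODELS = STUDY / "models"


def load_contexts(name: str, condition: str):
    contexts = []
    for path in sorted(MODELS.glob(f"{name}_*.json")):
        model = read_model(path)
        kind = "consensus" if path.stem.endswith("consensus") else "sample"
        ctx = context_from_model(model, condition=condition, context_id=path.stem.removeprefix(f"{name}_"))
        contexts.append((kind, ctx))
    return contexts


def main() -> None:
    config = load_config(STUDY / "config.yaml")
    drugs = read_drug_table(config.drugs)

    per_dataset = {name: load_contexts(name, ds.condition)
                   for name, ds in sorted(config.datasets.items())}
    gene_universe = sorted(
        set().union(*(set(ctx.model.genes)
                      for contexts in per_dataset.values()
                      for _, ctx in contexts))
    )

    for name, contexts in per_dataset.items():
        samples = [ctx for kind, ctx in contexts if kind == "sample"]
        consensus = [ctx for kind, ctx in contexts if kind == "consensus"]
        df = screen_dataset(samples, drugs=drugs, genes=gene_universe)
        df.to_csv(STUDY / f"outcomes_{name}.tsv", sep="\t", index=False)
        cons_df = screen_dataset(consensus, drugs=drugs, genes=gene_universe)
        cons_df.to_csv(STUDY / f"outcomes_{name}_consensus.tsv", sep="\t", index=False)
        lethal = df[(df.entity_kind == "drug") & (df.ratio == 0.0)].entity_id.nunique()
        print(f"{name}: {len(df)} sample outcomes over {len(samples)} models "
              f"({lethal} drugs fully lethal in at least one model)")


if __name__ == "__main__":
    main()
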