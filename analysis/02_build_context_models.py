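#!/usr/bin/env python
"""Build sample-specific and consensus context models.

Discretizes each dataset's expression with the per-sample Gaussian-mixture
rule, derives core reaction sets through the GPR rules, and extracts
flux-consistent context models with FASTCORE (biomass forced into tumour
cores, ATP maintenance into control cores). Models are serialized to
results/study/models/ and their sizes summarized.
"""

from pathlib import Path

import pandas as pd

from fluxscreen.context import (
    build_consensus_model,
    build_sample_models,
    discretize_expression,
    read_expression_tsv,
    write_calls_tsv,
)
from fluxscreen.fba import Medium
from fluxscreen.model_core import read_model, write_model
from fluxscreen.pipeline import load_config

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"
MODELS = STUDY / "models"


def main() -> None:
    config = load_config(STUDY / "config.yaml")
    model = read_model(config.model)
    medium = Medium(config.medium)
    MODELS.mkdir(parents=True, exist_ok=True)

    rows = []
    for name, ds in sorted(config.datasets.items()):
        matrix = read_expression_tsv(ds.expression)
        calls = discretize_expression(matrix)
        write_calls_tsv(calls, STUDY / f"calls_{name}.tsv")
        contexts = build_sample_models(model, calls, medium, ds.condition)
        for ctx in contexts:
            write_model(ctx.model, MODELS / f"{name}_{ctx.context_id}.json")
            rows.append({"dataset": name, "model": ctx.context_id,
                         "kind": "sample", "condition": ds.condition,
                         "n_reactions": len(ctx.kept_reactions),
                         "viable": ctx.viable})
        consensus = build_consensus_model(model, calls, medium, ds.condition,
                                          dataset_id=name)
        write_model(consensus.model, MODELS / f"{name}_consensus.json")
        rows.append({"dataset": name, "model": "consensus", "kind": "consensus",
                     "condition": ds.condition,
                     "n_reactions": len(consensus.kept_reactions),
                     "viable": consensus.viable})

    sizes = pd.DataFrame(rows)
    sizes.to_csv(STUDY / "model_sizes.tsv", sep="\t", index=False)
    print(f"models under {MODELS}")
    for name, group in sizes[sizes.kind == "sample"].groupby("dataset"):
        print(f"  {name}: {len(group)} sample models, "
              f"median {int(group.n_reactions.median())} reactions, "
              f"{int(group.viable.sum())} viable")
    cons = sizes[sizes.kind == "consensus"]
    for _, row in cons.iterrows():
        print(f"  {row.dataset} consensus: {row.n_reactions} reactions, viable={row.viable}")


if __name__ == "__main__":
    main()
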