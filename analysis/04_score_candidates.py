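#!/usr/bin/env python
"""Score the screens into essentiality calls, drug rankings and candidates.

Combines the tumour outcome tables with the pooled control arm, applies the
essentiality thresholds (cancer growth ratio < 0.5 in >= 50% of tumour
models, harm to control ATP maintenance in <= 10% of control models),
computes drug essentiality scores and NNT estimates, calls consensus-model
essentiality, intersects candidates across tumour datasets and tests the
predicted set for enrichment in anticancer-annotated drugs.
"""

from pathlib import Path

import pandas as pd

from fluxscreen.deletion import read_drug_table
from fluxscreen.pipeline import load_config
from fluxscreen.scoring import (
    Thresholds,
    call_essential_consensus,
    enrichment_score,
    intersect_candidates,
    score_entities,
)

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"


def main() -> None:
    config = load_config(STUDY / "config.yaml")
    th = Thresholds()
    drugs = read_drug_table(config.drugs)

    cancer_names = sorted(n for n, d in config.datasets.items() if d.condition == "cancer")
    control_names = sorted(n for n, d in config.datasets.items() if d.condition == "control")

    outcomes = {n: pd.read_csv(STUDY / f"outcomes_{n}.tsv", sep="\t")
                for n in config.datasets}
    control_pool = (pd.concat([outcomes[n] for n in control_names], ignore_index=True)
                    if control_names else None)

    predicted, essential_sets = {}, {}
    for name in cancer_names:
        report = score_entities(outcomes[name], control_pool, th)
        report.to_csv(STUDY / f"drug_ranking_{name}.tsv", sep="\t", index=False)
        drugs_called = report[(report.entity_kind == "drug")
                              & (report.essential_samples == True)]  # noqa: E712
        genes_called = report[(report.entity_kind == "gene")
                              & (report.essential_samples == True)]  # noqa: E712
        predicted[name] = sorted(drugs_called.entity_id)
        essential_sets[name] = set(genes_called.entity_id)
        print(f"{name}: {len(genes_called)} essential genes "
              f"{sorted(genes_called.entity_id)}; "
              f"{len(drugs_called)} candidate drugs {predicted[name]}")
        top = report[report.entity_kind == "drug"].iloc[0]
        print(f"  top drug {top.entity_id}: score {top.drug_essentiality_score:.2f}, "
              f"NNT {top.nnt}, control harm {top.control_harm:.2f}")

    shared_genes = sorted(set.intersection(*essential_sets.values())) if essential_sets else []
    pd.DataFrame({"gene": shared_genes}).to_csv(
        STUDY / "essential_genes_shared.tsv", sep="\t", index=False)

    shared, venn = intersect_candidates(predicted)
    venn.reset_index().to_csv(STUDY / "candidates_shared.tsv", sep="\t", index=False)
    print(f"shared essential genes across datasets: {shared_genes}")
    print(f"shared candidate drugs across datasets: {sorted(shared)}")

    universe = [d.drug_id for d in drugs]
    annotated = [d.drug_id for d in drugs if d.is_anticancer]
    union = sorted(set().union(*predicted.values())) if predicted else []
    k, p = enrichment_score(union, annotated, universe)
    print(f"anticancer enrichment: {k}/{len(union)} predicted drugs annotated "
          f"(universe {len(universe)}, annotated {len(annotated)}), "
          f"hypergeometric p = {p:.4f}")


if __name__ == "__main__":
    main()
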