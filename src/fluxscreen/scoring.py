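"""Essentiality calls, drug essentiality scores, NNT and enrichment.

Threshold semantics (all config-exposed through :class:`Thresholds`):

* consensus call — a gene/drug is essential when the cancer growth ratio is
  strictly below ``cancer_ratio_max`` (default 0.5) **and** the healthy
  (control) ratio is at least ``healthy_ratio_min`` (default 0.9, inclusive);
* sample-specific call — the cancer effect must occur in at least
  ``cancer_sample_fraction_min`` (default 0.5, inclusive) of screenable
  cancer models, while control harm (control ratio dropping below
  ``healthy_ratio_min``) is tolerated in at most ``healthy_sample_fraction_max``
  (default 0.1, inclusive) of the control models;
* drug essentiality score — the fraction of screenable sample models in which
  the drug pushes the objective below the condition's threshold; a score of 1
  means the drug is effective in 100% of the samples;
* NNT — number needed to treat, the reciprocal of the efficacy fraction,
  rounded up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Thresholds",
    "call_essential_consensus",
    "call_essential_samples",
    "drug_essentiality_score",
    "nnt_estimate",
    "enrichment_score",
    "benjamini_hochberg",
    "intersect_candidates",
    "score_entities",
]


@dataclass(frozen=True)
class Thresholds:
    """Essentiality thresholds; all values are proportions in [0, 1]."""

    cancer_ratio_max: float = 0.5
    healthy_ratio_min: float = 0.9
    cancer_sample_fraction_min: float = 0.5
    healthy_sample_fraction_max: float = 0.1
    consensus_activity_fraction: float = 0.9

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"threshold {name}={value} outside [0, 1]")


def call_essential_consensus(
    cancer_ratio: float,
    healthy_ratio: float | None,
    th: Thresholds = Thresholds(),
    missing_healthy_passes: bool = False,
) -> bool:
    """Consensus essentiality: cancer ratio strictly < max AND healthy ratio ≥ min.

    With no healthy ratio available the default is fail-safe (not essential);
    set ``missing_healthy_passes`` to treat a missing control as passing.
    """
    if cancer_ratio is None or (isinstance(cancer_ratio, float) and math.isnan(cancer_ratio)):
        return False
    cancer_hit = cancer_ratio < th.cancer_ratio_max
    if healthy_ratio is None or (isinstance(healthy_ratio, float) and math.isnan(healthy_ratio)):
        return cancer_hit and missing_healthy_passes
    return cancer_hit and healthy_ratio >= th.healthy_ratio_min


def call_essential_samples(
    cancer_ratios: Sequence[float],
    healthy_ratios: Sequence[float],
    th: Thresholds = Thresholds(),
) -> tuple[bool | None, float | None, float | None]:
    """Sample-specific essentiality call with its efficacy/harm fractions.

    Returns ``(essential, cancer_efficacy, control_harm)``. Efficacy is the
    fraction of screenable cancer models with ratio < ``cancer_ratio_max``;
    harm is the fraction of control models with ratio < ``healthy_ratio_min``.
    With zero screenable models in either arm the call is None (undefined).
    """
    cancer = [r for r in cancer_ratios if r is not None and not math.isnan(r)]
    healthy = [r for r in healthy_ratios if r is not None and not math.isnan(r)]
    efficacy = sum(r < th.cancer_ratio_max for r in cancer) / len(cancer) if cancer else None
    harm = sum(r < th.healthy_ratio_min for r in healthy) / len(healthy) if healthy else None
    if efficacy is None or harm is None:
        return None, efficacy, harm
    essential = (
        efficacy >= th.cancer_sample_fraction_min
        and harm <= th.healthy_sample_fraction_max
    )
    return essential, efficacy, harm


def drug_essentiality_score(
    ratios: Sequence[float],
    th: Thresholds = Thresholds(),
    condition: str = "cancer",
) -> float | None:
    """Fraction of sample models in which the deletion crosses the threshold.

    For cancer models the threshold is ``cancer_ratio_max`` (biomass reduced
    below 50% of wild type); for control models it is ``healthy_ratio_min``
    (ATP maintenance dropping below 90%, i.e. harm). None for an empty list.
    """
    values = [r for r in ratios if r is not None and not math.isnan(r)]
    if not values:
        return None
    cut = th.cancer_ratio_max if condition == "cancer" else th.healthy_ratio_min
    return sum(r < cut for r in values) / len(values)


def nnt_estimate(score: float | None) -> int | None:
    """Number needed to treat: ceil(1/score); undefined (None) for score 0."""
    if score is None or score <= 0:
        return None
    return math.ceil(1.0 / score)


def enrichment_score(
    predicted_drugs: Iterable[str],
    annotated_anticancer: Iterable[str],
    universe: Iterable[str],
) -> tuple[int, float]:
    """One-sided hypergeometric over-representation test.

    Returns ``(k, p)`` where k is the number of predicted drugs carrying the
    anticancer annotation and p the probability of observing ≥ k annotated
    among n predicted when drawing from a universe of N drugs with K
    annotated. An empty prediction (or a fully annotated universe) gives p=1.
    """
    universe = set(universe)
    predicted = set(predicted_drugs)
    if not predicted <= universe:
        raise ValueError(
            f"predicted drugs outside the universe: {sorted(predicted - universe)}"
        )
    annotated = set(annotated_anticancer) & universe
    N, K, n = len(universe), len(annotated), len(predicted)
    k = len(predicted & annotated)
    if n == 0:
        return 0, 1.0
    # P(X >= k) for X ~ Hypergeom(N, K, n)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k, min(p, 1.0)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values (for multiple drug categories)."""
    if len(p_values) == 0:
        return []
    return list(stats.false_discovery_control(np.asarray(p_values), method="bh"))


def intersect_candidates(
    per_dataset_predictions: Mapping[str, Iterable[str]],
) -> tuple[set[str], pd.DataFrame]:
    """Drugs shared by all datasets, plus a Venn-style membership table.

    The table has one row per drug in the union, one boolean column per
    dataset and an ``n_datasets`` count column.
    """
    sets = {name: set(v) for name, v in per_dataset_predictions.items()}
    if not sets:
        return set(), pd.DataFrame(columns=["n_datasets"])
    shared = set.intersection(*sets.values())
    union = sorted(set.union(*sets.values()))
    table = pd.DataFrame(
        {name: [d in members for d in union] for name, members in sets.items()},
        index=pd.Index(union, name="drug_id"),
    )
    table["n_datasets"] = table.sum(axis=1).astype(int)
    return shared, table


# ---------------------------------------------------------------------------
# Screen-level report
# ---------------------------------------------------------------------------

def score_entities(
    cancer_outcomes: pd.DataFrame,
    control_outcomes: pd.DataFrame | None,
    th: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Per-entity report over sample-specific screens.

    ``cancer_outcomes``/``control_outcomes`` are tidy outcome tables from
    :func:`fluxscreen.deletion.screen_dataset`. Produces one row per entity
    with efficacy and harm fractions, the sample-level essentiality call, the
    drug essentiality score (identical to cancer efficacy by definition) and
    the NNT estimate.
    """
    if control_outcomes is None:
        control_outcomes = pd.DataFrame(columns=cancer_outcomes.columns)
    rows = []
    for (entity, kind), group in cancer_outcomes.groupby(["entity_id", "entity_kind"], sort=True):
        ctrl = control_outcomes[
            (control_outcomes.entity_id == entity)
            & (control_outcomes.entity_kind == kind)
        ]
        essential, efficacy, harm = call_essential_samples(
            group.ratio.tolist(), ctrl.ratio.tolist(), th
        )
        score = drug_essentiality_score(group.ratio.tolist(), th, condition="cancer")
        rows.append(
            {
                "entity_id": entity,
                "entity_kind": kind,
                "n_cancer_models": len(group),
                "n_control_models": len(ctrl),
                "cancer_efficacy": efficacy,
                "control_harm": harm,
                "essential_samples": essential,
                "drug_essentiality_score": score,
                "nnt": nnt_estimate(score),
            }
        )
    report = pd.DataFrame(rows)
    if len(report):
        report = report.sort_values(
            ["entity_kind", "cancer_efficacy", "entity_id"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return report
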