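"""Context-specific model extraction from expression data.

The workflow turns a gene × sample expression matrix into one metabolic
model per sample (and one consensus model per condition):

1. **Discretize** expression per sample with a two-component Gaussian
   mixture on log2(value + 1): values at or above the upper component mean
   are *expressed*, at or below the lower component mean *not expressed*,
   in between *unknown* (treated as not expressed for core membership).
2. **Map to reactions** through the GPR rules: a reaction is *core* when its
   GPR is satisfied by the sample's expressed genes. Reactions without a GPR
   (transports, spontaneous) are never core but remain available scaffold.
3. **Extract** a flux-consistent subnetwork containing the core with the
   FASTCORE two-LP alternation (maximize core flux support / minimize added
   non-core flux), after force-including the condition's objective reaction
   (biomass for cancer, ATP maintenance for control) in the core.

Consensus models use the same machinery on the reactions that are core in at
least a stated fraction (default 90%, inclusive) of a condition's samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fba import DEFAULT_EPSILON, Medium, _LinearSystem, _lp7, _solve, _support, apply_medium, fastcc, fba_optimize
from .model_core import MetabolicModel, evaluate_gpr

__all__ = [
    "EXPRESSED",
    "NOT_EXPRESSED",
    "UNKNOWN",
    "BlockedCoreError",
    "ContextModel",
    "discretize_expression",
    "reaction_core_from_calls",
    "reactions_off_from_calls",
    "fastcore",
    "fastcore_extract",
    "build_sample_models",
    "build_consensus_model",
    "context_from_model",
]

# Ternary call coding used in memory and in the calls TSV.
EXPRESSED = 1
UNKNOWN = 0
NOT_EXPRESSED = -1

# Mixture components closer than this (in log2 units) are considered a
# degenerate unimodal fit; discretization then falls back to a global
# percentile cut.
SEPARATION_FLOOR = 1.0
FALLBACK_PERCENTILE = 75.0


class BlockedCoreError(ValueError):
    """A core reaction cannot carry flux in the consistent parent network."""

    def __init__(self, blocked: Iterable[str]):
        self.blocked = sorted(blocked)
        super().__init__(f"core reactions cannot carry flux: {self.blocked}")


@dataclass
class ContextModel:
    """A flux-consistent subnetwork supporting one sample or consensus core.

    ``provenance`` records how the model was built, e.g.
    ``{"sample_specific": "cancer_03"}`` or ``{"consensus": "cohort_a"}``.
    ``viable`` is True when the condition's objective optimum exceeds the
    flux-activity threshold in the extracted model.
    """

    parent_model_id: str
    kept_reactions: frozenset[str]
    provenance: dict
    condition: str  # "cancer" | "control"
    model: MetabolicModel
    objective_reaction: str | None
    objective_flux: float
    viable: bool

    @property
    def context_id(self) -> str:
        if "sample_specific" in self.provenance:
            return str(self.provenance["sample_specific"])
        return f"consensus:{self.provenance.get('consensus', self.parent_model_id)}"


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize_expression(
    matrix: pd.DataFrame,
    separation_floor: float = SEPARATION_FLOOR,
    fallback_percentile: float = FALLBACK_PERCENTILE,
) -> pd.DataFrame:
    """Ternary expressed / unknown / not-expressed calls per gene and sample.

    ``matrix`` holds nonnegative FPKM-like values, genes in rows, samples in
    columns.  Per sample a two-component Gaussian mixture is fitted to
    log2(value+1) of the nonzero entries; values ≥ the upper component mean
    are called expressed (boundary inclusive upward), values ≤ the lower
    component mean or exactly zero are not expressed, everything between is
    unknown.  When the two component means are closer than
    ``separation_floor`` log2 units the sample is treated as unimodal and a
    single cut at the sample's ``fallback_percentile`` of log values is used
    instead (with a warning).

    Returns a DataFrame of the same shape coded {1: expressed, 0: unknown,
    -1: not expressed}.
    """
    from sklearn.mixture import GaussianMixture

    if (matrix.values < 0).any():
        raise ValueError("expression matrix contains negative values")
    if matrix.columns.duplicated().any():
        raise ValueError("sample ids must be unique")

    calls = pd.DataFrame(
        NOT_EXPRESSED, index=matrix.index, columns=matrix.columns, dtype=int
    )
    log_all = np.log2(matrix.values.astype(float) + 1.0)
    for col_pos, sample in enumerate(matrix.columns):
        values = matrix[sample].values.astype(float)
        log_values = log_all[:, col_pos]
        nonzero = log_values[values > 0]
        upper = lower = None
        if nonzero.size >= 4:
            gmm = GaussianMixture(n_components=2, random_state=0, n_init=1)
            gmm.fit(nonzero.reshape(-1, 1))
            means = np.sort(gmm.means_.ravel())
            if means[1] - means[0] >= separation_floor:
                lower, upper = float(means[0]), float(means[1])
        if upper is None:
            cut = float(np.percentile(nonzero, fallback_percentile)) if nonzero.size else np.inf
            warnings.warn(
                f"sample {sample!r}: degenerate unimodal expression; "
                f"falling back to percentile cut at {cut:.3g}",
                stacklevel=2,
            )
            col = np.where(log_values >= cut, EXPRESSED, NOT_EXPRESSED)
        else:
            col = np.full(len(log_values), UNKNOWN, dtype=int)
            col[log_values >= upper] = EXPRESSED
            col[log_values <= lower] = NOT_EXPRESSED
        col[values == 0] = NOT_EXPRESSED
        calls[sample] = col
    return calls


# ---------------------------------------------------------------------------
# Core derivation
# ---------------------------------------------------------------------------

def reaction_core_from_calls(
    model: MetabolicModel, calls: pd.DataFrame, sample: str
) -> set[str]:
    """Core reaction set for one sample.

    A reaction is core iff its GPR evaluates True when expressed genes map to
    True and both not-expressed and unknown genes map to False; genes missing
    from the calls table count as not expressed. Reactions with an empty GPR
    are never core (they stay available as scaffold for the extraction).
    """
    if sample not in calls.columns:
        raise KeyError(f"sample {sample!r} not in calls")
    col = calls[sample]
    expressed = set(col.index[col == EXPRESSED])
    inactive = set(model.genes) - expressed
    core: set[str] = set()
    for rxn in model.reactions:
        if rxn.gpr.is_empty():
            continue
        if evaluate_gpr(rxn.gpr, inactive):
            core.add(rxn.reaction_id)
    return core


def reactions_off_from_calls(
    model: MetabolicModel, calls: pd.DataFrame, sample: str
) -> set[str]:
    """Reactions confidently silenced by one sample's calls.

    A reaction is off iff its GPR evaluates False with only the *confidently*
    not-expressed genes inactive — unknown-zone and unmeasured genes count as
    potentially active here, the mirror image of the conservative core rule.
    Off reactions are withheld from the extraction entirely, so a sample that
    silences every route to an objective yields a non-viable context.
    """
    if sample not in calls.columns:
        raise KeyError(f"sample {sample!r} not in calls")
    col = calls[sample]
    off_genes = set(col.index[col == NOT_EXPRESSED]) & set(model.genes)
    return {
        rxn.reaction_id
        for rxn in model.reactions
        if not rxn.gpr.is_empty() and not evaluate_gpr(rxn.gpr, off_genes)
    }


# ---------------------------------------------------------------------------
# FASTCORE extraction
# ---------------------------------------------------------------------------

def _lp10(sys: _LinearSystem, K: Sequence[int], P: Sequence[int],
          epsilon: float, scaling: float = 1e4) -> np.ndarray | None:
    """Minimize the L1 norm of non-core flux while forcing core flux through.

    min Σ_{p∈P} t_p  s.t.  S·v = 0,  -t_p ≤ v_p ≤ t_p,
    v_k ≥ epsilon·scaling (k∈K), with all bounds inflated by ``scaling``.
    Scaling the core requirement together with the bounds keeps supporting
    reactions well above the epsilon support threshold even when
    stoichiometric ratios dilute their flux relative to the core.
    """
    n = len(sys.reaction_ids)
    m = len(P)
    c = np.zeros(n + m)
    c[n:] = 1.0
    A_eq = np.hstack([sys.S, np.zeros((sys.S.shape[0], m))])
    b_eq = np.zeros(sys.S.shape[0])
    rows = []
    for row, p in enumerate(P):
        up = np.zeros(n + m)
        up[p] = 1.0
        up[n + row] = -1.0
        rows.append(up)
        dn = np.zeros(n + m)
        dn[p] = -1.0
        dn[n + row] = -1.0
        rows.append(dn)
    A_ub = np.vstack(rows) if rows else None
    b_ub = np.zeros(2 * m) if rows else None
    lb = sys.lb * scaling
    ub = sys.ub * scaling
    K_set = set(K)
    bounds = []
    for j in range(n):
        lo = max(lb[j], epsilon * scaling) if j in K_set else lb[j]
        bounds.append((lo, ub[j]))
    bounds.extend([(0.0, None)] * m)
    res = _solve(c, A_eq, b_eq, bounds, A_ub=A_ub, b_ub=b_ub)
    if not res.success:
        return None
    return res.x[:n]


def _find_sparse_mode(sys: _LinearSystem, J: Sequence[int], P: Sequence[int],
                      singleton: bool, epsilon: float) -> set[int]:
    if not J:
        return set()
    Ji = [J[0]] if singleton else list(J)
    v = _lp7(sys, Ji, epsilon)
    if v is None:
        return set()
    K = [j for j in Ji if v[j] >= 0.99 * epsilon]
    if not K:
        return set()
    v = _lp10(sys, K, P, epsilon)
    if v is None:
        return set()
    return _support(v, epsilon)


def fastcore(model: MetabolicModel, core: Iterable[str],
             epsilon: float = DEFAULT_EPSILON) -> set[str]:
    """Minimal-ish flux-consistent reaction set containing every core reaction.

    Alternates LP7 (push core reactions above epsilon) with an L1
    minimization of non-core flux, flipping unresolved reversible core
    reactions before declaring them blocked. The parent model must itself be
    flux-consistent (run :func:`fluxscreen.fba.fastcc` first); a core
    reaction that cannot carry flux raises :class:`BlockedCoreError`.
    """
    sys = _LinearSystem(model)
    unknown = set(core) - set(sys.index)
    if unknown:
        raise KeyError(f"core references unknown reactions {sorted(unknown)}")
    n = len(sys.reaction_ids)
    C = {sys.index[r] for r in core}
    if not C:
        return set()
    irreversible = {j for j in range(n) if sys.lb[j] >= 0}
    N = set(range(n))

    J = sorted(C & irreversible)
    P = sorted(N - C)
    A = _find_sparse_mode(sys, J, P, singleton=False, epsilon=epsilon)
    if set(J) - A:
        raise BlockedCoreError(sys.reaction_ids[j] for j in set(J) - A)
    J_set = C - A
    singleton = False
    flipped = False
    while J_set:
        P = sorted(N - C - A)
        supp = _find_sparse_mode(sys, sorted(J_set), P, singleton, epsilon)
        A |= supp
        if J_set & A:
            J_set -= A
            flipped = False
            singleton = False
            continue
        Ji = [min(J_set)] if singleton else sorted(J_set)
        rev = [j for j in Ji if j not in irreversible]
        if flipped or not rev:
            if singleton:
                raise BlockedCoreError([sys.reaction_ids[min(J_set)]])
            flipped = False
            singleton = True
        else:
            for j in rev:
                sys.flip(j)
            flipped = True
    return {sys.reaction_ids[j] for j in sorted(A)}


def fastcore_extract(
    model: MetabolicModel,
    core: Iterable[str],
    epsilon: float = DEFAULT_EPSILON,
    condition: str = "cancer",
    provenance: dict | None = None,
) -> ContextModel:
    """Extract a flux-consistent context model around a core reaction set.

    The condition's objective reaction (biomass for cancer, ATP maintenance
    for control) is force-included in the core when present in the model.
    The returned context is flagged viable iff the objective optimum of the
    extracted submodel exceeds ``epsilon``.
    """
    core = set(core)
    objective = (
        model.biomass_reaction if condition == "cancer" else model.atp_maintenance_reaction
    )
    if objective is not None:
        core.add(objective)
    kept = fastcore(model, core, epsilon=epsilon) if core else set()
    provenance = dict(provenance or {})
    provenance.setdefault("condition", condition)
    sub = model.subset(kept, provenance=provenance) if kept else model.subset([], provenance=provenance)
    flux = 0.0
    if objective is not None and objective in kept:
        flux = fba_optimize(sub, objective).objective_value
    return ContextModel(
        parent_model_id=model.model_id,
        kept_reactions=frozenset(kept),
        provenance=provenance,
        condition=condition,
        model=sub,
        objective_reaction=objective if (objective in kept) else None,
        objective_flux=flux,
        viable=flux > epsilon,
    )


# ---------------------------------------------------------------------------
# Sample-specific and consensus model building
# ---------------------------------------------------------------------------

def _prepare_consistent(model: MetabolicModel, medium: Medium | None,
                        epsilon: float) -> MetabolicModel:
    constrained = apply_medium(model, medium) if medium is not None else model
    consistent = fastcc(constrained, epsilon=epsilon)
    return constrained.subset(consistent)


def build_sample_models(
    model: MetabolicModel,
    calls: pd.DataFrame,
    medium: Medium | None,
    condition: str,
    epsilon: float = DEFAULT_EPSILON,
) -> list[ContextModel]:
    """One context model per sample column of ``calls``.

    The parent model is medium-constrained and reduced to its flux-consistent
    part once; each sample's core (intersected with the consistent part, plus
    the condition's objective) is then extracted with FASTCORE. Samples whose
    objective is unsupported yield a non-viable context with no reactions.
    """
    consistent = _prepare_consistent(model, medium, epsilon)
    objective = (
        model.biomass_reaction if condition == "cancer" else model.atp_maintenance_reaction
    )
    contexts: list[ContextModel] = []
    for sample in calls.columns:
        provenance = {"sample_specific": str(sample), "condition": condition}
        off = reactions_off_from_calls(consistent, calls, sample)
        contexts.append(
            _extract_available(
                model, consistent, set(consistent.reaction_ids) - off,
                lambda sub: reaction_core_from_calls(sub, calls, sample),
                objective, condition, provenance, epsilon,
            )
        )
    return contexts


def _extract_available(
    parent: MetabolicModel,
    consistent: MetabolicModel,
    available: set[str],
    core_fn,
    objective: str | None,
    condition: str,
    provenance: dict,
    epsilon: float,
) -> ContextModel:
    """Extract a context from the available (non-silenced) part of the parent.

    Re-checks flux consistency after removal (silencing may block downstream
    reactions); a missing or blocked objective yields a non-viable, empty
    context instead of an error.
    """
    def non_viable() -> ContextModel:
        return ContextModel(
            parent_model_id=parent.model_id,
            kept_reactions=frozenset(),
            provenance=provenance,
            condition=condition,
            model=consistent.subset([], provenance=provenance),
            objective_reaction=None,
            objective_flux=0.0,
            viable=False,
        )

    if objective is None or objective not in available:
        return non_viable()
    sub_avail = consistent.subset(available)
    sub_consistent = fastcc(sub_avail, epsilon=epsilon)
    if objective not in sub_consistent:
        return non_viable()
    sub = sub_avail.subset(sub_consistent)
    core = core_fn(sub) & sub_consistent
    return fastcore_extract(sub, core, epsilon=epsilon, condition=condition,
                            provenance=provenance)


def consensus_core(model: MetabolicModel, calls: pd.DataFrame,
                   activity_fraction: float = 0.9) -> set[str]:
    """Reactions core in at least ``activity_fraction`` of samples (inclusive)."""
    n_samples = len(calls.columns)
    if n_samples == 0:
        raise ValueError("consensus requires at least one sample")
    counts: dict[str, int] = {}
    for sample in calls.columns:
        for rid in reaction_core_from_calls(model, calls, sample):
            counts[rid] = counts.get(rid, 0) + 1
    return {rid for rid, k in counts.items() if k / n_samples >= activity_fraction}


def build_consensus_model(
    model: MetabolicModel,
    calls: pd.DataFrame,
    medium: Medium | None,
    condition: str,
    activity_fraction: float = 0.9,
    epsilon: float = DEFAULT_EPSILON,
    dataset_id: str = "consensus",
) -> ContextModel:
    """Consensus context model: extraction around the ≥ activity_fraction core."""
    consistent = _prepare_consistent(model, medium, epsilon)
    objective = (
        model.biomass_reaction if condition == "cancer" else model.atp_maintenance_reaction
    )
    core = consensus_core(consistent, calls, activity_fraction)
    if not core and (objective is None or objective not in set(consistent.reaction_ids)):
        raise ValueError(
            f"consensus core is empty and the {condition} objective is unreachable"
        )
    provenance = {
        "consensus": dataset_id,
        "condition": condition,
        "activity_fraction": activity_fraction,
        "n_samples": len(calls.columns),
    }
    # mirror of the consensus-core rule: a reaction confidently silenced in at
    # least activity_fraction of the samples is withheld from the extraction
    n_samples = len(calls.columns)
    off_counts: dict[str, int] = {}
    for sample in calls.columns:
        for rid in reactions_off_from_calls(consistent, calls, sample):
            off_counts[rid] = off_counts.get(rid, 0) + 1
    removed = {rid for rid, k in off_counts.items() if k / n_samples >= activity_fraction}
    available = set(consistent.reaction_ids) - removed
    return _extract_available(
        model, consistent, available, lambda sub: core & set(sub.reaction_ids),
        objective, condition, provenance, epsilon,
    )


def context_from_model(
    model: MetabolicModel,
    condition: str = "cancer",
    epsilon: float = DEFAULT_EPSILON,
    context_id: str | None = None,
) -> ContextModel:
    """Wrap a whole model as a screenable context (no extraction).

    Useful for screening a hand-built or already-extracted model directly.
    """
    objective = (
        model.biomass_reaction if condition == "cancer" else model.atp_maintenance_reaction
    )
    flux = fba_optimize(model, objective).objective_value if objective else 0.0
    return ContextModel(
        parent_model_id=model.model_id,
        kept_reactions=frozenset(model.reaction_ids),
        provenance={"sample_specific": context_id or model.model_id, "condition": condition},
        condition=condition,
        model=model,
        objective_reaction=objective,
        objective_flux=flux,
        viable=flux > epsilon,
    )


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    """Write ternary calls as TSV coded {1, 0, -1}; first column is the gene id."""
    calls.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path) -> pd.DataFrame:
    """Read an expression TSV (first column gene id, remaining columns samples)."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if (matrix.values < 0).any():
        raise ValueError(f"{path}: expression values must be nonnegative")
    return matrix
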