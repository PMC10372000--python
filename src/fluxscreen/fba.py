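"""Flux balance analysis and flux-consistency testing.

Flux balance analysis (FBA) maximizes the flux of an objective reaction
subject to steady-state mass balance ``S·v = 0`` and flux bounds
``lb ≤ v ≤ ub``; linear programs are solved with the HiGHS solver bundled in
scipy.  Flux consistency is tested with the FASTCC scheme: instead of one
flux-maximization LP per reaction, a small number of LP7 programs (maximize
the number of reactions carrying at least ``epsilon`` flux) are solved,
flipping candidate reversible reactions that have not yet shown support and
dropping the ones that never can.

Sign conventions: exchange flux > 0 is secretion, < 0 is uptake.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .model_core import MetabolicModel, Reaction

__all__ = [
    "FluxSolution",
    "Medium",
    "FEASIBILITY_TOL",
    "DEFAULT_EPSILON",
    "fba_optimize",
    "apply_medium",
    "fastcc",
]

# Flux-activity threshold and LP feasibility tolerance; the workflow treats
# any flux below epsilon as zero. Config-exposed wherever used.
DEFAULT_EPSILON = 1e-4
FEASIBILITY_TOL = 1e-7

# Reactions count as supporting a mode when they carry at least this fraction
# of epsilon (guards against LP round-off at the epsilon boundary).
_SUPPORT_FRACTION = 0.99


@dataclass(frozen=True)
class FluxSolution:
    """Result of one FBA solve.

    ``status`` is ``optimal``, ``infeasible`` or ``unbounded``. For
    non-optimal statuses the objective is reported as 0 so that knockout /
    wild-type ratios stay defined (a knockout that makes the LP infeasible
    kills growth).
    """

    status: str
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class Medium:
    """Growth-medium composition: exchange metabolite id → max uptake flux.

    Uptake values are nonnegative magnitudes (mmol·gDW⁻¹·h⁻¹); applying the
    medium turns them into negative lower bounds on the exchange reactions.
    """

    uptakes: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.uptakes.items() if v < 0}
        if bad:
            raise ValueError(f"medium uptake values must be >= 0, got {bad}")


# ---------------------------------------------------------------------------
# LP scaffolding
# ---------------------------------------------------------------------------

class _LinearSystem:
    """Dense S matrix plus bounds, with reaction orientation flipping.

    Dense storage is deliberate: the workflow's LPs are built per context
    model (hundreds to a few thousand reactions at genome scale, tens at
    fixture scale) and HiGHS converts to its own sparse form internally.
    """

    def __init__(self, model: MetabolicModel):
        self.reaction_ids = list(model.reaction_ids)
        self.met_ids = list(model.metabolite_ids)
        met_index = {m: i for i, m in enumerate(self.met_ids)}
        n_r, n_m = len(self.reaction_ids), len(self.met_ids)
        self.S = np.zeros((n_m, n_r))
        self.lb = np.zeros(n_r)
        self.ub = np.zeros(n_r)
        for j, rxn in enumerate(model.reactions):
            for met, coeff in rxn.stoichiometry.items():
                self.S[met_index[met], j] = coeff
            self.lb[j] = rxn.lower_bound
            self.ub[j] = rxn.upper_bound
        self.index = {r: j for j, r in enumerate(self.reaction_ids)}

    def flip(self, j: int) -> None:
        self.S[:, j] *= -1.0
        self.lb[j], self.ub[j] = -self.ub[j], -self.lb[j]


def _solve(c: np.ndarray, A_eq: np.ndarray, b_eq: np.ndarray,
           bounds: Sequence[tuple[float, float]],
           A_ub: np.ndarray | None = None, b_ub: np.ndarray | None = None):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL,
                 "dual_feasibility_tolerance": FEASIBILITY_TOL},
    )


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def fba_optimize(
    model: MetabolicModel,
    objective_reaction: str,
    disabled_reactions: Iterable[str] = (),
) -> FluxSolution:
    """Maximize flux through ``objective_reaction`` at steady state.

    ``disabled_reactions`` are clamped to [0, 0] for this solve only (the
    model is not mutated); ids absent from the model raise ``KeyError``.
    Deterministic for a fixed model and solver tolerance.
    """
    sys = _LinearSystem(model)
    if objective_reaction not in sys.index:
        raise KeyError(f"objective reaction {objective_reaction!r} not in model")
    disabled = set(disabled_reactions)
    unknown = disabled - set(sys.index)
    if unknown:
        raise KeyError(f"cannot disable unknown reactions {sorted(unknown)}")
    lb, ub = sys.lb.copy(), sys.ub.copy()
    for rid in disabled:
        j = sys.index[rid]
        lb[j] = ub[j] = 0.0
    c = np.zeros(len(sys.reaction_ids))
    c[sys.index[objective_reaction]] = -1.0  # maximize
    res = _solve(c, sys.S, np.zeros(len(sys.met_ids)), list(zip(lb, ub)))
    if res.status == 2:
        return FluxSolution(status="infeasible", objective_value=0.0)
    if res.status == 3:
        return FluxSolution(status="unbounded", objective_value=0.0)
    if not res.success:
        raise RuntimeError(f"LP solver failure: {res.message}")
    fluxes = {rid: float(res.x[j]) for rid, j in sys.index.items()}
    return FluxSolution(status="optimal", objective_value=float(-res.fun), fluxes=fluxes)


def apply_medium(model: MetabolicModel, medium: Medium,
                 warn: bool = True) -> MetabolicModel:
    """Constrain exchange reactions to a medium composition.

    Exchange reactions for metabolites listed in the medium get a lower
    bound of ``-uptake``; all other exchanges get their uptake closed
    (lower bound clamped to ≥ 0). Secretion (upper) bounds are untouched.
    Medium keys matching no exchanged metabolite produce a warning only.
    """
    import warnings

    exchanged: dict[str, list[int]] = {}
    for i, rxn in enumerate(model.reactions):
        if rxn.is_exchange:
            met = next(iter(rxn.stoichiometry))
            exchanged.setdefault(met, []).append(i)
    unmatched = set(medium.uptakes) - set(exchanged)
    if unmatched and warn:
        warnings.warn(
            f"medium lists metabolites with no exchange reaction: {sorted(unmatched)}",
            stacklevel=2,
        )
    new_reactions = list(model.reactions)
    for met, idxs in exchanged.items():
        for i in idxs:
            rxn = new_reactions[i]
            # exchanges are written met -> nothing with coefficient -1;
            # a +1 orientation inverts the uptake direction
            coeff = rxn.stoichiometry[met]
            if met in medium.uptakes:
                uptake = medium.uptakes[met]
                if coeff < 0:
                    new_reactions[i] = rxn.with_bounds(-uptake, rxn.upper_bound)
                else:
                    new_reactions[i] = rxn.with_bounds(rxn.lower_bound, uptake)
            else:
                if coeff < 0:
                    new_reactions[i] = rxn.with_bounds(max(rxn.lower_bound, 0.0), rxn.upper_bound)
                else:
                    new_reactions[i] = rxn.with_bounds(rxn.lower_bound, min(rxn.upper_bound, 0.0))
    return MetabolicModel(
        model_id=model.model_id,
        metabolites=list(model.metabolites),
        reactions=new_reactions,
        genes=list(model.genes),
        biomass_reaction=model.biomass_reaction,
        atp_maintenance_reaction=model.atp_maintenance_reaction,
        provenance=model.provenance,
    )


# ---------------------------------------------------------------------------
# LP7: maximize the number of reactions in J carrying >= epsilon flux
# ---------------------------------------------------------------------------

def _lp7(sys: _LinearSystem, J: Sequence[int], epsilon: float) -> np.ndarray | None:
    """Solve LP7 for index set J; returns the flux vector or None if infeasible.

    max Σ_j z_j  s.t.  S·v = 0,  z_j ≤ v_j,  0 ≤ z_j ≤ epsilon,
    lb ≤ v ≤ ub.  The optimum drives as many v_j as possible to ≥ epsilon.
    """
    n = len(sys.reaction_ids)
    k = len(J)
    if k == 0:
        return np.zeros(n)
    # variables: [v (n), z (k)]
    c = np.zeros(n + k)
    c[n:] = -1.0
    A_eq = np.hstack([sys.S, np.zeros((sys.S.shape[0], k))])
    b_eq = np.zeros(sys.S.shape[0])
    A_ub = np.zeros((k, n + k))
    for row, j in enumerate(J):
        A_ub[row, n + row] = 1.0
        A_ub[row, j] = -1.0
    b_ub = np.zeros(k)
    bounds = list(zip(sys.lb, sys.ub)) + [(0.0, epsilon)] * k
    res = _solve(c, A_eq, b_eq, bounds, A_ub=A_ub, b_ub=b_ub)
    if not res.success:
        return None
    return res.x[:n]


def _support(v: np.ndarray, epsilon: float) -> set[int]:
    return set(np.flatnonzero(np.abs(v) >= _SUPPORT_FRACTION * epsilon).tolist())


# ---------------------------------------------------------------------------
# FASTCC
# ---------------------------------------------------------------------------

def fastcc(model: MetabolicModel, epsilon: float = DEFAULT_EPSILON) -> set[str]:
    """Flux-consistent reaction set of a model.

    Returns exactly the reactions able to carry ``|flux| ≥ epsilon`` in some
    steady-state solution, via the iterative LP7 scheme: first test all
    irreversible reactions in one LP, then work through the remainder,
    flipping unresolved reversible reactions before declaring them blocked.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    sys = _LinearSystem(model)
    n = len(sys.reaction_ids)
    all_idx = set(range(n))
    irreversible = {j for j in range(n) if sys.lb[j] >= 0}

    J = sorted(all_idx & irreversible)
    v = _lp7(sys, J, epsilon)
    A: set[int] = _support(v, epsilon) if v is not None else set()
    blocked_irr = set(J) - A
    todo = sorted(all_idx - A - blocked_irr - irreversible)

    J_set = set(todo)
    singleton = False
    flipped = False
    while J_set:
        Ji = [min(J_set)] if singleton else sorted(J_set)
        v = _lp7(sys, Ji, epsilon)
        if v is not None:
            A |= _support(v, epsilon)
        if J_set & A:
            J_set -= A
            flipped = False
            singleton = False
            continue
        rev = [j for j in Ji if j not in irreversible]
        if flipped or not rev:
            if singleton:
                J_set.discard(Ji[0])  # genuinely blocked
                singleton = False
            else:
                singleton = True
            flipped = False
        else:
            for j in rev:
                sys.flip(j)
            flipped = True
    return {sys.reaction_ids[j] for j in sorted(A)}
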