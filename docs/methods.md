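# Methods

## Model and assumptions

The screen operates on constraint-based metabolic models: steady-state mass
balance `S·v = 0`, flux bounds `lb ≤ v ≤ ub` (mmol·gDW⁻¹·h⁻¹, nominal), and a
linear objective over single reactions. Proliferative capacity is proxied by
the maximal flux of a biomass drain; the resting energy balance of
non-proliferating (control) tissue by the maximal flux of an ATP-maintenance
hydrolysis. The central assumption of the workflow is that a knockout's
effect on these maxima, computed on a model tailored to a sample's
expression state, predicts the knockout's effect on the corresponding cell.
Only inhibitory drug–target relations are modelled; a drug is simulated as
the simultaneous loss of all of its targets that are present in the model.
Regulation, kinetics, enzyme capacities and thermodynamic constraints are
outside the model class.

All linear programs are solved with HiGHS (scipy.optimize.linprog). The
stoichiometric matrix is held dense; the LPs built here are per-context and
small enough that the solver's internal sparsification dominates. Solutions
are deterministic for a fixed model, so the whole pipeline is a pure
function of (inputs, config, seed).

## Expression discretization

Per sample, a two-component Gaussian mixture (scikit-learn, `random_state=0`,
single init) is fitted to log2(value+1) of the nonzero entries. Calls:

* **expressed** — log2(value+1) ≥ mean of the upper component (inclusive);
* **not expressed** — ≤ mean of the lower component, or the value is 0;
* **unknown** — between the two means.

The unknown zone is intrinsic to this rule: roughly half of each mode's mass
lies between the component means. Downstream, unknown genes are treated
asymmetrically on purpose: they do **not** support a reaction (conservative
for core membership) but they also do **not** silence one (a reaction is
removed only when the confidently not-expressed genes alone falsify its
GPR). Genes absent from the expression table follow the same asymmetry.
When the two fitted means are closer than a separation floor (default 1.0
log2 unit) the sample is treated as unimodal and a single cut at the
sample's 75th percentile of nonzero log values is used, with a warning.

## Context extraction

FASTCC decides flux consistency with the iterative LP7 scheme (maximize the
number of reactions carrying ≥ ε flux; flip unresolved reversible reactions
before declaring them blocked) rather than one LP per reaction; its output
equals the per-reaction flux-maximization definition, which the tests verify
exhaustively on networks of ≤ 20 reactions.

FASTCORE alternates LP7 on the not-yet-supported core with an L1
minimization of flux through non-core reactions. In the L1 step the bounds
*and* the core flux requirement are inflated by a scaling factor (10⁴):
without it, a supporting reaction whose stoichiometry dilutes its flux below
ε relative to the core (e.g. a reaction producing two units of a metabolite
the core consumes one of) would fall below the support threshold and the
returned set would not be self-consistent. Support is detected at 0.99·ε to
absorb solver round-off. The result is near-minimal, not minimal; the tests
bound the gap at one reaction on networks small enough for exhaustive
search.

Per sample, the order of operations is: apply medium → FASTCC on the parent
→ remove the sample's confidently-off reactions → FASTCC again (removal can
block downstream reactions) → derive the core from the calls → force the
condition's objective into the core → FASTCORE. A sample whose removals
leave the objective blocked yields an explicitly non-viable, empty context
rather than an error; non-viable contexts are excluded from every scoring
denominator. Consensus models use reactions core in ≥ 90% of samples
(inclusive) and, symmetrically, remove reactions off in ≥ 90% of samples.
Replicate pooling for cell-line data is treated as consensus building with
the same fraction.

## Knockout simulation and scoring

Deletions are simulated by bound closure (reactions with falsified GPRs get
[0, 0]), never by structural removal, so wild type and knockout share one LP
structure. Infeasible knockout LPs score objective 0 — a knockout that
destroys feasibility destroys growth. Ratios are checked against the
invariant ko ≤ wt and then clipped to [0, 1] to absorb LP jitter. A context
whose wild-type optimum is ≤ ε is unscreenable.

Thresholds (all configurable, defaults in parentheses): cancer growth ratio
strictly < 0.5; control ratio ≥ 0.9 (inclusive); effect required in ≥ 50% of
cancer sample models (inclusive); harm tolerated in ≤ 10% of control models
(inclusive). The 10% clause is read as a *tolerance for harm*, not as a
sufficiency condition — the alternative reading (control preserved in at
least 10% of models) would declare nearly everything safe and would void the
control arm as a safety filter. The drug essentiality score is the fraction
of screenable sample models below the condition's threshold; NNT = ⌈1/score⌉,
undefined at score 0. Enrichment of predicted drugs in anticancer
annotations is a one-sided hypergeometric tail; when several categories are
tested, Benjamini–Hochberg adjustment is available.

Missing control data is fail-safe: a gene without a control ratio is not
called essential, unless the run has no control datasets at all, in which
case calls are emitted with an explicit `no_safety_filter` flag.

## Synthetic data

The generator emulates the *shape* of a real study — a genome-scale
reconstruction, FPKM-like tumour/control cohorts, a drug–target catalogue —
at desk scale with planted truth. Defaults: 28 tumour and 3 control samples;
expression drawn as 2^N(μ, 1) with expressed/silent modes at μ = +5/−5
(separation ≥ 4 sd is enforced, which makes mixture discretization recover
the planted labels without hard flips); a network with a cancer-only biomass
pathway (two planted essential genes and an isozyme pair), a shared ATP
branch (the planted toxic drug's target), a GPR-free transport scaffold, a
planted dead end and three housekeeping chains; seven drugs covering
selective, toxic, inert, single-isozyme, housekeeping and no-target cases.
Truth labels are emitted alongside every artifact, so tests never re-derive
truth from the code under test.

What the synthetic data does *not* emulate: batch effects, dropout and
count noise, isoform structure, partially overlapping pathway usage between
samples, GPR rules with thousands of genes, and drugs with mixed
activating/inhibiting actions. Passing the planted-truth tests therefore
demonstrates correctness of the machinery under clean separation, not
predictive performance on real cohorts.

Problem sizes used throughout the tests and the acceptance script — random
networks of ≤ 20 reactions for oracle equivalence, ≤ 15 for exhaustive
near-minimality search, and the default 28+3 cohort for pipeline runs — were
chosen so that brute-force oracles are exact and a full validation run
completes in well under a minute on one CPU.

## Known limitations

* FASTCORE is near-minimal by construction; the one-reaction bound is an
  empirical property verified on small networks, not a guarantee.
* The discretization's unknown zone means borderline genes neither build nor
  remove reactions; cohorts with weak bimodality will fall back to the
  percentile cut and lose the unknown zone entirely.
* Exchange detection by single-metabolite stoichiometry will misclassify
  sink/demand pseudo-reactions as exchanges if a model encodes them that
  way; annotate `is_exchange` explicitly in the JSON dialect to override.
* Numeric gene coefficients and other non-boolean GPR constructs are
  rejected at parse time rather than approximated.
* Dense stoichiometric storage bounds practical model size to a few
  thousand reactions per context.
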