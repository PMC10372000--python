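# fluxscreen

In silico drug-repurposing screens on context-specific metabolic models.

Tumours rewire their metabolism, and some of that rewiring is a liability: a
reaction that a cancer cell needs for growth but a healthy cell can live
without is a drug target. `fluxscreen` implements the computational workflow
that finds such targets from bulk RNA-seq: it tailors a genome-scale
metabolic reconstruction to each expression sample, simulates gene and drug
knockouts on the tailored models, and ranks drugs by how reliably they
suppress cancer growth *without* harming the energy balance of control
tissue. It is written for computational/systems biologists who have an
expression cohort, a metabolic reconstruction (SBML-FBC) and a drug–target
table, and want a reproducible, fully scriptable screen.

## The method

**Flux balance analysis (FBA).** A metabolic network with stoichiometric
matrix `S` is assumed at steady state; flux vectors `v` satisfy `S·v = 0`
with bounds `lb ≤ v ≤ ub`. The growth capacity of a model is the linear
program `max v_biomass` (for control models: `max v_ATPM`, the
ATP-maintenance pseudo-reaction). Exchange flux > 0 is secretion, < 0 uptake;
the growth medium sets the uptake bounds.

**Context-specific extraction.** Expression is discretized per sample with a
two-component Gaussian mixture on log2(FPKM+1): values at or above the upper
component mean are *expressed*, at or below the lower mean *not expressed*,
in between *unknown*. Gene-protein-reaction (GPR) boolean rules map the calls
to reactions: a reaction whose rule is satisfied by the expressed genes is
*core*; a rule falsified by the confidently silent genes switches the
reaction off entirely. After a FASTCC flux-consistency pass removes blocked
reactions, FASTCORE extracts a compact flux-consistent subnetwork containing
every core reaction (the condition's objective is always forced into the
core). One model is built per sample, plus a consensus model per condition
from reactions core in ≥ 90% of samples.

**Knockout screening.** A gene deletion sets every reaction whose GPR
evaluates false to bounds [0, 0] and re-optimizes; the outcome is the growth
ratio knockout/wild-type. A *drug deletion* knocks out all mapped targets of
a drug simultaneously — this catches multi-target kills (e.g. both isozymes
of an `a or b` rule) that no single-gene deletion can produce.

**Scoring.** An entity is essential when the cancer ratio is < 0.5 and the
control ratio ≥ 0.9 (consensus models), or when those effects occur in
≥ 50% of cancer sample models with harm in ≤ 10% of control models
(sample-specific). The drug essentiality score is the fraction of sample
models in which the drug crosses the threshold (1.0 = effective everywhere);
NNT = ⌈1/score⌉ estimates patients treated per responder. Candidate sets are
intersected across independent datasets and tested for over-representation
of anticancer-annotated drugs with a one-sided hypergeometric test.

## Worked example

The package ships a synthetic study with known ground truth: a toy network
whose biomass drain depends on a cancer-specific pathway (expressed only in
the 28 tumour samples, silent in the 3 controls), an ATP branch shared by
both conditions, an isozyme pair, a dead-end reaction and housekeeping
pathways; a drug catalogue plants selective, toxic and inert drugs.

```bash
python analysis/01_generate_cohort.py
python analysis/02_build_context_models.py
python analysis/03_screen_deletions.py
python analysis/04_score_candidates.py
```

prints, among other lines:

```
  tumour: 28 sample models, median 21 reactions, 28 viable
tumour: 2 essential genes ['g_c1', 'g_c3']; 3 candidate drugs ['D_iso_pair', 'D_sel_branch', 'D_sel_direct']
  top drug D_iso_pair: score 1.00, NNT 1.0, control harm 0.00
anticancer enrichment: 3/3 predicted drugs annotated (universe 7, annotated 3), hypergeometric p = 0.0286
```

The two planted essential genes are recovered exactly; the planted toxic
drug (`D_tox`, hitting the ATP branch) reaches cancer efficacy 1.0 but is
rejected because it harms all control models; `D_iso_pair` is flagged even
though neither of its single targets is essential — the multi-target effect
the drug-deletion simulation exists for. All report tables (`drug_ranking_*`,
`essential_genes_*`, `efficacy_matrix_*`, `candidates_shared.tsv`) are
written as TSV under `results/study/`.

The same workflow runs from a single config via the CLI:

```bash
fluxscreen synth fixture_dir          # write synthetic inputs + config
fluxscreen run fixture_dir/config.yaml
fluxscreen validate mymodel.xml       # SBML-FBC or compact JSON
```

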