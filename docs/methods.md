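# Methods

`omicsflux` implements an integrated metabolomics–transcriptomics workflow
for grouped cell-line studies: metabolite footprinting (PCA, hierarchical
clustering, malignancy-association calls), RPKM-based differential gene
expression, expression-constrained flux balance analysis (FBA) with
replicate-wise differential-flux statistics, and metabolite–gene linkage
through a stoichiometric model. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Study design assumed throughout

One non-malignant control group and one or more malignant groups, each with
at least two (typically three) biological replicates. The defaults mirror a
three-cell-line breast epithelial panel: control vs two malignant lines,
3 + 3 + 3 replicates.

## Metabolomics footprinting

Input is a table of relative chromatographic peak areas (strictly positive;
metabolites × samples). Three normalization modes are provided:
`autoscale` (per-metabolite mean 0, sample SD 1 with the n−1 denominator),
`log_autoscale` (log10 then autoscale) and `none`. Autoscale is the default
for PCA and clustering, the common default of targeted-metabolomics
software; relative areas span orders of magnitude, so unscaled PCA is
dominated by the most abundant compounds. A zero-variance metabolite cannot
be autoscaled and is zeroed with a warning.

PCA treats samples as observations and metabolites as variables; the
variance fraction of component k is its eigenvalue share of the sample
covariance. `analyze_metabolite_table` reports PC1/PC2 percentages under
all three normalization modes so a published variance decomposition can be
matched against each preprocessing choice.

Two routes call malignancy-associated metabolites:

* **Statistical route** (`call_perturbed_metabolites`): Welch t-test of the
  pooled malignant replicates against the control on log10 abundances,
  Benjamini–Hochberg FDR (default 0.05), gated on sign consistency — each
  malignant group's mean must sit on the same side of the control mean.
  Welch is used here (unlike the expression t-test) because pooling two
  cell lines inflates the malignant-side variance.
* **Cluster route** (`perturbed_from_clusters`): Ward/Euclidean clustering
  of autoscaled profiles; a cluster is flagged when its mean profile
  separates pooled malignant from control by at least 1 autoscaled SD with
  per-line sign consistency. When the cut size k is not given, cuts from 2
  to 8 are scored by the smallest separation among flagged clusters and the
  sharpest cut wins — dilute cuts that merge shifted and unshifted
  metabolites score low. This is the formal analogue of reading
  red/blue blocks off a clustered heat-map, and like that reading it can
  occasionally carry along an unshifted metabolite whose noise co-varies
  with a block.

## Differential expression

RPKM(g, s) = counts(g, s) · 10⁹ / (length(g) · total(s)); totals default to
column sums. The per-gene test is a two-sample equal-variance (Student's)
t-test on log2(RPKM + 1) — the log stabilizes the strong mean–variance
relationship of expression data and is configurable off. Multiple testing
uses Benjamini–Hochberg (`statsmodels`); defaults are FDR ≤ 0.01 and fold
change ≥ 2 (or ≤ 1/2), with fold change computed on the RPKM scale as
(mean_case + 0.1) / (mean_control + 0.1). The pseudocount avoids division
by zero for genes silent in one condition; genes with zero RPKM in every
sample are excluded before testing so untestable hypotheses do not inflate
the correction. Consensus sets intersect the calls of two contrasts that
share a gene universe. Over-representation of a query set against a GMT
collection uses the upper-tail hypergeometric distribution with BH across
sets.

Note that RPKM is a relative measure: a strong expression change in a few
abundant genes shifts every other gene's RPKM through the library total.
This matters downstream (see the flux null).

## Expression-constrained FBA

Each reaction carrying a gene–protein–reaction (GPR) rule is capped at a
rate proportional to its aggregated expression, in the E-flux family:

* GPR aggregation: AND → minimum (an enzyme complex is limited by its
  scarcest subunit), OR → sum (isozymes act in parallel). A gene missing
  from the expression map counts 0 under AND and is ignored under OR —
  absent evidence must not unlock a complex.
* Bounds: upper = min(default upper, k · aggregate); reversible reactions
  are tightened symmetrically from below. Exchange and GPR-less reactions
  keep model defaults (only enzyme-catalyzed steps are expression-limited).
* The proportionality constant k (rate units per RPKM) has no natural
  value; only between-group comparisons matter. The `auto` policy pins the
  95th percentile of aggregated expression, over constrained reactions and
  all samples, to 10 mmol h⁻¹ gDW⁻¹, making runs comparable. k is computed
  once per study, never per sample.

FBA maximizes the biomass reaction subject to S·v = 0 and the bounds
(HiGHS via `scipy.optimize.linprog`). Because replicate-wise statistics are
meaningless if the solver returns arbitrary members of an optimal face,
degeneracy is resolved deterministically: total flux Σ|v| is minimized at
the fixed optimum (split-variable formulation), then each v_r is minimized
lexicographically in sorted reaction-id order. Constraint fixing uses
±1e-10 slack bands; the reported objective is the stage-1 LP optimum.
Every solution is verified post hoc — ‖S·v‖∞ ≤ 1e-6 and bounds to 1e-6 —
independent of solver status flags. An exhaustive vertex-enumeration
oracle (`brute_force_fba_objective`, sound for models of ≲8 reactions)
provides an independent check of optima in the test suite.

One FBA is solved per biological replicate using that sample's expression
column. Differential flux between two groups is a per-reaction Student's
t-test (matching the expression test) with BH FDR ≤ 0.05 and a practical
effect gate |Δv̄| > 0.001 mmol h⁻¹ gDW⁻¹. Deterministic LPs make exactly
constant replicate fluxes common; when both groups are constant, p is 1 if
the means coincide and 0 otherwise, and reactions with zero flux in every
replicate of both groups are excluded from the multiple-testing burden.
A **flux-controlling gene** is a differentially expressed gene appearing in
the GPR of a differentially used reaction.

## Metabolite–gene linkage

For each flagged metabolite, the 1-step neighborhood lists producing
reactions (positive stoichiometric coefficient), consuming reactions
(negative), reversible reactions under both roles, the genes behind each
reaction, each gene's DE call and each reaction's differential-flux status.
The integrated report emits one row per (metabolite, reaction, gene)
triple — the machine-readable analogue of annotating a pathway map in red
and blue. A depth-limited upstream walk (`trace_precursors`, depth ≤ 3) is
a navigation aid only; no causal inference is attempted.

## Synthetic data: what it emulates and what it does not

The generators plant known effects so every stage can be scored against
recorded truth:

* **Counts** (`simulate_counts`): negative binomial with variance
  μ + αμ², per-gene log-normal abundance propensities (σ = 1.5), gene
  lengths uniform in 0.5–5 kb. Default dispersion α = 0.01 (BCV 0.1), the
  standard magnitude for replicates of a cultured cell line; tissue-scale
  noise (α ≈ 0.05) is used only where a check explicitly asks for it.
  A fraction of genes carries a planted log2 fold change with random sign
  in every malignant group.
* **Metabolites** (`simulate_metabolomics`): log-normal with baseline
  log10 areas N(5, 0.5), replicate SD 0.15 (log10), and planted shifts of
  `shift_sd` replicate-SDs, same sign in both malignant groups. Power
  context (closed-form noncentral t, 6 vs 3 Welch): a 3σ shift is detected
  at p < 0.01 only ~53% of the time, a 5σ shift at p < 0.05 ~99% of the
  time. The study-level default plants 5σ shifts; even so, a single true
  effect among 33 metabolites keeps BH-corrected single-metabolite power
  modest (~35–50%) at three replicates — the cluster route and larger
  effect panels fare better.
* **Toy network** (`make_toy_network`): substrate uptake (capacity drawn
  in 8–12), a linear enzymatic pathway, optionally a three-reaction
  carrier cycle that taps the entry metabolite and emits a side product
  the biomass reaction also consumes, and a biomass drain. Every enzymatic
  step then carries the same flux, and in the unperturbed state the medium
  (uptake), not any expression cap, limits growth. The whole-study
  generator (`simulate_study`) places the network genes on a common
  expression scale (equal propensity and length) and, when throttling,
  plants a log2FC of −3 on the cycle gene in both malignant groups plus a
  depletion of the cycle's side product in the metabolite table: the
  knock-down caps the cycle reaction ~8-fold below the uptake-limited
  flux, so it binds, growth drops, and the planted reaction/gene/metabolite
  triple is recoverable end-to-end.

The null study for false-positive-rate checks plants no expression
differences at all. A "no-throttle" study that still plants background DE
is *not* a null for the flux statistics: RPKM is compositional, so large
planted genes genuinely shift every metabolic gene's relative expression
between groups, and the procedure correctly reports the induced flux
differences.

What the generators do **not** emulate: batch effects, library-size
pathologies, mass-spectral noise structure (missingness, drift), GC/length
bias, correlated gene modules, or genome-scale network redundancy
(isozyme-rich GPRs, parallel pathways). Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
noise models, not performance on real genome-scale data.

## Numerical choices and degenerate inputs

* LP tolerances: steady state 1e-6, bound satisfaction 1e-6 (post hoc),
  lexicographic slack 1e-10, "zero flux" threshold 1e-9.
* t-tests with zero variance on both sides: p = 1 on equal means, 0
  otherwise (flux and expression alike); metabolomics uses the same rule.
* BH on an empty vector returns an empty vector; ORA with an empty gene
  set reports p = 1.
* JSON is the canonical model format; SBML-FBC import strips the
  conventional `R_`/`M_`/`G_` id prefixes and maps
  `fbc:geneProductAssociation` trees to the internal GPR type. Default
  bounds are [0, 1000] (irreversible) and [−1000, 1000] (reversible)
  mmol h⁻¹ gDW⁻¹.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script runs use desk-scale instances chosen
to make every property measurable in seconds-to-minutes: 20-seed
Monte-Carlo loops; random LP-oracle models of ≤ 6 reactions; count matrices
of 100–200 genes (≈ 70 genes in the whole-study bundle) at depth 10⁶;
metabolite panels of 33 (study) or 12 (unit tests). These sizes are the
package's own test conditions; all thresholds (FDR 0.01/0.05, fold change
2, flux gate 0.001 mmol h⁻¹ gDW⁻¹) are the workflow defaults, not tuned to
the instances.

## Known limitations

* Genome-scale models are out of scope: the FBA core is exact but the
  vertex-enumeration oracle and the lexicographic tie-break (one LP per
  reaction) scale poorly past tens of reactions.
* The flux t-test treats LP outputs as data; their distribution is a
  deterministic transform of expression noise (minima of caps), which a
  t-test only approximates. The shipped null checks quantify this under
  the study conditions.
* The cluster route's flagged set depends on the linkage/metric and the
  separation threshold (1 SD); it is a formalized heat-map reading, not an
  inferential procedure.
* RPKM normalization is compositional; strongly asymmetric transcriptional
  programs will move flux caps globally. Within-study comparisons remain
  valid, but caps are not absolute rates.
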