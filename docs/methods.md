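# Methods

## Data model and scope

The analysis starts at the protein level: a protein × sample matrix of
log abundances produced upstream by a quantification tool (MSstats-style,
normalised and error-corrected), with missing cells marked explicitly.
The log base is deliberately treated as opaque — every statistic used
(differences of means, SDs, Cohen's d, t, chi-squared) is invariant to it
or inherits its units, so the pipeline never needs to know it. The design
is exactly two groups with at least two (typically six) replicates each.
Spectra, peptide evidence, protein inference and normalisation are out of
scope.

## Stage order and missingness

The stages run in a fixed order, and the order is load-bearing:

1. **Exclusive detection on the raw matrix.** A protein is exclusive to a
   group when the other group is entirely missing and the present group has
   ≥ 3 observed values (default `min_present = 3`, configurable; for group
   sizes other than six "all missing" simply means all values in that
   group). Under the default NA filter such a protein always carries at
   least 6 missing values and would be silently discarded, so detection must
   precede filtering — asserted as a pipeline test.
2. **NA filter.** Keep a protein iff it has ≥ 4 observed replicates in
   *each* group and ≤ 3 missing cells in total. Both conditions are checked
   independently; the decision table over all (na_control, na_case)
   patterns is verified against a brute-force rule transcription.
3. **Sample-mean imputation.** Each remaining hole is replaced by the mean
   of the observed values of its *sample column* (computed before any
   replacement), which preserves every column mean to machine precision.
   The phrase "sample mean" could also be read as a per-protein group mean;
   the column reading matches a per-replicate subsetting procedure and is
   the default, and no model-based imputation is offered — mean imputation
   is the method being modelled, not a placeholder.

## Differential expression

Per protein: group means, sample SDs (ddof = 1), FC = mean_case −
mean_control (a log fold change, since inputs are logged),
pooled SD = √((s₁² + s₂²)/2) — the equal-n pooled SD — and Cohen's
d = FC / pooled SD. The test is a two-sided two-sample t-test applied
robustly per protein; Welch's unequal-variance form is the default (it is
the default of the statistical environments this pipeline emulates) with
Student's pooled-variance t behind a flag. DEP calls use strict
inequalities: up iff p < 0.05 and d > 2; down iff p < 0.05 and d < −2.
Boundary ties (d = ±2 or p = 0.05 exactly) are deliberately not called.
Zero-variance-in-both-groups proteins are flagged `degenerate` and never
called (no finite test statistic exists); the special case where all
values are identical across both groups is reported as a null result
(FC = 0, d = 0, p = 1). No multiple-testing correction is applied by
default — the effect-size gate, not the p-value alone, drives selection —
though the classification cut-offs are parameters. FC and d are both
reported for every protein; they are distinct columns and never conflated.

|FC| outliers among the called DEPs use a parametric cut-off: mean(|FC|)
+ 2·SD(|FC|) over the DEP set only, strict inequality, reported split by
direction. With fewer than two DEPs the cut-off is undefined and the stage
errors (the pipeline records it as skipped).

The volcano representation floors p at 1e-300 so −log10 p stays finite.

## Sample-level QC

Samples are vectors over proteins. Euclidean distance and Pearson
correlation matrices feed a hierarchical clustering (complete linkage by
default, average/single available; linkage choice was not dictated by the
method being emulated, so the common default was kept) and the ordination:
k-means with k = 2, Euclidean distance, 10 seeded restarts (best
within-cluster SS wins), then PCA on the mean-centered, unscaled matrix —
unscaled because all features share the log-abundance scale. Confidence
ellipses are a plotting concern and are not computed.

## Category association

Up/down DEP counts per ontology category (GO-CC, GO-BP, GO-MF, KOG) form
a categories × 2 table; a DEP with several categories counts once per
category (GO is a DAG; no DAG propagation or genome-background enrichment
is attempted — the question is direction-vs-category homogeneity only).
The chi-squared statistic is compared against `n_sim = 2000` (the
conventional Monte-Carlo default) null tables with the observed margins
fixed, drawn by Patefield's algorithm; the p-value uses the standard +1
correction, p = (1 + #{χ²_sim ≥ χ²_obs}) / (n_sim + 1), so it is never
zero and is exact in expectation. Rows/columns with zero margin are
trimmed before sampling (they contribute nothing to any null statistic).
Pearson residuals (obs − exp)/√exp localise the association; the headline
significance rule is |r| > 2. Display bands map |r| to standard-normal
two-sided quantiles: [1.645, 1.960) → "•", [1.960, 2.241) → "*",
[2.241, ∞) → "**" (values beyond 2.576 are still shown as "**" with a log
note); the bands are presentation only and never feed a decision. The
identity Σ r² = χ² holds to 1e-9 and is asserted.

## Hub consensus

Edges with confidence strictly above 0.9 survive the filter (the boundary
value 0.9 is dropped); isolated nodes are retained so centralities are
defined on the full node set. Degree counts distinct neighbours. MNC(v) is
the node count of the largest connected component of the subgraph induced
by the open neighborhood N(v). MCC(v) = Σ over maximal cliques C ∋ v,
|C| ≥ 2, of (|C|−1)!, computed by exact Bron–Kerbosch enumeration with
pivoting and guarded by a configurable clique-count limit (default 10⁶)
against pathological graphs; consequently MCC(v) = degree(v) exactly when
no two neighbours of v are adjacent, and isolated nodes score 0. Selection
uses the raw score with an inclusive threshold (≥ 2 by default): the
phrasing of the method being emulated names a score threshold, not a rank,
so raw-score semantics are the default and a top-k rank mode is provided
as an option. The consensus is the three-way intersection. Node ids are
opaque strings; synonym reconciliation (e.g. the RPL23L/MRPL23 naming
split between species homolog tables) is left to an optional upstream
alias mapping rather than guessed.

## Gene–disease filter

Evidence records carry a gene, a DOID identifier, a channel (knowledge /
experimental / textmining) and a non-negative confidence score. Records
with score strictly above the threshold (default 2) pass; a gene passing
in any channel counts once toward the distinct-gene total, with
per-channel and per-disease breakdowns always reported. DOID restriction
is a literal identifier match; no disease-ontology traversal.

## Synthetic data: what it emulates and what it does not

`generate_abundance_dataset` draws, per protein, a baseline log abundance
~ Normal(20, 2) and replicate values ~ Normal(baseline + Δ·1{case},
within_sd = 0.5), with Δ = d · within_sd so the planted population effect
size is exactly d. Defaults: 5000 proteins, 6 + 6 replicates, 3% planted
DEPs with |d| ~ Uniform(2, 5) and random sign, 2% of those extreme
(|d| ∈ [8, 12]) to exercise the outlier stage, 1.5% MCAR missingness, and
10 exclusive proteins per group whose pattern (one group all-missing, 3–6
present in the other) is constructed exactly, overriding the random mask.
These values describe a realistic deep DIA brain-tissue experiment: ~5k
quantified proteins, low sporadic missingness after library-based
extraction, a small differential fraction. An intensity-dependent (MNAR)
missingness mode exists but is off by default, since no mechanism was
assumed by the procedure being emulated.

The generator is honest about its simplifications: within-group noise is
homoscedastic Gaussian on the log scale, proteins are independent (no
co-expression or shared-peptide correlation), missingness is MCAR by
default, and there is no batch structure. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under its own
assumptions, not robustness to correlated, heteroscedastic or MNAR real
data.

`generate_ppi_network` plants hubs as members of several disjoint
small cliques over a sparse Erdős–Rényi background (edge probability
0.02), which makes each planted hub dominate all three centralities by
construction; clique co-members may also enter the consensus, so recovery
is scored as "planted hubs ⊆ consensus". `generate_annotation_table`
assigns one category per ontology per protein multinomially, tilting one
designated category per direction by the enrichment factor;
`generate_disease_table` gives exactly `n_high` genes a record above the
score threshold.

## Numerical and reproducibility choices

- Strict vs inclusive boundaries follow each rule's definition: DEP and
  outlier cut-offs and the edge/score filters are strict; the hub score
  threshold is inclusive (≥).
- All simulation and Monte-Carlo stages take explicit seeds
  (`numpy.random.default_rng`); the pipeline fans one global seed out to
  per-stage sub-seeds by fixed offsets, so stage results are individually
  reproducible and the full report is byte-identical across reruns.
- Tolerances asserted in tests: imputation column-mean invariance and
  label-swap antisymmetry at 1e-12; Σ r² = χ² at 1e-9; PCA reconstruction
  at 1e-9.
- Degenerate inputs have defined behaviour throughout: empty networks and
  empty annotation/disease tables are valid; an all-missing sample column,
  an all-zero contingency table, or fewer than two samples per group raise
  typed errors naming the problem.

## Problem sizes used in the checks

The bundled verification suites run at sizes chosen to give stable
statistics on a laptop-class single core: null t-test calibration at 5000
proteins; Monte-Carlo chi-squared type-I error over 500 null 4 × 2 tables
with 2000 simulations each; DEP recovery at 2000 proteins × 5 seeds;
centrality-oracle equivalence on 100 random graphs of ≤ 12 nodes (the
brute-force MCC oracle enumerates all node subsets, which is the binding
constraint on graph size); hub recovery over 50 planted networks. The
headline counts of any one real experiment (total proteins quantified,
numbers of DEPs, network sizes) depend on the instrument run and on
external database versions and are not targets of the synthetic suites.

## Known limitations

- Welch-vs-Student is the only testing choice; no moderated-variance
  (limma-style) or rank-based tests.
- Mean imputation understates within-group variance when missingness is
  high; the filter's thresholds are meant to keep imputation rare (≤ 3
  cells per protein).
- The Monte-Carlo p-value's granularity is 1/(n_sim + 1); raise `n_sim`
  for small target α.
- MCC is exponential-time in the worst case; the clique guard turns
  pathological inputs into a clear error rather than an open-ended run.
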