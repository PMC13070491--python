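# Methods

`gliostate` implements the analysis stack used to read out a presurgical
(Phase 0) drug-exposure study in recurrent high-grade glioma from
single-nucleus RNA-seq, immunohistochemistry and CNS pharmacokinetic
measurements. This note records the models, the parameters that matter,
the synthetic-data conditions the tests run under, and the numerical
choices made where the design was open.

## Quality control and clustering

Cells are filtered on genes detected (> 500 and < 10 000, both strict)
and mitochondrial percentage (<= 5% of counts for nuclei; a 10% preset
for cultured whole cells, which retain their mitochondria). Doublets
are scored by an artificial-nearest-neighbor scheme: synthetic doublets
are averages of random cell pairs in log-normalized space, and each
cell's score is the artificial fraction among its k = 20 nearest
neighbors in a joint 30-PC embedding; the cutoff is the score quantile
matching the expected doublet rate (default 5%). The full pK-sweep of
dedicated doublet callers is not reproduced.

Clustering normalizes to counts-per-10k, log1p, selects 2000 highly
variable genes (a fixed gene list may be supplied instead), z-scores
clipped at ±10, computes 30 PCs, builds a k = 20 nearest-neighbor
graph, and runs Louvain modularity optimization (igraph multilevel) at
resolution 0.6. An optional per-batch mean-centering in PC space stands
in for heavier batch integration and is off by default. HVG/PC/k
defaults are configurable conventions, not claims about any particular
dataset. Clusters are labelled by the marker set with the highest mean
module score; exact ties go to the first label in a fixed order and are
logged.

## Expression-inferred CNV and malignancy calling

Per gene, log2(CP10K + 1) is centered by the mean over reference cells
(clusters labelled oligodendrocyte / neuron / myeloid; the
lowest-variance cluster if none exist), clipped at ±3, re-centered per
cell by the cell's mean, and smoothed by a centered 101-gene moving
average within each chromosome (windows truncate at chromosome edges;
mitochondrial genes are excluded). The per-cell re-centering matters:
library-depth differences shift the whole log2(CP10K + 1) track, and
without removing that offset nearly every cell decodes as genome-wide
gain or loss. The per-cell median was tried first and rejected — the
discrete, skewed count distribution puts the median well below the
mean, reintroducing a global offset; the mean removes it exactly.

States are decoded per chromosome with a 3-state Gaussian HMM (loss /
neutral / gain; means -0.2, 0, +0.2; shared sigma 0.1; symmetric stay
probability 0.9999; uniform start) by Viterbi. Altered fractions are
counted in gene space: fraction_gain(chr) = genes decoded gain / genes
on the chromosome. The malignancy call combines cluster identity and
CNV evidence: a malignant-candidate cluster cell with chr7 gain
fraction > 0.25 or chr10 loss fraction > 0.25 (strict) is malignant; a
candidate without the event, or a nonmalignant-cluster cell with the
event, is unresolved and excluded; the rest are nonmalignant. Samples
with fewer than 25 malignant cells are dropped from state analysis.

Because the 101-gene moving average makes neighboring track values
almost perfectly correlated, the HMM — which treats emissions as
independent — is overconfident, and pure noise excursions decode as
arm-length events in roughly 15–25% of nonmalignant cells per
hallmark chromosome at the default synthetic noise level. The
concordance rule absorbs these as "unresolved" (they are never called
malignant, since they sit in nonmalignant clusters), which is precisely
why the rule exists; recovery is therefore assessed on the
malignant-vs-not binary, where sensitivity and specificity both exceed
0.95 on the default synthetic cohort.

## Module scoring, state and cycling assignment

A module score is the mean log-normalized expression of a signature
minus the mean of expression-matched controls: genes are ranked by
average expression over the scored cells and split into 25 equal-count
bins; each signature gene draws 100 control genes from its bin (without
replacement when the bin allows, otherwise with). Draws are seeded and
retrievable, so any score can be recomputed independently for a fixed
draw. Scoring is performed separately within each tumor sample, on
malignant cells only; the four Neftel state scores (AC-, MES-, NPC-,
OPC-like) are argmaxed into a state call with ties broken in fixed
order (AC, MES, NPC, OPC) and counted. Cycling is thresholded on the
cell-cycle module score at 0.1, independent of state; the threshold is
configurable, and on the default synthetic data the planted cycling
fraction is recovered well within ±0.03 (scores of cycling vs
non-cycling cells separate by several times the threshold). Composition
tables report per-sample state fractions (summing to 1) and the cycling
fraction computed over all malignant cells of the sample.

## Cohort statistics

Two-sample comparisons use the Student pooled-variance t-test (the
plain "2-sided t-test"; Welch is available via the module but not the
default), paired comparisons use the one-sample t on differences, and
correlation uses sample Pearson r with the t-transform p on n - 2 df.
Zero-variance inputs are flagged rather than returned as NaN; fractions
are compared as raw proportions (no log-ratio transform). One call is
one declared comparison — no silent multiplicity, and no correction
across the five state metrics (a BH helper exists for callers who want
it).

## Pseudobulk differential expression and enrichment

Cells are summed per sample into integer pseudobulk profiles. Each gene
with total count >= 10 is fit by OLS on log2(CPM + 1) with
`expression ~ treatment + replicate`; the treatment coefficient is the
log2 fold change, its t-test p (residual df) is BH-adjusted, and DE
calls require padj < 0.05 AND |log2FC| > 1, both strict. Confounded
designs (treatment aliased with replicate) are rejected by a rank
check. The model is deliberately unmoderated — no dispersion shrinkage —
so at three replicates per arm the residual df is 2 and BH-adjusted
calls are essentially unreachable regardless of effect size; effect
estimates remain unbiased (planted ±1 log2 effects are recovered to
within 0.1 over 200 simulations) and the null p-distribution is
uniform. Users who need calls at minimal replication should add
replicates (the worked example uses six) or use a moderated engine.

Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum (weight
exponent 1) on the signed DE t-statistic (log2FC selectable). The null
permutes gene labels — with 3 replicates per arm a phenotype
permutation null is impossible — as seeded same-size random sets; NES
divides ES by the mean |null ES| of matching sign and p is the fraction
of same-sign null ES at least as extreme, floored at 1/(n_perm + 1).

## PK/PD arithmetic and the Phase 1 gate

Unbound concentration is total × fraction unbound, reported only when
both the total and the resulting unbound value sit at or above the
LLOQ (0.1 nM default) — tissue totals can be quantifiable while the
unbound fraction is not, which is exactly the everolimus regime. Kp is
tissue total / plasma total and Kp,uu the unbound analogue; both are
flagged undefined on any below-LLOQ input. The identity
Kp,uu = Kp × (f_u,tissue / f_u,plasma) holds algebraically on every
defined record and is property-tested. The Phase 1 gate requires, per
patient: unbound tumor (non-enhancing by default, configurable)
concentration strictly greater than 5 × IC50 for both drugs
(ribociclib 40 nM, everolimus 2 nM) and strictly greater than 30%
longitudinal decrease in both pRb and pS6; "5 times greater than" is
read as > 5 × IC50, so boundary equality fails. A zero pre-treatment
IHC value leaves the decrease undefined and the patient failed with a
flag. Cohort medians exclude below-LLOQ values and report their count.

## Synthetic data: what it emulates and what it does not

The generator is the test bench: a synthetic genome (22 autosomes × 250
genes on a uniform position grid plus 13 flagged mitochondrial genes —
no real genome build), and a negative-binomial count hierarchy
(dispersion 0.5, gamma–Poisson sampled): per-cell lognormal library
size (mean ≈ 6000, sigma 0.35) × lognormal gene baseline × cell-type
marker shift (120 genes per type, +3 log2) × CNV multiplier on affected
genes × metaprogram shift (+1.2 log2 over 100 genes per state; same for
cycling cells on the cell-cycle program). Defaults plant chr7 +0.4 /
chr10 −0.5 log2 across the whole chromosome in malignant cells only,
over six samples of 1500 cells at 50% malignant fraction; per-sample
state mixtures are Dirichlet(8); cycling fraction 0.2; doublet rate 5%
(doublets are NB draws around the sum of two parents' expected
vectors); mitochondrial fraction Beta(2, 60). Signature gene baselines
carry a 4× multiplier because real metaprogram genes are
moderately-to-highly expressed. Signature and marker blocks live on
chromosomes that carry no planted CNV, so state structure never
confounds the CNV readout. Per-batch gene-wise multiplicative noise is
available but off by default.

Deliberately not emulated: transcriptome-wide co-expression, splicing,
ambient RNA, spatial structure, empirical batch structure. Passing
tests therefore demonstrate that the pipeline recovers planted signal
under the stated noise model — not that it is robust to every artifact
of real tissue.

The pseudobulk experiment generator plants balanced up/down effects
(half +lfc, half −lfc): an all-up design biases CPM-based fold changes
by the effect-gene mass share (a compositional artifact), and balanced
responses are also the realistic condition for treatment studies.

The PK generator emits one row per patient × drug × compartment
(enhancing, non-enhancing, CSF, plasma) with lognormal inter-patient
variability (CV 0.6) around arm geometric means that scale linearly
with dose; the 400 mg ribociclib arm is parameterized to the trial's
regime (unbound non-enhancing ≈ 170 nM, Kp,uu ≈ 3) and everolimus
tumor rows are capped so unbound stays below the LLOQ, reproducing the
cohort-wide gate failure. The IHC generator plants a 30% mean Ki-67
decrease, a modest pRb decrease and slight pS6/p4EBP1 increases.

## Problem sizes and determinism

The default synthetic cohort (6 × 1500 cells, ≈ 5500 genes) runs the
full pipeline in about a minute on one CPU; tests and the acceptance
script use this scale, with smaller two-sample bundles for unit tests.
All randomness flows through explicit seeds (numpy Generator; the
igraph partition is seeded through Python's `random`), and a fixed seed
reproduces byte-identical count matrices and hash-identical per-cell
annotations and composition tables across runs. The pipeline driver
caches stage outputs and reruns only stages whose outputs are missing
or whose upstream reran.
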