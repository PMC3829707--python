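# Methods

This note documents the models, parameter choices, and numerical decisions
behind each stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coverage quantification

**Normalization.** Genes are partitioned at a provisional mean depth of
1000x; the bulk and highly expressed partitions are normalized separately,
because the read mass in the >1000x tail does not follow the distribution of
the rest of the genome and would otherwise dominate the scaling. Within each
partition, every replicate track (both strands, restricted to the
partition's gene footprint) is rescaled so that the replicate sums of each
time point equal that time point's mean of sums. Equalization is within time
points, not across all 15 samples: the normalization exists to make
biological replicates comparable for the CV analysis. Equalizing all samples
to one global total was evaluated and rejected — the cell cycle changes the
expression *composition* between stages, and a global target transfers that
swing into every constitutively expressed gene as a shared temporal
artifact, which the empirical-Bayes stage then mistakes for regulation.
Intergenic positions follow the bulk scaling. An all-zero replicate within a
partition is an error naming the replicate.

**Per-nucleotide CV.** Sample standard deviation over the replicates of one
time point divided by the mean, computed per strand. Positions with zero
mean get CV = 0: replicates that consistently report nothing are consistent,
so silent regions pass the filter and contribute zero coverage to gene
means. The cost of this convention is real: in genes expressed below ~1x,
most positions are all-zero (CV = 0) and a localized artifact at the few
covered positions is diluted below any threshold. Such genes are background
transcription by the classification below and are not quantifiable in
principle.

**Segmentation.** The CV signal is segmented by an exact dynamic program
minimizing the residual sum of squares of a piecewise-constant fit; the
number of segments k minimizes BIC = n·ln(RSS/n) + k·ln(n), with RSS floored
at a scale-aware epsilon (1e-12 × Σx²) so that numerically perfect fits tie
and ties resolve toward smaller k. The DP is O(n²k), so genome-scale signals
are processed in 10-kb windows; within each window the signal is averaged
into 25-nt bins and the DP runs exactly on the bins with max_segments =
max(2, window_length/250). Changepoints therefore land on 25-nt boundaries;
DP optimality holds exactly at bin resolution inside every window. 25 nt is
an order of magnitude below both the artifact scale emulated by the
generator (200-nt windows) and the 250-nt per-segment budget, so the
resolution loss is immaterial while the cost drops by ~625×. Segment means
for filtering are recomputed on the original per-nucleotide signal.

**Filtering and quantification.** Segments with mean CV above 1.0 are
discarded (high-CV regions are mapping artifacts, not signal). A gene's
expression per sample is the mean coverage over its retained nucleotides on
its own strand; genes losing every nucleotide fall back to the unfiltered
mean and are flagged, and every gene reports its retained fraction.

**Accuracy protocol.** The benefit of the filter is measured as RMSE on
log1p of time-point-mean expression against the generator truth, over genes
with planted peak ≥ 5x. The log scale is the appropriate accuracy scale for
a quantity that is power-law distributed over four decades; sub-5x genes are
excluded because they are the background stratum the pipeline itself labels
unquantifiable (see the CV = 0 dilution above). Under the default GC-noise
conditions (10% of windows, local replicate CV target 1.5) filtering reduces
this RMSE by roughly 25–40% depending on the seed.

## Expression structure

**Power law.** Continuous maximum likelihood: α̂ = 1 + n [Σ ln(xᵢ/x_min)]⁻¹.
When x_min is not fixed it is chosen to minimize the KS distance between the
tail and the fitted law over candidate cutoffs (the unique data values,
subsampled to ≤ 100). The continuous (not discrete) estimator is used
because expression values are averaged coverages, not integers.

**CV vs expression.** Tricube-weighted local linear regression (LOESS) of
per-gene CV on log expression, span 0.3 by default. Pooling over the time
course: per-gene expression is the mean of all 15 samples; per-gene CV is
the mean of the five per-time-point replicate CVs. Whether the study pooled
this way or computed one CV across all 15 samples is not determinable from
its text; the per-time-point average is used because a cross-sample CV would
conflate regulation with noise, and the choice is recorded in output
metadata.

**Groups.** low ⇔ maximal time-point mean < 5x; high ⇔ pooled mean > 1000x;
bulk otherwise. Group mean CVs are reported; on generator defaults the low
group is noisier than the bulk, reproducing the qualitative CV-vs-expression
shape.

## Cell-cycle-regulated gene detection

**Model space.** Each of the 2^(T−1) on/off choices of the T−1 boundaries
between consecutive time points defines a blocking of the time course into
contiguous equal-mean blocks; the zero-boundary blocking is the flat model,
and a distinguished silent model is appended (17 models for T = 5).
Up/down direction is read post hoc from fitted block means rather than
enforced by order constraints: the equal-mean groupings are the
likelihood-bearing structure, and order constraints would change the
likelihoods without a principled prior over directions.

**Priors.** For each model, Q = 100 genes are sampled; per block, a
method-of-moments NB (mean, dispersion) is estimated. Block means are stored
relative to the sampled gene's overall mean and re-anchored at the target
gene's own mean at likelihood time, so the prior carries block *shape* — the
quantity the model comparison is about — independent of expression scale.
Genes with zero counts are excluded from the sampling pool (they carry no
shape information and would inject degenerate zero-mean samples).

**Marginal likelihood.** Within a model, block parameters are a priori
independent: each block's likelihood is averaged over the Q prior samples
separately and the per-block marginals multiplied. This independence is what
creates the Occam factor — a model with more blocks must find prior support
matching every block separately, so needless splits are penalized. (A joint
draw of a whole gene's block profile lets many-block models imitate flat
genes for free and was rejected for exactly that failure.)

**Silent model.** NB with mean fixed at the 5th percentile of nonzero gene
means; its dispersion support is estimated from the sub-threshold gene
population itself and always includes strongly overdispersed points (φ = 1
and 10), since background transcription is bursty. Non-silent models anchor
their means at no less than the silent mean, so genuinely unexpressed genes
are captured by the silent model rather than by a flat model rescaled to
nothing.

**Posteriors and calls.** Model weights iterate as weight ∝ posterior mass
summed over genes (L∞ tolerance 1e-6, ≤ 100 iterations); genes with
non-finite likelihoods are flagged and excluded from weight estimation. The
CCR likelihood is the posterior mass on differential blockings; the call
threshold is 0.5 (the posterior favors regulation over constancy — the
study reports likelihoods without printing its cutoff). Expression values
are rounded to integers for the count likelihood; inference runs separately
on the >1000x partition and the bulk when the former has at least 50 genes,
mirroring the split normalization. Under the default scenario (2,000 genes,
25% CCR at geometric-mean fold 8.2, NB dispersion 0.05) sensitivity is
≈ 0.93 with FDR ≈ 0.05–0.09, and an all-flat genome yields essentially no
calls.

## Co-expression network

Signed adjacency ((1 + r)/2)^β with β = 36 as printed in the source study —
far above common soft-threshold defaults, but honored as the study's
parameter with a config override. TOM as defined above, vectorized via the
adjacency square with diagonal corrections. Modules: average-linkage
clustering of 1 − TOM cut at 0.995 of the maximum merge height, minimum
size 5; clusters below the minimum go to an unassigned pool. A plain static
height cut replaces dynamic tree-cut heuristics: it is deterministic,
simpler, and sufficient for planted-structure recovery. Module eigenvectors
come from the SVD of the per-gene standardized module matrix; the sign is
oriented so the mean gene contribution is positive, and contributions are
normalized to unit absolute sum (the study prints relative contributions
without defining a scale; this is this package's convention). The
network stage accepts a sample-selection mask; the default drop rule removes,
in each named time point, the replicate with the largest median distance to
its peers (the study dropped one replicate in three time points without
naming which).

## Phylogenetic signal

**Blomberg's K.** With V the Brownian tip covariance (V_ij = shared
root-to-MRCA path length), â the GLS grand mean, MSE₀ the ordinary and MSE
the V-weighted mean square, K = (MSE₀/MSE) / E[MSE₀/MSE] with
E[MSE₀/MSE] = [tr(V) − n/(1ᵀV⁻¹1)] / (n−1). On a star tree K = 1 exactly;
for Brownian traits on simulated trees the mean is ≈ 1. The p-value is the
fraction of tip permutations whose variance of standardized independent
contrasts is at most the observed (observed included in numerator and
denominator); the pruning recursion is flattened once per tree into an array
program, so permutations cost O(n) each. K permutations default to 999.

**SES-MPD / SES-MNTD.** MPD is the abundance-weighted mean pairwise
patristic distance among carrier species (weights = conservation counts; an
unweighted mode is provided since the study does not state the weighting);
MNTD the weighted mean nearest-carrier distance. The null shuffles profile
values across tips — the tree and distances stay fixed, and richness is
preserved automatically because values are permuted. z = (obs − null mean) /
null sd, with a degenerate-null guard (constant profiles get z = 0). The
library default is 9,999 randomizations; the pipeline and validation runs
use 999, where the z difference to the exhaustive small-tree null is < 0.01.

**Quadrants.** mpd_z ≤ −2 ⇒ quadrant 2 (or 3 if mntd_z ≤ −2 too): tree-wide
clustering. Only mntd_z ≤ −2 ⇒ quadrant 4: tip-level clustering. Otherwise
quadrant 1. The boundary is inclusive.

**Orthology and persistence.** Reciprocal best hits with similarity > 40%
in both directions and relative length difference < 20%, similarity ties
broken toward the lexicographically smallest subject. PI is the binary row
sum of the conservation matrix, with bands low (< 50) and persistent
(> 150). Representative-species selection cuts the tree at the depth whose
crossing-edge count is closest to the target clade number and draws one
uniform tip per clade.

## Synthetic-data generator

The generator emulates the *statistical* structure of the study, not its
sequences: an annotated GC-rich genome (no nucleotide sequence, only a GC
track whose fluctuation decorrelates over a few 200-nt windows, so high-GC
stretches stay localized); a power-law distribution of peak expression
(α = 1.74) split into the three strata at the study's group fractions
(738 : 3,136 : 90 of 3,964); planted CCR blockings drawn uniformly from the
16 contiguous patterns, with fold changes log-normal around geometric mean
8.2 — CCR flags are planted only in the bulk/high strata, since nearly all
regulated genes in such data exceed 5x and background noise genes cannot
carry a recoverable program; NB count noise (gene-level gamma with
dispersion 0.05, nucleotide-level Poisson); and GC-linked inconsistency as a
multiplicative log-normal factor per (affected window, replicate). The
log-normal sigma is calibrated by fixed-seed Monte Carlo so that the
*measured* replicate CV (3 samples) hits the target — the naive
distributional calibration undershoots badly because the few-sample CV
estimator is strongly biased down. Identical-sequence gene pairs share their
read mass evenly, emulating ambiguous mapping.

Conservation: an ultrametric constant-rate birth–death species tree
(dendropy, GSA sampling so terminal edges are not degenerate). Gene loss is
modeled as lineage-correlated, not iid per tip — loss is heritable, and iid
thinning produces no phylogenetic signal at all. Broadly conserved modules
keep a phylogenetically compact "core" clade (selected by mean within-clade
distance relative to the tree-wide mean) at light loss (scale/3) with heavy
loss outside (2× scale), giving the tree-wide clustering seen for widely
conserved modules; clade-specific modules occupy up to 16 two-tip clades
stratified along the tree's leaf order (clustered at the tips, spread over
the whole tree), jointly capped at 15% of species. Default loss scale 0.3
puts persistent genes in roughly two-thirds of species. End-to-end scenario
sizes chosen once: 236 species and 20 genes per module, matching the study's
counts.

What the generator does **not** emulate: read-level artifacts (mapping,
color-space errors, mismatch weighting — coverage is taken as already
weighted), operon structure and UTRs (genes are independent intervals),
sequence-driven GC bias (the affected windows are chosen by the GC track,
but the noise form is a stand-in — the study reports the phenomenon without
a generative model), horizontal transfer or gene gain in the conservation
matrix, and any real ortholog-detection noise. Passing tests therefore show
that each stage recovers what it is designed to recover under this noise
model; they do not certify performance on real libraries with unmodeled
artifacts.

## Problem sizes and determinism

Validation runs use: 200 random segmentation instances (n ≤ 12, k ≤ 4)
against exhaustive enumeration; 50 random 8-gene adjacencies against the
literal TOM formula; 50,000 power-law draws; a 200-gene / 200-kb coverage
simulation for the filter-accuracy comparison; 2,000 genes for CCR recovery
and for the all-flat null; 10 planted modules × 30 genes + 50 noise genes
for module recovery; 500 Brownian traits on a 64-tip tree for K; the
exhaustive 720-permutation null on 6 tips and 200 random profiles on 48 tips
for SES calibration; and 10 broad + 10 clade modules of 20 genes on 236
species for the quadrant analysis. All randomness flows from explicit seeds;
identical seeds give byte-identical outputs for every writer.

## Known limitations

- Sub-1x genes are unquantifiable under the zero-mean CV convention; they
  are classified as background, which is the intended reading, but a user
  looking for faint regulated transcripts will not find them.
- The composition of strongly regulated genes still leaks marginally into
  flat genes through per-time-point normalization when the genome is small
  (the end-to-end demo at 200 genes shows FDR ≈ 0.15–0.20 on
  coverage-derived counts versus ≈ 0.05–0.09 on direct counts at 2,000
  genes).
- β = 36 makes the adjacency numerically extreme (cor 0 maps to 1.5e-11);
  module detection effectively sees only strong positive correlations,
  which is the study's design but limits sensitivity to weaker co-expression.
- The quadrant classification inherits the randomization null's
  granularity: with 999 draws the attainable two-sided p floor is 2e-3,
  ample for a −2 z-score threshold but not for finer claims.
- The silent model's heavy-dispersion support points (φ = 1, 10) are a
  pragmatic device to keep all-zero genes out of the expressed models; their
  exact values are uncritical (any strong overdispersion works) but they are
  not data-estimated when no sub-threshold genes exist.
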