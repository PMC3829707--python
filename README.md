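# cycleseq

Analysis pipeline for bacterial cell-cycle transcriptomics from strand-specific
RNA-Seq coverage, modeled on the *Caulobacter crescentus* cell cycle (five
synchronized stages — swarmer, stalked, early predivisional, predivisional,
late predivisional — with three biological replicates each). It covers the
whole chain from per-nucleotide coverage tracks to the evolutionary analysis
of co-expression modules, together with a synthetic-data generator that
emulates the statistical structure of such a study so every stage can be
validated against planted ground truth.

## Who this is for

Microbial transcriptomics groups quantifying expression from deep coverage
tracks on GC-rich genomes, where inter-replicate inconsistency is locally
severe and correlates with GC content; and systems/evolutionary biologists
relating co-expression structure to gene conservation across a species
phylogeny.

## What it computes

**Quantification with replicate-CV filtering.** Replicate tracks are
normalized per time point (bulk and >1000x genes separately). The
per-nucleotide coefficient of variation CV = σ/μ across replicates is
segmented by an exact least-squares dynamic program (BIC model selection),
segments with mean CV > 1 are discarded, and a gene's expression is the mean
coverage over its retained nucleotides.

**Expression structure.** The gene-expression distribution follows a power
law p(e) ∝ e^(−α); α is fit by continuous maximum likelihood,
α̂ = 1 + n [Σ ln(xᵢ/x_min)]⁻¹, with x_min chosen to minimize the
Kolmogorov–Smirnov distance. Genes split into three groups: low (<5x, noisy,
background transcription), bulk (5–1000x, CV plateau ≈ 0.23), and highly
expressed (>1000x, elevated CV).

**Cell-cycle-regulated (CCR) genes.** An empirical-Bayes negative-binomial
model selection over all 2⁴ contiguous up/down blockings of the five time
points, plus a silent model (17 models). Marginal likelihoods integrate over
data-sampled priors with a-priori-independent blocks; per-gene posteriors use
iteratively estimated model weights. A gene's CCR likelihood is its posterior
mass on differential blockings.

**Signed co-expression network.** a_ij = ((1 + cor(x_i, x_j))/2)^β with
β = 36, topological overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1
− a_ij), average-linkage modules (minimum size 5), and per-module
eigenvectors: the first singular direction of the standardized module
matrix, with variance explained and per-gene contributions.

**Phylogenetic signal of modules.** Each module's conservation profile
(per-species count of conserved member genes) is a trait on the species
tree. Blomberg's K with a permutation p-value from independent-contrast
variances; abundance-weighted mean pairwise distance (MPD) and mean nearest
taxon distance (MNTD) standardized against a tip-shuffle null (z-scores).
Modules classify into quadrants at z ≤ −2: tree-wide clustering (quadrants
2/3), tip-level / clade-specific clustering (quadrant 4), no signal
(quadrant 1). Also here: reciprocal-best-hit orthology (similarity > 40%,
length difference < 20%), the gene persistence index (PI = number of
carrier species; persistent means PI > 150 of 236), and representative
species selection by clade cutting.

## Worked example

Run the full pipeline on a synthetic dataset (200 genes, 120 kb genome, 5
time points × 3 replicates, 80 species tree with planted broad and
clade-specific conservation modules):

```
cycleseq run --seed 4 --outdir run4
cycleseq report run4
```

The report (`run4/report.json`) from this exact command:

```json
{
  "sections": {
    "quantify": {"n_genes": 200, "mean_retained_fraction": 0.825},
    "classify": {"group_sizes": {"bulk": 159, "low": 38, "high": 3}},
    "de": {"n_ccr": 95},
    "network": {"n_modules": 5, "median_variance_explained": 0.711},
    "phylo": {"quadrant_tally": {"2": 3, "4": 3}}
  }
}
```

Reading it: 82.5% of nucleotides survived the CV > 1 filter; the genome
splits into 38 low / 159 bulk / 3 highly expressed genes; 95 genes are
called cell-cycle regulated (80 were planted — the residual excess comes
from GC-noise windows that slip under the CV threshold); they cluster into
5 co-expression modules; and of the 6 planted conservation modules the 3
broadly conserved ones land in quadrant 2 (tree-wide clustering) and the 3
clade-specific ones in quadrant 4 (tip-level clustering), matching the
planted truth. The run directory also holds the expression matrix, CCR
table (likelihood, best pattern, fold change, peak), module membership and
eigenvectors, the per-module phylogeny table (K, K p-value, MPD/MNTD
z-scores, quadrant), and a provenance manifest with seeds and checksums.

Every stage is also callable as a library function; see the module
docstrings in `src/cycleseq/`.

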