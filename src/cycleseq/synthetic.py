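"""Synthetic data generator for the whole pipeline.

Emulates the statistical structure of a bacterial cell-cycle RNA-Seq study:
a GC-rich annotated genome, strand-specific per-nucleotide coverage for 5
time points x 3 replicates with overdispersed count noise and GC-linked
replicate inconsistency, a heavy-tailed (power-law) distribution of
expression levels in three strata (low-noisy / bulk / highly expressed),
planted cell-cycle expression patterns, and a birth-death species tree with
planted broadly conserved and clade-specific co-conservation modules.

Every generated dataset carries its ground truth, so parameter-recovery
tests can compare pipeline output against what was planted.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from cycleseq import de
from cycleseq.coverage import CoverageExperiment

N_TIMEPOINTS = 5
N_REPLICATES = 3

#: group-size defaults: low(<5x) / bulk(5-1000x) / high(>1000x) strata and the
#: cell-cycle-regulated fraction, as proportions of an ~4k-gene genome
DEFAULT_STRATUM_FRACTIONS = (738 / 3964, 3136 / 3964, 90 / 3964)
DEFAULT_CCR_FRACTION = 1586 / 3964
DEFAULT_FOLD_CHANGE_MEAN = 8.2
DEFAULT_POWER_LAW_ALPHA = 1.74

LOW_CUT = 5.0
HIGH_CUT = 1000.0


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def _default_gc_profile(window: int) -> float:
    # GC-rich genome (~0.67); fluctuation decorrelates over a few windows so
    # high-GC stretches stay localized (a window is ~200 nt)
    return (
        0.67
        + 0.08 * np.sin(2.39 * window)
        + 0.05 * np.sin(0.71 * window + 1.3)
    )


@dataclass
class GenomeSpec:
    genome_length: int = 200_000
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (300, 1200)
    strand_fraction: float = 0.5
    gc_profile: Callable[[int], float] = _default_gc_profile
    duplicate_gene_pairs: int = 1
    gc_window: int = 200

    def validate(self) -> None:
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid gene_length_range")
        if not 0.0 <= self.strand_fraction <= 1.0:
            raise ValueError("strand_fraction must be in [0,1]")
        if self.duplicate_gene_pairs * 2 > self.n_genes:
            raise ValueError("not enough genes for the requested duplicate pairs")


def generate_genome(spec: GenomeSpec, seed: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Place non-overlapping stranded genes and evaluate the GC track.

    Returns a gene table (0-based, half-open, stranded; ``dup_group`` >= 0
    marks genes sharing a sequence-identity group) and per-window GC
    fractions.  Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n_windows = -(-spec.genome_length // spec.gc_window)
    gc = np.clip([spec.gc_profile(w) for w in range(n_windows)], 0.0, 1.0)
    gc = np.asarray(gc)

    if spec.n_genes == 0:
        ann = pd.DataFrame(
            columns=["gene_id", "start", "end", "strand", "dup_group"]
        )
        return ann, gc

    n_plus = int(round(spec.strand_fraction * spec.n_genes))
    rows = []
    gid = 0
    for strand, n_s in (("+", n_plus), ("-", spec.n_genes - n_plus)):
        if n_s == 0:
            continue
        lengths = rng.integers(
            spec.gene_length_range[0], spec.gene_length_range[1] + 1, size=n_s
        )
        slack = spec.genome_length - int(lengths.sum())
        if slack < 0:
            raise ValueError(
                f"cannot pack {n_s} genes of total length {lengths.sum()} "
                f"into genome of length {spec.genome_length} on strand {strand}"
            )
        # distribute the slack as random intergenic gaps (n_s + 1 gaps)
        gaps = rng.multinomial(slack, np.full(n_s + 1, 1.0 / (n_s + 1)))
        pos = 0
        for i in range(n_s):
            pos += int(gaps[i])
            rows.append(
                {
                    "gene_id": f"g{gid:04d}",
                    "start": pos,
                    "end": pos + int(lengths[i]),
                    "strand": strand,
                    "dup_group": -1,
                }
            )
            pos += int(lengths[i])
            gid += 1
    ann = pd.DataFrame(rows).sort_values(["start", "strand"]).reset_index(drop=True)

    # mark identical-sequence pairs (ambiguous mapping emulation)
    if spec.duplicate_gene_pairs:
        pick = rng.choice(
            len(ann), size=2 * spec.duplicate_gene_pairs, replace=False
        )
        for grp in range(spec.duplicate_gene_pairs):
            ann.loc[pick[2 * grp : 2 * grp + 2], "dup_group"] = grp
    return ann, gc


# ---------------------------------------------------------------------------
# expression programs
# ---------------------------------------------------------------------------


@dataclass
class ExpressionProgram:
    gene_id: str
    stratum: str  # low | bulk | high
    base_level: float  # expected peak coverage depth (x-fold)
    timepoint_multipliers: np.ndarray  # 5 positive reals, max = 1
    is_ccr: bool
    pattern_id: str | None = None

    @property
    def levels(self) -> np.ndarray:
        return self.base_level * self.timepoint_multipliers


def _truncated_pareto(
    rng: np.random.Generator, alpha: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Inverse-CDF sampling of a power law p(x) ~ x^-alpha on [lo, hi]."""
    a = alpha - 1.0
    u = rng.random(size)
    return lo * (1 - u * (1 - (lo / hi) ** a)) ** (-1 / a)


def assign_programs(
    n_genes: int,
    stratum_fractions: tuple[float, float, float] = DEFAULT_STRATUM_FRACTIONS,
    ccr_fraction: float = DEFAULT_CCR_FRACTION,
    fold_change_mean: float = DEFAULT_FOLD_CHANGE_MEAN,
    seed: int = 0,
    n_timepoints: int = N_TIMEPOINTS,
    alpha: float = DEFAULT_POWER_LAW_ALPHA,
    fold_sigma: float = 0.5,
    gene_ids: list[str] | None = None,
) -> list[ExpressionProgram]:
    """Draw per-gene expression programs.

    Peak levels follow a truncated power law with exponent ``alpha`` within
    each stratum's depth range (low <5x, bulk 5-1000x, high >1000x), so the
    pooled bulk+high distribution is heavy-tailed with the generating
    exponent.  CCR genes get a planted contiguous up/down blocking drawn
    uniformly from the differential model space, with a max/min multiplier
    ratio drawn log-normally around ``fold_change_mean`` (geometric mean).
    """
    fr = np.asarray(stratum_fractions, dtype=float)
    if np.any(fr < 0) or np.any(fr > 1) or not np.isclose(fr.sum(), 1.0):
        raise ValueError("stratum fractions must lie in [0,1] and sum to 1")
    if not 0.0 <= ccr_fraction <= 1.0:
        raise ValueError("ccr_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(n_genes)]

    counts = np.floor(fr * n_genes).astype(int)
    counts[np.argmax(fr)] += n_genes - counts.sum()
    strata = np.repeat(["low", "bulk", "high"], counts)
    rng.shuffle(strata)

    # CCR genes are regulated genes, not background: planted only in the
    # bulk/high strata (in the study, nearly all CCR genes exceed 5x)
    eligible = np.flatnonzero(strata != "low")
    n_ccr = min(int(round(ccr_fraction * n_genes)), len(eligible))
    ccr_idx = set(rng.choice(eligible, size=n_ccr, replace=False).tolist())
    patterns = de.differential_models(de.enumerate_models(n_timepoints))

    peaks = np.empty(n_genes)
    for name, lo, hi in (("low", 0.5, LOW_CUT * 0.98), ("bulk", LOW_CUT, HIGH_CUT),
                         ("high", HIGH_CUT, 20 * HIGH_CUT)):
        sel = strata == name
        peaks[sel] = _truncated_pareto(rng, alpha, lo, hi, int(sel.sum()))

    programs = []
    for i in range(n_genes):
        if i in ccr_idx:
            pat = patterns[rng.integers(len(patterns))]
            fold = float(
                np.exp(np.log(fold_change_mean) + fold_sigma * rng.normal())
            )
            fold = max(fold, 1.2)  # a planted pattern is never quieter than this
            blocks = np.asarray(pat.blocks)
            u = rng.random(pat.n_blocks)
            u = (u - u.min()) / max(u.max() - u.min(), 1e-12)  # span [0, 1]
            mult = fold ** (u[blocks] - 1.0)  # multipliers span [1/fold, 1]
            programs.append(
                ExpressionProgram(
                    gene_ids[i], str(strata[i]), float(peaks[i]), mult, True,
                    pat.pattern_id,
                )
            )
        else:
            programs.append(
                ExpressionProgram(
                    gene_ids[i], str(strata[i]), float(peaks[i]),
                    np.ones(n_timepoints), False, None,
                )
            )
    return programs


def programs_to_frame(programs: list[ExpressionProgram]) -> pd.DataFrame:
    rows = []
    for p in programs:
        row = {
            "gene_id": p.gene_id,
            "stratum": p.stratum,
            "base_level": p.base_level,
            "is_ccr": p.is_ccr,
            "pattern_id": p.pattern_id if p.pattern_id else "",
        }
        for t, m in enumerate(p.timepoint_multipliers):
            row[f"mult_t{t}"] = m
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------------


@dataclass
class GcNoise:
    """GC-linked replicate inconsistency: a multiplicative log-normal factor
    per (affected window, replicate) whose variance is set to reach
    ``cv_target`` locally.  Windows with the highest GC are affected."""

    affected_fraction: float = 0.1
    cv_target: float = 1.5


def _gc_sigma(cv_target: float, n_replicates: int) -> float:
    """Log-normal sigma whose *measured* replicate CV hits ``cv_target``.

    The sample CV of a few log-normal draws is strongly biased below the
    distributional CV (with 3 replicates it cannot exceed sqrt(3) ~ 1.73),
    so sigma is calibrated by bisection against a fixed-seed Monte Carlo
    median of the n-replicate sample CV.
    """
    if cv_target <= 0:
        return 0.0
    rng = np.random.default_rng(1234)
    z = rng.normal(size=(20_000, n_replicates))

    def median_cv(sigma: float) -> float:
        f = np.exp(sigma * z)
        return float(np.median(f.std(axis=1, ddof=1) / f.mean(axis=1)))

    lo, hi = 1e-3, 8.0
    if median_cv(hi) < cv_target:
        return hi  # target beyond what n replicates can express
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if median_cv(mid) < cv_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _expected_tracks(
    annotation: pd.DataFrame,
    programs: list[ExpressionProgram],
    genome_length: int,
    n_timepoints: int,
) -> dict[tuple[int, str], np.ndarray]:
    """Noise-free expected coverage per (timepoint, strand); reads from
    identical-sequence gene groups are split evenly across the copies."""
    prog = {p.gene_id: p for p in programs}
    # per-gene expected level per timepoint, after ambiguous-mapping split
    levels = {g: prog[g].levels.copy() for g in prog}
    if "dup_group" in annotation.columns:
        for grp, members in annotation[annotation["dup_group"] >= 0].groupby(
            "dup_group"
        ):
            ids = list(members["gene_id"])
            pooled = np.sum([prog[g].levels for g in ids], axis=0) / len(ids)
            for g in ids:
                levels[g] = pooled.copy()
    exp = {
        (t, s): np.zeros(genome_length)
        for t in range(n_timepoints)
        for s in ("+", "-")
    }
    for row in annotation.itertuples():
        for t in range(n_timepoints):
            exp[(t, row.strand)][row.start : row.end] = levels[row.gene_id][t]
    return exp


def simulate_coverage(
    annotation: pd.DataFrame,
    programs: list[ExpressionProgram],
    gc_track: np.ndarray,
    genome_length: int,
    n_timepoints: int = N_TIMEPOINTS,
    n_replicates: int = N_REPLICATES,
    gc_noise: GcNoise | None = None,
    dispersion: float = 0.05,
    nucleotide_noise: bool = True,
    gc_window: int = 200,
    seed: int = 0,
) -> CoverageExperiment:
    """Simulate replicate coverage tracks from planted expression programs.

    The count-noise model is negative binomial at gene level (a gamma
    multiplier with dispersion ``dispersion`` around the expected gene mean)
    and Poisson at nucleotide level around the gene mean.  With
    ``dispersion = 0``, ``nucleotide_noise = False`` and no GC noise, the
    replicates are identical to the expected coverage.
    """
    if gc_noise is None:
        gc_noise = GcNoise()
    rng = np.random.default_rng(seed)
    expected = _expected_tracks(annotation, programs, genome_length, n_timepoints)

    # flag the highest-GC windows as inconsistency-prone
    n_windows = len(gc_track)
    n_affected = int(round(gc_noise.affected_fraction * n_windows))
    affected = np.zeros(n_windows, dtype=bool)
    if n_affected > 0:
        order = np.argsort(gc_track + 1e-9 * rng.random(n_windows))
        affected[order[-n_affected:]] = True
    sigma = _gc_sigma(gc_noise.cv_target, n_replicates)
    sigma2 = sigma**2

    tracks: dict[tuple[int, int, str], np.ndarray] = {}
    for t in range(n_timepoints):
        for r in range(n_replicates):
            # one gene-level gamma factor per (gene, replicate, timepoint)
            gene_factor = {}
            for p in programs:
                if dispersion > 0:
                    shape = 1.0 / dispersion
                    gene_factor[p.gene_id] = rng.gamma(shape, dispersion)
                else:
                    gene_factor[p.gene_id] = 1.0
            for strand in ("+", "-"):
                base = expected[(t, strand)].copy()
                for row in annotation.itertuples():
                    base[row.start : row.end] *= gene_factor[row.gene_id]
                if nucleotide_noise:
                    base = rng.poisson(base).astype(float)
                if n_affected > 0:
                    # per-(window, replicate) multiplicative log-normal shock
                    factors = np.exp(
                        rng.normal(-sigma2 / 2, sigma, size=n_windows)
                    )
                    factors[~affected] = 1.0
                    per_nt = np.repeat(factors, gc_window)[:genome_length]
                    base *= per_nt
                tracks[(t, r, strand)] = base
    exp = CoverageExperiment(tracks, annotation, genome_length)
    exp.validate()
    return exp


@dataclass
class SimulatedExperiment:
    """Bundle of a simulated dataset with its ground truth."""

    experiment: CoverageExperiment
    programs: list[ExpressionProgram]
    gc_track: np.ndarray
    spec: GenomeSpec

    @property
    def truth_expression(self) -> pd.DataFrame:
        """Expected expression (genes x timepoints), after duplicate split."""
        prog = {p.gene_id: p for p in self.programs}
        levels = {g: prog[g].levels.copy() for g in prog}
        ann = self.experiment.annotation
        for grp, members in ann[ann["dup_group"] >= 0].groupby("dup_group"):
            ids = list(members["gene_id"])
            pooled = np.sum([prog[g].levels for g in ids], axis=0) / len(ids)
            for g in ids:
                levels[g] = pooled
        return pd.DataFrame(
            {g: levels[g] for g in ann["gene_id"]},
        ).T.rename_axis("gene_id")


def simulate_experiment(
    spec: GenomeSpec | None = None,
    seed: int = 0,
    gc_noise: GcNoise | None = None,
    dispersion: float = 0.05,
    nucleotide_noise: bool = True,
    **program_kwargs,
) -> SimulatedExperiment:
    """Convenience wrapper: genome -> programs -> coverage, with one seed."""
    if spec is None:
        spec = GenomeSpec()
    rng = np.random.default_rng(seed)
    s_genome, s_prog, s_cov = rng.integers(0, 2**31 - 1, size=3)
    ann, gc = generate_genome(spec, int(s_genome))
    programs = assign_programs(
        spec.n_genes, seed=int(s_prog), gene_ids=list(ann["gene_id"]),
        **program_kwargs,
    )
    exp = simulate_coverage(
        ann,
        programs,
        gc,
        spec.genome_length,
        gc_noise=gc_noise,
        dispersion=dispersion,
        nucleotide_noise=nucleotide_noise,
        gc_window=spec.gc_window,
        seed=int(s_cov),
    )
    return SimulatedExperiment(exp, programs, gc, spec)


def simulate_expression_counts(
    programs: list[ExpressionProgram],
    n_replicates: int = N_REPLICATES,
    dispersion: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-level expression counts straight from the programs.

    Bypasses the coverage layer: counts[g, (t, r)] ~ NB(mean = planted level,
    dispersion) via the gamma-Poisson mixture.  Useful for testing the
    differential-expression and network stages at scale.
    """
    rng = np.random.default_rng(seed)
    n_t = len(programs[0].timepoint_multipliers)
    cols = pd.MultiIndex.from_product(
        [range(n_t), range(n_replicates)], names=["timepoint", "replicate"]
    )
    data = np.zeros((len(programs), len(cols)))
    for gi, p in enumerate(programs):
        for ci, (t, r) in enumerate(cols):
            mean = p.levels[t]
            if dispersion > 0:
                lam = mean * rng.gamma(1.0 / dispersion, dispersion)
            else:
                lam = mean
            data[gi, ci] = rng.poisson(lam)
    return pd.DataFrame(
        data, index=pd.Index([p.gene_id for p in programs], name="gene_id"),
        columns=cols,
    )


def simulate_module_expression(
    n_modules: int,
    genes_per_module: int = 30,
    n_noise_genes: int = 50,
    noise_sd: float = 0.3,
    n_timepoints: int = N_TIMEPOINTS,
    n_replicates: int = N_REPLICATES,
    max_profile_cor: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted co-expression structure for the network stage.

    Each module gets a time-course profile drawn by rejection so that no two
    module profiles correlate above ``max_profile_cor`` (modules with nearly
    collinear profiles are one co-expression cluster, not two); member genes
    are the profile (replicated across replicates) plus Gaussian noise, and
    noise genes are pure noise.  Returns the expression matrix and the true
    labels (-1 = noise gene).
    """
    rng = np.random.default_rng(seed)
    profiles: list[np.ndarray] = []
    attempts = 0
    while len(profiles) < n_modules:
        cand = rng.normal(size=n_timepoints)
        cand = (cand - cand.mean()) / cand.std()
        if all(
            abs(np.corrcoef(cand, p)[0, 1]) <= max_profile_cor for p in profiles
        ):
            profiles.append(cand)
        attempts += 1
        if attempts > 10_000:
            raise ValueError(
                f"cannot place {n_modules} profiles with pairwise |cor| <= "
                f"{max_profile_cor} over {n_timepoints} time points"
            )
    cols = pd.MultiIndex.from_product(
        [range(n_timepoints), range(n_replicates)],
        names=["timepoint", "replicate"],
    )
    rows, labels, ids = [], [], []
    for m, prof in enumerate(profiles):
        for g in range(genes_per_module):
            rows.append(
                np.repeat(prof, n_replicates)
                + noise_sd * rng.normal(size=len(cols))
            )
            labels.append(m)
            ids.append(f"m{m:02d}_g{g:03d}")
    for g in range(n_noise_genes):
        rows.append(rng.normal(size=len(cols)))
        labels.append(-1)
        ids.append(f"noise_g{g:03d}")
    expr = pd.DataFrame(rows, index=pd.Index(ids, name="gene_id"), columns=cols)
    return expr, pd.Series(labels, index=expr.index, name="true_module")


# ---------------------------------------------------------------------------
# species tree and conservation
# ---------------------------------------------------------------------------


def _brownian_tip_field(tree: dendropy.Tree, rng: np.random.Generator) -> dict:
    """One Brownian-motion draw over the tree, evaluated at the tips."""
    value = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        el = node.edge.length or 0.0
        value[id(node)] = value[id(node.parent_node)] + rng.normal(
            0.0, np.sqrt(max(el, 1e-12))
        )
    return {leaf.taxon.label: value[id(leaf)] for leaf in tree.leaf_nodes()}


def _pick_cohesive_core(
    tree: dendropy.Tree,
    core_nodes: list,
    rng: np.random.Generator,
    distances: pd.DataFrame | None = None,
) -> set:
    """Pick a dense-conservation core clade that is phylogenetically compact.

    Candidates are scored by their mean within-clade patristic distance
    relative to the tree-wide mean pairwise distance; a clade whose tips
    share most of their history scores low.  The largest clade scoring
    <= 0.7 is used (the tree's conserved backbone, shared by the broad
    modules); if none qualifies the lowest-scoring candidate is used.
    """
    if distances is None:
        from cycleseq.phylo import tree_distance_matrix

        distances = tree_distance_matrix(tree)
    d = distances.values
    n = d.shape[0]
    grand = d.sum() / (n * (n - 1))
    pos = {label: i for i, label in enumerate(distances.index)}
    scored = []
    for node in core_nodes:
        idx = [pos[l.taxon.label] for l in node.leaf_iter()]
        sub = d[np.ix_(idx, idx)]
        within = sub.sum() / (len(idx) * (len(idx) - 1))
        scored.append((within / grand, node))
    good = [n_ for s, n_ in scored if s <= 0.7]
    if good:
        pick = max(good, key=lambda n_: len(n_.leaf_nodes()))
    else:
        pick = min(scored, key=lambda t: t[0])[1]
    return {l.taxon.label for l in pick.leaf_iter()}


def simulate_tree_and_conservation(
    n_species: int,
    module_truths: list[dict],
    loss_probability: float = 0.3,
    seed: int = 0,
    birth_rate: float = 1.0,
    death_rate: float = 0.5,
    clade_max_fraction: float = 0.15,
    field_strength: float = 1.5,
) -> tuple[dendropy.Tree, pd.DataFrame, pd.DataFrame]:
    """Simulate an ultrametric birth-death species tree and a planted
    gene x species presence matrix.

    Each module truth is ``{"module_id", "depth_class" ("broad"|"clade"),
    "size"}``.

    Broad modules originate at the root; their per-tip loss probabilities
    form a phylogenetically autocorrelated field (a Brownian draw on the
    tree, exponentiated and scaled so the mean per-tip loss equals
    ``loss_probability``), shared by the module's genes.  Gene loss is a
    heritable, lineage-correlated process, so a broadly conserved module is
    denser in some parts of the tree than others — tree-wide clustering —
    rather than uniformly thinned.

    Clade modules occupy a few narrow clades (each subtending at most
    ``clade_max_fraction`` of the tips, jointly capped at the same fraction)
    scattered over the tree, with the per-tip loss probability applied
    uniformly inside them: their species are clustered near the tips
    (strongly low nearest-taxon distances) without tree-wide clustering.

    A gene losing every tip is redrawn so each gene survives somewhere.
    """
    if n_species < 4:
        raise ValueError("need at least 4 species")
    pyrng = random.Random(seed)
    # GSA sampling: without it the simulation stops exactly at the n-th
    # birth, leaving zero-length terminal edges (a singular tip covariance)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_species,
        gsa_ntax=n_species + max(2, n_species // 10),
        rng=pyrng,
        is_retain_extinct_tips=False,
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"s{i:04d}"
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]

    # candidate origins for clade-specific modules
    clade_cap = max(2, int(np.floor(clade_max_fraction * n_species)))
    internal = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        n_desc = len(node.leaf_nodes())
        if 2 <= n_desc <= clade_cap:
            internal.append(node)
    if not internal:
        raise ValueError("tree has no clade small enough for clade modules")
    for j, node in enumerate(internal):
        node.label = node.label or f"n{j:04d}"
    tree.seed_node.label = tree.seed_node.label or "root"

    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for mt in module_truths:
        if mt["depth_class"] == "broad":
            origin_label = tree.seed_node.label
            # one coherent dense region: retention is higher inside a deep
            # "core" clade (a large ancestral retention event), iid thinning
            # elsewhere, scaled so the mean per-tip loss is loss_probability
            core_nodes = [
                n
                for n in tree.preorder_internal_node_iter()
                if n is not tree.seed_node
                and 0.10 * n_species <= len(n.leaf_nodes()) <= 0.6 * n_species
            ]
            loss_tip = np.full(len(species), loss_probability)
            if core_nodes and loss_probability > 0:
                # the core must be a *cohesive* deep clade: long shared stem,
                # so within-core distances are well below the tree-wide mean
                # (a clade splitting right at the root carries no signal)
                core_tips = _pick_cohesive_core(tree, core_nodes, rng)
                in_core = np.array([sp in core_tips for sp in species])
                # loss_probability sets the scale: light loss in the core,
                # heavy outside, a fixed contrast regardless of core size
                li = loss_probability / 3.0
                lo = min(2.0 * loss_probability, 0.95)
                loss_tip = np.where(in_core, li, lo)
            allowed = np.ones(len(species), dtype=bool)
        elif mt["depth_class"] == "clade":
            # several narrow clades (2-4 tips) scattered over the tree:
            # tip-level clustering without tree-wide clustering
            narrow = [n for n in internal if len(n.leaf_nodes()) <= 2]
            if not narrow:
                narrow = [n for n in internal if len(n.leaf_nodes()) <= 3]
            cap = max(2, int(np.floor(clade_max_fraction * n_species)))
            # stratified placement along the tree's leaf order: clumps are
            # spread over the whole tree, not concentrated in one region
            leaf_pos = {
                leaf.taxon.label: i
                for i, leaf in enumerate(tree.leaf_node_iter())
            }
            narrow = sorted(
                narrow, key=lambda n: min(leaf_pos[l.taxon.label]
                                          for l in n.leaf_iter())
            )
            n_clumps = min(16, len(narrow), cap // 2)
            phase = rng.random()
            idxs = (
                np.floor((np.arange(n_clumps) + phase) * len(narrow) / n_clumps)
                .astype(int) % len(narrow)
            )
            chosen, covered = [], set()
            for idx in idxs:
                node = narrow[idx]
                tips = {leaf.taxon.label for leaf in node.leaf_iter()}
                if tips & covered or len(covered) + len(tips) > cap:
                    continue
                chosen.append(node)
                covered |= tips
            if not chosen:
                raise ValueError("no narrow clades available for clade module")
            origin_label = ";".join(n.label for n in chosen)
            allowed = np.array([sp in covered for sp in species])
            loss_tip = np.full(len(species), loss_probability)
        else:
            raise ValueError(f"unknown depth_class {mt['depth_class']!r}")
        for k in range(mt["size"]):
            gid = f"{mt['module_id']}_g{k:03d}"
            while True:
                keep = allowed & (rng.random(len(species)) >= loss_tip)
                if keep.any():
                    break
            rows.append(
                {"gene_id": gid, **{sp: int(v) for sp, v in zip(species, keep)}}
            )
            truth_rows.append(
                {
                    "gene_id": gid,
                    "module_id": mt["module_id"],
                    "depth_class": mt["depth_class"],
                    "origin_node": origin_label,
                    "loss_probability": loss_probability,
                }
            )
    conservation = pd.DataFrame(rows).set_index("gene_id")[species]
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return tree, conservation, truth
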