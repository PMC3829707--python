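"""Replicate coverage tracks -> gene expression.

The quantification chain is: split normalization of replicate tracks at a
depth threshold, per-nucleotide coefficient of variation (CV) across the
replicates of each time point, exact dynamic-programming segmentation of the
CV signal into piecewise-constant segments, removal of high-CV segments, and
mean coverage over the retained nucleotides of each gene.

Coordinates are 0-based half-open internally; GFF3 (1-based closed) and
bedGraph (0-based half-open) are converted at the I/O boundary only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRANDS = ("+", "-")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CoverageExperiment:
    """Per-nucleotide, per-strand coverage for every (time point, replicate).

    ``tracks`` maps ``(timepoint, replicate, strand)`` to a float array of
    length ``genome_length``; ``annotation`` holds stranded gene intervals
    (columns: gene_id, start, end, strand, and optionally dup_group).
    """

    tracks: dict[tuple[int, int, str], np.ndarray]
    annotation: pd.DataFrame
    genome_length: int

    @property
    def timepoints(self) -> list[int]:
        return sorted({t for t, _, _ in self.tracks})

    @property
    def replicates(self) -> list[int]:
        return sorted({r for _, r, _ in self.tracks})

    def copy(self) -> "CoverageExperiment":
        return CoverageExperiment(
            {k: v.copy() for k, v in self.tracks.items()},
            self.annotation.copy(),
            self.genome_length,
        )

    def validate(self) -> None:
        for key, track in self.tracks.items():
            if len(track) != self.genome_length:
                raise ValueError(f"track {key} length != genome_length")
            if np.any(track < 0):
                raise ValueError(f"track {key} has negative coverage")


@dataclass
class Segmentation:
    """Piecewise-constant segmentation of a 1-D signal.

    ``changepoints`` are segment bounds (0-based, half-open): segment ``i``
    covers ``[changepoints[i], changepoints[i+1])``.
    """

    changepoints: np.ndarray  # length n_segments + 1
    segment_means: np.ndarray
    retained: np.ndarray | None = None

    @property
    def n_segments(self) -> int:
        return len(self.segment_means)


@dataclass
class ExpressionMatrix:
    """Genes x (timepoint, replicate) expression with QC annotations."""

    values: pd.DataFrame  # index gene_id, columns MultiIndex (timepoint, replicate)
    retained_fraction: pd.Series
    fallback_flag: pd.Series  # True where no nucleotide survived filtering
    timepoint_means: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.timepoint_means = self.values.T.groupby(level=0).mean().T


# ---------------------------------------------------------------------------
# split normalization
# ---------------------------------------------------------------------------


def _gene_footprint_masks(
    annotation: pd.DataFrame, genome_length: int, gene_set: set
) -> dict[str, np.ndarray]:
    masks = {s: np.zeros(genome_length, dtype=bool) for s in STRANDS}
    for row in annotation.itertuples():
        if row.gene_id in gene_set:
            masks[row.strand][row.start : row.end] = True
    return masks


def provisional_gene_means(experiment: CoverageExperiment) -> pd.Series:
    """Mean coverage of each gene over all tracks of its own strand."""
    means = {}
    by_strand = {
        s: np.mean(
            [trk for (t, r, st), trk in experiment.tracks.items() if st == s], axis=0
        )
        for s in STRANDS
    }
    for row in experiment.annotation.itertuples():
        means[row.gene_id] = float(by_strand[row.strand][row.start : row.end].mean())
    return pd.Series(means, name="provisional_mean")


def normalize_split(
    experiment: CoverageExperiment, split_threshold: float = 1000.0
) -> CoverageExperiment:
    """Normalize replicate tracks separately for bulk and highly expressed genes.

    Genes are partitioned by provisional mean depth at ``split_threshold``.
    Within each partition, the coverage of every replicate track restricted to
    that partition's gene footprint is rescaled so the replicate sums of each
    time point equal that time point's mean of sums.  Equalization is within
    time points: the normalization exists to make biological replicates
    comparable for the CV analysis, and forcing all time points to one global
    total would push the cell cycle's composition changes into every flat
    gene as a shared temporal artifact.  Intergenic positions follow the bulk
    (<= threshold) scaling, so a handful of extremely expressed genes cannot
    distort the normalization of the rest of the genome.
    """
    prov = provisional_gene_means(experiment)
    high_genes = set(prov.index[prov > split_threshold])
    bulk_genes = set(prov.index) - high_genes

    out = experiment.copy()
    ann = experiment.annotation
    high_masks = _gene_footprint_masks(ann, experiment.genome_length, high_genes)
    bulk_masks = {
        s: ~high_masks[s] for s in STRANDS
    }  # bulk footprint + intergenic follow bulk scaling

    samples = sorted({(t, r) for t, r, _ in experiment.tracks})
    timepoints = sorted({t for t, _ in samples})
    for masks, label in ((bulk_masks, "bulk"), (high_masks, "high")):
        if not any(m.any() for m in masks.values()):
            continue  # partition has no footprint (e.g. no high genes)
        for t in timepoints:
            # a replicate spans both strands of one time point
            sums = {
                r: sum(
                    float(experiment.tracks[(t, r, s)][masks[s]].sum())
                    for s in STRANDS
                )
                for tt, r in samples
                if tt == t
            }
            total = sum(sums.values())
            if total == 0:
                continue
            target = total / len(sums)
            for r, s_sum in sums.items():
                if s_sum == 0:
                    raise ValueError(
                        f"replicate (timepoint {t}, replicate {r}) has zero "
                        f"total coverage in the {label} partition; cannot "
                        f"normalize"
                    )
                for s in STRANDS:
                    out.tracks[(t, r, s)][masks[s]] *= target / s_sum
    return out


# ---------------------------------------------------------------------------
# per-nucleotide CV
# ---------------------------------------------------------------------------


def compute_cv(
    experiment: CoverageExperiment, timepoint: int
) -> dict[str, np.ndarray]:
    """Per-nucleotide CV (sample sd / mean) across replicates of one time point.

    Positions where the replicate mean is zero get CV = 0: replicates that
    consistently report nothing are consistent, so silent regions are retained
    by the downstream filter and contribute zero coverage.
    """
    out = {}
    for strand in STRANDS:
        reps = [
            trk
            for (t, r, s), trk in sorted(experiment.tracks.items())
            if t == timepoint and s == strand
        ]
        if len(reps) < 2:
            raise ValueError(
                f"timepoint {timepoint} strand {strand}: need >= 2 replicates"
            )
        stack = np.vstack(reps)
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, sd / mean, 0.0)
        out[strand] = cv
    return out


# ---------------------------------------------------------------------------
# dynamic-programming segmentation
# ---------------------------------------------------------------------------


def _dp_segment(values: np.ndarray, max_segments: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact least-squares piecewise-constant DP.

    Returns (rss_per_k, backpointers) where rss_per_k[k-1] is the optimal
    residual sum of squares with exactly k segments.  Fully vectorized over
    the (start, end) cost matrix; O(n^2) memory, O(n^2 * k) work.
    """
    n = len(values)
    c1 = np.concatenate([[0.0], np.cumsum(values)])
    c2 = np.concatenate([[0.0], np.cumsum(values**2)])

    # cost[j, i] = RSS of the single segment [j, i), inf for j >= i
    idx = np.arange(n + 1)
    length = idx[None, :] - idx[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        s1 = c1[None, :] - c1[:, None]
        s2 = c2[None, :] - c2[:, None]
        cost = s2 - s1 * s1 / length
    cost[length <= 0] = np.inf
    # clamp tiny negative round-off
    np.maximum(cost, 0.0, where=np.isfinite(cost), out=cost)

    dp_prev = np.full(n + 1, np.inf)
    dp_prev[0] = 0.0
    rss = np.empty(max_segments)
    back = np.zeros((max_segments + 1, n + 1), dtype=np.int64)
    for k in range(1, max_segments + 1):
        cand = dp_prev[:, None] + cost
        back[k] = np.argmin(cand, axis=0)
        dp_prev = cand[back[k], idx]
        rss[k - 1] = dp_prev[n]
    return rss, back


def _backtrack(back: np.ndarray, k: int, n: int) -> np.ndarray:
    bounds = [n]
    i = n
    for kk in range(k, 0, -1):
        i = int(back[kk, i])
        bounds.append(i)
    return np.array(bounds[::-1])


def segment_signal(
    values: np.ndarray, max_segments: int, penalty: str = "bic"
) -> Segmentation:
    """Segment a signal into piecewise-constant pieces by exact DP.

    For each candidate number of segments k <= ``max_segments`` the optimal
    (minimum-RSS) changepoints are found by dynamic programming; the returned
    k minimizes the BIC ``n*ln(RSS/n) + k*ln(n)``, ties broken toward smaller
    k.  RSS is floored at machine epsilon so a perfect fit does not produce
    -inf.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("cannot segment an empty sequence")
    if max_segments < 1:
        raise ValueError("max_segments must be >= 1")
    if max_segments > n:
        warnings.warn(f"max_segments {max_segments} > n {n}; clipping to n")
        max_segments = n
    if penalty != "bic":
        raise ValueError(f"unknown penalty {penalty!r}")

    rss, back = _dp_segment(values, max_segments)
    ks = np.arange(1, max_segments + 1)
    # scale-aware floor: a numerically perfect fit must tie, not win on
    # round-off noise, so ties resolve toward smaller k
    floor = 1e-12 * max(1.0, float(np.sum(values**2)))
    bic = n * np.log(np.maximum(rss, floor) / n) + ks * np.log(n)
    best_k = int(ks[np.argmin(bic)])  # argmin returns the first (smallest k) tie
    bounds = _backtrack(back, best_k, n)
    means = np.array(
        [values[bounds[i] : bounds[i + 1]].mean() for i in range(best_k)]
    )
    return Segmentation(changepoints=bounds, segment_means=means)


def segment_signal_windowed(
    values: np.ndarray,
    window: int = 10_000,
    min_max_segments: int = 2,
    bp_per_segment: int = 250,
    bin_size: int = 25,
) -> Segmentation:
    """Segment a genome-scale signal window by window.

    The exact DP is O(n^2 k), so the signal is processed in ``window``-sized
    pieces; within each window the signal is first averaged into ``bin_size``-
    nucleotide bins and the DP runs exactly on the binned signal with
    ``max_segments = max(min_max_segments, window_len // bp_per_segment)``.
    Changepoints therefore land on bin boundaries; DP optimality holds at bin
    resolution within every window.  Per-segment means are recomputed on the
    original per-nucleotide signal.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    bounds = [0]
    means: list[float] = []
    for start in range(0, n, window):
        chunk = values[start : start + window]
        m = len(chunk)
        n_bins = -(-m // bin_size)
        pad = n_bins * bin_size - m
        padded = np.concatenate([chunk, np.full(pad, chunk[-1])]) if pad else chunk
        binned = padded.reshape(n_bins, bin_size).mean(axis=1)
        k_max = min(max(min_max_segments, m // bp_per_segment), n_bins)
        seg = segment_signal(binned, k_max)
        nt_bounds = np.minimum(seg.changepoints[1:] * bin_size, m) + start
        for a, b in zip([bounds[-1]] + nt_bounds[:-1].tolist(), nt_bounds):
            means.append(float(values[a:b].mean()))
        bounds.extend(nt_bounds.tolist())
    return Segmentation(
        changepoints=np.array(bounds), segment_means=np.array(means)
    )


def filter_segments(
    segmentation: Segmentation, cv_threshold: float = 1.0
) -> np.ndarray:
    """Boolean mask of retained nucleotides: segments with mean CV > threshold
    are discarded, everything else is kept."""
    n = int(segmentation.changepoints[-1])
    keep = np.ones(n, dtype=bool)
    retained = segmentation.segment_means <= cv_threshold
    for i, ok in enumerate(retained):
        if not ok:
            a, b = segmentation.changepoints[i], segmentation.changepoints[i + 1]
            keep[a:b] = False
    segmentation.retained = retained
    return keep


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------


def quantify_genes(
    experiment: CoverageExperiment,
    retained_sets: dict[int, dict[str, np.ndarray]],
) -> ExpressionMatrix:
    """Expression(g, t, r) = mean coverage over retained nucleotides of g.

    ``retained_sets[timepoint][strand]`` is a boolean keep-mask over the
    genome.  Genes whose footprint is entirely discarded at a time point fall
    back to the unfiltered mean there and are flagged.
    """
    ann = experiment.annotation
    for row in ann.itertuples():
        if row.start < 0 or row.end > experiment.genome_length:
            raise ValueError(f"gene {row.gene_id} outside genome bounds")

    gene_ids = list(ann["gene_id"])
    cols = sorted({(t, r) for t, r, _ in experiment.tracks})
    data = np.zeros((len(gene_ids), len(cols)))
    retained_frac = np.zeros(len(gene_ids))
    fallback = np.zeros(len(gene_ids), dtype=bool)

    for gi, row in enumerate(ann.itertuples()):
        sl = slice(row.start, row.end)
        frac_acc = []
        for ci, (t, r) in enumerate(cols):
            track = experiment.tracks[(t, r, row.strand)]
            keep = retained_sets[t][row.strand][sl]
            frac_acc.append(keep.mean())
            if keep.any():
                data[gi, ci] = track[sl][keep].mean()
            else:
                data[gi, ci] = track[sl].mean()
                fallback[gi] = True
        retained_frac[gi] = float(np.mean(frac_acc))

    values = pd.DataFrame(
        data,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=pd.MultiIndex.from_tuples(cols, names=["timepoint", "replicate"]),
    )
    return ExpressionMatrix(
        values=values,
        retained_fraction=pd.Series(retained_frac, index=values.index),
        fallback_flag=pd.Series(fallback, index=values.index),
    )


def quantify_experiment(
    experiment: CoverageExperiment,
    cv_threshold: float = 1.0,
    split_threshold: float = 1000.0,
    window: int = 10_000,
    normalize: bool = True,
    filter_cv: bool = True,
) -> ExpressionMatrix:
    """Run the full quantification chain on a coverage experiment."""
    exp = normalize_split(experiment, split_threshold) if normalize else experiment
    retained_sets: dict[int, dict[str, np.ndarray]] = {}
    for t in exp.timepoints:
        cv = compute_cv(exp, t)
        retained_sets[t] = {}
        for strand in STRANDS:
            if filter_cv:
                seg = segment_signal_windowed(cv[strand], window=window)
                retained_sets[t][strand] = filter_segments(seg, cv_threshold)
            else:
                retained_sets[t][strand] = np.ones(exp.genome_length, dtype=bool)
    return quantify_genes(exp, retained_sets)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_gff3(annotation: pd.DataFrame, path) -> None:
    """Write gene intervals as GFF3 (1-based, closed intervals)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples():
            attrs = f"ID={row.gene_id}"
            if "dup_group" in annotation.columns and row.dup_group >= 0:
                attrs += f";dup_group={row.dup_group}"
            fh.write(
                "\t".join(
                    [
                        "chr",
                        "cycleseq",
                        "gene",
                        str(row.start + 1),
                        str(row.end),
                        ".",
                        row.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "gene_id": attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"),
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6],
                    "dup_group": int(attrs.get("dup_group", -1)),
                }
            )
    return pd.DataFrame(rows)


def write_bedgraph(track: np.ndarray, path, chrom: str = "chr") -> None:
    """Write a per-nucleotide track as bedGraph (0-based half-open),
    run-length collapsed."""
    track = np.asarray(track)
    with open(path, "w") as fh:
        if len(track) == 0:
            return
        change = np.flatnonzero(np.diff(track)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(track)]])
        for a, b in zip(starts, ends):
            fh.write(f"{chrom}\t{a}\t{b}\t{track[a]:g}\n")


def read_bedgraph(path, genome_length: int) -> np.ndarray:
    track = np.zeros(genome_length)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            _, a, b, v = line.split("\t")
            track[int(a) : int(b)] = float(v)
    return track
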