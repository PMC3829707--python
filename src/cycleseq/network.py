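"""Signed weighted co-expression network over CCR genes.

Adjacency a_ij = ((1 + cor(x_i, x_j)) / 2)^beta with a high soft-threshold
power (beta = 36 by default) so that only strongly positively correlated
genes stay connected; topological overlap combines direct adjacency with
shared-neighbor weight; modules are average-linkage clusters of 1 - TOM cut
at a fixed height; each module is summarized by the first singular direction
of its standardized expression matrix (the module eigenvector) together with
the variance it explains and the per-gene contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

DEFAULT_BETA = 36.0
DEFAULT_MIN_SIZE = 5
DEFAULT_CUT_HEIGHT = 0.995

UNASSIGNED = 0


def signed_adjacency(expr: pd.DataFrame, beta: float = DEFAULT_BETA) -> pd.DataFrame:
    """Signed adjacency ((1 + Pearson correlation)/2)^beta over samples."""
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples per gene")
    var = expr.var(axis=1)
    dead = var[var == 0]
    if len(dead):
        raise ValueError(f"zero-variance gene(s): {', '.join(map(str, dead.index))}")
    cor = np.corrcoef(expr.values)
    adj = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    the shared-neighbor sum over u != i, j and k the off-diagonal row sum."""
    a = adjacency.values
    n = a.shape[0]
    shared = a @ a
    # remove u = i and u = j terms (diagonal of a is 1)
    shared = shared - a * np.diag(a)[:, None] - a * np.diag(a)[None, :]
    k = a.sum(axis=1) - np.diag(a)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore"):  # 0/0 on the (overwritten) diagonal
        tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


@dataclass
class ModuleSet:
    labels: pd.Series  # gene -> module id (0 = unassigned)
    eigenvectors: pd.DataFrame | None = None  # samples x modules
    variance_explained: pd.Series | None = None
    contributions: pd.Series | None = None  # per gene, within its module

    @property
    def modules(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for gene, mid in self.labels.items():
            if mid != UNASSIGNED:
                out.setdefault(int(mid), []).append(gene)
        return out


def detect_modules(
    tom: pd.DataFrame,
    min_size: int = DEFAULT_MIN_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM, cut at ``cut_height`` of the
    merge-height range; clusters smaller than ``min_size`` go to the
    unassigned pool (module id 0).  Deterministic given its input."""
    genes = tom.index
    if len(genes) < min_size:
        return ModuleSet(pd.Series(UNASSIGNED, index=genes, name="module"))
    dis = 1.0 - tom.values
    np.fill_diagonal(dis, 0.0)
    dis = np.maximum(dis, 0.0)
    link = hierarchy.linkage(squareform(dis, checks=False), method="average")
    hmax = link[:, 2].max()
    raw = hierarchy.fcluster(link, t=cut_height * hmax, criterion="distance")

    labels = pd.Series(UNASSIGNED, index=genes, name="module")
    next_id = 1
    # stable module ids: order clusters by first gene occurrence
    seen: dict[int, int] = {}
    counts = pd.Series(raw).value_counts()
    for gi, cl in enumerate(raw):
        if counts[cl] < min_size:
            continue
        if cl not in seen:
            seen[cl] = next_id
            next_id += 1
        labels.iloc[gi] = seen[cl]
    return ModuleSet(labels)


def module_eigenvector(
    expr: pd.DataFrame,
) -> tuple[np.ndarray, float, pd.Series]:
    """First singular direction of a module's standardized expression.

    Gene profiles are scaled to mean 0, sd 1 across samples; the eigenvector
    is the first right singular vector (one value per sample);
    variance_explained is the first squared singular value over the total;
    contribution(g) is the projection of g's scaled profile onto the
    eigenvector, normalized so the absolute contributions sum to 1; the sign
    is oriented so the mean contribution is positive.
    """
    if expr.shape[0] < 2:
        raise ValueError("module must have at least 2 genes")
    x = expr.values.astype(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        bad = expr.index[(sd == 0).ravel()]
        raise ValueError(f"constant gene(s) in module: {', '.join(map(str, bad))}")
    z = (x - mu) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    contrib = z @ eig
    if contrib.mean() < 0:
        eig = -eig
        contrib = -contrib
    total = np.abs(contrib).sum()
    if total > 0:
        contrib = contrib / total
    return eig, var_explained, pd.Series(contrib, index=expr.index, name="contribution")


def summarize_modules(expr: pd.DataFrame, module_set: ModuleSet) -> ModuleSet:
    """Attach eigenvectors, variance explained and contributions to a label set."""
    eigs, var_exp, contribs = {}, {}, []
    for mid, genes in sorted(module_set.modules.items()):
        eig, ve, c = module_eigenvector(expr.loc[genes])
        eigs[mid] = eig
        var_exp[mid] = ve
        contribs.append(c)
    cols = (
        pd.MultiIndex.from_tuples(list(expr.columns))
        if isinstance(expr.columns, pd.MultiIndex)
        else expr.columns
    )
    module_set.eigenvectors = pd.DataFrame(eigs, index=cols)
    module_set.variance_explained = pd.Series(var_exp, name="variance_explained")
    module_set.contributions = (
        pd.concat(contribs) if contribs else pd.Series(dtype=float)
    )
    return module_set


def cluster_module_eigenvectors(
    module_set: ModuleSet, n_groups: int = 3
) -> tuple[pd.DataFrame, pd.Series, list[int]]:
    """Pairwise Pearson correlations of module eigenvectors with an
    average-linkage ordering and a ``n_groups``-cluster cut.

    Returns (correlation matrix, group labels per module, leaf order).
    """
    eig = module_set.eigenvectors
    if eig is None or eig.shape[1] < 2:
        raise ValueError("need at least 2 modules with eigenvectors")
    cor = np.corrcoef(eig.values.T)
    cor_df = pd.DataFrame(cor, index=eig.columns, columns=eig.columns)
    dis = 1.0 - cor
    np.fill_diagonal(dis, 0.0)
    link = hierarchy.linkage(squareform(np.maximum(dis, 0), checks=False),
                             method="average")
    order = hierarchy.leaves_list(link).tolist()
    groups = hierarchy.fcluster(link, t=min(n_groups, len(eig.columns)),
                                criterion="maxclust")
    return cor_df, pd.Series(groups, index=eig.columns, name="group"), order


def drop_inconsistent_replicates(
    expr: pd.DataFrame, timepoints: list[int]
) -> pd.DataFrame:
    """For each named time point, drop the replicate whose profile has the
    largest median distance to its two peers (a sample-selection mask used
    before network construction)."""
    drop = []
    for t in timepoints:
        cols = [c for c in expr.columns if c[0] == t]
        if len(cols) < 3:
            continue
        sub = expr[cols].values
        med_dist = []
        for i in range(len(cols)):
            dists = [
                np.median(np.abs(sub[:, i] - sub[:, j]))
                for j in range(len(cols))
                if j != i
            ]
            med_dist.append(np.median(dists))
        drop.append(cols[int(np.argmax(med_dist))])
    return expr.drop(columns=drop)


def run_network(
    expr: pd.DataFrame,
    beta: float = DEFAULT_BETA,
    min_size: int = DEFAULT_MIN_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    drop_replicates_at: list[int] | None = None,
) -> ModuleSet:
    """Full network stage: optional replicate drop, signed adjacency, TOM,
    module detection, eigenvector summaries."""
    if drop_replicates_at:
        expr = drop_inconsistent_replicates(expr, drop_replicates_at)
    adj = signed_adjacency(expr, beta)
    tom = topological_overlap(adj)
    module_set = detect_modules(tom, min_size, cut_height)
    return summarize_modules(expr, module_set)
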