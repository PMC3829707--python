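"""Phylogenetic signal of co-expression modules.

A module's conservation profile (per-species counts of conserved member
genes) is treated as a trait on the species tree.  Blomberg's K measures
whether the trait's variance structure matches the Brownian-motion
expectation on that tree (K = 1 under Brownian motion); its p-value comes
from tip-label permutations of the variance of phylogenetically independent
contrasts.  Standardized effect sizes of the mean pairwise distance (MPD)
and mean nearest taxon distance (MNTD) among the species carrying the module
locate the signal: strongly negative MPD z-scores indicate tree-wide
clustering, strongly negative MNTD z-scores with unremarkable MPD indicate
tip-level (clade-specific) clustering.

Also here: reciprocal-best-hit orthology, the gene persistence index, and
representative-species selection by clade cutting.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

QUADRANT_THRESHOLD = -2.0
PI_LOW = 50.0
PI_HIGH = 150.0


# ---------------------------------------------------------------------------
# orthology and persistence
# ---------------------------------------------------------------------------


def bbh_orthologs(
    hit_table: pd.DataFrame,
    sim_min: float = 40.0,
    len_diff_max: float = 0.20,
) -> set[tuple[str, str]]:
    """Reciprocal-best-hit ortholog pairs from a directed similarity table.

    ``hit_table`` columns: query, subject, similarity (percent),
    query_length, subject_length; it must cover both search directions.
    (a, b) is an ortholog pair iff b is a's best-similarity hit and a is
    b's, the similarity exceeds ``sim_min`` in both directions, and the
    relative length difference is below ``len_diff_max``.  Similarity ties
    are broken toward the lexicographically smallest subject id.
    """
    required = {"query", "subject", "similarity", "query_length", "subject_length"}
    missing = required - set(hit_table.columns)
    if missing:
        raise ValueError(f"hit table missing column(s): {', '.join(sorted(missing))}")

    df = hit_table.sort_values(
        ["query", "similarity", "subject"], ascending=[True, False, True]
    )
    best = df.drop_duplicates("query", keep="first").set_index("query")

    pairs: set[tuple[str, str]] = set()
    for a, row in best.iterrows():
        b = row["subject"]
        if a >= b or b not in best.index:
            continue
        back = best.loc[b]
        if back["subject"] != a:
            continue
        if row["similarity"] <= sim_min or back["similarity"] <= sim_min:
            continue
        la, lb = float(row["query_length"]), float(row["subject_length"])
        if abs(la - lb) / max(la, lb) >= len_diff_max:
            continue
        pairs.add((a, b))
    return pairs


def persistence_index(conservation: pd.DataFrame) -> pd.DataFrame:
    """PI(g) = number of species carrying an ortholog of g (binary row sum),
    with conservation bands: low (PI < 50), mid, persistent (PI > 150)."""
    vals = conservation.values
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("conservation matrix must be binary")
    pi = conservation.sum(axis=1).astype(int).rename("persistence_index")
    band = pd.Series("mid", index=pi.index, name="band")
    band[pi < PI_LOW] = "low"
    band[pi > PI_HIGH] = "persistent"
    return pd.DataFrame({"persistence_index": pi, "band": band})


def select_representatives(
    tree: dendropy.Tree, target_clades: int = 300, seed: int = 0
) -> list[str]:
    """Cut the tree into about ``target_clades`` clades at one depth and pick
    one uniformly random tip per clade.

    The depth threshold is found by searching the candidate node depths for
    the cut whose crossing-edge count is closest to the target; each edge
    crossing the cut subtends one clade.
    """
    tips = tree.leaf_nodes()
    if target_clades >= len(tips):
        return [leaf.taxon.label for leaf in tips]

    tree.calc_node_root_distances(return_leaf_distances_only=False)
    parent_d, child_d, nodes = [], [], []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_d.append(node.parent_node.root_distance)
        child_d.append(node.root_distance)
        nodes.append(node)
    parent_d = np.asarray(parent_d)
    child_d = np.asarray(child_d)

    candidates = np.unique(child_d)
    best_tau, best_diff = None, None
    for tau in candidates:
        count = int(np.sum((parent_d < tau) & (tau <= child_d)))
        diff = abs(count - target_clades)
        if best_diff is None or diff < best_diff:
            best_tau, best_diff = tau, diff
    crossing = [
        n
        for n, pd_, cd_ in zip(nodes, parent_d, child_d)
        if pd_ < best_tau <= cd_
    ]
    rng = np.random.default_rng(seed)
    reps = []
    for node in crossing:
        clade_tips = [leaf.taxon.label for leaf in node.leaf_iter()]
        reps.append(clade_tips[rng.integers(len(clade_tips))])
    return reps


# ---------------------------------------------------------------------------
# module conservation profiles
# ---------------------------------------------------------------------------


def module_species_profile(
    module_genes: list[str], conservation: pd.DataFrame
) -> pd.Series:
    """Per-species count of conserved module genes (column sums over the
    module's rows)."""
    unknown = [g for g in module_genes if g not in conservation.index]
    if unknown:
        raise KeyError(f"unknown gene id(s): {', '.join(map(str, unknown))}")
    return conservation.loc[module_genes].sum(axis=0).rename("profile")


# ---------------------------------------------------------------------------
# tree algebra
# ---------------------------------------------------------------------------


def tree_distance_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Patristic (cophenetic) distances between all tip pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    labels = [t.label for t in taxa]
    return pd.DataFrame(d, index=labels, columns=labels)


def brownian_covariance(tree: dendropy.Tree) -> pd.DataFrame:
    """Brownian tip covariance: V_ij = shared root-to-MRCA path length."""
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_nodes()}
    dist = tree_distance_matrix(tree)
    labels = list(dist.index)
    dvec = np.array([depth[l] for l in labels])
    v = (dvec[:, None] + dvec[None, :] - dist.values) / 2.0
    return pd.DataFrame(v, index=labels, columns=labels)


def _pic_structure(tree: dendropy.Tree):
    """Flatten the tree into an array program for repeated PIC evaluation.

    Branch-length bookkeeping (Felsenstein pruning) depends only on the tree,
    so it is run once here; each merge record carries the precomputed
    effective variances.  Multifurcations are folded pairwise.  Returns
    (tip_order, merges, n_slots) with merges = (slot_i, slot_j, out_slot,
    v_i, v_j) in evaluation order.
    """
    tips = list(tree.leaf_node_iter())
    tip_order = [leaf.taxon.label for leaf in tips]
    slot = {id(leaf): i for i, leaf in enumerate(tips)}
    v = {i: max(leaf.edge.length or 0.0, 1e-12) for i, leaf in enumerate(tips)}
    next_slot = len(tips)
    merges = []
    for node in tree.postorder_internal_node_iter():
        children = node.child_nodes()
        acc = slot[id(children[0])]
        for child in children[1:]:
            si, sj = acc, slot[id(child)]
            vi, vj = v[si], v[sj]
            merges.append((si, sj, next_slot, vi, vj))
            v[next_slot] = vi * vj / (vi + vj)
            acc = next_slot
            next_slot += 1
        v[acc] += node.edge.length or 0.0
        v[acc] = max(v[acc], 1e-12)
        slot[id(node)] = acc
    return tip_order, merges, next_slot


def _pic_contrast_variance(values: np.ndarray, merges, n_slots: int) -> float:
    """Variance (mean square) of standardized independent contrasts."""
    x = np.empty(n_slots)
    x[: len(values)] = values
    acc = 0.0
    for si, sj, out, vi, vj in merges:
        c = (x[si] - x[sj]) / np.sqrt(vi + vj)
        acc += c * c
        x[out] = (x[si] / vi + x[sj] / vj) / (1.0 / vi + 1.0 / vj)
    return acc / len(merges)


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------


@dataclass
class PhyloSignalResult:
    module_id: object
    k: float | None
    k_p: float | None
    mpd_obs: float | None
    mpd_z: float | None
    mntd_obs: float | None
    mntd_z: float | None
    quadrant: int | None
    flagged: bool = False


def blomberg_k(
    tree: dendropy.Tree,
    trait: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Blomberg's K with a permutation p-value.

    K = (MSE0/MSE) / E[MSE0/MSE] where, with V the Brownian tip covariance
    and a-hat the GLS grand mean, MSE0 is the ordinary mean square about
    a-hat and MSE the V-weighted one; the expectation under Brownian motion
    is [tr(V) - n / sum(V^-1)] / (n - 1).  The p-value is the fraction of
    tip-label permutations whose variance of standardized independent
    contrasts is at most the observed one (observed included in numerator
    and denominator).
    """
    vdf = brownian_covariance(tree)
    y = trait.reindex(vdf.index).values.astype(float)
    if np.any(np.isnan(y)):
        raise ValueError("trait missing for some tips")
    if np.allclose(y, y[0]):
        raise ValueError("zero-variance trait; K undefined")
    v = vdf.values
    n = len(y)
    try:
        vinv = np.linalg.inv(v)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular Brownian covariance matrix") from exc
    ones = np.ones(n)
    denom = ones @ vinv @ ones
    a_hat = (ones @ vinv @ y) / denom
    resid = y - a_hat
    mse0 = (resid @ resid) / (n - 1)
    mse = (resid @ vinv @ resid) / (n - 1)
    expected = (np.trace(v) - n / denom) / (n - 1)
    k = float((mse0 / mse) / expected)

    tip_order, merges, n_slots = _pic_structure(tree)
    order_idx = [list(vdf.index).index(t) for t in tip_order]
    y_tree = y[order_idx]
    obs = _pic_contrast_variance(y_tree, merges, n_slots)
    rng = np.random.default_rng(seed)
    hits = 1  # observed counts in both numerator and denominator
    for _ in range(n_permutations):
        perm = rng.permutation(y_tree)
        if _pic_contrast_variance(perm, merges, n_slots) <= obs:
            hits += 1
    return k, hits / (n_permutations + 1)


# ---------------------------------------------------------------------------
# SES-MPD / SES-MNTD
# ---------------------------------------------------------------------------


def _mpd(w: np.ndarray, d: np.ndarray) -> float:
    s = w.sum()
    denom = (s * s - np.sum(w * w)) / 2.0
    return float((w @ d @ w) / 2.0 / denom)


def _mntd(w: np.ndarray, d: np.ndarray) -> float:
    present = np.flatnonzero(w > 0)
    sub = d[np.ix_(present, present)].astype(float).copy()
    np.fill_diagonal(sub, np.inf)
    nearest = sub.min(axis=1)
    wp = w[present]
    return float(np.sum(wp * nearest) / np.sum(wp))


def ses_mpd_mntd(
    profile: pd.Series,
    distances: pd.DataFrame,
    n_randomizations: int = 9999,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> dict:
    """Standardized effect sizes of MPD and MNTD against a tip-shuffle null.

    MPD is the (weight-)averaged pairwise distance among species with a
    positive profile value; MNTD the weighted mean distance of each present
    species to its nearest present neighbor.  The null shuffles the profile
    values across tips uniformly, keeping the tree distances fixed;
    z = (observed - null mean) / null sd.
    """
    w = profile.reindex(distances.index).fillna(0.0).values.astype(float)
    if not abundance_weighted:
        w = (w > 0).astype(float)
    n_present = int(np.sum(w > 0))
    if n_present < 2:
        out = {
            "mpd_obs": None, "mpd_z": None, "mntd_obs": None, "mntd_z": None,
            "flagged": True, "n_present": n_present,
        }
        return out
    d = distances.values
    mpd_obs = _mpd(w, d)
    mntd_obs = _mntd(w, d)
    rng = np.random.default_rng(seed)
    null_mpd = np.empty(n_randomizations)
    null_mntd = np.empty(n_randomizations)
    for i in range(n_randomizations):
        p = rng.permutation(w)
        null_mpd[i] = _mpd(p, d)
        null_mntd[i] = _mntd(p, d)

    def z(obs, null):
        mean, sd = null.mean(), null.std(ddof=1)
        if sd <= 1e-9 * max(abs(mean), 1e-12):
            return 0.0  # degenerate null (e.g. constant profile)
        return float((obs - mean) / sd)

    return {
        "mpd_obs": mpd_obs,
        "mpd_z": z(mpd_obs, null_mpd),
        "mntd_obs": mntd_obs,
        "mntd_z": z(mntd_obs, null_mntd),
        "flagged": False,
        "n_present": n_present,
    }


def classify_quadrant(
    mpd_z: float, mntd_z: float, threshold: float = QUADRANT_THRESHOLD
) -> int | None:
    """Quadrant label: 2/3 = tree-wide clustering (MPD z at or below the
    threshold; 3 if MNTD too), 4 = tip-level clustering (only MNTD z at or
    below), 1 = no signal.  Non-finite inputs are unclassified (None)."""
    if mpd_z is None or mntd_z is None:
        return None
    if not (np.isfinite(mpd_z) and np.isfinite(mntd_z)):
        return None
    if mpd_z <= threshold:
        return 3 if mntd_z <= threshold else 2
    return 4 if mntd_z <= threshold else 1


def contribution_vs_persistence(
    contributions: pd.Series,
    pi: pd.Series,
    persistent_cut: float = 150.0,
) -> dict:
    """Two-sample KS test of module contributions, persistent genes
    (PI >= cut) vs the rest."""
    pi = pi.reindex(contributions.index)
    a = contributions[pi >= persistent_cut]
    b = contributions[pi < persistent_cut]
    if len(a) == 0 or len(b) == 0:
        return {"statistic": None, "pvalue": None, "flagged": True}
    res = stats.ks_2samp(a, b)
    return {
        "statistic": float(res.statistic),
        "pvalue": float(res.pvalue),
        "flagged": len(a) < 2 or len(b) < 2,
        "n_persistent": int(len(a)),
        "n_rest": int(len(b)),
    }


def analyze_modules(
    tree: dendropy.Tree,
    conservation: pd.DataFrame,
    modules: dict[int, list[str]],
    n_randomizations: int = 9999,
    n_permutations: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """Per-module phylogenetic signal table: K, K p-value, MPD/MNTD z-scores
    and the quadrant label."""
    distances = tree_distance_matrix(tree)
    rows = []
    rng = np.random.default_rng(seed)
    for mid, genes in sorted(modules.items()):
        genes = [g for g in genes if g in conservation.index]
        sub_seed = int(rng.integers(2**31 - 1))
        if not genes:
            rows.append(PhyloSignalResult(mid, *([None] * 6), None, True))
            continue
        profile = module_species_profile(genes, conservation)
        try:
            k, k_p = blomberg_k(tree, profile, n_permutations, seed=sub_seed)
        except ValueError:
            k, k_p = None, None
        ses = ses_mpd_mntd(
            profile, distances, n_randomizations, seed=sub_seed,
            abundance_weighted=abundance_weighted,
        )
        quad = classify_quadrant(ses["mpd_z"], ses["mntd_z"])
        rows.append(
            PhyloSignalResult(
                mid, k, k_p, ses["mpd_obs"], ses["mpd_z"], ses["mntd_obs"],
                ses["mntd_z"], quad, ses["flagged"],
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("module_id")
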