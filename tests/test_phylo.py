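"""Orthology, persistence, Blomberg's K, SES-MPD/MNTD, quadrants."""

import random
from itertools import permutations

import dendropy
import numpy as np
import pandas as pd
import pytest
from dendropy.simulate import treesim

from cycleseq import phylo, synthetic
from cycleseq.phylo import (
    bbh_orthologs,
    blomberg_k,
    brownian_covariance,
    classify_quadrant,
    contribution_vs_persistence,
    module_species_profile,
    persistence_index,
    select_representatives,
    ses_mpd_mntd,
    tree_distance_matrix,
)


def star_tree(n: int, depth: float = 1.0) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    for t in taxa:
        tree.seed_node.new_child(taxon=t, edge_length=depth)
    return tree


def balanced_tree(depth: int) -> dendropy.Tree:
    tree = dendropy.Tree()
    nodes = [tree.seed_node]
    for _ in range(depth):
        nxt = []
        for node in nodes:
            nxt.append(node.new_child(edge_length=1.0))
            nxt.append(node.new_child(edge_length=1.0))
        nodes = nxt
    ns = dendropy.TaxonNamespace()
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = ns.new_taxon(f"t{i:02d}")
    tree.taxon_namespace = ns
    return tree


def hit_rows(*rows):
    return pd.DataFrame(
        rows,
        columns=["query", "subject", "similarity", "query_length",
                 "subject_length"],
    )


class TestBbhOrthologs:
    def test_reciprocal_best_pair_accepted(self):
        table = hit_rows(("a", "b", 60.0, 100, 100), ("b", "a", 60.0, 100, 100))
        assert bbh_orthologs(table) == {("a", "b")}

    def test_low_similarity_rejected(self):
        table = hit_rows(("a", "b", 35.0, 100, 100), ("b", "a", 35.0, 100, 100))
        assert bbh_orthologs(table) == set()

    def test_non_reciprocal_rejected(self):
        table = hit_rows(
            ("a", "b", 80.0, 100, 100),
            ("b", "c", 90.0, 100, 100),
            ("c", "b", 90.0, 100, 100),
        )
        assert ("a", "b") not in bbh_orthologs(table)

    def test_length_difference_rejected(self):
        table = hit_rows(("a", "b", 80.0, 100, 79), ("b", "a", 80.0, 79, 100))
        assert bbh_orthologs(table) == set()

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="query_length"):
            bbh_orthologs(pd.DataFrame({"query": [], "subject": [],
                                        "similarity": []}))


class TestPersistenceIndex:
    def test_bands(self):
        cons = pd.DataFrame(
            [np.ones(236), np.zeros(236),
             np.concatenate([np.ones(150), np.zeros(86)])],
            index=["all", "none", "150"],
        ).astype(int)
        out = persistence_index(cons)
        assert out.loc["all", "persistence_index"] == 236
        assert out.loc["all", "band"] == "persistent"
        assert out.loc["none", "band"] == "low"
        assert out.loc["150", "band"] == "mid"  # not > 150

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            persistence_index(pd.DataFrame([[0, 2]]))


class TestSelectRepresentatives:
    def test_star_tree_all_tips(self):
        reps = select_representatives(star_tree(12), target_clades=12)
        assert set(reps) == {f"t{i}" for i in range(12)}

    def test_balanced_tree_one_per_subtree(self):
        tree = balanced_tree(4)  # 16 tips
        reps = select_representatives(tree, target_clades=4, seed=0)
        assert len(reps) == 4
        # one representative from each depth-2 subtree of 4 tips
        blocks = [set(f"t{j:02d}" for j in range(i * 4, i * 4 + 4))
                  for i in range(4)]
        for block in blocks:
            assert len(block & set(reps)) == 1

    def test_deterministic(self, planted_tree):
        tree, _, _ = planted_tree
        r1 = select_representatives(tree, 30, seed=3)
        r2 = select_representatives(tree, 30, seed=3)
        assert r1 == r2


class TestModuleProfile:
    def test_sums_module_rows(self):
        cons = pd.DataFrame(
            {"s1": [1, 1, 0], "s2": [0, 1, 1]}, index=["a", "b", "c"]
        )
        prof = module_species_profile(["a", "b"], cons)
        assert prof.tolist() == [2, 1]

    def test_single_gene_module_is_row(self):
        cons = pd.DataFrame({"s1": [1, 0], "s2": [0, 1]}, index=["a", "b"])
        assert module_species_profile(["b"], cons).tolist() == [0, 1]

    def test_unknown_gene_rejected(self):
        cons = pd.DataFrame({"s1": [1]}, index=["a"])
        with pytest.raises(KeyError):
            module_species_profile(["zzz"], cons)


class TestBlombergK:
    def test_star_tree_k_exactly_one(self):
        tree = star_tree(10)
        trait = pd.Series(np.arange(10.0), index=[f"t{i}" for i in range(10)])
        k, _ = blomberg_k(tree, trait, n_permutations=19, seed=0)
        assert k == pytest.approx(1.0, abs=1e-10)

    def test_brownian_traits_calibrated(self):
        tree, _, _ = synthetic.simulate_tree_and_conservation(
            64, [{"module_id": "b", "depth_class": "broad", "size": 2}],
            seed=5,
        )
        v = brownian_covariance(tree)
        chol = np.linalg.cholesky(v.values)
        rng = np.random.default_rng(3)
        ks = []
        for _ in range(500):
            y = chol @ rng.normal(size=64)
            k, _ = blomberg_k(
                tree, pd.Series(y, index=v.index), n_permutations=0, seed=0
            )
            ks.append(k)
        assert 0.9 <= np.mean(ks) <= 1.1

    def test_clade_indicator_significant(self):
        tree, cons, truth = synthetic.simulate_tree_and_conservation(
            32, [{"module_id": "c", "depth_class": "clade", "size": 6}],
            loss_probability=0.0, seed=9,
        )
        prof = module_species_profile(list(truth.index), cons).astype(float)
        _, p = blomberg_k(tree, prof, n_permutations=999, seed=4)
        assert p <= 0.05

    def test_scale_invariance(self):
        tree, _, _ = synthetic.simulate_tree_and_conservation(
            16, [{"module_id": "b", "depth_class": "broad", "size": 2}],
            seed=6,
        )
        labels = [l.taxon.label for l in tree.leaf_nodes()]
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=16), index=labels)
        k1, _ = blomberg_k(tree, y, n_permutations=0, seed=0)
        k2, _ = blomberg_k(tree, 7.3 * y, n_permutations=0, seed=0)
        assert k1 == pytest.approx(k2, rel=1e-12)
        scaled = tree.clone(depth=1)
        for e in scaled.preorder_edge_iter():
            if e.length is not None:
                e.length *= 4.2
        k3, _ = blomberg_k(scaled, y, n_permutations=0, seed=0)
        assert k3 == pytest.approx(k1, rel=1e-9)

    def test_constant_trait_rejected(self):
        tree = star_tree(5)
        trait = pd.Series(2.0, index=[f"t{i}" for i in range(5)])
        with pytest.raises(ValueError, match="zero-variance"):
            blomberg_k(tree, trait)


class TestSesMpdMntd:
    def test_two_present_species(self):
        tree = star_tree(4)
        d = tree_distance_matrix(tree)
        prof = pd.Series([1.0, 1.0, 0.0, 0.0], index=d.index)
        res = ses_mpd_mntd(prof, d, n_randomizations=99, seed=0)
        assert res["mpd_obs"] == pytest.approx(d.iloc[0, 1])
        assert res["mntd_obs"] == pytest.approx(d.iloc[0, 1])

    def test_uniform_presence_null_invariant(self):
        tree, _, _ = synthetic.simulate_tree_and_conservation(
            24, [{"module_id": "b", "depth_class": "broad", "size": 2}],
            seed=2,
        )
        d = tree_distance_matrix(tree)
        prof = pd.Series(1.0, index=d.index)
        res = ses_mpd_mntd(prof, d, n_randomizations=999, seed=1,
                           abundance_weighted=False)
        grand = d.values[np.triu_indices(len(d), 1)].mean()
        assert res["mpd_obs"] == pytest.approx(grand)
        assert abs(res["mpd_z"]) < 0.2

    def test_single_present_species_flagged(self):
        tree = star_tree(4)
        d = tree_distance_matrix(tree)
        prof = pd.Series([3.0, 0, 0, 0], index=d.index)
        assert ses_mpd_mntd(prof, d, n_randomizations=9, seed=0)["flagged"]

    def test_matches_exhaustive_permutation_null(self):
        tree = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=6, gsa_ntax=8,
            rng=random.Random(2),
        )
        for i, leaf in enumerate(tree.leaf_node_iter()):
            leaf.taxon.label = f"x{i}"
        d = tree_distance_matrix(tree)
        w = np.array([3.0, 1.0, 0.0, 0.0, 2.0, 0.0])
        prof = pd.Series(w, index=d.index)
        res = ses_mpd_mntd(prof, d, n_randomizations=9999, seed=1)
        mpds, mntds = [], []
        for pm in set(permutations(w.tolist())):
            pw = np.array(pm)
            mpds.append(phylo._mpd(pw, d.values))
            mntds.append(phylo._mntd(pw, d.values))
        z_mpd = (res["mpd_obs"] - np.mean(mpds)) / np.std(mpds, ddof=1)
        z_mntd = (res["mntd_obs"] - np.mean(mntds)) / np.std(mntds, ddof=1)
        assert res["mpd_z"] == pytest.approx(z_mpd, abs=0.1)
        assert res["mntd_z"] == pytest.approx(z_mntd, abs=0.1)

    def test_random_profile_calibration(self):
        tree, _, _ = synthetic.simulate_tree_and_conservation(
            48, [{"module_id": "b", "depth_class": "broad", "size": 2}],
            seed=3,
        )
        d = tree_distance_matrix(tree)
        rng = np.random.default_rng(4)
        zs = []
        for _ in range(100):
            prof = pd.Series(
                rng.binomial(8, 0.3, size=len(d)).astype(float), index=d.index
            )
            res = ses_mpd_mntd(prof, d, n_randomizations=199,
                               seed=int(rng.integers(2**31)))
            zs.append(res["mpd_z"])
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.25
        assert (zs <= -2).mean() <= 0.05


class TestQuadrants:
    @pytest.mark.parametrize(
        "mpd_z,mntd_z,expected",
        [(-3, -3, 3), (-3, 0, 2), (-1, -3, 4), (0, 0, 1), (-2.0, -2.0, 3)],
    )
    def test_classification(self, mpd_z, mntd_z, expected):
        assert classify_quadrant(mpd_z, mntd_z) == expected

    def test_non_finite_unclassified(self):
        assert classify_quadrant(np.nan, 0.0) is None


class TestContributionVsPersistence:
    def test_identical_distributions_zero_statistic(self):
        idx = [f"g{i}" for i in range(40)]
        contrib = pd.Series(np.tile(np.linspace(0, 1, 20), 2), index=idx)
        pi = pd.Series([200] * 20 + [10] * 20, index=idx)
        out = contribution_vs_persistence(contrib, pi)
        assert out["statistic"] == pytest.approx(0.0)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(7)
        idx = [f"g{i}" for i in range(400)]
        pi = pd.Series([200] * 200 + [10] * 200, index=idx)
        contrib = pd.Series(
            np.concatenate(
                [rng.normal(0.7, 0.1, 200), rng.normal(0.5, 0.1, 200)]
            ),
            index=idx,
        )
        out = contribution_vs_persistence(contrib, pi)
        assert out["pvalue"] < 1e-5

    def test_single_element_groups_flagged(self):
        contrib = pd.Series([0.5, 0.7], index=["a", "b"])
        pi = pd.Series([200, 10], index=["a", "b"])
        out = contribution_vs_persistence(contrib, pi)
        assert out["flagged"]
        assert out["statistic"] in (0.0, 1.0)
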