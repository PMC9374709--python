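"""Rarefaction, UniFrac, Ward and PERMANOVA against independent oracles."""

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from skbio.stats.distance import DistanceMatrix
from sklearn.metrics import adjusted_rand_score

import diopower as dp
from diopower.clustering import cut_tree, arm_label_stability
from diopower.simulate import random_coalescent_newick
from diopower.tables import ZotuTable

from oracles import (
    naive_weighted_unifrac, naive_ward_partitions, brute_force_max_k,
    exact_permanova_p,
)


# --------------------------------------------------------------- rarefy
def test_rarefy_excludes_below_and_keeps_at_threshold():
    counts = np.array([[9_999, 0], [5_000, 5_000], [15_000, 10_000]])
    table = ZotuTable(["low", "exact", "high"], ["z1", "z2"], counts)
    rare, excluded = dp.rarefy(table, 10_000, seed=0)
    assert [m for m, _ in excluded] == ["low"]
    assert "9999" in excluded[0][1]
    assert rare.mouse_ids == ["exact", "high"]
    assert (rare.counts[0] == [5_000, 5_000]).all()  # unchanged at threshold
    assert (rare.depth == 10_000).all()


def test_rarefy_is_hypergeometric_in_the_mean():
    """A 20,000-read mouse subsampled to 10,000: E[count_j] = c_j / 2."""
    row = np.array([[12_000, 6_000, 2_000]])
    table = ZotuTable(["m"], ["a", "b", "c"], row)
    draws = np.array([
        dp.rarefy(table, 10_000, seed=s)[0].counts[0] for s in range(300)
    ])
    se = draws.std(axis=0) / np.sqrt(len(draws))
    assert np.all(np.abs(draws.mean(axis=0) - row[0] / 2) <= 3 * se)


def test_rarefy_all_below_depth_errors():
    table = ZotuTable(["m"], ["z"], np.array([[5]]))
    with pytest.raises(ValueError, match="no clusterable samples"):
        dp.rarefy(table, 10, seed=0)


def test_rarefy_deterministic_for_fixed_seed():
    rng = np.random.default_rng(0)
    table = ZotuTable(["m1", "m2"], [f"z{i}" for i in range(20)],
                      rng.integers(500, 2000, size=(2, 20)))
    a, _ = dp.rarefy(table, 10_000, seed=77)
    b, _ = dp.rarefy(table, 10_000, seed=77)
    assert (a.counts == b.counts).all()


# -------------------------------------------------------------- UniFrac
def test_unifrac_identical_samples_distance_zero(rng):
    counts = np.tile(rng.integers(0, 50, size=8), (2, 1))
    taxa = [f"z{i}" for i in range(8)]
    tree = random_coalescent_newick(taxa, rng)
    dm = dp.weighted_unifrac(ZotuTable(["a", "b"], taxa, counts), tree)
    assert dm["a", "b"] == pytest.approx(0.0, abs=1e-12)


def test_unifrac_disjoint_two_leaf_communities_distance_one():
    """All mass on opposite leaves of a two-leaf tree: (1+1)/(1+1) = 1."""
    tree = "(a:1.0,b:1.0);"
    table = ZotuTable(["A", "B"], ["a", "b"], np.array([[10, 0], [0, 10]]))
    dm = dp.weighted_unifrac(table, tree)
    assert dm["A", "B"] == pytest.approx(1.0, abs=1e-12)


def test_unifrac_matches_naive_branch_oracle(rng):
    for _ in range(10):
        taxa = [f"z{i}" for i in range(8)]
        tree = random_coalescent_newick(taxa, rng)
        counts = rng.integers(0, 40, size=(3, 8))
        counts[counts.sum(axis=1) == 0, 0] = 1
        table = ZotuTable(["a", "b", "c"], taxa, counts)
        dm = dp.weighted_unifrac(table, tree)
        for i, j in ((0, 1), (0, 2), (1, 2)):
            expected = naive_weighted_unifrac(counts[i], counts[j], taxa, tree)
            assert dm.data[i, j] == pytest.approx(expected, abs=1e-10)


def test_unifrac_semimetric_properties(rng):
    taxa = [f"z{i}" for i in range(12)]
    tree = random_coalescent_newick(taxa, rng)
    counts = rng.integers(1, 100, size=(6, 12))
    dm = dp.weighted_unifrac(ZotuTable([f"m{i}" for i in range(6)], taxa,
                                       counts), tree)
    assert np.allclose(dm.data, dm.data.T, atol=1e-12)
    assert np.all(np.diag(dm.data) == 0)
    assert np.all((dm.data >= 0) & (dm.data <= 1 + 1e-12))


def test_unifrac_names_missing_zotu(rng):
    tree = "(a:1.0,b:1.0);"
    table = ZotuTable(["m"], ["a", "ghost"], np.array([[5, 5]]))
    with pytest.raises(ValueError, match="ghost"):
        dp.weighted_unifrac(table, tree)


# ----------------------------------------------------------------- Ward
def _dm(values, ids=None):
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return DistanceMatrix(values, ids)


def test_ward_recovers_two_tight_pairs():
    pts = np.array([0.0, 0.1, 10.0, 10.1])
    d = np.abs(pts[:, None] - pts[None, :])
    link = dp.ward_linkage(_dm(d))
    labels = cut_tree(link, 2)
    assert labels[0] == labels[1] != labels[2] == labels[3]


def test_ward_merge_heights_non_decreasing(rng):
    pts = rng.normal(size=(6, 2))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    link = dp.ward_linkage(_dm(d))
    assert np.all(np.diff(link[:, 2]) >= -1e-12)


def test_ward_matches_lance_williams_oracle(rng):
    for _ in range(5):
        pts = rng.normal(size=(10, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        link = dp.ward_linkage(_dm(d))
        partitions = naive_ward_partitions(d)
        for k in range(1, 11):
            ours = cut_tree(link, k)
            blocks = partitions[k]
            oracle = np.empty(10, dtype=int)
            for lab, blk in enumerate(blocks):
                for m in blk:
                    oracle[m] = lab
            assert adjusted_rand_score(ours, oracle) == pytest.approx(1.0)


def test_ward_single_sample_errors():
    with pytest.raises(ValueError):
        dp.ward_linkage(_dm(np.zeros((1, 1))))


# ------------------------------------------------- cluster-count rule
def _linkage_from_points(pts):
    d = np.abs(pts[:, None] - pts[None, :]).astype(float)
    return dp.ward_linkage(_dm(d)), d


def test_single_arm_branches_force_k_one():
    """Two clean branches perfectly aligned with the arms: k must fall
    back to 1 because k = 2 leaves each cluster single-arm."""
    pts = np.array([0.0, 0.1, 10.0, 10.1])
    link, _ = _linkage_from_points(pts)
    ids = ["a", "b", "c", "d"]
    arms = {"a": "liraglutide", "b": "liraglutide",
            "c": "vehicle", "d": "vehicle"}
    res = dp.select_cluster_count(link, ids, arms, k_max=4)
    assert res.k == 1
    assert set(res.labels.values()) == {1}


def test_four_mixed_branches_allow_k_four():
    pts = np.array([0.0, 0.1, 10.0, 10.1, 20.0, 20.1, 30.0, 30.1])
    link, _ = _linkage_from_points(pts)
    ids = [f"m{i}" for i in range(8)]
    arms = {m: ("liraglutide" if i % 2 == 0 else "vehicle")
            for i, m in enumerate(ids)}
    res = dp.select_cluster_count(link, ids, arms, k_max=4)
    assert res.k == 4


def test_cluster_count_equals_brute_force(rng):
    for trial in range(30):
        n = int(rng.integers(6, 14))
        pts = rng.normal(size=n)
        link, d = _linkage_from_points(pts)
        ids = [f"m{i}" for i in range(n)]
        arms = {m: rng.choice(["liraglutide", "vehicle"]) for m in ids}
        k_max = int(rng.integers(1, 7))
        res = dp.select_cluster_count(link, ids, arms, k_max=k_max)
        # brute force the representation predicate on the same dendrogram
        partition_by_k = {
            k: tuple(
                frozenset(np.array(ids)[cut_tree(link, k) == c])
                for c in range(1, k + 1)
            )
            for k in range(1, min(k_max, n) + 1)
        }
        expected = brute_force_max_k(partition_by_k, arms, min(k_max, n))
        assert res.k == expected


def test_selected_k_is_maximal(rng):
    """The representation predicate fails at k + 1 whenever k < k_max."""
    for trial in range(10):
        n = 12
        pts = rng.normal(size=n)
        link, _ = _linkage_from_points(pts)
        ids = [f"m{i}" for i in range(n)]
        arms = {m: rng.choice(["liraglutide", "vehicle"]) for m in ids}
        res = dp.select_cluster_count(link, ids, arms, k_max=6)
        if res.k < 6:
            labels = cut_tree(link, res.k + 1)
            arm_vec = np.array([arms[m] for m in ids])
            ok = all(len(set(arm_vec[labels == c])) >= 2
                     for c in range(1, labels.max() + 1))
            assert not (ok and labels.max() == res.k + 1)


# ------------------------------------------------------------ PERMANOVA
def test_permanova_maximal_separation_gives_minimal_p():
    """Identical rows within groups and unit distance between them: no
    permutation (other than ones reproducing the partition, which are
    vanishingly rare at n = 16) can reach the observed separation."""
    d = np.zeros((16, 16))
    d[:8, 8:] = 1.0
    d[8:, :8] = 1.0
    res = dp.permanova(_dm(d), ["g1"] * 8 + ["g2"] * 8,
                       n_permutations=99, seed=0)
    assert res.p_value == pytest.approx(1 / 100)
    assert res.r_squared > 0.9


def test_permanova_matches_exact_enumeration(rng):
    pts = rng.normal(size=(6, 2))
    pts[3:] += 1.0
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    groups = ["a"] * 3 + ["b"] * 3
    exact = exact_permanova_p(d, groups)
    res = dp.permanova(_dm(d), groups, n_permutations=9_999, seed=1)
    assert res.p_value == pytest.approx(exact, abs=0.02)


def test_permanova_pseudo_f_matches_skbio(rng):
    from skbio.stats.distance import permanova as skbio_permanova
    pts = rng.normal(size=(12, 3))
    pts[6:] += 0.8
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    groups = ["a"] * 6 + ["b"] * 6
    ours = dp.permanova(_dm(d), groups, n_permutations=99, seed=0)
    ref = skbio_permanova(_dm(d), groups, permutations=99)
    assert ours.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-10)


def test_permanova_rejects_single_group():
    with pytest.raises(ValueError, match="two groups"):
        dp.permanova(_dm(np.zeros((3, 3))), ["g"] * 3, n_permutations=99)


def test_permanova_requires_enough_permutations():
    with pytest.raises(ValueError, match="99"):
        dp.permanova(_dm(np.zeros((4, 4))), ["a", "a", "b", "b"],
                     n_permutations=10)


# ----------------------------------------------------- pipeline recovery
def test_pipeline_recovers_planted_clusters():
    """With strongly separated synthetic clusters the Ward dendrogram cut
    at the planted cluster count matches the ground truth (ARI > 0.9)
    in at least 90% of seeds."""
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        study = dp.generate_study(dp.SimulationConfig(seed=seed))
        rare, _ = dp.rarefy(study.zotu_tables[0], seed=seed)
        dm = dp.weighted_unifrac(rare, study.tree_newick)
        link = dp.ward_linkage(dm)
        rec = cut_tree(link, study.config.n_true_clusters)
        true = [study.true_cluster_labels[m] for m in dm.ids]
        if adjusted_rand_score(true, rec) > 0.9:
            hits += 1
    assert hits >= 0.9 * n_seeds


def test_selected_k_consistent_with_planted_structure(small_study):
    """The design-constrained cut never merges distinct planted clusters
    when it selects k at or above the planted count."""
    a, dm = dp.cluster_study_table(
        small_study.zotu_tables[0], small_study.tree_newick,
        small_study.arms, seed=0)
    assert a.k >= 1
    if a.k >= small_study.config.n_true_clusters:
        true = [small_study.true_cluster_labels[m] for m in dm.ids]
        rec = [a.labels[m] for m in dm.ids]
        # the design-constrained cut may refine the planted clusters but
        # must still largely agree with them
        assert adjusted_rand_score(true, rec) > 0.5


def test_arm_label_stability_report_sums_to_one(rng):
    pts = rng.normal(size=12)
    link, _ = _linkage_from_points(pts)
    ids = [f"m{i}" for i in range(12)]
    arms = {m: ("liraglutide" if i < 6 else "vehicle")
            for i, m in enumerate(ids)}
    rep = arm_label_stability(link, ids, arms, k_max=5,
                              n_permutations=50, seed=3)
    assert rep.sum() == pytest.approx(1.0)
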