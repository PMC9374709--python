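"""Rarefaction, weighted UniFrac, Ward clustering and PERMANOVA.

The clustering procedure mirrors a group-independent microbiota analysis:
count tables are rarefied to a common depth (mice below it are excluded),
pairwise normalized weighted UniFrac dissimilarities are computed on a
rooted phylogeny, samples are merged by Ward's minimum-variance method
(ward.D2 semantics applied directly to the UniFrac matrix), and the
dendrogram is cut at the largest cluster count for which every cluster
still contains mice from both the treatment and the control arm — the
design constraint that makes the clusters usable as an ANOVA factor.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from skbio import TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.distance import DistanceMatrix

from .tables import ZotuTable

__all__ = [
    "ClusterAssignment",
    "PermanovaResult",
    "rarefy",
    "weighted_unifrac",
    "ward_linkage",
    "select_cluster_count",
    "permanova",
    "cluster_study_table",
    "arm_label_stability",
]

RAREFACTION_DEPTH = 10_000


@dataclass
class ClusterAssignment:
    """Mouse -> cluster labels (1..k) plus excluded mice with reasons."""

    labels: dict[str, int]
    k: int
    excluded: list[tuple[str, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        present = set(self.labels.values())
        if self.labels and present != set(range(1, self.k + 1)):
            raise ValueError(
                f"labels must cover 1..{self.k} with no empty cluster, "
                f"got {sorted(present)}"
            )

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="cluster")

    def write_csv(self, path) -> None:
        rows = [{"mouse_id": m, "cluster": c, "excluded_reason": ""}
                for m, c in self.labels.items()]
        rows += [{"mouse_id": m, "cluster": "", "excluded_reason": r}
                 for m, r in self.excluded]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    r_squared: float


# -------------------------------------------------------------- rarefy
def rarefy(table: ZotuTable, depth: int = RAREFACTION_DEPTH,
           seed=None) -> tuple[ZotuTable, list[tuple[str, str]]]:
    """Subsample each mouse's counts to exactly ``depth`` reads.

    Sampling is without replacement (multivariate hypergeometric), so a
    mouse with exactly ``depth`` reads is retained unchanged. Mice below
    the target depth cannot be rarefied and are excluded with a reason.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    keep_idx, excluded = [], []
    depths = table.depth
    for i, m in enumerate(table.mouse_ids):
        if depths[i] < depth:
            excluded.append((m, f"insufficient reads ({depths[i]} < {depth})"))
        else:
            keep_idx.append(i)
    if not keep_idx:
        raise ValueError("no clusterable samples: all mice below depth")
    counts = np.empty((len(keep_idx), table.n_zotus), dtype=np.int64)
    for r, i in enumerate(keep_idx):
        row = table.counts[i]
        if depths[i] == depth:
            counts[r] = row
        else:
            counts[r] = rng.multivariate_hypergeometric(row, depth)
    sub = ZotuTable([table.mouse_ids[i] for i in keep_idx],
                    list(table.zotu_ids), counts)
    return sub, excluded


# ------------------------------------------------------------- UniFrac
def weighted_unifrac(table: ZotuTable, tree) -> DistanceMatrix:
    """Pairwise normalized weighted UniFrac dissimilarities.

    For samples A and B the dissimilarity is
    ``sum_b l_b |p_A(b) - p_B(b)| / sum_b l_b (p_A(b) + p_B(b))`` over
    tree branches b with length l_b, where p(b) is the fraction of the
    sample's reads descending from b; values lie in [0, 1].
    """
    if isinstance(tree, str):
        tree = TreeNode.read(io.StringIO(tree))
    leaves = {t.name for t in tree.tips()}
    missing = [z for z in table.zotu_ids if z not in leaves]
    if missing:
        raise ValueError(f"zOTUs missing from the tree: {missing[:5]}")
    if np.any(table.depth == 0):
        empty = [m for m, d in zip(table.mouse_ids, table.depth) if d == 0]
        raise ValueError(f"samples with zero reads: {empty[:5]}")
    return beta_diversity(
        "weighted_unifrac", table.counts, ids=table.mouse_ids,
        taxa=table.zotu_ids, tree=tree, normalized=True,
    )


# ---------------------------------------------------------------- Ward
def ward_linkage(d: DistanceMatrix) -> np.ndarray:
    """Ward's minimum-variance merge tree on a dissimilarity matrix.

    Applies the Lance-Williams Ward update directly to the (UniFrac)
    dissimilarities, i.e. ward.D2 semantics; no Euclidean embedding is
    performed first.
    """
    if len(d.ids) < 2:
        raise ValueError("need at least two samples to cluster")
    return sch.linkage(d.condensed_form(), method="ward")


def cut_tree(linkage: np.ndarray, k: int) -> np.ndarray:
    """Partition into k groups, labels 1..k by first appearance."""
    raw = sch.fcluster(linkage, t=k, criterion="maxclust")
    # relabel deterministically in order of first occurrence
    remap: dict[int, int] = {}
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    return np.array([remap[lab] for lab in raw])


def select_cluster_count(linkage: np.ndarray, ids: list[str],
                         arms: dict[str, str], k_max: int = 8,
                         excluded: list[tuple[str, str]] | None = None
                         ) -> ClusterAssignment:
    """Largest k <= k_max with both arms represented in every cluster.

    Scans k from k_max down to 1 and returns the first cut of the Ward
    dendrogram in which each cluster contains at least one treated and
    one control mouse; k = 1 is always feasible.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    arm_vec = np.array([arms[m] for m in ids])
    if len(set(arm_vec)) < 2 and k_max > 1:
        k_max = 1
    n = len(ids)
    for k in range(min(k_max, n), 0, -1):
        labels = cut_tree(linkage, k) if k > 1 else np.ones(n, dtype=int)
        ok = all(
            len(set(arm_vec[labels == c])) >= 2
            for c in range(1, labels.max() + 1)
        ) if k > 1 else True
        if ok and labels.max() == k:
            return ClusterAssignment(
                labels={m: int(c) for m, c in zip(ids, labels)},
                k=k,
                excluded=list(excluded or []),
                metadata={"k_max": k_max, "linkage": "ward.D2"},
            )
    raise AssertionError("unreachable: k=1 is always feasible")


# ----------------------------------------------------------- PERMANOVA
def _pseudo_f(d2: np.ndarray, masks: np.ndarray, sizes: np.ndarray,
              ss_total: float) -> tuple[float, float]:
    """Anderson's pseudo-F from squared distances and group masks."""
    n = d2.shape[0]
    a = len(sizes)
    ss_within = 0.0
    for g in range(a):
        b = masks[g]
        ss_within += (b @ d2 @ b) / (2.0 * sizes[g])
    ss_among = ss_total - ss_within
    if ss_within == 0.0:
        f = np.inf if ss_among > 0 else 0.0
    else:
        f = (ss_among / (a - 1)) / (ss_within / (n - a))
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(d: DistanceMatrix, groups, n_permutations: int = 999,
              seed=None) -> PermanovaResult:
    """One-way PERMANOVA of group separation in a distance matrix.

    The pseudo-F follows Anderson's sum-of-squares formulation computed
    directly from the distance matrix; the p-value is
    ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)`` under random
    relabelling of the samples.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    groups = np.asarray(list(groups))
    if isinstance(d, DistanceMatrix):
        dist = d.data
    else:
        dist = np.asarray(d, dtype=float)
    n = dist.shape[0]
    if len(groups) != n:
        raise ValueError("groups length must match the distance matrix")
    levels, inverse = np.unique(groups, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    d2 = dist ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    sizes = np.bincount(inverse).astype(float)
    masks = np.stack([(inverse == g).astype(float) for g in range(len(levels))])
    f_obs, r2 = _pseudo_f(d2, masks, sizes, ss_total)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        pm = masks[:, perm]
        f_perm, _ = _pseudo_f(d2, pm, sizes, ss_total)
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_F=float(f_obs), p_value=float(p),
        n_permutations=n_permutations, r_squared=float(r2),
    )


# ------------------------------------------------------------- pipeline
def cluster_study_table(table: ZotuTable, tree, arms: dict[str, str],
                        depth: int = RAREFACTION_DEPTH, k_max: int = 8,
                        seed=None) -> tuple[ClusterAssignment, DistanceMatrix]:
    """Full clustering chain for one timepoint's zOTU table.

    rarefy -> weighted UniFrac -> Ward -> design-constrained cut. The
    returned assignment records the rarefaction seed and the excluded
    mice; the distance matrix covers retained mice only.
    """
    rare, excluded = rarefy(table, depth=depth, seed=seed)
    dm = weighted_unifrac(rare, tree)
    link = ward_linkage(dm)
    assignment = select_cluster_count(link, list(dm.ids), arms,
                                      k_max=k_max, excluded=excluded)
    assignment.metadata.update({
        "rarefaction_depth": depth,
        "rarefaction_seed": seed,
        "unifrac": "weighted, normalized",
    })
    return assignment, dm


def arm_label_stability(linkage: np.ndarray, ids: list[str],
                        arms: dict[str, str], k_max: int = 8,
                        n_permutations: int = 100,
                        seed=None) -> pd.Series:
    """Stability of the selected cluster count under arm-label permutation.

    This is an interpretation of an otherwise under-specified
    permutation step, offered as a diagnostic only: the treatment/control
    labels are permuted across mice ``n_permutations`` times and the
    design-constrained cluster count re-selected each time. The returned
    series is the frequency of each selected k.
    """
    rng = np.random.default_rng(seed)
    arm_vec = np.array([arms[m] for m in ids])
    ks = []
    for _ in range(n_permutations):
        perm = rng.permutation(len(ids))
        permuted = {m: arm_vec[j] for m, j in zip(ids, perm)}
        ks.append(select_cluster_count(linkage, ids, permuted, k_max).k)
    return pd.Series(ks, name="k").value_counts(normalize=True).sort_index()
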