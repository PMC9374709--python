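"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives a quantity from its definition by direct
enumeration, deliberately sharing no code with the package paths it
checks.
"""

import io
import itertools

import numpy as np
from skbio import TreeNode


def naive_weighted_unifrac(counts_a, counts_b, taxa, newick):
    """Normalized weighted UniFrac by explicit enumeration of branches.

    For every node (branch above it), accumulate
    length * |p_A - p_B| and length * (p_A + p_B), where p is the
    fraction of the sample's reads on leaves below the branch.
    """
    tree = TreeNode.read(io.StringIO(newick))
    a = {t: c for t, c in zip(taxa, counts_a)}
    b = {t: c for t, c in zip(taxa, counts_b)}
    tot_a, tot_b = sum(a.values()), sum(b.values())
    num = den = 0.0
    for node in tree.postorder():
        if node.is_root() or not node.length:
            continue
        leaves = [t.name for t in node.tips()] or [node.name]
        pa = sum(a.get(l, 0) for l in leaves) / tot_a
        pb = sum(b.get(l, 0) for l in leaves) / tot_b
        num += node.length * abs(pa - pb)
        den += node.length * (pa + pb)
    return num / den if den else 0.0


def naive_ward_partitions(dist):
    """Lance-Williams ward.D2 agglomeration; partition at every k.

    Returns {k: tuple of frozensets} for k = n..1, merging the pair with
    the minimal criterion at each step.
    """
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    # ward.D2 operates on squared dissimilarities
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = dist[i, j] ** 2
    sizes = {i: 1 for i in range(n)}
    partitions = {n: tuple(clusters.values())}
    next_id = n
    while len(clusters) > 1:
        (i, j), _ = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        si, sj = sizes[i], sizes[j]
        merged = clusters[i] | clusters[j]
        new_d2 = {}
        for k in clusters:
            if k in (i, j):
                continue
            sk = sizes[k]
            dik = d2[tuple(sorted((i, k)))]
            djk = d2[tuple(sorted((j, k)))]
            dij = d2[(i, j)]
            new_d2[k] = ((si + sk) * dik + (sj + sk) * djk - sk * dij) \
                / (si + sj + sk)
        del clusters[i], clusters[j], sizes[i], sizes[j]
        d2 = {key: v for key, v in d2.items()
              if i not in key and j not in key}
        clusters[next_id] = merged
        sizes[next_id] = si + sj
        for k, v in new_d2.items():
            d2[tuple(sorted((k, next_id)))] = v
        partitions[len(clusters)] = tuple(clusters.values())
        next_id += 1
    return partitions


def brute_force_max_k(partition_by_k, arm_of, k_max):
    """Largest k <= k_max whose partition has both arms in every block."""
    for k in range(k_max, 0, -1):
        if k not in partition_by_k:
            continue
        blocks = partition_by_k[k]
        if all(len({arm_of[m] for m in blk}) >= 2 for blk in blocks):
            return k
    return 1


def exact_permanova_p(dist, groups):
    """Exact permutation p-value by enumerating all distinct labelings."""
    groups = np.asarray(groups)
    n = len(groups)

    def pseudo_f(labels):
        d2 = dist ** 2
        ss_t = d2[np.triu_indices(n, 1)].sum() / n
        ss_w = 0.0
        a = 0
        for g in np.unique(labels):
            idx = np.where(labels == g)[0]
            a += 1
            for p, q in itertools.combinations(idx, 2):
                ss_w += d2[p, q] / len(idx)
        return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))

    f_obs = pseudo_f(groups)
    count = total = 0
    for perm in set(itertools.permutations(groups)):
        total += 1
        if pseudo_f(np.array(perm)) >= f_obs - 1e-12:
            count += 1
    return count / total


def simulate_two_group_rejection(d, sd, n, reps, rng, alpha=0.05):
    """Empirical rejection rate of the two-sided pooled t test."""
    import scipy.stats as sps
    a = rng.normal(d, sd, size=(reps, n))
    b = rng.normal(0.0, sd, size=(reps, n))
    sp = np.sqrt((a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)) / 2)
    t = (a.mean(axis=1) - b.mean(axis=1)) / (sp * np.sqrt(2 / n))
    crit = sps.t.ppf(1 - alpha / 2, 2 * n - 2)
    return float(np.mean(np.abs(t) >= crit))


def simulate_factorial_rejection(d, sd, n, n_blocks, reps, rng, alpha=0.05,
                                 block_sd=5.0):
    """Rejection rate of the treatment F test in a balanced additive
    two-way ANOVA with ``n_blocks`` blocks (vectorized over reps)."""
    import scipy.stats as sps
    m = max(n // n_blocks, 1)  # mice per block per arm
    n_tot = m * n_blocks
    y = rng.normal(0.0, sd, size=(reps, n_blocks, 2, m))
    y += rng.normal(0.0, block_sd, size=(reps, n_blocks, 1, 1))
    y[:, :, 0, :] += d
    grand = y.mean(axis=(1, 2, 3), keepdims=True)
    arm_mean = y.mean(axis=(1, 3), keepdims=True)
    blk_mean = y.mean(axis=(2, 3), keepdims=True)
    ss_a = n_tot * ((arm_mean - grand) ** 2).sum(axis=(1, 2, 3))
    ss_b = 2 * m * ((blk_mean - grand) ** 2).sum(axis=(1, 2, 3))
    ss_res = ((y - grand) ** 2).sum(axis=(1, 2, 3)) - ss_a - ss_b
    df_res = 2 * n_tot - 2 - (n_blocks - 1)
    f = ss_a / (ss_res / df_res)
    crit = sps.f.ppf(1 - alpha, 1, df_res)
    return float(np.mean(f >= crit))


def shannon_evenness(freqs):
    freqs = np.asarray(freqs, dtype=float)
    freqs = freqs / freqs.sum()
    if len(freqs) == 1:
        return 1.0
    h = -(freqs * np.log(freqs)).sum()
    return h / np.log(len(freqs))
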