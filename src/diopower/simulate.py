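"""Synthetic DIO-mouse intervention studies with latent microbiota clusters.

Generates every input the analysis pipeline consumes: zOTU count tables at
two sampling timepoints (Dirichlet-multinomial around cluster-specific
centroid compositions, lognormal sequencing depth with a dropout fraction
below the rarefaction threshold), a rooted phylogeny over the zOTUs (random
coalescent topology with exponential branch lengths), STR genotypes
realizing a target allele-frequency band spectrum, and pre/post phenotypes
whose treated Δ-values carry cluster-specific means and standard deviations.
Latent cluster membership is drawn independently of the treatment arm, so
any power gain from cluster adjustment reflects variance explained, not
confounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import (
    SimulationConfig, DELTA_ENDPOINTS, TERMINAL_ENDPOINTS, ENDPOINTS,
)
from .stats import (
    OgttCurve, PhenotypeRecord, OGTT_TIMES, ogtt_auc, phenotypes_to_frame,
)
from .strs import StrGenotypeTable, MISSING
from .tables import ZotuTable

__all__ = [
    "SyntheticStudy",
    "generate_study",
    "generate_zotu_table",
    "generate_str_genotypes",
    "generate_phenotypes",
    "random_coalescent_newick",
    "cluster_centroids",
]

# OGTT curve shape: fasting baseline, gavage peak at 15-30 min, slow return
_OGTT_SHAPE = np.array([1.0, 2.3, 2.6, 2.1, 1.6, 1.25])

_PRE_MEANS = {"hba1c": (42.0, 2.5), "body_weight": (44.0, 4.0)}
_FASTING_GLUCOSE = (9.0, 0.8)  # mmol/L at t=0, pre-intervention
_INSULIN_LOG = (math.log(3000.0), 0.30)  # pg/ml, vehicle terminal
_LEPTIN_LOG = (math.log(70_000.0), 0.35)  # pg/ml, vehicle terminal


@dataclass
class SyntheticStudy:
    """A complete simulated study: inputs plus hidden ground truth."""

    config: SimulationConfig
    phenotypes: list[PhenotypeRecord]
    zotu_tables: list[ZotuTable]  # one per timepoint
    tree_newick: str
    str_genotypes: StrGenotypeTable
    true_cluster_labels: dict[str, int] = field(repr=False)
    arms: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        mice = [p.mouse_id for p in self.phenotypes]
        if len(set(mice)) != len(mice):
            raise ValueError("duplicate mouse_id in phenotypes")
        for tab in self.zotu_tables:
            if sorted(tab.mouse_ids) != sorted(mice):
                raise ValueError("zOTU table mice differ from phenotype mice")
        if sorted(self.str_genotypes.mouse_ids) != sorted(mice):
            raise ValueError("STR table mice differ from phenotype mice")

    def write(self, out_dir) -> dict[str, Path]:
        """Serialize every component; returns the map of written paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for t, tab in enumerate(self.zotu_tables, start=1):
            p = out / f"zotu_time{t}.tsv"
            tab.write_tsv(p)
            paths[f"zotu_time{t}_tsv"] = p
            pb = out / f"zotu_time{t}.biom"
            tab.write_biom(pb)
            paths[f"zotu_time{t}_biom"] = pb
        paths["tree"] = out / "tree.nwk"
        paths["tree"].write_text(self.tree_newick)
        paths["phenotypes"] = out / "phenotypes.csv"
        phenotypes_to_frame(self.phenotypes).to_csv(
            paths["phenotypes"], index=False)
        paths["str_genotypes"] = out / "str_genotypes.csv"
        self.str_genotypes.write_csv(paths["str_genotypes"])
        paths["config"] = out / "config.yaml"
        self.config.to_yaml(paths["config"])
        paths["true_clusters"] = out / "true_clusters.csv"
        with open(paths["true_clusters"], "w") as fh:
            fh.write("mouse_id,true_cluster,arm\n")
            for m in sorted(self.true_cluster_labels):
                fh.write(f"{m},{self.true_cluster_labels[m]},{self.arms[m]}\n")
        return paths


# ------------------------------------------------------------------ tree
def random_coalescent_newick(leaf_names: list[str],
                             rng: np.random.Generator) -> str:
    """Rooted random-coalescent topology with exponential branch lengths."""
    if len(leaf_names) < 2:
        raise ValueError("need at least two leaves")
    nodes = [(name, 0.0) for name in leaf_names]
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        merged = f"({na}:{height - ha:.6f},{nb}:{height - hb:.6f})"
        nodes = [nodes[m] for m in range(k) if m not in (i, j)]
        nodes.append((merged, height))
    return nodes[0][0] + ";"


# ------------------------------------------------------------- microbiome
def cluster_centroids(config: SimulationConfig,
                      rng: np.random.Generator,
                      n_clusters: int | None = None) -> np.ndarray:
    """Cluster-specific composition vectors over the zOTU panel.

    A shared lognormal baseline profile, with a disjoint block of zOTUs
    boosted per cluster; ``cluster_separation`` scales the boost (0 makes
    all centroids identical).
    """
    k = n_clusters if n_clusters is not None else config.n_true_clusters
    base = rng.lognormal(0.0, 1.0, size=config.n_zotus)
    block = max(3, config.n_zotus // max(3 * k, 1))
    boost = math.exp(2.2 * config.cluster_separation)
    centroids = np.tile(base, (k, 1))
    for c in range(k):
        lo, hi = c * block, min((c + 1) * block, config.n_zotus)
        centroids[c, lo:hi] *= boost
    return centroids / centroids.sum(axis=1, keepdims=True)


def generate_zotu_table(cluster_labels: dict[str, int],
                        config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        centroids: np.ndarray | None = None) -> ZotuTable:
    """Dirichlet-multinomial counts conditional on latent cluster.

    Per-mouse depth is lognormal, truncated below at the dropout
    threshold except for a ``dropout_fraction`` of mice whose library is
    drawn uniformly below it (these cannot be rarefied and will be
    excluded downstream).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mice = list(cluster_labels)
    labels = np.array([cluster_labels[m] for m in mice])
    if centroids is None:
        centroids = cluster_centroids(config, rng, int(labels.max()) + 1)
    if labels.max() >= len(centroids):
        raise ValueError(
            f"{labels.max() + 1} clusters but only {len(centroids)} "
            "composition vectors"
        )
    zotus = [f"zOTU{j + 1:04d}" for j in range(config.n_zotus)]
    counts = np.zeros((len(mice), config.n_zotus), dtype=np.int64)
    for i, c in enumerate(labels):
        comp = rng.dirichlet(centroids[c] * config.dirichlet_concentration)
        if rng.random() < config.dropout_fraction:
            depth = int(rng.integers(config.dropout_threshold // 2,
                                     config.dropout_threshold))
        else:
            raw = rng.lognormal(config.read_depth_log_mean,
                                config.read_depth_log_sd)
            depth = max(config.dropout_threshold, int(round(raw)))
        counts[i] = rng.multinomial(depth, comp)
    return ZotuTable(mice, zotus, counts)


# -------------------------------------------------------------------- STR
def generate_str_genotypes(config: SimulationConfig,
                           rng: np.random.Generator | None = None,
                           mouse_ids: list[str] | None = None
                           ) -> StrGenotypeTable:
    """STR genotypes whose realized band spectrum matches the spec exactly.

    For each marker the most-prevalent-allele count over the 2N allele
    slots is drawn inside its assigned frequency band and the remaining
    slots are partitioned among 1-5 minor alleles (each kept at or below
    the major count so the band is exact by construction). Slots are
    paired at random into per-mouse calls, which yields heterozygous
    calls wherever minor alleles exist.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if mouse_ids is None:
        n = 2 * config.n_mice_per_arm * config.n_substrains
        mouse_ids = [f"m{i + 1:03d}" for i in range(n)]
    n = len(mouse_ids)
    slots = 2 * n
    spec = tuple(config.str_band_spec)
    if sum(spec) != config.n_str_markers:
        raise ValueError("str_band_spec must sum to n_str_markers")
    band_edges = ((1.0, 1.0), (0.9, 1.0), (0.8, 0.9), (0.7, 0.8),
                  (0.6, 0.7), (0.5, 0.6), (0.4, 0.5))
    bands_per_marker: list[int] = []
    for b, count in enumerate(spec):
        bands_per_marker.extend([b] * count)
    order = rng.permutation(len(bands_per_marker))
    markers = [f"STR{j + 1:03d}" for j in range(config.n_str_markers)]
    a1 = np.zeros((n, config.n_str_markers), dtype=np.int64)
    a2 = np.zeros_like(a1)
    for j, idx in enumerate(order):
        band = bands_per_marker[idx]
        lo, hi = band_edges[band]
        if band == 0:
            major = slots
        else:
            k_lo = math.ceil(lo * slots)
            k_hi = math.ceil(hi * slots) - 1  # strictly below the upper edge
            if k_hi < k_lo:
                raise ValueError(
                    f"band {band} is unrealizable with {slots} allele slots"
                )
            major = int(rng.integers(k_lo, k_hi + 1))
        rest = slots - major
        if rest == 0:
            counts = [major]
        else:
            m_min = math.ceil(rest / major)  # keep minors <= major
            m_max = min(5, rest)
            m = int(rng.choice([x for x in (1, 2, 3, 4, 5)
                                if m_min <= x <= m_max] or [m_min]))
            minors = [1] * m
            for _ in range(rest - m):
                open_idx = [t for t in range(m) if minors[t] < major]
                minors[open_idx[int(rng.integers(len(open_idx)))]] += 1
            counts = [major] + minors
        base = int(rng.integers(80, 350))
        sizes = base + 2 * np.arange(len(counts))
        sizes = sizes[rng.permutation(len(sizes))]
        pool = np.repeat(sizes, counts)
        rng.shuffle(pool)
        a1[:, j] = pool[0::2]
        a2[:, j] = pool[1::2]
    if config.str_missing_rate > 0:
        miss = rng.random((n, config.n_str_markers)) < config.str_missing_rate
        a1[miss] = MISSING
        a2[miss] = MISSING
    return StrGenotypeTable(list(mouse_ids), markers, a1, a2)


# -------------------------------------------------------------- phenotypes
def _draw_delta(endpoint: str, cluster: int, treated: bool,
                config: SimulationConfig, rng: np.random.Generator) -> float:
    sds = config.residual_sd_by_cluster.get(endpoint)
    sd = sds[cluster] if sds is not None else 3.0
    if treated:
        effects = config.treatment_effect_by_cluster.get(endpoint)
        mean = effects[cluster] if effects is not None else 0.0
    else:
        mean = config.vehicle_drift.get(endpoint, 0.0)
    return float(rng.normal(mean, sd))


def generate_phenotypes(cluster_labels: dict[str, int],
                        arms: dict[str, str],
                        config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        substrains: dict[str, str] | None = None
                        ) -> list[PhenotypeRecord]:
    """Pre/post phenotypes with cluster-conditional treatment effects.

    Δ-endpoints are realized exactly: the post value is the pre value
    scaled by the drawn Δ. The post OGTT curve is built so its
    trapezoidal AUC carries the drawn OGTT Δ while its t=0 point carries
    the drawn fasting-glucose Δ. Terminal insulin and leptin are
    lognormal with a multiplicative treatment effect; leptin is censored
    at the assay ceiling.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times = np.asarray(OGTT_TIMES)
    # trapezoid weights: AUC = sum(w_i * g_i)
    w = np.zeros_like(times)
    w[0] = (times[1] - times[0]) / 2
    w[-1] = (times[-1] - times[-2]) / 2
    w[1:-1] = (times[2:] - times[:-2]) / 2
    records: list[PhenotypeRecord] = []
    for mouse in cluster_labels:
        c = cluster_labels[mouse]
        treated = arms[mouse] == "liraglutide"
        deltas = {e: _draw_delta(e, c, treated, config, rng)
                  for e in ENDPOINTS}

        hba1c_pre = rng.normal(*_PRE_MEANS["hba1c"])
        hba1c_post = hba1c_pre * (1 + deltas["hba1c"] / 100)
        bw_pre = rng.normal(*_PRE_MEANS["body_weight"])
        bw_post = bw_pre * (1 + deltas["body_weight"] / 100)

        fasting = rng.normal(*_FASTING_GLUCOSE)
        shape_noise = 1 + rng.normal(0, 0.05, size=len(times))
        shape_noise[0] = 1.0
        g_pre = np.maximum(fasting * _OGTT_SHAPE * shape_noise, 0.5)
        auc_pre = float(np.dot(w, g_pre))
        g0_post = g_pre[0] * (1 + deltas["fasting_glucose"] / 100)
        target_auc = auc_pre * (1 + deltas["ogtt_auc"] / 100)
        scale = (target_auc - w[0] * g0_post) / (auc_pre - w[0] * g_pre[0])
        g_post = np.concatenate([[g0_post], scale * g_pre[1:]])
        if np.any(g_post <= 0):
            raise ValueError(
                "configured OGTT/fasting-glucose deltas produce a "
                "non-positive glucose curve"
            )

        insulin = math.exp(rng.normal(*_INSULIN_LOG))
        insulin *= 1 + deltas["insulin"] / 100
        leptin = math.exp(rng.normal(*_LEPTIN_LOG))
        leptin *= 1 + deltas["leptin"] / 100
        leptin = min(leptin, config.leptin_ceiling)

        records.append(PhenotypeRecord(
            mouse_id=mouse,
            substrain=(substrains or {}).get(mouse, "sim1"),
            arm=arms[mouse],
            hba1c_pre=float(hba1c_pre),
            hba1c_post=float(hba1c_post),
            ogtt_pre=OgttCurve(tuple(times), tuple(map(float, g_pre))),
            ogtt_post=OgttCurve(tuple(times), tuple(map(float, g_post))),
            bw_pre=float(bw_pre),
            bw_post=float(bw_post),
            fasting_glucose=float(g_post[0]),
            insulin=float(max(insulin, 1.0)),
            leptin=float(max(leptin, 1.0)),
        ))
    return records


# ------------------------------------------------------------------ study
def generate_study(config: SimulationConfig,
                   seed: int | None = None) -> SyntheticStudy:
    """Generate a full synthetic study; bit-reproducible for a fixed seed."""
    config.validate()
    root = config.seed if seed is None else seed
    rng = np.random.default_rng(root)
    mixing = np.asarray(config.mixing)

    cluster_labels: dict[str, int] = {}
    arms: dict[str, str] = {}
    substrains: dict[str, str] = {}
    for s in range(config.n_substrains):
        name = f"sim{s + 1}"
        n = 2 * config.n_mice_per_arm
        mice = [f"{name}_m{i + 1:03d}" for i in range(n)]
        arm_vec = np.array(["liraglutide"] * config.n_mice_per_arm
                           + ["vehicle"] * config.n_mice_per_arm)
        arm_vec = arm_vec[rng.permutation(n)]
        # latent clusters drawn independently of arm
        labs = rng.choice(config.n_true_clusters, size=n, p=mixing)
        for m, a, c in zip(mice, arm_vec, labs):
            arms[m] = str(a)
            cluster_labels[m] = int(c) + s * config.n_true_clusters
            substrains[m] = name

    zotus = [f"zOTU{j + 1:04d}" for j in range(config.n_zotus)]
    tree_newick = random_coalescent_newick(zotus, rng)
    n_total_clusters = config.n_substrains * config.n_true_clusters
    centroids = cluster_centroids(config, rng, n_total_clusters)
    tables = [
        generate_zotu_table(cluster_labels, config, rng, centroids)
        for _ in range(config.n_timepoints)
    ]
    genotypes = generate_str_genotypes(config, rng, list(cluster_labels))
    phenotypes = generate_phenotypes(cluster_labels, arms, config, rng,
                                     substrains)
    return SyntheticStudy(
        config=config,
        phenotypes=phenotypes,
        zotu_tables=tables,
        tree_newick=tree_newick,
        str_genotypes=genotypes,
        true_cluster_labels=cluster_labels,
        arms=arms,
    )
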