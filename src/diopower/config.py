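"""Study-design configuration for the synthetic-data generator.

The defaults describe the study conditions the pipeline is built around: two
arms (liraglutide vs vehicle), a latent gut-microbiota cluster structure that
modulates the treatment effect on glucose-related endpoints, lognormal
sequencing depth with a dropout fraction below the 10,000-read rarefaction
threshold, a 243-marker STR panel with a Janvier-like allele-frequency band
spectrum, and leptin censored at the 100,000 pg/ml assay ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = [
    "SimulationConfig",
    "ENDPOINTS",
    "DELTA_ENDPOINTS",
    "TERMINAL_ENDPOINTS",
    "STR_BANDS",
    "B6NRJ_BAND_SPEC",
    "B6NTAC_BAND_SPEC",
]

#: Endpoints expressed as pre/post Δ-values (percent of pre).
DELTA_ENDPOINTS = ("hba1c", "ogtt_auc", "body_weight", "fasting_glucose")
#: Endpoints measured only at termination, analysed on the raw scale.
TERMINAL_ENDPOINTS = ("insulin", "leptin")
ENDPOINTS = DELTA_ENDPOINTS + TERMINAL_ENDPOINTS

#: Frequency bands for the most prevalent allele of an STR, highest first:
#: 100%, >=90%<100%, >=80%<90%, >=70%<80%, >=60%<70%, >=50%<60%, >=40%<50%.
STR_BANDS = (
    "100%",
    ">=90%<100%",
    ">=80%<90%",
    ">=70%<80%",
    ">=60%<70%",
    ">=50%<60%",
    ">=40%<50%",
)
_BAND_EDGES = ((1.0, 1.0), (0.9, 1.0), (0.8, 0.9), (0.7, 0.8),
               (0.6, 0.7), (0.5, 0.6), (0.4, 0.5))

#: Observed band spectra of the two C57BL/6N sub-strain colonies
#: (number of markers per band, summing to the 243-marker panel).
B6NRJ_BAND_SPEC = (72, 101, 36, 14, 8, 10, 2)
B6NTAC_BAND_SPEC = (138, 89, 10, 3, 2, 1, 0)


# Canonical 3-cluster mean treated Δ (percent); heterogeneous across
# clusters, which is exactly the structure cluster-adjusted analysis
# exploits.
_CANONICAL_EFFECTS = {
    "hba1c": (0.0, -5.0, -15.0),
    "ogtt_auc": (-10.0, -20.0, -30.0),
    "body_weight": (-8.0, -12.0, -16.0),
    "fasting_glucose": (-5.0, -10.0, -15.0),
    "insulin": (-10.0, -20.0, -30.0),
    "leptin": (-20.0, -30.0, -40.0),
}


def _default_effects(k: int) -> dict[str, tuple[float, ...]]:
    out = {}
    for e, (lo, mid, hi) in _CANONICAL_EFFECTS.items():
        if k == 3:
            out[e] = (lo, mid, hi)
        elif k == 1:
            out[e] = ((lo + mid + hi) / 3.0,)
        else:
            out[e] = tuple(float(x) for x in np.linspace(lo, hi, k))
    return out


def _default_sds(k: int) -> dict[str, tuple[float, ...]]:
    return {e: (3.0,) * k for e in ENDPOINTS}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic DIO-mouse intervention study.

    Attributes
    ----------
    n_mice_per_arm : int
        Mice per treatment arm per sub-strain (16 mirrors the Taconic
        groups; the Janvier groups used 23).
    n_substrains : int
        Independent sub-strain colonies to simulate.
    n_true_clusters : int
        Latent microbiota clusters per sub-strain.
    cluster_mixing : tuple of float, optional
        Probability of each cluster; uniform when omitted.
    n_zotus : int
        zOTUs in the count table.
    read_depth_log_mean, read_depth_log_sd : float
        Natural-log parameters of the per-mouse total read count.
    dropout_threshold : int
        Rarefaction depth in reads; mice below it cannot be clustered.
    dropout_fraction : float
        Probability that a mouse's library lands below the threshold.
    treatment_effect_by_cluster : dict
        endpoint -> per-cluster mean treated Δ (percent).
    residual_sd_by_cluster : dict
        endpoint -> per-cluster within-cluster s.d. of Δ (percent points).
    vehicle_drift : dict
        endpoint -> mean vehicle-arm Δ (percent); default 0 everywhere.
    cluster_separation : float
        Scales the divergence of cluster centroid compositions; 0 removes
        all microbiota structure.
    dirichlet_concentration : float
        Dirichlet precision around each centroid (larger = tighter).
    n_str_markers : int
        STR panel size.
    str_band_spec : tuple of int
        Markers per most-prevalent-allele frequency band (see STR_BANDS);
        must sum to ``n_str_markers``.
    str_missing_rate : float
        Probability that a genotype call is missing.
    leptin_ceiling : float
        Assay detection ceiling in pg/ml; larger values are censored.
    seed : int
        Root seed; a fixed seed reproduces the study bit for bit.
    """

    n_mice_per_arm: int = 16
    n_substrains: int = 1
    n_true_clusters: int = 3
    cluster_mixing: tuple[float, ...] | None = None
    n_zotus: int = 150
    read_depth_log_mean: float = math.log(30_000.0)
    read_depth_log_sd: float = 0.35
    dropout_threshold: int = 10_000
    dropout_fraction: float = 0.1
    treatment_effect_by_cluster: dict | None = None
    residual_sd_by_cluster: dict | None = None
    vehicle_drift: dict = field(default_factory=dict)
    cluster_separation: float = 2.0
    dirichlet_concentration: float = 200.0
    n_timepoints: int = 2
    n_str_markers: int = 243
    str_band_spec: tuple[int, ...] = B6NRJ_BAND_SPEC
    str_missing_rate: float = 0.0
    leptin_ceiling: float = 100_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.treatment_effect_by_cluster is None:
            self.treatment_effect_by_cluster = _default_effects(
                self.n_true_clusters)
        if self.residual_sd_by_cluster is None:
            self.residual_sd_by_cluster = _default_sds(self.n_true_clusters)
        self.validate()

    # ------------------------------------------------------------ checks
    def validate(self) -> None:
        for name in ("n_mice_per_arm", "n_substrains", "n_true_clusters",
                     "n_zotus", "n_timepoints", "n_str_markers",
                     "dropout_threshold"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.cluster_mixing is not None:
            p = tuple(self.cluster_mixing)
            if len(p) != self.n_true_clusters:
                raise ValueError(
                    "cluster_mixing must have n_true_clusters entries"
                )
            if any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
                raise ValueError("cluster_mixing must sum to 1")
            self.cluster_mixing = p
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout_fraction must lie in [0, 1)")
        if not 0.0 <= self.str_missing_rate < 1.0:
            raise ValueError("str_missing_rate must lie in [0, 1)")
        if self.read_depth_log_sd < 0:
            raise ValueError("read_depth_log_sd must be non-negative")
        if self.dropout_threshold > math.exp(self.read_depth_log_mean):
            raise ValueError(
                "dropout_threshold exceeds the typical read depth "
                "(dropout_threshold must be <= exp(read_depth_log_mean))"
            )
        for name, table in (
            ("treatment_effect_by_cluster", self.treatment_effect_by_cluster),
            ("residual_sd_by_cluster", self.residual_sd_by_cluster),
        ):
            for endpoint, per_cluster in table.items():
                if endpoint not in ENDPOINTS:
                    raise ValueError(f"{name}: unknown endpoint {endpoint!r}")
                if len(per_cluster) != self.n_true_clusters:
                    raise ValueError(
                        f"{name}[{endpoint!r}] must give one value per cluster"
                    )
        for sds in self.residual_sd_by_cluster.values():
            if any(s <= 0 for s in sds):
                raise ValueError("residual_sd_by_cluster values must be > 0")
        if len(self.str_band_spec) > len(STR_BANDS):
            raise ValueError(
                f"str_band_spec has {len(self.str_band_spec)} entries; "
                f"at most {len(STR_BANDS)} bands exist"
            )
        if tuple(self.str_band_spec) and sum(self.str_band_spec) != self.n_str_markers:
            raise ValueError(
                f"str_band_spec sums to {sum(self.str_band_spec)}, "
                f"expected n_str_markers = {self.n_str_markers}"
            )
        if self.cluster_separation < 0:
            raise ValueError("cluster_separation must be non-negative")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if self.leptin_ceiling <= 0:
            raise ValueError("leptin_ceiling must be positive")

    @property
    def mixing(self) -> tuple[float, ...]:
        if self.cluster_mixing is not None:
            return tuple(self.cluster_mixing)
        k = self.n_true_clusters
        return tuple(1.0 / k for _ in range(k))

    # --------------------------------------------------------------- I/O
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("cluster_mixing", "str_band_spec"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        for key in ("treatment_effect_by_cluster", "residual_sd_by_cluster"):
            if raw.get(key):
                raw[key] = {k: tuple(v) for k, v in raw[key].items()}
        return cls(**raw)


def band_of(frequency: float) -> str:
    """Map a most-prevalent-allele frequency to its band label.

    Frequencies below the lowest tabulated band fall into a catch-all
    "<40%" class (never produced by the generator, but arbitrary input
    tables may reach it).
    """
    if frequency >= 1.0:
        return STR_BANDS[0]
    for label, (lo, hi) in zip(STR_BANDS[1:], _BAND_EDGES[1:]):
        if lo <= frequency < hi:
            return label
    return "<40%"


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
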