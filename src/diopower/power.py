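"""Noncentral-F power and minimum group size, one-way and cluster-adjusted.

For a two-arm comparison the treatment F test has noncentrality
``lambda = n * d^2 / (2 * sd^2)`` at n mice per arm, detectable difference
d and residual s.d. sd; power is the upper tail of the noncentral F beyond
the central-F critical value. The cluster-adjusted ("general full
factorial") design uses the cluster-size-weighted mean of the per-cluster
treatment differences as d and the pooled within-cluster s.d. as sd — a
deliberately conservative aggregation — and loses (n_blocks - 1)
denominator degrees of freedom to the block factor. When clusters explain
real variance the pooled within-cluster s.d. is smaller than the marginal
s.d., which is the entire source of the group-size reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist, ncf

__all__ = [
    "EffectSummary",
    "PowerResult",
    "marginal_effect_summary",
    "weighted_effect_summary",
    "one_way_power",
    "one_way_min_n",
    "factorial_power",
    "factorial_min_n",
    "power_report",
]

MAX_N = 10_000


@dataclass
class EffectSummary:
    """Detectable difference and s.d. for a design, per cluster if adjusted.

    ``difference``/``sd`` describe the one-way (marginal) design. When
    cluster structure is present, ``per_cluster`` holds
    (n_c, d_c, s_c) for each cluster, ``weighted_difference`` is the
    cluster-size-weighted mean of the d_c and ``pooled_sd`` pools the
    within-cluster variances with df weights n_c - 2 (two arm means
    estimated per cluster).
    """

    difference: float
    sd: float
    per_cluster: list[tuple[int, float, float]] = field(default_factory=list)
    weighted_difference: float = float("nan")
    pooled_sd: float = float("nan")
    n_blocks: int = 1

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass
class PowerResult:
    design: str  # "one_way" | "factorial"
    alpha: float
    target_power: float
    n_per_group: int
    achieved_power: float
    min_n_per_group: int


# ------------------------------------------------------------ summaries
def marginal_effect_summary(values, arm) -> EffectSummary:
    """Observed treated-vehicle difference and pooled across-arm s.d."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "arm": np.asarray(arm)})
    arms = sorted(df["arm"].unique())
    if len(arms) != 2:
        raise ValueError("expected exactly two arms")
    treated = "liraglutide" if "liraglutide" in arms else arms[1]
    control = [a for a in arms if a != treated][0]
    t = df.loc[df["arm"] == treated, "value"]
    v = df.loc[df["arm"] == control, "value"]
    pooled_var = (
        ((len(t) - 1) * t.var(ddof=1) + (len(v) - 1) * v.var(ddof=1))
        / (len(t) + len(v) - 2)
    )
    return EffectSummary(difference=float(t.mean() - v.mean()),
                         sd=float(np.sqrt(pooled_var)))


def weighted_effect_summary(values, arm, clusters) -> EffectSummary:
    """Cluster-weighted treatment difference and pooled within-cluster s.d.

    Per cluster c: d_c = mean(treated) - mean(vehicle) and s_c the
    residual s.d. around the two arm means (df = n_c - 2). The weighted
    difference uses cluster sizes n_c as weights; the pooled s.d. is
    ``sqrt(sum (n_c - 2) s_c^2 / sum (n_c - 2))``.
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "arm": np.asarray(arm),
        "cluster": np.asarray(list(clusters)),
    })
    marginal = marginal_effect_summary(df["value"], df["arm"])
    per_cluster: list[tuple[int, float, float]] = []
    for c, sub in df.groupby("cluster", observed=True):
        arms_here = sub["arm"].unique()
        if len(arms_here) < 2:
            raise ValueError(
                f"cluster {c!r} contains a single arm; clustering contract "
                "requires both arms in every cluster"
            )
        t = sub.loc[sub["arm"] != "vehicle", "value"] \
            if "vehicle" in set(arms_here) else \
            sub.loc[sub["arm"] == sorted(arms_here)[1], "value"]
        v = sub.loc[~sub.index.isin(t.index), "value"]
        n_c = len(sub)
        d_c = float(t.mean() - v.mean())
        ss = float(((t - t.mean()) ** 2).sum() + ((v - v.mean()) ** 2).sum())
        s_c = float(np.sqrt(ss / (n_c - 2))) if n_c > 2 else float("nan")
        per_cluster.append((n_c, d_c, s_c))
    n_tot = sum(n for n, _, _ in per_cluster)
    weighted_diff = sum(n * d for n, d, _ in per_cluster) / n_tot
    df_sum = sum(n - 2 for n, _, _ in per_cluster)
    if df_sum <= 0:
        raise ValueError("too few mice to pool within-cluster variances")
    pooled_var = sum(
        (n - 2) * s ** 2 for n, _, s in per_cluster if not np.isnan(s)
    ) / df_sum
    return EffectSummary(
        difference=marginal.difference,
        sd=marginal.sd,
        per_cluster=per_cluster,
        weighted_difference=float(weighted_diff),
        pooled_sd=float(np.sqrt(pooled_var)),
        n_blocks=len(per_cluster),
    )


# ----------------------------------------------------------- power core
def _ncf_power(difference: float, sd: float, n_per_group: int,
               df_den: int, alpha: float) -> float:
    lam = n_per_group * difference ** 2 / (2.0 * sd ** 2)
    crit = f_dist.ppf(1.0 - alpha, 1, df_den)
    if lam == 0:
        return alpha
    return float(ncf.sf(crit, 1, df_den, lam))


def one_way_power(difference: float, sd: float, n_per_group: int,
                  alpha: float = 0.05) -> float:
    """Power of the two-group treatment F test at n mice per group."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if n_per_group < 2:
        raise ValueError("need n_per_group >= 2")
    return _ncf_power(difference, sd, n_per_group, 2 * n_per_group - 2, alpha)


def factorial_power(summary: EffectSummary, n_per_group: int,
                    n_blocks: int | None = None,
                    alpha: float = 0.05) -> float:
    """Power of the treatment test in the block-adjusted (factorial) design.

    Uses the weighted difference and pooled within-cluster s.d.; the
    denominator df are ``2n - 2 - (n_blocks - 1)``. With one block this
    is exactly the one-way power.
    """
    blocks = n_blocks if n_blocks is not None else summary.n_blocks
    if blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    d = summary.weighted_difference if blocks > 1 else summary.difference
    sd = summary.pooled_sd if blocks > 1 else summary.sd
    if np.isnan(d) or np.isnan(sd):
        d, sd = summary.difference, summary.sd
    df_den = 2 * n_per_group - 2 - (blocks - 1)
    if df_den <= 0:
        raise ValueError("design too small: non-positive denominator df")
    return _ncf_power(d, sd, n_per_group, df_den, alpha)


def _min_n(power_fn, target_power: float) -> int:
    """Doubling then bisection for the smallest feasible n per group."""
    lo, hi = 2, 2
    while True:
        try:
            p = power_fn(hi)
        except ValueError:  # df too small at this n
            p = 0.0
        if p >= target_power:
            break
        lo = hi
        hi *= 2
        if hi > MAX_N:
            raise ValueError(
                f"infeasible: power {target_power} not reached by n={MAX_N}"
            )
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        try:
            p = power_fn(mid)
        except ValueError:
            p = 0.0
        if p >= target_power:
            hi = mid
        else:
            lo = mid
    try:
        if power_fn(hi - 1) >= target_power and hi - 1 >= 2:
            hi -= 1
    except ValueError:
        pass
    return hi


def one_way_min_n(difference: float, sd: float,
                  target_power: float = 0.90,
                  alpha: float = 0.05) -> int:
    """Smallest n per group with one-way power >= target_power."""
    if difference == 0:
        raise ValueError("infeasible: zero difference")
    return _min_n(lambda n: one_way_power(difference, sd, n, alpha),
                  target_power)


def factorial_min_n(summary: EffectSummary,
                    n_blocks: int | None = None,
                    target_power: float = 0.90,
                    alpha: float = 0.05) -> int:
    """Smallest n per group with block-adjusted power >= target_power."""
    blocks = n_blocks if n_blocks is not None else summary.n_blocks
    d = summary.weighted_difference if blocks > 1 else summary.difference
    if d == 0 or np.isnan(d):
        raise ValueError("infeasible: zero weighted difference")
    return _min_n(lambda n: factorial_power(summary, n, blocks, alpha),
                  target_power)


# -------------------------------------------------------------- report
def power_report(summary: EffectSummary, n_actual: int,
                 alpha: float = 0.05,
                 target_power: float = 0.90) -> list[PowerResult]:
    """One-way and (when clusters are present) factorial power results."""
    out = [PowerResult(
        design="one_way", alpha=alpha, target_power=target_power,
        n_per_group=n_actual,
        achieved_power=one_way_power(summary.difference, summary.sd,
                                     n_actual, alpha),
        min_n_per_group=one_way_min_n(summary.difference, summary.sd,
                                      target_power, alpha),
    )]
    if summary.n_blocks > 1:
        out.append(PowerResult(
            design="factorial", alpha=alpha, target_power=target_power,
            n_per_group=n_actual,
            achieved_power=factorial_power(summary, n_actual, alpha=alpha),
            min_n_per_group=factorial_min_n(summary, target_power=target_power,
                                            alpha=alpha),
        ))
    return out
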