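"""Endpoint construction and ANOVA for liraglutide-vs-vehicle comparisons.

Endpoints for HbA1c, OGTT AUC, body weight and fasting glucose are Δ-values,
the pre-to-post change as a percentage of the pre-intervention value; insulin
and leptin are terminal-only and analysed on the raw scale. Treatment effects
are tested by a one-tailed one-way ANOVA and by additive two-way ANOVAs with
treatment plus either a microbiota-cluster or an STR-allele factor. When a
group fails the Anderson–Darling normality check or Levene's equal-variance
check, the endpoint vector is rank-transformed before testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .config import DELTA_ENDPOINTS, TERMINAL_ENDPOINTS, ENDPOINTS

__all__ = [
    "OgttCurve",
    "PhenotypeRecord",
    "AnovaResult",
    "AssumptionReport",
    "ogtt_auc",
    "delta_effect",
    "compute_effects",
    "check_assumptions",
    "rank_transform",
    "one_way_anova",
    "two_way_anova",
    "endpoint_analysis",
    "phenotypes_to_frame",
    "frame_to_phenotypes",
    "DIRECTIONS",
]

ARMS = ("liraglutide", "vehicle")
OGTT_TIMES = (0.0, 15.0, 30.0, 60.0, 90.0, 120.0)

#: Pre-specified direction of the liraglutide effect per endpoint
#: (-1: treatment lowers the endpoint). Fixed a priori; used for the
#: one-tailed treatment p-value.
DIRECTIONS = {e: -1.0 for e in ENDPOINTS}


@dataclass
class OgttCurve:
    """Blood glucose (mmol/L) sampled at fixed minutes after gavage."""

    times: tuple[float, ...] = OGTT_TIMES
    glucose: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.times) != len(self.glucose):
            raise ValueError("times and glucose must have equal length")
        t = np.asarray(self.times, dtype=float)
        if len(t) and (t[0] != 0 or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be strictly increasing from 0")


@dataclass
class PhenotypeRecord:
    """One mouse's arm assignment and clinico-chemical measurements."""

    mouse_id: str
    substrain: str
    arm: str
    hba1c_pre: float  # mmol/mol
    hba1c_post: float
    ogtt_pre: OgttCurve
    ogtt_post: OgttCurve
    bw_pre: float  # g
    bw_post: float
    fasting_glucose: float  # mmol/L, terminal
    insulin: float  # pg/ml, terminal
    leptin: float  # pg/ml, terminal, censored at the assay ceiling

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")


@dataclass
class AssumptionReport:
    gaussian: dict[str, bool]
    equal_variance: bool

    @property
    def all_ok(self) -> bool:
        return all(self.gaussian.values()) and self.equal_variance


@dataclass
class AnovaResult:
    """F-tests from a one-way or additive two-way fixed-effects ANOVA."""

    design: str  # "one_way" | "two_way"
    factor_terms: dict[str, tuple[float, float, float, float]]  # F, df_n, df_d, p
    one_tailed_treatment_p: float
    two_tailed_treatment_p: float
    ranked: bool
    n_per_cell: pd.DataFrame = field(repr=False, default=None)
    observed_difference: float = float("nan")  # treated - vehicle


# ----------------------------------------------------------- endpoints
def ogtt_auc(curve: OgttCurve) -> float:
    """Trapezoidal area under the glucose curve, in mmol/L·min."""
    t = np.asarray(curve.times, dtype=float)
    g = np.asarray(curve.glucose, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two OGTT points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("OGTT times must be strictly increasing")
    return float(np.trapezoid(g, t))


def delta_effect(pre: float, post: float) -> float:
    """Pre-to-post change as a percentage of the pre value."""
    if pre <= 0:
        raise ValueError(f"pre-intervention value must be positive, got {pre}")
    return (post - pre) / pre * 100.0


def _endpoint_value(rec: PhenotypeRecord, endpoint: str) -> float:
    if endpoint == "hba1c":
        return delta_effect(rec.hba1c_pre, rec.hba1c_post)
    if endpoint == "ogtt_auc":
        return delta_effect(ogtt_auc(rec.ogtt_pre), ogtt_auc(rec.ogtt_post))
    if endpoint == "body_weight":
        return delta_effect(rec.bw_pre, rec.bw_post)
    if endpoint == "fasting_glucose":
        # fasting glucose is the t=0 point of each OGTT
        return delta_effect(rec.ogtt_pre.glucose[0], rec.ogtt_post.glucose[0])
    if endpoint == "insulin":
        return rec.insulin
    if endpoint == "leptin":
        return rec.leptin
    raise ValueError(f"unknown endpoint {endpoint!r}")


def compute_effects(records: list[PhenotypeRecord], endpoint: str) -> pd.DataFrame:
    """Per-mouse endpoint values (Δ percent or raw terminal value)."""
    rows = [
        {
            "mouse_id": r.mouse_id,
            "substrain": r.substrain,
            "arm": r.arm,
            "value": _endpoint_value(r, endpoint),
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    df.attrs["endpoint"] = endpoint
    df.attrs["is_delta"] = endpoint in DELTA_ENDPOINTS
    return df


# ------------------------------------------------- assumptions & ranks
def check_assumptions(values, groups, alpha: float = 0.05) -> AssumptionReport:
    """Anderson–Darling normality per group and Levene across groups.

    Levene uses median centering (Brown–Forsythe), which is robust to
    non-normality. A constant group has no defined normality and is
    flagged non-Gaussian.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    gaussian: dict[str, bool] = {}
    samples = []
    for g in pd.unique(groups):
        x = values[groups == g]
        samples.append(x)
        if len(x) < 3 or np.ptp(x) == 0:
            gaussian[str(g)] = False
            continue
        res = sps.anderson(x, dist="norm", method="interpolate")
        gaussian[str(g)] = bool(res.pvalue > alpha)
    if all(np.ptp(s) == 0 for s in samples):
        equal = True
    else:
        _, p = sps.levene(*samples, center="median")
        equal = bool(p > alpha)
    return AssumptionReport(gaussian=gaussian, equal_variance=equal)


def rank_transform(values) -> np.ndarray:
    """Midranks of the pooled endpoint vector (ties share average rank)."""
    return sps.rankdata(np.asarray(values, dtype=float))


# -------------------------------------------------------------- ANOVA
def _one_tailed(p_two: float, diff: float, direction: float) -> float:
    if diff == 0:
        return 0.5
    if diff * direction > 0:
        return p_two / 2.0
    return 1.0 - p_two / 2.0


def one_way_anova(values, arm, direction: float = -1.0,
                  ranked: bool = False) -> AnovaResult:
    """One-way ANOVA of treatment, with a one-tailed treatment p-value.

    With two arms the F test equals the squared pooled t test; the
    one-tailed p is p/2 when the observed difference has the
    pre-specified direction and 1 - p/2 otherwise (0.5 at exactly zero
    difference).
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "arm": np.asarray(arm)})
    arms = pd.unique(df["arm"])
    if len(arms) < 2:
        raise ValueError("one_way_anova needs two arms")
    groups = [df.loc[df["arm"] == a, "value"].to_numpy() for a in arms]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 mice per arm")
    grand = df["value"].mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_n = len(arms) - 1
    df_d = len(df) - len(arms)
    if ss_within == 0:
        f_stat = 0.0 if ss_between == 0 else float("inf")
    else:
        f_stat = (ss_between / df_n) / (ss_within / df_d)
    p_two = float(sps.f.sf(f_stat, df_n, df_d)) if np.isfinite(f_stat) else 0.0
    if f_stat == 0.0:
        p_two = 1.0
    diff = _treated_minus_vehicle(df)
    n_cell = df.groupby("arm", observed=True)["value"].count().to_frame("n")
    return AnovaResult(
        design="one_way",
        factor_terms={"treatment": (f_stat, float(df_n), float(df_d), p_two)},
        one_tailed_treatment_p=_one_tailed(p_two, diff, direction),
        two_tailed_treatment_p=p_two,
        ranked=ranked,
        n_per_cell=n_cell,
        observed_difference=diff,
    )


def _treated_minus_vehicle(df: pd.DataFrame) -> float:
    arms = set(df["arm"])
    if arms == set(ARMS):
        t = df.loc[df["arm"] == "liraglutide", "value"].mean()
        v = df.loc[df["arm"] == "vehicle", "value"].mean()
        return float(t - v)
    a, b = sorted(arms)
    return float(df.loc[df["arm"] == b, "value"].mean()
                 - df.loc[df["arm"] == a, "value"].mean())


def two_way_anova(values, arm, factor, direction: float = -1.0,
                  ranked: bool = False,
                  pool_single_arm_levels: bool = True) -> AnovaResult:
    """Additive two-way ANOVA: treatment + cluster (or STR-allele) factor.

    Fits ``value ~ arm + factor`` by least squares with Type-II sums of
    squares (appropriate for unbalanced cells under an additive model).
    Factor levels containing only one arm violate the design and are, by
    default, pooled into an ``"other"`` level; a factor fully aliased
    with the arm raises.
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "arm": np.asarray(arm).astype(str),
        "factor": np.asarray(factor).astype(str),
    })
    if df["arm"].nunique() < 2:
        raise ValueError("two_way_anova needs two arms")
    if pool_single_arm_levels:
        tab = df.groupby("factor", observed=True)["arm"].nunique()
        bad = tab[tab < 2].index
        if len(bad):
            df.loc[df["factor"].isin(bad), "factor"] = "other"
    tab = df.groupby("factor", observed=True)["arm"].nunique()
    if (tab < 2).all():
        raise ValueError("factor is collinear with treatment arm")
    if df["factor"].nunique() < 2:
        # single factor level: the model reduces exactly to the one-way fit
        res = one_way_anova(df["value"], df["arm"], direction, ranked)
        res.design = "two_way"
        return res
    model = smf.ols("value ~ C(arm) + C(factor)", data=df).fit()
    table = anova_lm(model, typ=2)
    terms = {}
    df_d = float(table.loc["Residual", "df"])
    ms_resid = table.loc["Residual", "sum_sq"] / df_d
    for row, name in (("C(arm)", "treatment"), ("C(factor)", "factor")):
        f_stat = float(table.loc[row, "F"])
        if ms_resid == 0:
            f_stat = 0.0 if table.loc[row, "sum_sq"] == 0 else float("inf")
        terms[name] = (
            f_stat,
            float(table.loc[row, "df"]),
            df_d,
            float(table.loc[row, "PR(>F)"]) if np.isfinite(f_stat) else 0.0,
        )
    p_two = terms["treatment"][3]
    if terms["treatment"][0] == 0.0:
        p_two = 1.0
    diff = _adjusted_difference(model, df)
    n_cell = df.pivot_table(index="factor", columns="arm", values="value",
                            aggfunc="count", observed=True).fillna(0).astype(int)
    return AnovaResult(
        design="two_way",
        factor_terms=terms,
        one_tailed_treatment_p=_one_tailed(p_two, diff, direction),
        two_tailed_treatment_p=p_two,
        ranked=ranked,
        n_per_cell=n_cell,
        observed_difference=diff,
    )


def _adjusted_difference(model, df: pd.DataFrame) -> float:
    """Treatment coefficient as treated-minus-vehicle on the model scale."""
    for name, coef in model.params.items():
        if name.startswith("C(arm)[T."):
            level = name[len("C(arm)[T."):-1]
            return float(coef) if level == "liraglutide" else float(-coef)
    return 0.0


def endpoint_analysis(effects: pd.DataFrame, factor=None,
                      direction: float = -1.0,
                      alpha: float = 0.05) -> tuple[AnovaResult, AssumptionReport]:
    """Assumption-checked ANOVA of one endpoint.

    Runs the Anderson–Darling / Levene checks on the arm groups; on
    failure the pooled endpoint vector is rank-transformed before the
    ANOVA (the rank path leaves inference invariant under monotone
    transforms of the endpoint). With ``factor`` given, fits the
    additive two-way model; otherwise the one-way model.
    """
    values = effects["value"].to_numpy(dtype=float)
    arms = effects["arm"].to_numpy()
    report = check_assumptions(values, arms, alpha=alpha)
    ranked = not report.all_ok
    y = rank_transform(values) if ranked else values
    if factor is None:
        res = one_way_anova(y, arms, direction, ranked=ranked)
    else:
        res = two_way_anova(y, arms, factor, direction, ranked=ranked)
    return res, report


# ----------------------------------------------------------------- I/O
def phenotypes_to_frame(records: list[PhenotypeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "mouse_id": r.mouse_id,
            "substrain": r.substrain,
            "arm": r.arm,
            "hba1c_pre": r.hba1c_pre,
            "hba1c_post": r.hba1c_post,
            "bw_pre": r.bw_pre,
            "bw_post": r.bw_post,
            "fasting_glucose": r.fasting_glucose,
            "insulin": r.insulin,
            "leptin": r.leptin,
        }
        for phase, curve in (("pre", r.ogtt_pre), ("post", r.ogtt_post)):
            for t, g in zip(curve.times, curve.glucose):
                row[f"ogtt_{phase}_{int(t)}"] = g
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_phenotypes(df: pd.DataFrame) -> list[PhenotypeRecord]:
    records = []
    for _, row in df.iterrows():
        curves = {}
        for phase in ("pre", "post"):
            cols = sorted(
                (c for c in df.columns if c.startswith(f"ogtt_{phase}_")),
                key=lambda c: float(c.rsplit("_", 1)[1]),
            )
            times = tuple(float(c.rsplit("_", 1)[1]) for c in cols)
            curves[phase] = OgttCurve(times, tuple(row[c] for c in cols))
        records.append(PhenotypeRecord(
            mouse_id=str(row["mouse_id"]),
            substrain=str(row["substrain"]),
            arm=str(row["arm"]),
            hba1c_pre=float(row["hba1c_pre"]),
            hba1c_post=float(row["hba1c_post"]),
            ogtt_pre=curves["pre"],
            ogtt_post=curves["post"],
            bw_pre=float(row["bw_pre"]),
            bw_post=float(row["bw_post"]),
            fasting_glucose=float(row["fasting_glucose"]),
            insulin=float(row["insulin"]),
            leptin=float(row["leptin"]),
        ))
    return records
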