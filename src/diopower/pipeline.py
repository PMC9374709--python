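"""End-to-end orchestration: simulate/load -> cluster -> STR -> ANOVA -> power.

``run`` executes the whole workflow for one study and produces a
Table-2-style report: per endpoint and factor source, the one-tailed
one-way treatment p, the two-way (cluster- or allele-adjusted) treatment
p, the effective per-arm n after read-depth exclusions, and achieved
power / minimum group size for both designs. All randomness flows from a
single root seed through named substreams so each stage is independently
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, power as pw, stats, strs
from .config import SimulationConfig, ENDPOINTS
from .simulate import SyntheticStudy, generate_study
from .stats import DIRECTIONS, compute_effects, endpoint_analysis
from .tables import read_zotu_tsv, read_zotu_biom, ZotuTable

__all__ = ["RunConfig", "StudyReport", "run", "load_inputs"]

# fixed substream tags hashed into the root seed
_STREAMS = {"rarefy_t1": 11, "rarefy_t2": 12, "permanova_t1": 21,
            "permanova_t2": 22, "simulate": 1}


def _substream_seed(root: int, name: str) -> int:
    ss = np.random.SeedSequence([int(root), _STREAMS[name]])
    return int(ss.generate_state(1, np.uint32)[0]) % (2 ** 31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulation`` (a :class:`SimulationConfig`) or
    ``inputs`` (paths: ``zotu_time1``, optionally ``zotu_time2``,
    ``tree``, ``phenotypes``, optionally ``str_genotypes``) must be set.
    """

    simulation: SimulationConfig | None = None
    inputs: dict[str, str] | None = None
    depth: int = clustering.RAREFACTION_DEPTH
    k_max: int = 8
    alpha: float = 0.05
    target_power: float = 0.90
    endpoints: tuple[str, ...] = ENDPOINTS
    factor_sources: tuple[str, ...] = ("cluster_time1", "cluster_time2")
    n_permutations: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'simulation' or 'inputs' must be given"
            )
        if not self.endpoints:
            raise ValueError("at least one endpoint is required")
        for e in self.endpoints:
            if e not in ENDPOINTS:
                raise ValueError(f"unknown endpoint {e!r}")
        for fs in self.factor_sources:
            if fs not in ("cluster_time1", "cluster_time2") \
                    and not fs.startswith("str_marker:"):
                raise ValueError(f"unknown factor source {fs!r}")


@dataclass
class StudyReport:
    """Per endpoint x factor-source results plus diagnostics."""

    rows: list[dict] = field(default_factory=list)
    cluster_diagnostics: dict = field(default_factory=dict)
    str_diagnostics: dict = field(default_factory=dict)
    failed: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "report.tsv", sep="\t", index=False)
        payload = {
            "rows": self.rows,
            "cluster_diagnostics": self.cluster_diagnostics,
            "str_diagnostics": self.str_diagnostics,
            "failed": self.failed,
            "metadata": self.metadata,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


# --------------------------------------------------------------- inputs
def load_inputs(paths: dict[str, str]):
    """Read a study from files (TSV/BIOM, Newick, CSVs)."""
    tables = []
    for key in ("zotu_time1", "zotu_time2"):
        if key in paths:
            p = str(paths[key])
            tables.append(read_zotu_biom(p) if p.endswith(".biom")
                          else read_zotu_tsv(p))
    tree = Path(paths["tree"]).read_text()
    phenotypes = stats.frame_to_phenotypes(pd.read_csv(paths["phenotypes"]))
    genotypes = None
    if "str_genotypes" in paths:
        genotypes = strs.read_genotype_csv(paths["str_genotypes"])
    return tables, tree, phenotypes, genotypes


def _marker_factor(genotypes: strs.StrGenotypeTable, marker: str
                   ) -> dict[str, str]:
    if marker not in genotypes.marker_ids:
        raise ValueError(f"unknown STR marker {marker!r}")
    j = genotypes.marker_ids.index(marker)
    out = {}
    for i, m in enumerate(genotypes.mouse_ids):
        a1, a2 = genotypes.allele1[i, j], genotypes.allele2[i, j]
        out[m] = "missing" if a1 == strs.MISSING else f"{a1}/{a2}"
    return out


# ------------------------------------------------------------------ run
def run(config: RunConfig, out_dir) -> StudyReport:
    """Execute the full workflow and write every intermediate artifact.

    Stage failures for one endpoint x factor combination are recorded in
    ``report.failed`` and do not abort the remaining combinations.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = StudyReport(metadata={
        "seed": config.seed,
        "depth": config.depth,
        "k_max": config.k_max,
        "alpha": config.alpha,
        "target_power": config.target_power,
        "linkage": "ward.D2 on normalized weighted UniFrac",
        "sums_of_squares": "Type II (additive model)",
        "one_tailed_directions": {e: DIRECTIONS[e] for e in config.endpoints},
    })

    # ---- inputs
    if config.simulation is not None:
        study = generate_study(config.simulation,
                               seed=_substream_seed(config.seed, "simulate"))
        study.write(out / "inputs")
        tables = study.zotu_tables
        tree = study.tree_newick
        phenotypes = study.phenotypes
        genotypes = study.str_genotypes
    else:
        tables, tree, phenotypes, genotypes = load_inputs(config.inputs)
    arms = {p.mouse_id: p.arm for p in phenotypes}

    # ---- clustering per requested timepoint
    assignments: dict[str, clustering.ClusterAssignment] = {}
    for fs in config.factor_sources:
        if not fs.startswith("cluster_time"):
            continue
        t = int(fs.removeprefix("cluster_time"))
        if t > len(tables):
            report.failed.append({"stage": fs,
                                  "reason": f"no zOTU table for timepoint {t}"})
            continue
        try:
            seed = _substream_seed(config.seed, f"rarefy_t{t}")
            assignment, dm = clustering.cluster_study_table(
                tables[t - 1], tree, arms, depth=config.depth,
                k_max=config.k_max, seed=seed)
            perm = clustering.permanova(
                dm, [assignment.labels[m] for m in dm.ids],
                n_permutations=config.n_permutations,
                seed=_substream_seed(config.seed, f"permanova_t{t}"))
            assignments[fs] = assignment
            assignment.write_csv(out / f"clusters_time{t}.csv")
            dm.to_data_frame().to_csv(out / f"unifrac_time{t}.tsv", sep="\t")
            report.cluster_diagnostics[fs] = {
                "k": assignment.k,
                "n_clustered": len(assignment.labels),
                "n_excluded": len(assignment.excluded),
                "permanova_pseudo_F": perm.pseudo_F,
                "permanova_p": perm.p_value,
                "permanova_r2": perm.r_squared,
                **assignment.metadata,
            }
            with open(out / f"permanova_time{t}.json", "w") as fh:
                json.dump(asdict(perm), fh, indent=2)
        except Exception as exc:  # noqa: BLE001 - stage isolation
            report.failed.append({"stage": fs, "reason": str(exc)})

    # ---- STR summaries
    if genotypes is not None:
        try:
            consensus = strs.consensus_genotype(genotypes)
            scores = strs.conformity(genotypes, consensus)
            summaries = strs.allele_summary(genotypes)
            hist = strs.band_histogram(summaries)
            hist.to_csv(out / "str_band_histogram.tsv", sep="\t", index=False)
            pd.DataFrame([asdict(s) for s in summaries]).to_csv(
                out / "str_marker_summary.tsv", sep="\t", index=False)
            pd.DataFrame([asdict(s) for s in scores]).to_csv(
                out / "str_conformity.csv", index=False)
            report.str_diagnostics = {
                "n_markers": genotypes.n_markers,
                "mean_conformity": float(np.nanmean(
                    [s.score for s in scores])),
                "band_histogram": hist.to_dict(orient="records"),
                "most_alleles": strs.select_markers(
                    summaries, "most_alleles", 3),
                "most_even": strs.select_markers(summaries, "most_even", 3),
            }
        except Exception as exc:  # noqa: BLE001
            report.failed.append({"stage": "str", "reason": str(exc)})

    # ---- per-endpoint analysis
    for endpoint in config.endpoints:
        try:
            effects = compute_effects(phenotypes, endpoint)
        except Exception as exc:  # noqa: BLE001
            report.failed.append({"stage": endpoint, "reason": str(exc)})
            continue
        direction = DIRECTIONS[endpoint]
        try:
            one_way, assumptions = endpoint_analysis(
                effects, None, direction, config.alpha)
            summary = pw.marginal_effect_summary(effects["value"],
                                                 effects["arm"])
            n_arm = int(effects.groupby("arm")["value"].count().min())
            one_power = pw.one_way_power(summary.difference, summary.sd,
                                         n_arm, config.alpha)
            one_min_n = pw.one_way_min_n(summary.difference, summary.sd,
                                         config.target_power, config.alpha)
        except Exception as exc:  # noqa: BLE001
            report.failed.append({"stage": f"{endpoint}/one_way",
                                  "reason": str(exc)})
            continue
        base_row = {
            "endpoint": endpoint,
            "one_way_p_one_tailed": one_way.one_tailed_treatment_p,
            "one_way_p_two_tailed": one_way.two_tailed_treatment_p,
            "ranked": one_way.ranked,
            "n_per_arm": n_arm,
            "difference": summary.difference,
            "sd": summary.sd,
            "one_way_power": one_power,
            "one_way_min_n": one_min_n,
        }
        if not config.factor_sources:
            report.rows.append({**base_row, "factor_source": ""})
        for fs in config.factor_sources:
            row = dict(base_row)
            row["factor_source"] = fs
            try:
                if fs.startswith("cluster_time"):
                    if fs not in assignments:
                        raise ValueError("clustering unavailable")
                    labels = assignments[fs].labels
                    sub = effects[effects["mouse_id"].isin(labels)]
                    factor = [labels[m] for m in sub["mouse_id"]]
                else:
                    if genotypes is None:
                        raise ValueError("no STR genotype table given")
                    marker = fs.split(":", 1)[1]
                    fac_map = _marker_factor(genotypes, marker)
                    sub = effects[effects["mouse_id"].isin(fac_map)]
                    factor = [fac_map[m] for m in sub["mouse_id"]]
                two_way, _ = endpoint_analysis(
                    sub, factor, direction, config.alpha)
                wsum = pw.weighted_effect_summary(
                    _pooled_values(sub, two_way),
                    sub["arm"], _pooled_factor(sub, factor, two_way))
                n_eff = int(sub.groupby("arm")["value"].count().min())
                row.update({
                    "two_way_p_one_tailed": two_way.one_tailed_treatment_p,
                    "two_way_p_two_tailed": two_way.two_tailed_treatment_p,
                    "two_way_ranked": two_way.ranked,
                    "effective_n_per_arm": n_eff,
                    "k_levels": wsum.n_blocks,
                    "weighted_difference": wsum.weighted_difference,
                    "pooled_sd": wsum.pooled_sd,
                    "adjusted_power": pw.factorial_power(
                        wsum, n_eff, alpha=config.alpha),
                    "adjusted_min_n": pw.factorial_min_n(
                        wsum, target_power=config.target_power,
                        alpha=config.alpha),
                })
                report.rows.append(row)
            except Exception as exc:  # noqa: BLE001
                report.failed.append({"stage": f"{endpoint}/{fs}",
                                      "reason": str(exc)})
                row["two_way_p_one_tailed"] = float("nan")
                report.rows.append(row)

    report.write(out)
    return report


def _pooled_values(sub: pd.DataFrame, result) -> np.ndarray:
    return sub["value"].to_numpy(dtype=float)


def _pooled_factor(sub: pd.DataFrame, factor, result) -> list:
    """Mirror two_way_anova's pooling of single-arm factor levels."""
    df = pd.DataFrame({"arm": sub["arm"].to_numpy(),
                       "factor": np.asarray(factor).astype(str)})
    tab = df.groupby("factor", observed=True)["arm"].nunique()
    bad = set(tab[tab < 2].index)
    return ["other" if f in bad else f for f in df["factor"]]
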