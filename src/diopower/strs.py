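"""Consensus genotypes, conformity scores and allele spectra for STR panels.

Inbred colonies are monitored with a panel of highly polymorphic short
tandem repeats (STRs). Each mouse carries an unordered pair of allele
sizes per marker. The colony consensus is the modal pair; a mouse's
conformity is the mean over markers of 1 (exact pair match), 0.75
(heterozygous match: exactly one allele agrees) or 0 (no allele agrees),
expressed as a percent. Markers are summarised by their most prevalent
allele frequency band and number of alleles, and can be ranked for use
as ANOVA factors by polymorphism or Shannon evenness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps

from .config import STR_BANDS, band_of

__all__ = [
    "StrGenotypeTable",
    "MarkerSummary",
    "ConformityScore",
    "consensus_genotype",
    "conformity",
    "compare_conformity",
    "allele_summary",
    "band_histogram",
    "select_markers",
    "read_genotype_csv",
]

MISSING = -1


@dataclass
class StrGenotypeTable:
    """Mice x markers table of unordered allele pairs (integer bp sizes).

    Alleles are stored sorted within each pair; a missing call is
    ``(-1, -1)`` in both allele matrices.
    """

    mouse_ids: list[str]
    marker_ids: list[str]
    allele1: np.ndarray = field(repr=False)  # (n_mice, n_markers)
    allele2: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.allele1 = np.asarray(self.allele1, dtype=np.int64)
        self.allele2 = np.asarray(self.allele2, dtype=np.int64)
        shape = (len(self.mouse_ids), len(self.marker_ids))
        if self.allele1.shape != shape or self.allele2.shape != shape:
            raise ValueError("allele matrices must be n_mice x n_markers")
        if len(self.marker_ids) == 0:
            raise ValueError("marker count must be positive")
        # normalize storage order so conformity cannot depend on it
        lo = np.minimum(self.allele1, self.allele2)
        hi = np.maximum(self.allele1, self.allele2)
        self.allele1, self.allele2 = lo, hi

    @property
    def n_mice(self) -> int:
        return len(self.mouse_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_mask(self) -> np.ndarray:
        return (self.allele1 == MISSING) | (self.allele2 == MISSING)

    # ----------------------------------------------------------------- I/O
    def to_frame(self) -> pd.DataFrame:
        """One row per mouse, columns ``<marker>_a1`` / ``<marker>_a2``."""
        data = {"mouse_id": self.mouse_ids}
        for j, m in enumerate(self.marker_ids):
            a1 = self.allele1[:, j].astype(object)
            a2 = self.allele2[:, j].astype(object)
            miss = self.missing_mask()[:, j]
            a1[miss] = ""
            a2[miss] = ""
            data[f"{m}_a1"] = a1
            data[f"{m}_a2"] = a2
        return pd.DataFrame(data)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_genotype_csv(path) -> StrGenotypeTable:
    df = pd.read_csv(path, dtype={"mouse_id": str})
    markers = [c[:-3] for c in df.columns if c.endswith("_a1")]
    a1 = np.full((len(df), len(markers)), MISSING, dtype=np.int64)
    a2 = np.full_like(a1, MISSING)
    for j, m in enumerate(markers):
        for k, arr in ((f"{m}_a1", a1), (f"{m}_a2", a2)):
            col = pd.to_numeric(df[k], errors="coerce")
            arr[:, j] = col.fillna(MISSING).astype(np.int64)
    return StrGenotypeTable(list(df["mouse_id"]), markers, a1, a2)


@dataclass
class MarkerSummary:
    marker_id: str
    n_alleles: int
    most_prevalent_frequency: float
    evenness: float
    band: str


@dataclass
class ConformityScore:
    mouse_id: str
    score: float  # percent in [0, 100]; NaN when all calls are missing
    n_markers_used: int


# ------------------------------------------------------------- consensus
def consensus_genotype(table: StrGenotypeTable) -> dict[str, tuple[int, int]]:
    """Modal allele pair per marker; ties go to the smaller allele sizes."""
    out: dict[str, tuple[int, int]] = {}
    miss = table.missing_mask()
    for j, marker in enumerate(table.marker_ids):
        ok = ~miss[:, j]
        if not ok.any():
            raise ValueError(f"marker {marker} has no genotype calls")
        pairs = list(zip(table.allele1[ok, j], table.allele2[ok, j]))
        counts: dict[tuple[int, int], int] = {}
        for p in pairs:
            counts[p] = counts.get(p, 0) + 1
        best = max(counts.items(), key=lambda kv: (kv[1], (-kv[0][0], -kv[0][1])))
        out[marker] = (int(best[0][0]), int(best[0][1]))
    return out


def conformity(table: StrGenotypeTable,
               consensus: dict[str, tuple[int, int]] | None = None
               ) -> list[ConformityScore]:
    """Percent match of each mouse with the strain consensus genotype.

    Per marker: 1 if the pair equals the consensus pair, 0.75 if exactly
    one allele matches a consensus allele (heterozygous match), 0 if
    neither does. The sum is divided by the number of scored markers
    (missing calls drop out of numerator and denominator) and reported
    as a percent.
    """
    if consensus is None:
        consensus = consensus_genotype(table)
    missing = [m for m in table.marker_ids if m not in consensus]
    if missing:
        raise ValueError(f"consensus lacks markers: {missing[:5]}")
    cons1 = np.array([consensus[m][0] for m in table.marker_ids])
    cons2 = np.array([consensus[m][1] for m in table.marker_ids])
    miss = table.missing_mask()
    scores: list[ConformityScore] = []
    exact = (table.allele1 == cons1[None, :]) & (table.allele2 == cons2[None, :])
    # count how many of the mouse's two alleles agree with consensus alleles
    one_match = (
        (table.allele1 == cons1[None, :]) | (table.allele1 == cons2[None, :])
        | (table.allele2 == cons1[None, :]) | (table.allele2 == cons2[None, :])
    )
    per_marker = np.where(exact, 1.0, np.where(one_match, 0.75, 0.0))
    per_marker[miss] = np.nan
    for i, mouse in enumerate(table.mouse_ids):
        used = int((~miss[i]).sum())
        if used == 0:
            scores.append(ConformityScore(mouse, float("nan"), 0))
            continue
        score = float(np.nansum(per_marker[i]) / used * 100.0)
        scores.append(ConformityScore(mouse, score, used))
    return scores


def compare_conformity(scores_a: list[ConformityScore],
                       scores_b: list[ConformityScore]
                       ) -> tuple[float, float]:
    """Welch's unpaired t-test between two groups of conformity scores.

    Returns (t statistic, two-sided p with Satterthwaite df). Two
    identical degenerate groups (zero variance, equal means) give p = 1.
    """
    a = np.array([s.score for s in scores_a if not math.isnan(s.score)])
    b = np.array([s.score for s in scores_b if not math.isnan(s.score)])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 scores per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# --------------------------------------------------------- allele spectra
def allele_summary(table: StrGenotypeTable) -> list[MarkerSummary]:
    """Per-marker allele spectrum over the 2N allele slots.

    Frequencies are counted per allele slot (two per mouse); the band is
    the frequency class of the most prevalent allele. Evenness is Shannon
    H / ln(n_alleles); a monomorphic marker has evenness 1 by convention.
    """
    miss = table.missing_mask()
    out: list[MarkerSummary] = []
    for j, marker in enumerate(table.marker_ids):
        ok = ~miss[:, j]
        alleles = np.concatenate([table.allele1[ok, j], table.allele2[ok, j]])
        if len(alleles) == 0:
            raise ValueError(f"marker {marker} has no genotype calls")
        _, counts = np.unique(alleles, return_counts=True)
        freqs = counts / counts.sum()
        top = float(freqs.max())
        k = len(counts)
        if k == 1:
            evenness = 1.0
        else:
            h = -(freqs * np.log(freqs)).sum()
            evenness = float(h / math.log(k))
        out.append(MarkerSummary(marker, k, top, evenness, band_of(top)))
    return out


def band_histogram(summaries: list[MarkerSummary]) -> pd.DataFrame:
    """Markers per most-prevalent-allele frequency band (Table-1 layout)."""
    counts = {b: 0 for b in STR_BANDS}
    for s in summaries:
        counts[s.band] = counts.get(s.band, 0) + 1
    n = len(summaries)
    df = pd.DataFrame({
        "band": list(counts),
        "n_markers": list(counts.values()),
    })
    df["percent"] = df["n_markers"] / n * 100.0
    return df


def select_markers(summaries: list[MarkerSummary], mode: str,
                   top_k: int) -> list[str]:
    """Rank markers for use as a two-way ANOVA factor.

    mode="most_alleles" ranks by allele count; mode="most_even" ranks by
    Shannon evenness with monomorphic markers excluded. Ties break by
    marker ID.
    """
    if not summaries:
        raise ValueError("no marker summaries given")
    if mode == "most_alleles":
        pool = sorted(summaries, key=lambda s: (-s.n_alleles, s.marker_id))
    elif mode == "most_even":
        pool = [s for s in summaries if s.n_alleles > 1]
        pool.sort(key=lambda s: (-s.evenness, s.marker_id))
    else:
        raise ValueError("mode must be 'most_alleles' or 'most_even'")
    if top_k > len(pool):
        warnings.warn(
            f"requested top_k={top_k} but only {len(pool)} eligible markers",
            stacklevel=2,
        )
    return [s.marker_id for s in pool[:top_k]]
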