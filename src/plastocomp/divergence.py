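"""Divergence statistics and fast-evolving marker ranking.

p-distance is the uncorrected proportion of differing sites between two
aligned sequences.  Per-region variability is summarised by the
mutation-event proportion (NS / L) * 100, where NS is the number of
variable alignment columns and L the aligned length, and by the count
and percentage of parsimony-informative sites (PIS).  Candidate markers
are single-copy regions whose percentage of variable sites exceeds a
threshold (default 5%).  Gap- or N-containing columns are excluded
entirely (complete deletion) unless pairwise deletion is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .align import GAP, Msa

_MISSING = {GAP, "N", "?"}


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray  # symmetric p-distances in [0, 1]
    deletion: str       # complete | pairwise

    def value(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)


@dataclass
class MarkerReport:
    region: str
    category: str
    aligned_length: int
    n_variable: int
    pct_variable: float
    n_pis: int
    pct_pis: float
    rank: int | None = None


def p_distance(msa: Msa, deletion: str = "complete") -> DistanceMatrix:
    """Pairwise p-distances under complete or pairwise deletion."""
    if deletion not in ("complete", "pairwise"):
        raise ValueError("deletion must be 'complete' or 'pairwise'")
    taxa = msa.taxa
    if len(taxa) < 2:
        raise ValueError("p-distance needs at least two taxa")
    rows = [msa.rows[t] for t in taxa]
    arr = np.array([list(r) for r in rows])
    missing = np.isin(arr, list(_MISSING))
    n = len(taxa)
    D = np.zeros((n, n))
    if deletion == "complete":
        keep = ~missing.any(axis=0)
        arr = arr[:, keep]
        if arr.shape[1] == 0:
            raise ValueError("no comparable sites under complete deletion")
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = np.mean(arr[i] != arr[j])
    else:
        for i in range(n):
            for j in range(i + 1, n):
                keep = ~(missing[i] | missing[j])
                if not keep.any():
                    raise ValueError(
                        f"no comparable sites between {taxa[i]} and {taxa[j]}")
                D[i, j] = D[j, i] = np.mean(arr[i, keep] != arr[j, keep])
    return DistanceMatrix(taxa=taxa, matrix=D, deletion=deletion)


def group_divergence(dm: DistanceMatrix, groups: dict[str, str],
                     digits: int = 3) -> dict[str, float]:
    """Mean pairwise distance within each group and between group pairs.

    Keys are "within:<group>" and "between:<g1>|<g2>" (groups sorted);
    singleton groups have no within mean and are omitted.
    """
    out: dict[str, list[float]] = {}
    taxa = dm.taxa
    for i, a in enumerate(taxa):
        for j in range(i + 1, len(taxa)):
            b = taxa[j]
            ga, gb = groups.get(a), groups.get(b)
            if ga is None or gb is None:
                continue
            if ga == gb:
                key = f"within:{ga}"
            else:
                key = "between:" + "|".join(sorted((ga, gb)))
            out.setdefault(key, []).append(dm.matrix[i, j])
    return {k: round(float(np.mean(v)), digits) for k, v in sorted(out.items())}


def site_stats(msa: Msa) -> tuple[int, float, int, int, float]:
    """(L, pct_variable, n_variable, n_PIS, pct_PIS) under complete deletion.

    A column is variable if >=2 distinct bases occur; parsimony-
    informative if >=2 distinct bases each occur in >=2 taxa.  Columns
    containing a gap, N or ? in any taxon are excluded and L is the
    total aligned length (excluded columns count toward L, matching the
    aligned-sequence-length denominator of the mutation-proportion
    score).
    """
    if len(msa.taxa) < 2:
        raise ValueError("site stats need at least two taxa")
    L = msa.n_columns
    n_var = n_pis = 0
    rows = list(msa.rows.values())
    for j in range(L):
        col = [r[j] for r in rows]
        if any(c in _MISSING for c in col):
            continue
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        if len(counts) >= 2:
            n_var += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                n_pis += 1
    pct_var = 100.0 * n_var / L if L else 0.0
    pct_pis = 100.0 * n_pis / L if L else 0.0
    return L, pct_var, n_var, n_pis, pct_pis


def mutation_event_proportion(msa: Msa) -> float:
    """(NS / L) * 100 with NS the variable-column count."""
    L, pct_var, _, _, _ = site_stats(msa)
    if L == 0:
        raise ValueError("empty alignment")
    return pct_var


def marker_report(msa: Msa, category: str = "noncoding") -> MarkerReport:
    L, pct_var, n_var, n_pis, pct_pis = site_stats(msa)
    return MarkerReport(region=msa.region, category=category, aligned_length=L,
                        n_variable=n_var, pct_variable=pct_var,
                        n_pis=n_pis, pct_pis=pct_pis)


def rank_markers(reports: list[MarkerReport],
                 threshold_pct: float = 5.0) -> list[MarkerReport]:
    """Retain regions with pct_variable > threshold, ranked descending
    (alphabetical on ties)."""
    kept = [r for r in reports if r.pct_variable > threshold_pct]
    kept.sort(key=lambda r: (-r.pct_variable, r.region))
    for i, r in enumerate(kept):
        r.rank = i + 1
    return kept


def markers_table(reports: list[MarkerReport]) -> pd.DataFrame:
    return pd.DataFrame([{
        "region": r.region, "category": r.category, "L": r.aligned_length,
        "NS": r.n_variable, "pct_variable": r.pct_variable,
        "n_PIS": r.n_pis, "pct_PIS": r.pct_pis, "rank": r.rank,
    } for r in reports])


def pis_variability_regression(reports: list[MarkerReport]
                               ) -> tuple[float, float, float]:
    """OLS of pct_PIS on pct_variable: returns (R^2, p-value, slope)."""
    if len(reports) < 3:
        raise ValueError("regression needs at least three regions")
    x = np.array([r.pct_variable for r in reports])
    y = np.array([r.pct_pis for r in reports])
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in predictor")
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2), float(res.pvalue), float(res.slope)
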