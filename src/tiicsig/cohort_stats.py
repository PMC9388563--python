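"""Descriptive and comparative cohort statistics.

Pearson chi-square here is deliberately *uncorrected* (no Yates
continuity correction): the printed cohort-balance p-values match the
uncorrected statistic. Mann–Whitney uses the exact null distribution for
small tie-free samples, the tie-corrected normal approximation
otherwise. Dunn's post-hoc test after Kruskal–Wallis applies a
Bonferroni product by default.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError

CPS_BANDS = ("<1", "1-5", "5-10", ">=10")

#: Lineage markers counted as lymphocytes / macrophages in the CPS numerator.
LYMPHOCYTE_MARKERS = ("CD8", "CD4", "CD20")
MACROPHAGE_MARKER = "CD68"


def chi_square(table: Sequence[Sequence[float]] | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction: (statistic, df, p)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise DegenerateDataError("contingency table must be at least 2x2")
    if np.any(t < 0) or not np.all(t == np.floor(t)):
        raise DegenerateDataError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateDataError("zero row or column marginal")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def mann_whitney(a: Iterable[float], b: Iterable[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U: exact when n·m <= 400 and tie-free."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateDataError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size * b.size <= 400 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_dunn(
    groups: Sequence[Iterable[float]],
    adjust: str = "bonferroni",
) -> tuple[float, float, pd.DataFrame]:
    """Kruskal–Wallis omnibus plus pairwise Dunn z-tests.

    Returns (H, omnibus p, pairwise frame with z, raw p and adjusted p).
    The Dunn statistic uses mean ranks on the pooled sample with the
    standard tie correction.
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise DegenerateDataError("every group must be non-empty")
    if len(arrays) < 2:
        raise DegenerateDataError("need at least two groups")

    pooled = np.concatenate(arrays)
    n = pooled.size
    if np.ptp(pooled) == 0:
        h_stat, p_omni = 0.0, 1.0
    else:
        h_stat, p_omni = stats.kruskal(*arrays)

    ranks = stats.rankdata(pooled)
    sizes = [a.size for a in arrays]
    offsets = np.cumsum([0, *sizes])
    mean_ranks = [
        ranks[offsets[i]:offsets[i + 1]].mean() for i in range(len(arrays))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n - 1)) if n > 1 else 0.0

    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        var = (n * (n + 1) / 12 - tie_term) * (1 / sizes[i] + 1 / sizes[j])
        if var <= 0:
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
            p_raw = 2 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p_adj = min(1.0, p_raw * n_pairs)
        elif adjust == "none":
            p_adj = p_raw
        else:
            raise ValueError(f"unknown adjustment '{adjust}'")
        rows.append({"group_a": i, "group_b": j, "z": float(z),
                     "p_raw": float(p_raw), "p_adj": float(p_adj)})
    return float(h_stat), float(p_omni), pd.DataFrame(rows)


def compute_cps(cells: pd.DataFrame, pdl1_col: str = "PD-L1") -> tuple[float, str]:
    """PD-L1 combined positive score from a per-cell frame.

    CPS = 100 × (PD-L1⁺ tumour cells + PD-L1⁺ lymphocytes + PD-L1⁺
    macrophages) / viable tumour cells. Lymphocytes are CD8/CD4/CD20
    lineage cells, macrophages CD68⁺; PD-L1⁺ neutrophils and other
    lineages are excluded from the numerator.
    """
    tumour = cells["is_tumour_cell"].to_numpy(dtype=bool)
    n_tumour = int(tumour.sum())
    if n_tumour == 0:
        raise DegenerateDataError("CPS undefined without tumour cells")
    pdl1 = cells[pdl1_col].to_numpy(dtype=bool)
    lymph = np.zeros(len(cells), dtype=bool)
    for m in LYMPHOCYTE_MARKERS:
        lymph |= cells[m].to_numpy(dtype=bool)
    macro = cells[MACROPHAGE_MARKER].to_numpy(dtype=bool)
    numerator = int((pdl1 & (tumour | ((lymph | macro) & ~tumour))).sum())
    cps = 100.0 * numerator / n_tumour
    return cps, cps_band(cps)


def cps_band(cps: float) -> str:
    if cps < 1:
        return CPS_BANDS[0]
    if cps < 5:
        return CPS_BANDS[1]
    if cps < 10:
        return CPS_BANDS[2]
    return CPS_BANDS[3]


def reproducibility_cv(section_densities: Mapping[str, Iterable[float]]) -> pd.DataFrame:
    """Coefficient of variation (sample sd / mean) across repeat sections.

    One row per case; a zero mean leaves the CV undefined (NaN, flagged).
    """
    rows = []
    for case, values in section_densities.items():
        v = np.asarray(list(values), dtype=float)
        if v.size < 2:
            raise DegenerateDataError(f"case '{case}': need >= 2 sections")
        mean = v.mean()
        if mean == 0:
            rows.append({"case": case, "mean": 0.0, "sd": float(v.std(ddof=1)),
                         "cv": np.nan, "flag": "zero_mean"})
        else:
            sd = float(v.std(ddof=1))
            rows.append({"case": case, "mean": float(mean), "sd": sd,
                         "cv": sd / mean, "flag": ""})
    return pd.DataFrame(rows).set_index("case")


def pearson(a: Iterable[float], b: Iterable[float]) -> tuple[float, float]:
    """Thin wrapper: Pearson correlation coefficient and two-sided p."""
    r, p = stats.pearsonr(np.asarray(list(a), float), np.asarray(list(b), float))
    return float(r), float(p)
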