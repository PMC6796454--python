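"""Group-wise differential expression, list overlap and metabolic-module selection.

Per-gene two-sided Mann-Whitney (Wilcoxon rank-sum) tests between the HIGH and
LOW groups, Benjamini-Hochberg adjustment across all tested genes, and a
direction call by comparison of group means on the analyzed scale. Metabolic
candidates are the significant HIGH-direction genes of an annotation set whose
expression is also Pearson-correlated with the signature score.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ValidationError
from .scoring import GroupSplit, ScoreVector

__all__ = [
    "OverlapReport",
    "mann_whitney_de",
    "bh_adjust",
    "overlap",
    "select_correlated_metabolic",
    "correlate_genes_with_score",
]

EXACT_MAX_N = 8  # exact Mann-Whitney enumeration when both groups are this small


@dataclass
class OverlapReport:
    n_a: int
    n_b: int
    n_intersection: int
    percent_a_in_b: float
    percent_b_in_a: float
    intersection: tuple[str, ...]


def _values(matrix) -> np.ndarray:
    if isinstance(matrix, ad.AnnData):
        x = matrix.X
        if hasattr(x, "toarray"):
            x = x.toarray()
        return np.asarray(x, dtype=float)
    return np.asarray(matrix, dtype=float)


def mann_whitney_de(matrix, split: GroupSplit, alpha: float = 0.01) -> pd.DataFrame:
    """Per-gene two-sided Mann-Whitney test between the HIGH and LOW groups.

    Normal approximation with tie correction; exact enumeration when both
    groups have <= 8 members. BH adjustment across all tested genes; direction
    (HIGH or LOW) is assigned only to genes with adjusted p < alpha, by the
    larger group mean. UNASSIGNED items are excluded.
    """
    x = _values(matrix)
    gene_ids = (
        list(matrix.var.index)
        if isinstance(matrix, ad.AnnData)
        else [str(j) for j in range(x.shape[1])]
    )
    labels = split.labels.to_numpy()
    hi = np.flatnonzero(labels == "HIGH")
    lo = np.flatnonzero(labels == "LOW")
    if len(hi) < 2 or len(lo) < 2:
        raise ValidationError(
            f"mann_whitney_de: need >= 2 members per group, got HIGH={len(hi)}, LOW={len(lo)}"
        )
    xh, xl = x[hi], x[lo]
    mean_high, mean_low = xh.mean(axis=0), xl.mean(axis=0)
    pooled = np.concatenate([xh, xl], axis=0)
    constant = pooled.max(axis=0) == pooled.min(axis=0)
    if len(hi) <= EXACT_MAX_N and len(lo) <= EXACT_MAX_N:
        u = np.empty(x.shape[1])
        p = np.empty(x.shape[1])
        for j in range(x.shape[1]):
            if constant[j]:
                u[j], p[j] = len(hi) * len(lo) / 2.0, 1.0
            else:
                res = stats.mannwhitneyu(xh[:, j], xl[:, j], method="exact", alternative="two-sided")
                u[j], p[j] = res.statistic, res.pvalue
    else:
        res = stats.mannwhitneyu(xh, xl, axis=0, method="asymptotic", alternative="two-sided")
        u = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        u[constant] = len(hi) * len(lo) / 2.0
        p[constant] = 1.0
    p_adj = bh_adjust(p)
    significant = p_adj < alpha
    direction = np.where(
        significant, np.where(mean_high > mean_low, "HIGH", "LOW"), ""
    )
    return pd.DataFrame(
        {
            "U": u,
            "p": p,
            "p_adj": p_adj,
            "direction": direction,
            "mean_high": mean_high,
            "mean_low": mean_low,
        },
        index=pd.Index(gene_ids, name="gene"),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving, monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust: expected a 1-d vector of p-values")
    if ((p < 0) | (p > 1) | np.isnan(p)).any():
        raise ValidationError("bh_adjust: p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def overlap(list_a, list_b) -> OverlapReport:
    """Set intersection of two gene lists with both directional percentages."""
    a, b = set(list_a), set(list_b)
    inter = a & b
    return OverlapReport(
        n_a=len(a),
        n_b=len(b),
        n_intersection=len(inter),
        percent_a_in_b=100.0 * len(inter) / len(a) if a else 0.0,
        percent_b_in_a=100.0 * len(inter) / len(b) if b else 0.0,
        intersection=tuple(sorted(inter)),
    )


def correlate_genes_with_score(matrix, genes, scores: ScoreVector) -> pd.DataFrame:
    """Pearson r and two-sided p of each gene's expression vs the score."""
    x = _values(matrix[:, list(genes)] if isinstance(matrix, ad.AnnData) else matrix)
    s = scores.values.to_numpy(dtype=float)
    n = len(s)
    if x.shape[0] != n:
        raise ValidationError("correlate_genes_with_score: scores not aligned to matrix cells")
    xc = x - x.mean(axis=0)
    sc = s - s.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (sc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (xc * sc[:, None]).sum(axis=0) / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.isnan(r), np.nan, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return pd.DataFrame({"r": r, "p": p}, index=pd.Index(list(genes), name="gene"))


def select_correlated_metabolic(
    de_table: pd.DataFrame,
    annotation,
    scores: ScoreVector,
    matrix,
    p_threshold: float = 0.01,
) -> list[str]:
    """Significant HIGH-direction genes of the annotation set whose expression
    is Pearson-correlated with the score at p < p_threshold, ordered by |r|."""
    annotation = set(annotation)
    if not annotation:
        raise ConfigurationError("select_correlated_metabolic: empty annotation set")
    up = [
        g
        for g in de_table.index[(de_table["direction"] == "HIGH")]
        if g in annotation
    ]
    if not up:
        return []
    corr = correlate_genes_with_score(matrix, up, scores)
    hits = corr[(corr["p"] < p_threshold) & corr["r"].notna()]
    return list(hits.reindex(hits["r"].abs().sort_values(ascending=False).index).index)
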