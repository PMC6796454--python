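"""Mutual-information co-expression skeleton and hub ranking.

Pairwise mutual information (bits) between genes is estimated by plug-in
entropy after equal-frequency discretization. Edges are retained when the
observed MI exceeds a per-pair permutation null with BH-style control of the
false discovery rate. The "densest node" of the resulting skeleton is the gene
with the highest degree (ties by summed edge weight, then identifier).

This is a deliberately simplified skeleton: it recovers which gene is the most
densely connected node, but does not orient edges or prune by conditional
independence the way full multivariate information-based causal methods do.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import anndata as ad
import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .de import bh_adjust

__all__ = [
    "MINetwork",
    "mutual_information_matrix",
    "infer_skeleton",
    "rank_degree",
]


@dataclass
class MINetwork:
    nodes: tuple[str, ...]
    edges: pd.DataFrame  # columns: u, v, mi, p, null_q95
    degrees: pd.Series
    weighted_degrees: pd.Series
    fdr_q: float
    n_permutations: int
    seed: int


def _values(matrix, genes=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, ad.AnnData):
        sub = matrix[:, list(genes)] if genes is not None else matrix
        x = sub.X
        if hasattr(x, "toarray"):
            x = x.toarray()
        return np.asarray(x, dtype=float), list(sub.var.index)
    x = np.asarray(matrix, dtype=float)
    ids = list(genes) if genes is not None else [str(j) for j in range(x.shape[1])]
    return x, ids


def _discretize(x: np.ndarray, bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-frequency binning per gene; returns codes and a constant-gene mask.

    Genes with at most ``bins`` distinct values keep one bin per value; for the
    rest, quantile edges equal to the minimum and duplicated edges (heavy ties,
    e.g. zero inflation) are dropped so no bin is empty by construction.
    """
    n, g = x.shape
    codes = np.zeros((n, g), dtype=np.int64)
    constant = np.zeros(g, dtype=bool)
    for j in range(g):
        col = x[:, j]
        uniq = np.unique(col)
        if len(uniq) < 2:
            constant[j] = True
            continue
        if len(uniq) <= bins:
            codes[:, j] = np.searchsorted(uniq, col)
            continue
        edges = np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1])
        edges = np.unique(edges[edges > uniq[0]])
        codes[:, j] = np.searchsorted(edges, col, side="right")
    return codes, constant


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _mi_bits(a: np.ndarray, b: np.ndarray, ka: int, kb: int) -> float:
    joint = np.bincount(a * kb + b, minlength=ka * kb).astype(float)
    n = joint.sum()
    pij = joint / n
    pa = pij.reshape(ka, kb).sum(axis=1)
    pb = pij.reshape(ka, kb).sum(axis=0)
    outer = (pa[:, None] * pb[None, :]).ravel()
    nz = pij > 0
    return float((pij[nz] * np.log2(pij[nz] / outer[nz])).sum())


def mutual_information_matrix(matrix, genes=None, bins: int = 8) -> pd.DataFrame:
    """Symmetric gene x gene MI matrix (bits) from equal-frequency bins.

    The diagonal holds each gene's marginal entropy. Constant genes get a zero
    row/column and a warning.
    """
    x, ids = _values(matrix, genes)
    if x.shape[1] < 2:
        raise ConfigurationError("mutual_information_matrix: need at least 2 genes")
    if x.shape[0] < bins * 5:
        warnings.warn(
            f"mutual_information_matrix: only {x.shape[0]} cells for {bins} bins; "
            "estimates will be noisy",
            stacklevel=2,
        )
    codes, constant = _discretize(x, bins)
    if constant.any():
        warnings.warn(
            f"mutual_information_matrix: {int(constant.sum())} constant gene(s) set to MI 0",
            stacklevel=2,
        )
    g = x.shape[1]
    k = codes.max(axis=0) + 1
    mi = np.zeros((g, g))
    for i in range(g):
        if constant[i]:
            continue
        mi[i, i] = _entropy_bits(np.bincount(codes[:, i]).astype(float))
        for j in range(i + 1, g):
            if constant[j]:
                continue
            mi[i, j] = mi[j, i] = max(0.0, _mi_bits(codes[:, i], codes[:, j], k[i], k[j]))
    return pd.DataFrame(mi, index=ids, columns=ids)


def infer_skeleton(
    mi_matrix: pd.DataFrame,
    matrix,
    n_permutations: int = 200,
    fdr_q: float = 0.05,
    seed: int = 0,
    bins: int = 8,
) -> MINetwork:
    """Permutation-thresholded MI skeleton.

    For each gene pair, one gene's cells are shuffled ``n_permutations`` times
    to build a null MI distribution; the pair's p-value is the fraction of null
    values at or above the observed MI (add-one corrected). Edges significant
    under BH control at ``fdr_q`` are retained, each recording its p and the
    null 95th percentile.
    """
    if n_permutations < 20:
        raise ConfigurationError(
            f"infer_skeleton: n_permutations must be >= 20, got {n_permutations}"
        )
    ids = list(mi_matrix.index)
    x, got_ids = _values(matrix, ids)
    if got_ids != ids:
        raise ValidationError("infer_skeleton: matrix does not contain the MI matrix genes")
    rng = np.random.default_rng(seed)
    codes, constant = _discretize(x, bins)
    k = codes.max(axis=0) + 1
    g = len(ids)
    pairs = [(i, j) for i in range(g) for j in range(i + 1, g) if not (constant[i] or constant[j])]
    pvals, q95s = [], []
    for i, j in pairs:
        obs = mi_matrix.iloc[i, j]
        null = np.empty(n_permutations)
        a = codes[:, i]
        for r in range(n_permutations):
            null[r] = _mi_bits(rng.permutation(a), codes[:, j], k[i], k[j])
        pvals.append((1.0 + (null >= obs).sum()) / (n_permutations + 1.0))
        q95s.append(float(np.quantile(null, 0.95)))
    if pairs:
        adj = bh_adjust(np.array(pvals))
    else:
        adj = np.array([])
    rows = [
        {
            "u": ids[i],
            "v": ids[j],
            "mi": float(mi_matrix.iloc[i, j]),
            "p": pvals[idx],
            "p_adj": float(adj[idx]),
            "null_q95": q95s[idx],
        }
        for idx, (i, j) in enumerate(pairs)
        if adj[idx] < fdr_q
    ]
    edges = pd.DataFrame(rows, columns=["u", "v", "mi", "p", "p_adj", "null_q95"])
    degrees = pd.Series(0, index=ids, dtype=int)
    weighted = pd.Series(0.0, index=ids)
    for _, e in edges.iterrows():
        degrees[e["u"]] += 1
        degrees[e["v"]] += 1
        weighted[e["u"]] += e["mi"]
        weighted[e["v"]] += e["mi"]
    return MINetwork(
        nodes=tuple(ids),
        edges=edges,
        degrees=degrees,
        weighted_degrees=weighted,
        fdr_q=fdr_q,
        n_permutations=n_permutations,
        seed=seed,
    )


def rank_degree(network: MINetwork) -> pd.DataFrame:
    """Nodes sorted by degree, ties by summed edge weight then identifier;
    the top node is flagged as the hub."""
    if len(network.nodes) == 0:
        raise ValidationError("rank_degree: empty network")
    table = pd.DataFrame(
        {
            "degree": network.degrees,
            "weighted_degree": network.weighted_degrees,
        }
    )
    # ascending id first, then a stable descending sort: ties fall back to id order
    table = table.sort_index(kind="stable").sort_values(
        by=["degree", "weighted_degree"], ascending=False, kind="stable"
    )
    table["is_hub"] = False
    table.iloc[0, table.columns.get_loc("is_hub")] = True
    return table
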