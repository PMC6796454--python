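"""QC filtering, normalization variants and gene-selection treatments.

All functions take and return :class:`anndata.AnnData`; the value semantics of
a matrix is tracked in ``uns["semantics"]`` (``counts``, ``cpm_log``,
``binary``, ``standardized``, ``hkg_normalized``) and every treatment appends
itself to the ``uns["treatments"]`` provenance chain. Cell order and
identifiers are always preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

__all__ = [
    "FilterReport",
    "filter_cells",
    "filter_genes",
    "cpm_log",
    "hkg_normalize",
    "standardize_within_group",
    "binarize",
    "select_overdispersed",
    "select_most_expressed",
    "exclude_genes",
]


@dataclass
class FilterReport:
    """Which items a QC filter removed and why."""

    kind: str  # "cells" or "genes"
    thresholds: dict
    removed: pd.DataFrame  # index = removed ids, column "reason"
    n_retained: int

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    @property
    def n_input(self) -> int:
        return self.n_removed + self.n_retained


def _values(adata: ad.AnnData) -> np.ndarray:
    x = adata.X
    if hasattr(x, "toarray"):
        x = x.toarray()
    return np.asarray(x)


def _with_x(adata: ad.AnnData, x: np.ndarray, semantics: str, treatment: str) -> ad.AnnData:
    out = ad.AnnData(X=x, obs=adata.obs.copy(), var=adata.var.copy())
    out.uns.update({k: v for k, v in adata.uns.items() if k not in ("semantics", "treatments")})
    out.uns["semantics"] = semantics
    out.uns["treatments"] = list(adata.uns.get("treatments", [])) + [treatment]
    return out


def _require(adata: ad.AnnData, semantics: str, op: str) -> None:
    got = adata.uns.get("semantics")
    if got != semantics:
        raise ValidationError(f"{op} expects a {semantics!r} matrix, got {got!r}")


def filter_cells(
    adata: ad.AnnData, min_reads: int = 90_000, min_genes: int = 1_700
) -> tuple[ad.AnnData, FilterReport]:
    """Remove low-complexity cells: strictly fewer than ``min_reads`` total
    transcript reads OR strictly fewer than ``min_genes`` detected genes."""
    if adata.n_obs == 0:
        raise FormatError("filter_cells: empty input (0 cells)")
    x = _values(adata)
    if (x < 0).any():
        raise FormatError("filter_cells: counts must be non-negative")
    total = x.sum(axis=1)
    detected = (x > 0).sum(axis=1)
    low_reads = total < min_reads
    low_genes = detected < min_genes
    drop = low_reads | low_genes
    reasons = np.where(
        low_reads & low_genes,
        "low_reads+low_genes",
        np.where(low_reads, "low_reads", "low_genes"),
    )
    removed = pd.DataFrame({"reason": reasons[drop]}, index=adata.obs.index[drop])
    report = FilterReport(
        kind="cells",
        thresholds={"min_reads": min_reads, "min_genes": min_genes},
        removed=removed,
        n_retained=int((~drop).sum()),
    )
    return adata[~drop].copy(), report


def filter_genes(adata: ad.AnnData, min_cells: int = 3) -> tuple[ad.AnnData, FilterReport]:
    """Keep genes detected (nonzero) in at least ``min_cells`` cells."""
    if min_cells > adata.n_obs:
        raise ConfigurationError(
            f"filter_genes: min_cells={min_cells} exceeds the {adata.n_obs} cells present"
        )
    x = _values(adata)
    n_detect = (x > 0).sum(axis=0)
    keep = n_detect >= min_cells
    removed = pd.DataFrame(
        {"reason": [f"detected_in_{int(n)}_cells" for n in n_detect[~keep]]},
        index=adata.var.index[~keep],
    )
    report = FilterReport(
        kind="genes",
        thresholds={"min_cells": min_cells},
        removed=removed,
        n_retained=int(keep.sum()),
    )
    return adata[:, keep].copy(), report


def cpm_log(adata: ad.AnnData) -> ad.AnnData:
    """log2(CPM + 1): per-cell library normalization to one million reads."""
    x = _values(adata).astype(float)
    totals = x.sum(axis=1)
    if (totals == 0).any():
        bad = adata.obs.index[totals == 0][0]
        raise ValidationError(f"cpm_log: cell {bad!r} has zero total reads")
    out = np.log2(x / totals[:, None] * 1e6 + 1.0)
    return _with_x(adata, out, "cpm_log", "cpm_log")


def hkg_normalize(adata: ad.AnnData, hkg: list[str]) -> ad.AnnData:
    """Rescale each cell by a housekeeping-gene factor.

    The per-cell factor is the geometric mean of (value + 1) over the
    housekeeping genes, divided by the cohort median of those factors; all
    values of the cell are divided by its factor. Robust to single-gene
    outliers; the factors are stored in ``obs["hkg_factor"]``.
    """
    _require(adata, "cpm_log", "hkg_normalize")
    if len(hkg) == 0:
        raise ConfigurationError("hkg_normalize: empty housekeeping gene list")
    missing = [g for g in hkg if g not in adata.var.index]
    if missing:
        raise ConfigurationError(f"hkg_normalize: genes absent from matrix: {missing}")
    sub = _values(adata[:, hkg])
    if (sub.sum(axis=0) == 0).any():
        dead = [g for g, s in zip(hkg, sub.sum(axis=0)) if s == 0]
        raise ConfigurationError(f"hkg_normalize: housekeeping genes never detected: {dead}")
    geo = np.exp(np.log(sub + 1.0).mean(axis=1))
    factors = geo / np.median(geo)
    out = _with_x(adata, _values(adata) / factors[:, None], "hkg_normalized", "hkg_normalize")
    out.obs["hkg_factor"] = factors
    return out


def standardize_within_group(adata: ad.AnnData, group_labels) -> ad.AnnData:
    """Center and reduce each gene within each group (sample SD, n-1).

    Genes with zero SD inside a group map to 0 for that group's cells, keeping
    the matrix shape stable.
    """
    labels = np.asarray(group_labels)
    if labels.shape[0] != adata.n_obs:
        raise ValidationError("standardize_within_group: labels length mismatch")
    x = _values(adata).astype(float)
    out = np.zeros_like(x)
    for grp in pd.unique(labels):
        rows = np.flatnonzero(labels == grp)
        if len(rows) < 2:
            raise ValidationError(
                f"standardize_within_group: group {grp!r} has {len(rows)} cell(s); need >= 2"
            )
        block = x[rows]
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        safe = sd > 0
        out[np.ix_(rows, np.flatnonzero(safe))] = (block[:, safe] - mean[safe]) / sd[safe]
    return _with_x(adata, out, "standardized", "standardize_within_group")


def binarize(adata: ad.AnnData) -> ad.AnnData:
    """1 for every detected (positive) value, 0 otherwise."""
    x = (_values(adata) > 0).astype(float)
    return _with_x(adata, x, "binary", "binarize")


def select_overdispersed(
    adata: ad.AnnData, n: int, mode: str = "keep", n_bins: int = 20
) -> list[str]:
    """Rank genes by bin-wise z-scored dispersion (variance/mean).

    Genes are grouped into ``n_bins`` equal-frequency mean-expression bins;
    within each bin the dispersion is z-scored so highly expressed genes do not
    dominate. ``mode="keep"`` returns the top ``n`` genes, ``mode="exclude"``
    returns the complement. Ties are broken by gene identifier order.
    """
    _require(adata, "cpm_log", "select_overdispersed")
    if mode not in ("keep", "exclude"):
        raise ConfigurationError(f"select_overdispersed: unknown mode {mode!r}")
    if n > adata.n_vars:
        raise ConfigurationError(
            f"select_overdispersed: n={n} exceeds the {adata.n_vars} genes present"
        )
    x = _values(adata)
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    n_bins = min(n_bins, adata.n_vars)
    # equal-frequency bins on mean expression; rank-based to dodge ties
    order = np.argsort(mean, kind="stable")
    bin_of = np.empty(adata.n_vars, dtype=int)
    bin_of[order] = (np.arange(adata.n_vars) * n_bins) // adata.n_vars
    z = np.zeros(adata.n_vars)
    for b in range(n_bins):
        members = np.flatnonzero(bin_of == b)
        if len(members) == 0:
            continue
        mu, sd = disp[members].mean(), disp[members].std(ddof=1) if len(members) > 1 else 0.0
        z[members] = (disp[members] - mu) / sd if sd > 0 else 0.0
    ranking = sorted(range(adata.n_vars), key=lambda i: (-z[i], adata.var.index[i]))
    top = ranking[:n]
    if mode == "keep":
        chosen = top  # in decreasing-dispersion order
    else:
        top_set = set(top)
        chosen = [i for i in range(adata.n_vars) if i not in top_set]
    return [adata.var.index[i] for i in chosen]


def select_most_expressed(adata: ad.AnnData, threshold: float) -> list[str]:
    """Genes whose aggregate expression log2(mean linear CPM + 1) >= threshold."""
    _require(adata, "cpm_log", "select_most_expressed")
    linear = np.exp2(_values(adata)) - 1.0
    aggregate = np.log2(linear.mean(axis=0) + 1.0)
    return [g for g, ea in zip(adata.var.index, aggregate) if ea >= threshold]


def exclude_genes(adata: ad.AnnData, genes: list[str]) -> ad.AnnData:
    """Drop the listed genes; absent ids are ignored with a warning count."""
    present = [g for g in genes if g in adata.var.index]
    absent = len(genes) - len(present)
    if absent:
        warnings.warn(f"exclude_genes: {absent} listed gene(s) not in matrix", stacklevel=2)
    keep = ~adata.var.index.isin(present)
    if not keep.any():
        raise ValidationError("exclude_genes: exclusion would remove every gene")
    out = adata[:, keep].copy()
    out.uns["treatments"] = list(adata.uns.get("treatments", [])) + [
        f"exclude_genes({len(present)})"
    ]
    return out
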