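"""Geometric-mean signature scoring and HIGH/LOW splitting.

A signature score is the per-cell geometric mean of the log2(CPM+1) expression
values of the signature genes, with exact zeros imputed to 1 before taking the
product. Cells are split at the arithmetic mean of the score distribution
(HIGH above, LOW at or below); smoother tissue-level distributions are split
at the extreme quartiles instead, leaving the middle half unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError

__all__ = [
    "Signature",
    "TUMORIGENIC_SIGNATURE",
    "ScoreVector",
    "GroupSplit",
    "DetectionReport",
    "validate_signature",
    "score",
    "split_by_mean",
    "split_by_quartiles",
    "correlate_scores",
]


@dataclass(frozen=True)
class Signature:
    """A named, non-empty list of unique gene identifiers."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ConfigurationError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ConfigurationError(f"signature {self.name!r} has duplicate genes")


#: The experimentally defined 5-transcription-factor tumorigenic signature.
TUMORIGENIC_SIGNATURE = Signature(
    name="tumorigenic", genes=("ARNT2", "POU3F2", "OLIG2", "SOX9", "SALL2")
)


@dataclass
class DetectionReport:
    signature: str
    detection: pd.Series  # fraction of cells with nonzero expression, per gene
    min_detection: float
    passed: bool


@dataclass
class ScoreVector:
    values: pd.Series  # index = cell ids, strictly positive
    signature: str
    n_imputed: int

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class GroupSplit:
    labels: pd.Series  # HIGH / LOW / UNASSIGNED
    rule: str  # "mean" or "quartiles"
    thresholds: tuple[float, ...]

    def members(self, which: str) -> pd.Index:
        return self.labels.index[self.labels == which]


def _values(adata: ad.AnnData) -> np.ndarray:
    x = adata.X
    if hasattr(x, "toarray"):
        x = x.toarray()
    return np.asarray(x, dtype=float)


def validate_signature(
    adata: ad.AnnData, signature: Signature, min_detection: float = 0.25, strict: bool = True
) -> DetectionReport:
    """Check every signature gene is present and detected in at least
    ``min_detection`` of the cells (boundary inclusive)."""
    if adata.n_obs == 0:
        raise ValidationError("validate_signature: empty matrix")
    missing = [g for g in signature.genes if g not in adata.var.index]
    if missing:
        raise ValidationError(f"signature {signature.name!r}: genes absent from matrix: {missing}")
    sub = _values(adata[:, list(signature.genes)])
    frac = pd.Series((sub > 0).mean(axis=0), index=list(signature.genes))
    passed = bool((frac >= min_detection).all())
    report = DetectionReport(
        signature=signature.name, detection=frac, min_detection=min_detection, passed=passed
    )
    if strict and not passed:
        bad = frac[frac < min_detection]
        raise ValidationError(
            f"signature {signature.name!r}: genes below {min_detection:.0%} detection: "
            + ", ".join(f"{g} ({v:.1%})" for g, v in bad.items())
        )
    return report


def score(adata: ad.AnnData, signature: Signature) -> ScoreVector:
    """Per-cell geometric mean of the signature genes' expression values.

    Exact zeros are imputed to 1 (which is neutral in the product); values in
    (0, 1) are used as-is. Expects a log2(CPM+1) matrix.
    """
    if adata.uns.get("semantics") not in ("cpm_log", "hkg_normalized"):
        raise ValidationError(
            f"score expects a cpm_log matrix, got {adata.uns.get('semantics')!r}"
        )
    missing = [g for g in signature.genes if g not in adata.var.index]
    if missing:
        raise ValidationError(f"signature {signature.name!r}: genes absent from matrix: {missing}")
    sub = _values(adata[:, list(signature.genes)])
    zeros = sub == 0
    sub = np.where(zeros, 1.0, sub)
    values = np.exp(np.log(sub).mean(axis=1))
    return ScoreVector(
        values=pd.Series(values, index=adata.obs.index, name=signature.name),
        signature=signature.name,
        n_imputed=int(zeros.sum()),
    )


def split_by_mean(scores: ScoreVector) -> GroupSplit:
    """HIGH above the arithmetic mean of the scores, LOW at or below it."""
    v = scores.values
    if len(v) < 2:
        raise ValidationError("split_by_mean: need at least 2 items")
    if float(v.max()) == float(v.min()):
        raise ValidationError("split_by_mean: constant scores, no split exists")
    threshold = float(v.mean())
    labels = pd.Series(np.where(v > threshold, "HIGH", "LOW"), index=v.index, name="group")
    return GroupSplit(labels=labels, rule="mean", thresholds=(threshold,))


def split_by_quartiles(scores: ScoreVector) -> GroupSplit:
    """LOW at or below Q1, HIGH at or above Q3, middle half UNASSIGNED.

    Quartiles use linear interpolation (type-7).
    """
    v = scores.values
    if len(v) < 4:
        raise ValidationError("split_by_quartiles: need at least 4 items")
    q1, q3 = np.quantile(v.to_numpy(), [0.25, 0.75])
    if q1 == q3:
        raise ValidationError("split_by_quartiles: degenerate distribution (Q1 == Q3)")
    labels = pd.Series(
        np.where(v <= q1, "LOW", np.where(v >= q3, "HIGH", "UNASSIGNED")),
        index=v.index,
        name="group",
    )
    return GroupSplit(labels=labels, rule="quartiles", thresholds=(float(q1), float(q3)))


def correlate_scores(scores_a, scores_b, method: str = "pearson") -> tuple[float, float]:
    """Correlation between two per-cell value vectors with a two-sided p."""
    a = np.asarray(scores_a.values if isinstance(scores_a, ScoreVector) else scores_a, dtype=float)
    b = np.asarray(scores_b.values if isinstance(scores_b, ScoreVector) else scores_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValidationError("correlate_scores: vectors must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("correlate_scores: zero variance in an input vector")
    if method == "pearson":
        r, p = stats.pearsonr(a, b)
    elif method == "spearman":
        r, p = stats.spearmanr(a, b)
    else:
        raise ConfigurationError(f"correlate_scores: unknown method {method!r}")
    return float(r), float(p)
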