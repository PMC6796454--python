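"""Clustering on principal components and cluster/label agreement diagnostics.

The grouping approach mirrors hierarchical clustering on principal components
(HCPC): cells are embedded on a handful of top principal components, Ward
agglomeration is cut at the level with the largest relative loss of
within-cluster inertia, and an optional k-means step consolidates the
partition. Agreement between a clustering and an external label (e.g. the
tumor of origin) is quantified by normalized mutual information,

    NMI(A, B) = I(A; B) / sqrt(H(A) * H(B)),

computed from the contingency table with natural logarithms (Strehl-Ghosh
normalization). NMI is 1 iff the partitions are identical up to relabeling
and 0 when every cluster contains all labels in identical proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ConfigurationError, ValidationError

__all__ = [
    "Embedding",
    "ClusterAssignment",
    "NMIResult",
    "DownsamplingReport",
    "pca_embed",
    "hcpc_cluster",
    "describe_clusters",
    "nmi",
    "downsampling_experiment",
    "cluster_matrix",
]


@dataclass
class Embedding:
    """Cell scores on the retained principal components.

    ``scores @ components + mean`` reconstructs the (centered-then-restored)
    input when all components are retained.
    """

    scores: np.ndarray  # cells x components
    explained_variance: np.ndarray
    n_components: int
    components: np.ndarray | None = None  # components x genes
    mean: np.ndarray | None = None


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # int in [0, k)
    k: int
    linkage: str = "ward"
    consolidated: bool = False


@dataclass
class NMIResult:
    value: float
    contingency: np.ndarray
    entropy_a: float
    entropy_b: float
    mutual_information: float
    variant: str = "sqrt"
    degenerate: bool = False

    def __float__(self) -> float:
        return self.value


@dataclass
class DownsamplingReport:
    """Replicate NMIs per gene-set size plus one-sample t-tests vs a reference."""

    table: pd.DataFrame  # index = size; columns mean, sd, t, p, degenerate
    nmis: dict[int, np.ndarray]
    reference_nmi: float
    seed: int
    reps: int


def _matrix_values(matrix) -> np.ndarray:
    if isinstance(matrix, ad.AnnData):
        x = matrix.X
        if hasattr(x, "toarray"):
            x = x.toarray()
        return np.asarray(x, dtype=float)
    return np.asarray(matrix, dtype=float)


def pca_embed(matrix, n_components: int) -> Embedding:
    """Top principal components of the gene-centered matrix.

    Component signs are fixed so that each component's largest-magnitude gene
    loading is positive, making the embedding deterministic.
    """
    x = _matrix_values(matrix)
    bound = min(x.shape[0] - 1, x.shape[1])
    if n_components > bound or n_components < 1:
        raise ConfigurationError(
            f"pca_embed: n_components={n_components} outside [1, {bound}] for shape {x.shape}"
        )
    solver = "full" if min(x.shape) <= 500 or n_components > 0.5 * min(x.shape) else "randomized"
    pca = PCA(n_components=n_components, svd_solver=solver, random_state=0)
    scores = pca.fit_transform(x)
    flip = np.sign(pca.components_[np.arange(n_components), np.abs(pca.components_).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return Embedding(
        scores=scores * flip[None, :],
        explained_variance=pca.explained_variance_.copy(),
        n_components=n_components,
        components=pca.components_ * flip[:, None],
        mean=pca.mean_.copy(),
    )


def _within_inertia(scores: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        block = scores[labels == lab]
        w += ((block - block.mean(axis=0)) ** 2).sum()
    return float(w)


def hcpc_cluster(embedding: Embedding, k_max: int = 10, consolidate: bool = False) -> ClusterAssignment:
    """Ward clustering of the component scores with a data-driven cut.

    k in [2, k_max] is chosen to maximize the relative loss of within-cluster
    inertia between successive cuts, Q(k) = (W(k-1) - W(k)) / (W(k) - W(k+1)).
    With ``consolidate`` the partition is polished by k-means initialized at
    the cluster centroids (<= 10 iterations), which keeps determinism.
    """
    scores = embedding.scores
    n = scores.shape[0]
    if k_max < 2:
        raise ConfigurationError(f"hcpc_cluster: k_max must be >= 2, got {k_max}")
    if n <= k_max:
        raise ConfigurationError(f"hcpc_cluster: need more than k_max={k_max} cells, got {n}")
    total_inertia = ((scores - scores.mean(axis=0)) ** 2).sum()
    if total_inertia <= 0:
        raise ConfigurationError("hcpc_cluster: zero inertia (all cells identical); no valid cut")
    z = sch.linkage(scores, method="ward")
    cuts = {k: sch.fcluster(z, k, criterion="maxclust") for k in range(1, k_max + 2)}
    w = {k: _within_inertia(scores, cuts[k]) for k in cuts}
    best_k, best_q = 2, -np.inf
    for k in range(2, k_max + 1):
        drop_here = w[k - 1] - w[k]
        drop_next = w[k] - w[k + 1]
        q = np.inf if drop_next <= 0 else drop_here / drop_next
        if q > best_q:
            best_k, best_q = k, q
    labels = cuts[best_k]
    if consolidate:
        centroids = np.vstack(
            [scores[labels == lab].mean(axis=0) for lab in np.unique(labels)]
        )
        km = KMeans(
            n_clusters=len(centroids), init=centroids, n_init=1, max_iter=10, random_state=0
        ).fit(scores)
        labels = km.labels_ + 1
    # compact to [0, k)
    _, compact = np.unique(labels, return_inverse=True)
    return ClusterAssignment(labels=compact, k=int(compact.max()) + 1, consolidated=consolidate)


def describe_clusters(matrix, clusters: ClusterAssignment, p_threshold: float = 0.05) -> pd.DataFrame:
    """Genes whose mean in a cluster differs from the global mean (v-test).

    v = (mean_k - mean) / sqrt(((N - n_k) / (N - 1)) * s^2 / n_k) with s^2 the
    global (population) variance of the gene; two-sided normal p-value; rows
    with p < p_threshold are returned, signed by direction.
    """
    x = _matrix_values(matrix)
    gene_ids = (
        list(matrix.var.index) if isinstance(matrix, ad.AnnData) else [str(j) for j in range(x.shape[1])]
    )
    labels = clusters.labels
    n = x.shape[0]
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("describe_clusters: need at least 2 clusters")
    gmean = x.mean(axis=0)
    gvar = x.var(axis=0, ddof=0)
    rows = []
    for lab in uniq:
        members = labels == lab
        nk = int(members.sum())
        mk = x[members].mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(((n - nk) / (n - 1)) * gvar / nk)
            v = np.where(se > 0, (mk - gmean) / np.where(se > 0, se, 1.0), 0.0)
        p = 2.0 * stats.norm.sf(np.abs(v))
        keep = p < p_threshold
        for j in np.flatnonzero(keep):
            rows.append((gene_ids[j], int(lab), float(v[j]), float(p[j]),
                         "up" if v[j] > 0 else "down"))
    return pd.DataFrame(rows, columns=["gene", "cluster", "v", "p", "direction"])


def nmi(labels_a, labels_b) -> NMIResult:
    """Normalized mutual information between two partitions.

    Computed from the contingency table with natural logs and normalized by
    sqrt(H(A) * H(B)). If either partition has zero entropy the value is
    defined as 0 and flagged degenerate.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValidationError(f"nmi: length mismatch ({a.shape} vs {b.shape})")
    if a.size < 2:
        raise ValidationError("nmi: need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(table, (ai, bi), 1.0)
    n = table.sum()
    pa = table.sum(axis=1) / n
    pb = table.sum(axis=0) / n
    ha = float(-(pa[pa > 0] * np.log(pa[pa > 0])).sum())
    hb = float(-(pb[pb > 0] * np.log(pb[pb > 0])).sum())
    pij = table / n
    outer = pa[:, None] * pb[None, :]
    nz = pij > 0
    mi = float((pij[nz] * np.log(pij[nz] / outer[nz])).sum())
    mi = max(mi, 0.0)
    if ha == 0.0 or hb == 0.0:
        return NMIResult(0.0, table, ha, hb, mi, degenerate=True)
    value = mi / np.sqrt(ha * hb)
    value = float(np.clip(value, 0.0, 1.0))
    if abs(value - 1.0) < 1e-12:
        value = 1.0
    return NMIResult(value, table, ha, hb, mi)


def cluster_matrix(
    matrix, n_components: int = 5, k_max: int = 10, consolidate: bool = False
) -> ClusterAssignment:
    """Convenience: PCA embedding followed by the Ward cut (the HCPC recipe)."""
    x = _matrix_values(matrix)
    n_components = min(n_components, x.shape[0] - 1, x.shape[1])
    return hcpc_cluster(pca_embed(x, n_components), k_max=k_max, consolidate=consolidate)


def downsampling_experiment(
    matrix,
    tumor_labels,
    reference_nmi: float,
    sizes=(2000, 1000, 500, 250, 100, 50),
    reps: int = 10,
    seed: int = 0,
    n_components: int = 5,
    k_max: int = 10,
) -> DownsamplingReport:
    """Random gene down-sampling: cluster on ``reps`` random gene subsets per
    size, score each clustering against the tumor labels with NMI, and test the
    replicate NMIs against ``reference_nmi`` with a one-sample t-test.

    Zero-variance replicate sets make the t-test degenerate: flagged, p = 1.
    """
    x = _matrix_values(matrix)
    labels = np.asarray(tumor_labels)
    sizes = sorted(set(int(s) for s in sizes), reverse=True)
    if reps < 2:
        raise ConfigurationError(f"downsampling_experiment: reps must be >= 2, got {reps}")
    if max(sizes) > x.shape[1]:
        raise ConfigurationError(
            f"downsampling_experiment: size {max(sizes)} exceeds {x.shape[1]} genes"
        )
    rng = np.random.default_rng(seed)
    nmis: dict[int, np.ndarray] = {}
    rows = []
    for size in sizes:
        vals = np.empty(reps)
        for r in range(reps):
            genes = np.sort(rng.choice(x.shape[1], size=size, replace=False))
            assignment = cluster_matrix(
                x[:, genes], n_components=n_components, k_max=k_max
            )
            vals[r] = nmi(assignment.labels, labels).value
        nmis[size] = vals
        degenerate = bool(np.allclose(vals.std(ddof=1), 0.0))
        if degenerate:
            t_stat, p = np.nan, 1.0
        else:
            t_stat, p = stats.ttest_1samp(vals, reference_nmi)
        rows.append(
            {
                "size": size,
                "mean": vals.mean(),
                "sd": vals.std(ddof=1),
                "t": t_stat,
                "p": p,
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame(rows).set_index("size")
    return DownsamplingReport(
        table=table, nmis=nmis, reference_nmi=float(reference_nmi), seed=seed, reps=reps
    )
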