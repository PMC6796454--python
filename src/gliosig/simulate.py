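"""Synthetic single-cell count generator.

Emulates the statistical structure of a multi-patient tumor scRNA-seq cohort:

* **Tumor identity dispersed over all genes.** Every cancer cell of tumor *t*
  carries a small per-(gene, tumor) log2 shift ``delta[g, t] ~ N(0, tumor_effect_sd)``
  on *every* gene — there is no circumscribed tumor marker set. This is the
  generative analog of tumor-of-origin information being spread across the
  whole transcript repertoire.
* **Lineage identity for normal cells.** Normal cells carry no tumor term;
  each normal lineage up-shifts a dedicated marker block, so normal cells
  cluster by lineage, not by the patient they were sampled from.
* **A latent tumorigenic state.** Each cancer cell has a state
  ``s ~ 0.5*Beta(2,5) + 0.5*Beta(5,2)`` in [0, 1] (a bimodal low/high mixture).
  A small transcription-factor signature is shifted by ``state_effect_size * s``,
  and a correlated metabolic module is driven through a single hub gene
  (``h = s + noise``; module gene j shifted by ``beta_j * h + noise``), giving
  the hub an unambiguous top position in any co-expression network.
* **Counts.** Expected counts are ``library_size * softmax(log2 expression)``
  drawn as negative binomial (single dispersion), then thinned by a
  logistic-in-log-mean dropout. The dropout logit carries two tumor terms: a
  small sample-level shift applied to every cell of a tumor (a coherent
  detection-depth axis, the analog of residual batch variation that gives
  normal cells their small nonzero tumor NMI), and a cancer-only
  per-(gene, tumor) repertoire term (which genes a tumor's cells tend to
  detect) so that even binarized data retains dispersed tumor identity.
* **Optional CNV blocks** multiply expected counts of a gene range in one
  tumor by ``2**multiplier``.

The same seed yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import ConfigurationError, FormatError

_LN2 = math.log(2.0)

#: gene role labels used in ``var["role"]``
ROLES = ("background", "lineage_marker", "housekeeping", "module", "hub", "signature")


@dataclass(frozen=True)
class CNVBlock:
    """A copy-number block: genes [start, stop) of one tumor scaled by 2**log2_multiplier."""

    tumor: int
    start: int
    stop: int
    log2_multiplier: float


@dataclass
class SimulationConfig:
    """Parameters of the generative model (defaults define the study conditions).

    Log2-scale effect sizes; ``nb_dispersion`` is the negative-binomial shape
    (variance = mu + mu**2 / nb_dispersion); library sizes are log-normal;
    dropout keep-probability is ``sigmoid(slope * (ln lambda - midpoint) + shift_t)``.
    """

    n_tumors: int = 4
    cancer_cells_per_tumor: int = 250
    normal_cells_per_lineage: int = 150
    n_lineages: int = 3
    n_genes: int = 5000
    tumor_effect_sd: float = 0.15
    lineage_effect_size: float = 1.0
    lineage_marker_count: int = 40
    signature_gene_count: int = 5
    module_gene_count: int = 16
    state_effect_size: float = 1.0
    nb_dispersion: float = 30.0
    library_size_meanlog: float = math.log(250_000.0)
    library_size_sdlog: float = 0.35
    dropout_midpoint: float = 2.5
    dropout_slope: float = 2.0
    tumor_dropout_shift: tuple[float, ...] | None = None
    tumor_repertoire_sd: float = 0.8
    cnv_blocks: tuple[CNVBlock, ...] | None = None
    housekeeping_gene_count: int = 17
    n_chromosomes: int = 22
    base_meanlog: float = 1.0
    base_sdlog: float = 1.5
    special_mean_boost: float = 4.3
    seed: int = 0

    def resolved_dropout_shift(self) -> np.ndarray:
        if self.tumor_dropout_shift is None:
            if self.n_tumors == 1:
                return np.zeros(1)
            return np.linspace(-0.7, 0.7, self.n_tumors)
        return np.asarray(self.tumor_dropout_shift, dtype=float)

    def resolved_cnv_blocks(self) -> tuple[CNVBlock, ...]:
        """Default: each tumor gains one chromosome (single-copy gain, x1.5)."""
        if self.cnv_blocks is not None:
            return tuple(self.cnv_blocks)
        blocks = []
        chrom_bounds = _chromosome_bounds(self.n_genes, self.n_chromosomes)
        for t in range(min(self.n_tumors, self.n_chromosomes)):
            start, stop = chrom_bounds[t]
            blocks.append(CNVBlock(tumor=t, start=start, stop=stop, log2_multiplier=math.log2(1.5)))
        return tuple(blocks)

    def validate(self) -> None:
        counts = {
            "n_tumors": self.n_tumors,
            "cancer_cells_per_tumor": self.cancer_cells_per_tumor,
            "normal_cells_per_lineage": self.normal_cells_per_lineage,
            "n_lineages": self.n_lineages,
            "n_genes": self.n_genes,
            "lineage_marker_count": self.lineage_marker_count,
            "signature_gene_count": self.signature_gene_count,
            "module_gene_count": self.module_gene_count,
            "n_chromosomes": self.n_chromosomes,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if self.tumor_effect_sd < 0:
            raise ConfigurationError(f"tumor_effect_sd must be >= 0, got {self.tumor_effect_sd}")
        if self.nb_dispersion <= 0:
            raise ConfigurationError(f"nb_dispersion must be > 0, got {self.nb_dispersion}")
        if self.tumor_repertoire_sd < 0:
            raise ConfigurationError(
                f"tumor_repertoire_sd must be >= 0, got {self.tumor_repertoire_sd}"
            )
        if self.library_size_sdlog < 0:
            raise ConfigurationError(f"library_size_sdlog must be >= 0, got {self.library_size_sdlog}")
        if self.housekeeping_gene_count < 0:
            raise ConfigurationError(
                f"housekeeping_gene_count must be >= 0, got {self.housekeeping_gene_count}"
            )
        needed = (
            self.signature_gene_count
            + self.module_gene_count
            + self.n_lineages * self.lineage_marker_count
            + self.housekeeping_gene_count
        )
        if self.n_genes < needed:
            raise ConfigurationError(
                f"n_genes={self.n_genes} is smaller than the {needed} genes required for "
                "signature + module + lineage markers + housekeeping roles"
            )
        shifts = self.resolved_dropout_shift()
        if shifts.shape != (self.n_tumors,):
            raise ConfigurationError(
                f"tumor_dropout_shift must have one entry per tumor ({self.n_tumors}), "
                f"got shape {shifts.shape}"
            )
        for block in self.resolved_cnv_blocks():
            if not (0 <= block.tumor < self.n_tumors):
                raise ConfigurationError(f"cnv_blocks: tumor index {block.tumor} out of range")
            if not (0 <= block.start < block.stop <= self.n_genes):
                raise ConfigurationError(
                    f"cnv_blocks: gene range [{block.start}, {block.stop}) out of bounds"
                )


def _chromosome_bounds(n_genes: int, n_chromosomes: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, n_genes, n_chromosomes + 1).astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n_chromosomes)]


def _gene_roles(config: SimulationConfig) -> pd.DataFrame:
    """Disjoint role partition; special roles packed at the high-index end so the
    default CNV blocks (low chromosomes) do not overlap them."""
    g = config.n_genes
    role = np.array(["background"] * g, dtype=object)
    marker_lineage = np.full(g, -1)
    cursor = g
    cursor -= config.signature_gene_count
    sig = slice(cursor, cursor + config.signature_gene_count)
    role[sig] = "signature"
    cursor -= config.module_gene_count
    module = slice(cursor, cursor + config.module_gene_count)
    role[module] = "module"
    role[cursor] = "hub"  # first gene of the module block is the hub
    cursor -= config.housekeeping_gene_count
    role[cursor : cursor + config.housekeeping_gene_count] = "housekeeping"
    for lin in range(config.n_lineages - 1, -1, -1):
        cursor -= config.lineage_marker_count
        role[cursor : cursor + config.lineage_marker_count] = "lineage_marker"
        marker_lineage[cursor : cursor + config.lineage_marker_count] = lin
    chrom = np.minimum(
        (np.arange(g) * config.n_chromosomes) // g, config.n_chromosomes - 1
    )
    var = pd.DataFrame(
        {
            "role": role,
            "chromosome": chrom.astype(int),
            "marker_lineage": marker_lineage.astype(int),
        },
        index=pd.Index([f"g{i:05d}" for i in range(g)], name="gene_id"),
    )
    return var


def simulate_dataset(config: SimulationConfig) -> ad.AnnData:
    """Draw one synthetic cohort; returns an AnnData of integer counts.

    ``obs`` carries per-cell truth (tumor, cell_class, lineage, latent_state);
    ``var`` carries per-gene truth (role, chromosome, marker_lineage);
    ``uns["semantics"]`` is ``"counts"``. Same config + seed => bit-identical.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_cancer = config.n_tumors * config.cancer_cells_per_tumor
    n_normal = config.n_lineages * config.normal_cells_per_lineage
    n_cells = n_cancer + n_normal
    g = config.n_genes
    var = _gene_roles(config)
    role = var["role"].to_numpy()

    # --- gene base means (log2 scale), with detectability boost for the
    # signature / module / housekeeping genes (the study requires them
    # detected in >= 25% of cells)
    base_ln = rng.normal(config.base_meanlog, config.base_sdlog, g)
    special = np.isin(role, ("signature", "module", "hub", "housekeeping"))
    # signature/module/housekeeping genes sit in a tight, well-detected
    # abundance band (the study requires them detected in >= 25% of cells)
    base_ln[special] = rng.normal(
        config.base_meanlog + config.special_mean_boost, 0.4, int(special.sum())
    )
    base_ln[role == "lineage_marker"] += 1.0
    log2_mu = base_ln / _LN2

    # --- per-(gene, tumor) identity shifts on ALL genes
    delta = rng.normal(0.0, config.tumor_effect_sd, (config.n_tumors, g))
    # tumor-specific gene-repertoire term (cancer only, dropout-logit scale):
    # which genes a tumor's cells tend to detect, dispersed over all genes
    repertoire = rng.normal(0.0, config.tumor_repertoire_sd, (config.n_tumors, g))

    # --- latent tumorigenic state and the hub/module chain
    b_low = rng.beta(2.0, 5.0, n_cancer)
    b_high = rng.beta(5.0, 2.0, n_cancer)
    take_high = rng.random(n_cancer) < 0.5
    s = np.where(take_high, b_high, b_low)
    h = s + rng.normal(0.0, 0.1, n_cancer)
    n_spokes = config.module_gene_count - 1
    beta_spokes = config.state_effect_size * rng.uniform(0.4, 0.9, n_spokes)
    spoke_noise = rng.normal(0.0, 0.1, (n_cancer, n_spokes))
    beta_hub = 1.2 * config.state_effect_size

    sig_idx = np.flatnonzero(role == "signature")
    hub_idx = int(np.flatnonzero(role == "hub")[0])
    spoke_idx = np.flatnonzero(role == "module")  # module minus the hub

    # --- expected log2 expression per cell
    tumor_of = np.concatenate(
        [
            np.repeat(np.arange(config.n_tumors), config.cancer_cells_per_tumor),
            np.arange(n_normal) % config.n_tumors,  # normal cells balanced over tumors
        ]
    )
    lineage_of = np.concatenate(
        [
            np.full(n_cancer, -1),
            np.repeat(np.arange(config.n_lineages), config.normal_cells_per_lineage),
        ]
    )
    expr = np.tile(log2_mu, (n_cells, 1))
    expr[:n_cancer] += delta[tumor_of[:n_cancer]]
    expr[:n_cancer, sig_idx] += config.state_effect_size * s[:, None]
    expr[:n_cancer, hub_idx] += beta_hub * h
    expr[:n_cancer, spoke_idx] += beta_spokes[None, :] * h[:, None] + spoke_noise
    for lin in range(config.n_lineages):
        rows = np.flatnonzero(lineage_of == lin)
        cols = np.flatnonzero(var["marker_lineage"].to_numpy() == lin)
        expr[np.ix_(rows, cols)] += config.lineage_effect_size

    # --- expected counts: library size x softmax over genes, then CNV scaling
    library = rng.lognormal(config.library_size_meanlog, config.library_size_sdlog, n_cells)
    w = np.exp2(expr)
    lam = w * (library / w.sum(axis=1))[:, None]
    for block in config.resolved_cnv_blocks():
        rows = np.flatnonzero((tumor_of == block.tumor) & (lineage_of == -1))
        lam[np.ix_(rows, np.arange(block.start, block.stop))] *= 2.0 ** block.log2_multiplier

    # --- negative binomial sampling, then mean-dependent dropout
    theta = config.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + lam)).astype(np.int64)
    # the dropout shift is a sample-level (per-tumor) detection property and
    # applies to every cell of the sample, normal cells included; the
    # repertoire term applies to cancer cells only (biological identity)
    shift = config.resolved_dropout_shift()[tumor_of]
    logit = config.dropout_slope * (np.log(lam) - config.dropout_midpoint) + shift[:, None]
    logit[:n_cancer] += repertoire[tumor_of[:n_cancer]]
    keep_p = 1.0 / (1.0 + np.exp(-logit))
    counts *= rng.random(counts.shape) < keep_p

    obs = pd.DataFrame(
        {
            "tumor": [f"T{t}" for t in tumor_of],
            "cell_class": ["cancer"] * n_cancer + ["normal"] * n_normal,
            "lineage": ["none"] * n_cancer + [f"L{l}" for l in lineage_of[n_cancer:]],
            "latent_state": np.concatenate([s, np.full(n_normal, np.nan)]),
        },
        index=pd.Index([f"c{i:05d}" for i in range(n_cells)], name="cell_id"),
    )
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.uns["semantics"] = "counts"
    adata.uns["simulation"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in asdict(config).items()
        if k != "cnv_blocks"
    }
    return adata


def signature_genes(adata: ad.AnnData) -> list[str]:
    """Gene ids of the simulated tumorigenic signature (truth channel)."""
    return list(adata.var.index[adata.var["role"] == "signature"])


def module_genes(adata: ad.AnnData, include_hub: bool = True) -> list[str]:
    """Gene ids of the simulated metabolic module; hub first when included."""
    hub = list(adata.var.index[adata.var["role"] == "hub"])
    spokes = list(adata.var.index[adata.var["role"] == "module"])
    return (hub + spokes) if include_hub else spokes


def housekeeping_genes(adata: ad.AnnData) -> list[str]:
    return list(adata.var.index[adata.var["role"] == "housekeeping"])


# ---------------------------------------------------------------------------
# fixture I/O: Matrix Market counts + TSV metadata
# ---------------------------------------------------------------------------

_MTX = "matrix.mtx"
_CELLS = "cells.tsv"
_GENES = "genes.tsv"


def write_fixture(adata: ad.AnnData, directory: str | Path) -> None:
    """Write counts as coordinate-integer MTX plus cells.tsv / genes.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    x = adata.X
    if sp.issparse(x):
        x = x.toarray()
    scipy.io.mmwrite(directory / _MTX, sp.coo_matrix(np.asarray(x)), field="integer")
    adata.obs.to_csv(directory / _CELLS, sep="\t")
    adata.var.to_csv(directory / _GENES, sep="\t")


def read_fixture(directory: str | Path) -> ad.AnnData:
    """Inverse of :func:`write_fixture`; raises FormatError on missing or
    dimension-mismatched files."""
    directory = Path(directory)
    for name in (_MTX, _CELLS, _GENES):
        if not (directory / name).exists():
            raise FormatError(f"fixture file missing: {directory / name}")
    try:
        mat = scipy.io.mmread(directory / _MTX)
    except Exception as exc:  # malformed MTX
        raise FormatError(f"could not parse {directory / _MTX}: {exc}") from exc
    counts = np.asarray(sp.coo_matrix(mat).todense()).astype(np.int64)
    obs = pd.read_csv(directory / _CELLS, sep="\t", index_col=0)
    var = pd.read_csv(directory / _GENES, sep="\t", index_col=0)
    if counts.shape != (len(obs), len(var)):
        raise FormatError(
            f"matrix is {counts.shape} but metadata describes "
            f"({len(obs)}, {len(var)}) — dimension mismatch"
        )
    if (counts < 0).any():
        raise FormatError("count matrix contains negative entries")
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.uns["semantics"] = "counts"
    return adata
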