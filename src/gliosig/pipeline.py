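"""Config-driven orchestration of the full analysis.

Stages: simulate/load -> QC -> normalization treatments -> clustering + NMI
battery -> gene down-sampling -> signature scoring and HIGH/LOW split ->
differential expression -> overlap -> metabolic-module selection -> MI network
and hub -> principal curve. All outputs are written as TSV/JSON; the same
config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .errors import ConfigurationError, GliosigError
from . import simulate as sim
from . import preprocess as pp
from . import grouping as gr
from . import scoring as sc
from . import de as de_mod
from . import network as net
from . import curve as cv

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "nmi_battery"]

#: treatment vocabulary of the NMI battery (metacell variants are named hooks
#: that are reported as skipped, not implemented)
BATTERY_TREATMENTS = (
    "cells",
    "binarized",
    "standardized",
    "hkg_normalized",
    "cnv_excluded",
    "de_excluded",
    "odg_top500",
    "odg_top1000",
    "odg_excluded",
    "most_expressed",
)
PLACEHOLDER_TREATMENTS = ("mc_h", "mc_s")


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of simulate/fixture as source."""

    simulate: dict | None = None  # overrides for SimulationConfig
    fixture: str | None = None  # directory with matrix.mtx + TSV metadata
    signature_file: str | None = None  # newline-delimited gene ids; None -> truth roles
    treatments: tuple[str, ...] = BATTERY_TREATMENTS
    qc_min_reads: int = 90_000
    qc_min_genes: int = 1_700
    gene_min_cells: int = 3
    de_alpha: float = 0.01
    min_detection: float = 0.25
    downsampling_sizes: tuple[int, ...] = (2000, 1000, 500, 250, 100, 50)
    downsampling_reps: int = 10
    n_components: int = 5
    k_max: int = 10
    most_expressed_threshold: float = 4.0
    network_permutations: int = 200
    network_fdr_q: float = 0.05
    mi_bins: int = 8
    seed: int = 0
    out_dir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        for key in ("treatments", "downsampling_sizes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if (self.simulate is None) == (self.fixture is None):
            raise ConfigurationError(
                "config must set exactly one input source: 'simulate' or 'fixture'"
            )
        if self.fixture is not None and not Path(self.fixture).is_dir():
            raise ConfigurationError(f"fixture directory not found: {self.fixture}")
        if self.signature_file is not None and not Path(self.signature_file).is_file():
            raise ConfigurationError(f"signature file not found: {self.signature_file}")
        bad = [t for t in self.treatments if t not in BATTERY_TREATMENTS + PLACEHOLDER_TREATMENTS]
        if bad:
            raise ConfigurationError(f"unknown treatments: {bad}")


@dataclass
class ReportBundle:
    out_dir: Path
    battery: pd.DataFrame
    downsampling: gr.DownsamplingReport | None
    scores: sc.ScoreVector
    split: sc.GroupSplit
    de_table: pd.DataFrame
    overlap: de_mod.OverlapReport
    metabolic_genes: list[str]
    network: net.MINetwork
    hub_ranking: pd.DataFrame
    projection: cv.CurveProjection
    manifest: dict
    partial: bool = False
    failed_stage: str | None = None


def _inter_tumor_de_genes(cpm: ad.AnnData, tumors: np.ndarray, n: int = 100) -> list[str]:
    """Top inter-tumor differentially expressed genes by Kruskal-Wallis H."""
    x = cpm.X if not hasattr(cpm.X, "toarray") else cpm.X.toarray()
    x = np.asarray(x, dtype=float)
    groups = [x[tumors == t] for t in pd.unique(tumors)]
    h = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        cols = [g[:, j] for g in groups]
        if all(np.ptp(c) == 0 for c in cols):
            continue
        try:
            h[j] = stats.kruskal(*cols).statistic
        except ValueError:  # all values identical
            h[j] = 0.0
    order = np.argsort(-h, kind="stable")[:n]
    return [cpm.var.index[i] for i in order]


def nmi_battery(
    counts: ad.AnnData,
    tumor_labels,
    treatments=BATTERY_TREATMENTS,
    hkg: list[str] | None = None,
    cnv_chromosomes: list[int] | None = None,
    n_components: int = 5,
    k_max: int = 10,
    most_expressed_threshold: float = 4.0,
) -> pd.DataFrame:
    """NMI of HCPC clustering vs tumor labels under each data treatment.

    ``counts`` must be a QC-filtered count matrix. Returns one row per
    requested treatment (placeholder metacell hooks are reported skipped).
    """
    tumors = np.asarray(tumor_labels)
    cpm = pp.cpm_log(counts)

    def _cluster_nmi(matrix) -> tuple[float, int]:
        assignment = gr.cluster_matrix(matrix, n_components=n_components, k_max=k_max)
        return gr.nmi(assignment.labels, tumors).value, assignment.k

    rows = []
    for name in treatments:
        if name in PLACEHOLDER_TREATMENTS:
            rows.append({"treatment": name, "nmi": np.nan, "k": 0, "status": "skipped"})
            continue
        if name == "cells":
            matrix = cpm
        elif name == "binarized":
            matrix = pp.binarize(cpm)
        elif name == "standardized":
            matrix = pp.standardize_within_group(cpm, tumors)
        elif name == "hkg_normalized":
            genes = hkg if hkg is not None else sim.housekeeping_genes(counts)
            matrix = pp.hkg_normalize(cpm, genes)
        elif name == "cnv_excluded":
            if cnv_chromosomes is None:
                rows.append({"treatment": name, "nmi": np.nan, "k": 0,
                             "status": "skipped_no_cnv_annotation"})
                continue
            drop = [
                g
                for g, c in zip(cpm.var.index, cpm.var["chromosome"])
                if int(c) in set(cnv_chromosomes)
            ]
            matrix = pp.exclude_genes(cpm, drop)
        elif name == "de_excluded":
            matrix = pp.exclude_genes(cpm, _inter_tumor_de_genes(cpm, tumors, 100))
        elif name == "odg_top500":
            n = min(500, cpm.n_vars)
            matrix = cpm[:, pp.select_overdispersed(cpm, n, "keep")].copy()
        elif name == "odg_top1000":
            n = min(1000, cpm.n_vars)
            matrix = cpm[:, pp.select_overdispersed(cpm, n, "keep")].copy()
        elif name == "odg_excluded":
            n = min(500, cpm.n_vars - 50)
            matrix = cpm[:, pp.select_overdispersed(cpm, n, "exclude")].copy()
        elif name == "most_expressed":
            genes = pp.select_most_expressed(cpm, most_expressed_threshold)
            matrix = cpm[:, genes].copy() if genes else cpm
        else:  # pragma: no cover - guarded by config validation
            raise ConfigurationError(f"unknown treatment {name!r}")
        value, k = _cluster_nmi(matrix)
        rows.append({"treatment": name, "nmi": value, "k": k, "status": "ok"})
    return pd.DataFrame(rows)


def _load_input(config: PipelineConfig) -> ad.AnnData:
    if config.simulate is not None:
        overrides = dict(config.simulate)
        overrides.setdefault("seed", config.seed)
        simcfg = sim.SimulationConfig(**overrides)
        return sim.simulate_dataset(simcfg)
    return sim.read_fixture(config.fixture)


def _resolve_signature(config: PipelineConfig, adata: ad.AnnData) -> sc.Signature:
    if config.signature_file is not None:
        genes = [
            line.strip()
            for line in Path(config.signature_file).read_text().splitlines()
            if line.strip()
        ]
        return sc.Signature(name=Path(config.signature_file).stem, genes=tuple(genes))
    if "role" in adata.var:
        return sc.Signature(name="tumorigenic", genes=tuple(sim.signature_genes(adata)))
    return sc.TUMORIGENIC_SIGNATURE


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage in order and write all outputs under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "stages": {},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]

    stage = "load"
    try:
        adata = _load_input(config)
        signature = _resolve_signature(config, adata)

        stage = "qc"
        cells, cell_report = pp.filter_cells(
            adata, min_reads=config.qc_min_reads, min_genes=config.qc_min_genes
        )
        cells, gene_report = pp.filter_genes(cells, min_cells=config.gene_min_cells)
        cell_report.removed.to_csv(out / "qc_removed_cells.tsv", sep="\t")
        gene_report.removed.to_csv(out / "qc_removed_genes.tsv", sep="\t")
        manifest["stages"]["qc"] = {
            "cells_removed": cell_report.n_removed,
            "genes_removed": gene_report.n_removed,
            "cells_retained": cell_report.n_retained,
            "genes_retained": gene_report.n_retained,
        }

        is_cancer = (
            cells.obs["cell_class"] == "cancer"
            if "cell_class" in cells.obs
            else pd.Series(True, index=cells.obs.index)
        )
        cancer = cells[is_cancer].copy()
        normal = cells[~is_cancer].copy() if (~is_cancer).any() else None
        tumors = cancer.obs["tumor"].to_numpy()

        stage = "battery"
        cnv_chroms = None
        if config.simulate is not None and "chromosome" in cancer.var:
            overrides = dict(config.simulate)
            overrides.setdefault("seed", config.seed)
            simcfg = sim.SimulationConfig(**overrides)
            full_chrom = sim._gene_roles(simcfg)["chromosome"].to_numpy()
            cnv_chroms = sorted(
                {
                    int(c)
                    for b in simcfg.resolved_cnv_blocks()
                    for c in full_chrom[b.start : b.stop]
                }
            )
        battery = nmi_battery(
            cancer,
            tumors,
            treatments=config.treatments,
            cnv_chromosomes=cnv_chroms,
            n_components=config.n_components,
            k_max=config.k_max,
            most_expressed_threshold=config.most_expressed_threshold,
        )
        normal_nmi = np.nan
        if normal is not None and normal.n_obs > config.k_max:
            norm_cpm = pp.cpm_log(normal)
            assignment = gr.cluster_matrix(
                norm_cpm, n_components=config.n_components, k_max=config.k_max
            )
            normal_nmi = gr.nmi(assignment.labels, normal.obs["tumor"].to_numpy()).value
        battery = pd.concat(
            [
                battery,
                pd.DataFrame(
                    [{"treatment": "normal_reference", "nmi": normal_nmi, "k": 0,
                      "status": "ok" if not np.isnan(normal_nmi) else "skipped"}]
                ),
            ],
            ignore_index=True,
        )
        battery.to_csv(out / "nmi_battery.tsv", sep="\t", index=False)

        stage = "downsampling"
        reference = float(battery.loc[battery["treatment"] == "cells", "nmi"].iloc[0])
        cancer_cpm = pp.cpm_log(cancer)
        sizes = [s for s in config.downsampling_sizes if s <= cancer.n_vars]
        downsampling = None
        if sizes:
            downsampling = gr.downsampling_experiment(
                cancer_cpm,
                tumors,
                reference_nmi=reference,
                sizes=sizes,
                reps=config.downsampling_reps,
                seed=config.seed + 1,
                n_components=config.n_components,
                k_max=config.k_max,
            )
            downsampling.table.to_csv(out / "downsampling.tsv", sep="\t")

        stage = "scoring"
        sc.validate_signature(cancer_cpm, signature, min_detection=config.min_detection)
        scores = sc.score(cancer_cpm, signature)
        split = sc.split_by_mean(scores)
        pd.DataFrame({"score": scores.values, "group": split.labels}).to_csv(
            out / "scores.tsv", sep="\t"
        )
        manifest["stages"]["scoring"] = {
            "threshold": split.thresholds[0],
            "n_high": int((split.labels == "HIGH").sum()),
            "n_low": int((split.labels == "LOW").sum()),
            "n_imputed": scores.n_imputed,
        }

        stage = "de"
        de_table = de_mod.mann_whitney_de(cancer_cpm, split, alpha=config.de_alpha)
        de_table.to_csv(out / "de.tsv", sep="\t")

        stage = "metabolic_selection"
        if "role" in cancer_cpm.var:
            annotation = set(sim.module_genes(cancer_cpm))
        else:
            annotation = set(cancer_cpm.var.index)
        metabolic = de_mod.select_correlated_metabolic(
            de_table, annotation, scores, cancer_cpm, p_threshold=config.de_alpha
        )
        (out / "metabolic_genes.txt").write_text("\n".join(metabolic) + "\n")
        up_genes = list(de_table.index[de_table["direction"] == "HIGH"])
        overlap_report = de_mod.overlap(up_genes, sorted(annotation))
        (out / "overlap.json").write_text(
            json.dumps(
                {
                    "n_up": overlap_report.n_a,
                    "n_annotation": overlap_report.n_b,
                    "n_intersection": overlap_report.n_intersection,
                    "percent_annotation_recovered": overlap_report.percent_b_in_a,
                },
                indent=2,
            )
        )

        stage = "network"
        module = metabolic if len(metabolic) >= 3 else sorted(annotation)
        mi = net.mutual_information_matrix(cancer_cpm, module, bins=config.mi_bins)
        skeleton = net.infer_skeleton(
            mi,
            cancer_cpm,
            n_permutations=config.network_permutations,
            fdr_q=config.network_fdr_q,
            seed=config.seed + 2,
            bins=config.mi_bins,
        )
        ranking = net.rank_degree(skeleton)
        skeleton.edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
        ranking.to_csv(out / "network_degree_ranking.tsv", sep="\t")
        (out / "network.json").write_text(
            json.dumps(
                {
                    "nodes": list(skeleton.nodes),
                    "edges": skeleton.edges.to_dict(orient="records"),
                    "hub": ranking.index[0],
                },
                indent=2,
            )
        )

        stage = "curve"
        module_matrix = cancer_cpm[:, module].copy()
        embedding = gr.pca_embed(module_matrix, min(2, len(module) - 1, cancer.n_obs - 1))
        pcurve = cv.fit_principal_curve(embedding)
        module_scores = sc.score(cancer_cpm, sc.Signature(name="module", genes=tuple(module)))
        projection = cv.project_with_overlays(
            pcurve,
            embedding,
            overlays={
                "tumorigenic": scores.values.to_numpy(),
                "module": module_scores.values.to_numpy(),
            },
            cell_ids=cancer.obs.index,
            orient_by="tumorigenic",
        )
        pd.DataFrame(
            {"position": projection.positions, "distance": projection.distances}
        ).to_csv(out / "curve_projection.tsv", sep="\t")

        bundle = ReportBundle(
            out_dir=out,
            battery=battery,
            downsampling=downsampling,
            scores=scores,
            split=split,
            de_table=de_table,
            overlap=overlap_report,
            metabolic_genes=metabolic,
            network=skeleton,
            hub_ranking=ranking,
            projection=projection,
            manifest=manifest,
        )
    except GliosigError:
        if stage == "load" or stage == "qc" and not manifest["stages"]:
            raise  # fail fast before any stage output exists
        manifest["stages"][stage] = {"status": "failed"}
        manifest["partial"] = True
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    manifest["partial"] = False
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return bundle
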