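"""Shared helpers for the numbered analysis drivers."""

from pathlib import Path

import gliosig as gs

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def study_cohort():
    """The default study-condition cohort, QC-filtered, with cancer/normal split."""
    adata = gs.simulate_dataset(gs.SimulationConfig(seed=SEED))
    cells, cell_report = gs.filter_cells(adata)
    cells, gene_report = gs.filter_genes(cells)
    cancer = cells[cells.obs["cell_class"] == "cancer"].copy()
    normal = cells[cells.obs["cell_class"] == "normal"].copy()
    return dict(
        raw=adata,
        cells=cells,
        cancer=cancer,
        normal=normal,
        cell_report=cell_report,
        gene_report=gene_report,
    )


def out_path(name: str) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS / name
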