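"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

import gliosig as gs


@pytest.fixture(scope="session")
def default_dataset():
    """The full-size study-condition cohort (4 tumors x 250 cancer cells,
    3 lineages x 150 normal cells, 5000 genes)."""
    return gs.simulate_dataset(gs.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_qc(default_dataset):
    cells, _ = gs.filter_cells(default_dataset)
    cells, _ = gs.filter_genes(cells)
    return cells


@pytest.fixture(scope="session")
def cancer_cpm(default_qc):
    cancer = default_qc[default_qc.obs["cell_class"] == "cancer"].copy()
    return gs.cpm_log(cancer)


@pytest.fixture(scope="session")
def normal_cpm(default_qc):
    normal = default_qc[default_qc.obs["cell_class"] == "normal"].copy()
    return gs.cpm_log(normal)


@pytest.fixture(scope="session")
def tumor_labels(cancer_cpm):
    return cancer_cpm.obs["tumor"].to_numpy()


@pytest.fixture(scope="session")
def truth_signature(default_qc):
    return gs.Signature(name="tumorigenic", genes=tuple(gs.signature_genes(default_qc)))


@pytest.fixture(scope="session")
def tumorigenic_scores(cancer_cpm, truth_signature):
    return gs.score(cancer_cpm, truth_signature)


@pytest.fixture(scope="session")
def small_dataset():
    """A light cohort for unit-level checks (seconds, not minutes)."""
    cfg = gs.SimulationConfig(
        n_tumors=2,
        cancer_cells_per_tumor=120,
        normal_cells_per_lineage=40,
        n_lineages=2,
        n_genes=800,
        lineage_marker_count=20,
        special_mean_boost=3.0,
        seed=11,
    )
    return gs.simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
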