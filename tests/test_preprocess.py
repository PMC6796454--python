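"""QC thresholds, normalization formulas and gene-selection treatments."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gliosig as gs
from gliosig.errors import ConfigurationError, FormatError, ValidationError


def make_counts(x, cell_ids=None, gene_ids=None):
    x = np.asarray(x)
    obs = pd.DataFrame(index=cell_ids or [f"c{i}" for i in range(x.shape[0])])
    var = pd.DataFrame(index=gene_ids or [f"g{j}" for j in range(x.shape[1])])
    adata = ad.AnnData(X=x.astype(np.int64), obs=obs, var=var)
    adata.uns["semantics"] = "counts"
    return adata


class TestFilterCells:
    def test_strict_fewer_than_semantics(self):
        # one cell just below the read threshold, one exactly at both thresholds
        n_genes = 1700
        below = np.full(n_genes, 52)          # 88,400 reads, 1700 genes detected
        below[0] = 52 + (89_999 - 52 * n_genes)  # exactly 89,999 reads
        at = np.full(n_genes, 52)
        at[0] = 52 + (90_000 - 52 * n_genes)     # exactly 90,000 reads
        adata = make_counts(np.vstack([below, at]))
        kept, report = gs.filter_cells(adata)
        assert list(kept.obs.index) == ["c1"]
        assert report.removed.loc["c0", "reason"] == "low_reads"
        assert report.n_removed + report.n_retained == 2

    def test_low_gene_count_removed(self):
        x = np.zeros((2, 2000), dtype=int)
        x[0, :1699] = 100   # plenty of reads, too few genes
        x[1, :1700] = 100
        kept, report = gs.filter_cells(adata := make_counts(x))
        assert list(kept.obs.index) == ["c1"]
        assert "low_genes" in report.removed.loc["c0", "reason"]

    def test_all_passing_is_identity(self, small_dataset):
        kept, report = gs.filter_cells(small_dataset, min_reads=0, min_genes=0)
        assert kept.shape == small_dataset.shape
        assert report.n_removed == 0
        assert list(kept.obs.index) == list(small_dataset.obs.index)

    def test_empty_input_raises(self):
        with pytest.raises(FormatError):
            gs.filter_cells(make_counts(np.zeros((0, 5), dtype=int)))


class TestFilterGenes:
    def test_detection_boundary_inclusive(self):
        x = np.zeros((4, 2), dtype=int)
        x[:2, 0] = 1  # detected in 2 cells -> removed at min_cells=3
        x[:3, 1] = 1  # detected in 3 cells -> retained
        kept, report = gs.filter_genes(make_counts(x), min_cells=3)
        assert list(kept.var.index) == ["g1"]
        assert report.n_removed == 1

    def test_min_cells_zero_is_identity(self, small_dataset):
        kept, report = gs.filter_genes(small_dataset, min_cells=0)
        assert kept.n_vars == small_dataset.n_vars
        assert report.n_removed == 0

    def test_min_cells_above_n_cells_raises(self):
        with pytest.raises(ConfigurationError):
            gs.filter_genes(make_counts(np.ones((3, 4), dtype=int)), min_cells=5)


class TestCpmLog:
    def test_known_values(self):
        x = np.zeros((1, 3), dtype=int)
        x[0] = [1, 0, 999_999]
        # totals 10^6: CPM of count 1 is 1 -> log2(2) = 1
        out = gs.cpm_log(make_counts(x))
        assert out.X[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert out.X[0, 1] == 0.0
        x2 = np.zeros((1, 2), dtype=int)
        x2[0] = [100, 999_900]
        out2 = gs.cpm_log(make_counts(x2))
        assert out2.X[0, 0] == pytest.approx(np.log2(101), abs=1e-12)

    def test_zero_total_cell_raises_naming_cell(self):
        x = np.zeros((2, 3), dtype=int)
        x[0] = [1, 2, 3]
        with pytest.raises(ValidationError, match="c1"):
            gs.cpm_log(make_counts(x))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_antilog_totals_equal_one_million(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 50, size=(5, 30))
        x[:, 0] += 1  # no zero-total cells
        out = gs.cpm_log(make_counts(x))
        totals = (np.exp2(np.asarray(out.X)) - 1.0).sum(axis=1)
        assert np.allclose(totals, 1e6, rtol=1e-9)


class TestHkgNormalize:
    def test_identical_cells_unchanged_up_to_scale(self):
        x = np.tile(np.arange(1, 7), (3, 1))
        cpm = gs.cpm_log(make_counts(x))
        out = gs.hkg_normalize(cpm, ["g0", "g1"])
        np.testing.assert_allclose(np.asarray(out.X), np.asarray(cpm.X), rtol=1e-12)

    def test_doubled_hkg_cell_gets_double_factor(self):
        base = np.array([[4.0, 4.0, 1.0], [4.0, 4.0, 2.0], [9.0, 9.0, 3.0]])
        cpm = make_counts(np.zeros((3, 3), dtype=int))
        cpm.X = base
        cpm.uns["semantics"] = "cpm_log"
        out = gs.hkg_normalize(cpm, ["g0", "g1"])
        factors = out.obs["hkg_factor"]
        assert factors["c2"] == pytest.approx(2.0 * factors["c0"], rel=1e-9)

    def test_empty_or_missing_hkg_raises(self, small_dataset):
        cpm = gs.cpm_log(small_dataset)
        with pytest.raises(ConfigurationError):
            gs.hkg_normalize(cpm, [])
        with pytest.raises(ConfigurationError, match="absent"):
            gs.hkg_normalize(cpm, ["not_a_gene"])


class TestStandardize:
    def test_forced_values(self):
        x = make_counts(np.array([[2], [4], [6]]))
        out = gs.standardize_within_group(x, ["a", "a", "a"])
        np.testing.assert_allclose(np.asarray(out.X).ravel(), [-1, 0, 1], atol=1e-12)

    def test_constant_gene_maps_to_zero(self):
        x = make_counts(np.array([[5, 1], [5, 2], [5, 3]]))
        out = gs.standardize_within_group(x, ["a"] * 3)
        assert np.all(np.asarray(out.X)[:, 0] == 0)

    def test_group_means_vanish(self, rng):
        x = make_counts(rng.integers(0, 30, size=(20, 8)))
        groups = np.array(["a"] * 8 + ["b"] * 12)
        out = gs.standardize_within_group(x, groups)
        vals = np.asarray(out.X)
        for g in ("a", "b"):
            assert np.abs(vals[groups == g].mean(axis=0)).max() < 1e-9
            sd = vals[groups == g].std(axis=0, ddof=1)
            assert np.allclose(sd[sd > 0], 1.0)

    def test_singleton_group_raises(self):
        x = make_counts(np.ones((3, 2), dtype=int))
        with pytest.raises(ValidationError):
            gs.standardize_within_group(x, ["a", "b", "b"])


class TestBinarize:
    def test_rule_and_idempotence(self):
        x = make_counts(np.zeros((1, 3), dtype=int))
        x.X = np.array([[0.0, 0.1, 7.0]])
        out = gs.binarize(x)
        np.testing.assert_array_equal(np.asarray(out.X), [[0, 1, 1]])
        again = gs.binarize(out)
        np.testing.assert_array_equal(np.asarray(again.X), np.asarray(out.X))


class TestOverdispersed:
    def _cpm(self, x):
        a = make_counts(np.zeros(x.shape, dtype=int))
        a.X = np.asarray(x, dtype=float)
        a.uns["semantics"] = "cpm_log"
        return a

    def test_outlier_dispersion_ranked_first(self, rng):
        base = rng.normal(5, 0.3, size=(60, 50))
        base[:, 7] = 5 + rng.normal(0, 3.0, size=60)  # 10x the variance of bin mates
        cpm = self._cpm(np.abs(base))
        top = gs.select_overdispersed(cpm, 5, "keep", n_bins=5)
        assert "g7" in top[:2]

    def test_tie_breaking_by_identifier(self):
        # every gene has identical values -> identical dispersion -> id order
        cpm = self._cpm(np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 6)))
        ranked = gs.select_overdispersed(cpm, 6, "keep", n_bins=2)
        assert ranked == sorted(ranked)

    def test_keep_all_and_exclude_complement(self, small_dataset):
        cpm = gs.cpm_log(small_dataset)
        n = cpm.n_vars
        assert len(gs.select_overdispersed(cpm, n, "keep")) == n
        top = set(gs.select_overdispersed(cpm, 100, "keep"))
        rest = set(gs.select_overdispersed(cpm, 100, "exclude"))
        assert top.isdisjoint(rest) and len(top | rest) == n
        with pytest.raises(ConfigurationError):
            gs.select_overdispersed(cpm, n + 1, "keep")


class TestMostExpressed:
    def test_threshold_semantics(self):
        # linear means 0, 3, 15 -> aggregates log2(1)=0, 2, 4
        lin = np.tile([0.0, 3.0, 15.0], (5, 1))
        a = make_counts(np.zeros(lin.shape, dtype=int))
        a.X = np.log2(lin + 1.0)
        a.uns["semantics"] = "cpm_log"
        assert gs.select_most_expressed(a, 0.0) == ["g0", "g1", "g2"]
        assert gs.select_most_expressed(a, 2.0) == ["g1", "g2"]
        assert gs.select_most_expressed(a, 99.0) == []


class TestExcludeGenes:
    def test_identity_and_errors(self, small_dataset):
        same = gs.exclude_genes(small_dataset, [])
        assert same.n_vars == small_dataset.n_vars
        with pytest.raises(ValidationError):
            gs.exclude_genes(small_dataset, list(small_dataset.var.index))

    def test_absent_gene_warns(self, small_dataset):
        with pytest.warns(UserWarning, match="1 listed"):
            out = gs.exclude_genes(small_dataset, ["g00001", "absent_gene"])
        assert out.n_vars == small_dataset.n_vars - 1


def test_treatments_preserve_cell_order(small_dataset):
    cpm = gs.cpm_log(small_dataset)
    ids = list(small_dataset.obs.index)
    for treated in (
        cpm,
        gs.binarize(cpm),
        gs.standardize_within_group(cpm, small_dataset.obs["tumor"]),
        gs.exclude_genes(cpm, list(cpm.var.index[:10])),
    ):
        assert list(treated.obs.index) == ids
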