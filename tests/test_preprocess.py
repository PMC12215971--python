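"""QC metrics, MAD outlier flags, normalization, vst HVG ranking and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from growthplate import DataError
from growthplate.preprocess import (
    MAD_CONSTANT,
    compute_qc_metrics,
    filter_low_abundance_genes,
    flag_outlier_cells,
    log_normalize,
    pca_scores,
    run_pca,
    scale_matrix,
    select_hvg_vst,
)

from conftest import make_counts


class TestQCMetrics:
    def test_arithmetic_example(self):
        # one cell, counts [2, 0, 3], third gene mitochondrial
        cm = make_counts([[2], [0], [3]], gene_ids=["a", "b", "mt-x"])
        m = compute_qc_metrics(cm, "mt-")
        assert m.loc[0, "library_size"] == 5
        assert m.loc[0, "n_genes_detected"] == 2
        assert m.loc[0, "mito_fraction"] == pytest.approx(0.6)

    def test_all_zero_cell(self):
        cm = make_counts([[0, 1], [0, 2]], gene_ids=["a", "mt-x"])
        m = compute_qc_metrics(cm, "mt-")
        assert m.loc[0, "library_size"] == 0
        assert m.loc[0, "n_genes_detected"] == 0
        assert m.loc[0, "mito_fraction"] == 0.0

    def test_no_mito_gene_warns_and_zeroes(self, caplog):
        cm = make_counts([[1, 2]], gene_ids=["a"])
        with caplog.at_level("WARNING", logger="growthplate"):
            m = compute_qc_metrics(cm, "mt-")
        assert (m["mito_fraction"] == 0).all()
        assert any("mitochondrial" in r.message for r in caplog.records)

    def test_matches_brute_force_on_random_fixture(self, random_counts):
        m = compute_qc_metrics(random_counts, "mt-")
        dense = random_counts.values.toarray()
        assert np.array_equal(m["library_size"], dense.sum(axis=0))
        assert np.array_equal(m["n_genes_detected"], (dense > 0).sum(axis=0))


class TestOutlierFlags:
    @staticmethod
    def _metrics(lib, ngenes, mito):
        return pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(len(lib))],
            "library_size": lib, "n_genes_detected": ngenes, "mito_fraction": mito,
        })

    def test_identical_metrics_no_flags(self):
        m = self._metrics([10] * 5, [3] * 5, [0.1] * 5)
        f = flag_outlier_cells(m)
        assert f["pass_qc"].all()

    def test_single_high_mito_cell_flagged(self):
        # brute-force oracle: median 0.05, MAD 0 on 99 identical -> only the
        # deviating cell can flag; with mixed values verify threshold math
        rng = np.random.default_rng(0)
        mito = np.r_[rng.normal(0.05, 0.005, 99).clip(0, 1), 0.9]
        m = self._metrics([100] * 100, [50] * 100, mito)
        f = flag_outlier_cells(m, n_mads=3.0)
        med = np.median(mito)
        mad = MAD_CONSTANT * np.median(np.abs(mito - med))
        expected = mito - med > 3.0 * mad
        assert np.array_equal(f["fail_mito"], expected)
        assert f.loc[99, "fail_mito"] and f["fail_mito"].sum() == 1

    def test_low_mito_never_flagged(self):
        mito = np.r_[np.full(20, 0.2), 0.0]  # far BELOW the median
        m = self._metrics([100] * 21, [50] * 21, mito)
        f = flag_outlier_cells(m)
        assert not f.loc[20, "fail_mito"]

    def test_library_two_sided(self):
        lib = np.r_[np.random.default_rng(1).poisson(1000, 50), 2, 100000]
        m = self._metrics(lib, [50] * 52, [0.1] * 52)
        f = flag_outlier_cells(m)
        assert f.loc[50, "fail_library"] and f.loc[51, "fail_library"]

    def test_invariant_under_reordering(self):
        rng = np.random.default_rng(5)
        m = self._metrics(rng.poisson(500, 40), rng.poisson(100, 40),
                          rng.uniform(0, 0.2, 40))
        f = flag_outlier_cells(m).set_index("cell_id")
        perm = rng.permutation(40)
        f2 = flag_outlier_cells(m.iloc[perm].reset_index(drop=True)).set_index("cell_id")
        pd.testing.assert_frame_equal(f2.loc[f.index], f)

    def test_needs_two_cells(self):
        with pytest.raises(DataError):
            flag_outlier_cells(self._metrics([1], [1], [0.0]))


class TestAbundanceFilter:
    def test_mean_threshold_brute_force(self):
        n_cells = 2000
        counts = np.zeros((2, n_cells), dtype=int)
        counts[0, 0] = 1          # mean 5e-4 -> removed
        counts[1, :4] = 1         # mean 2e-3 -> retained
        cm = make_counts(counts)
        out = filter_low_abundance_genes(cm, 1e-3)
        assert list(out.gene_ids) == ["g1"]

    def test_threshold_zero_is_identity(self, random_counts):
        out = filter_low_abundance_genes(random_counts, 0.0)
        assert np.array_equal(out.gene_ids, random_counts.gene_ids)

    def test_all_removed_is_error(self):
        cm = make_counts(np.zeros((3, 5), dtype=int))
        with pytest.raises(DataError, match="every gene"):
            filter_low_abundance_genes(cm, 1e-3)

    def test_survivor_order_preserved(self, random_counts):
        out = filter_low_abundance_genes(random_counts, 1.5)
        kept = [g for g in random_counts.gene_ids if g in set(out.gene_ids)]
        assert list(out.gene_ids) == kept


class TestLogNormalize:
    def test_closed_form(self):
        cm = make_counts([[1], [1], [2]])
        norm = log_normalize(cm, 1e4)
        # library 4: third value ln(1 + 1e4 * 2/4) = ln(5001)
        assert norm.values[2, 0] == pytest.approx(np.log(5001.0), rel=1e-12)

    def test_zero_count_stays_zero(self):
        cm = make_counts([[0, 1], [2, 3]])
        norm = log_normalize(cm, 1e4)
        assert norm.values[0, 0] == 0.0
        assert norm.values.nnz == cm.values.nnz  # sparsity preserved

    def test_zero_library_cell_named(self):
        cm = make_counts([[1, 0], [2, 0]], cell_ids=["good", "empty"])
        with pytest.raises(DataError, match="empty"):
            log_normalize(cm, 1e4)

    @settings(deadline=None, max_examples=25)
    @given(arrays(np.int64, (6, 8), elements=st.integers(0, 50)))
    def test_conservation_property(self, counts):
        # every cell must back-transform to exactly the scale factor
        counts[0] += 1  # guarantee positive libraries
        norm = log_normalize(make_counts(counts), 1e4)
        totals = np.expm1(norm.values.toarray()).sum(axis=0)
        assert np.allclose(totals, 1e4, rtol=1e-6)


class TestHVG:
    def test_exact_count_selected(self, small_synth):
        counts, _, _ = small_synth
        hvg = select_hvg_vst(counts, 100)
        assert int(hvg["selected"].sum()) == 100

    def test_constant_gene_never_selected_over_variable(self):
        rng = np.random.default_rng(2)
        mat = rng.poisson(3.0, size=(20, 200))
        mat[5] = 4  # constant gene
        hvg = select_hvg_vst(make_counts(mat), 10)
        assert hvg.loc[5, "variance_standardized"] == 0.0
        assert not hvg.loc[5, "selected"]

    def test_bursty_outranks_flat_brute_force(self):
        rng = np.random.default_rng(3)
        n = 500
        flat = rng.poisson(2.0, n)
        bursty = np.where(rng.uniform(size=n) < 0.1, rng.poisson(30.0, n), 0)
        filler = rng.poisson(np.linspace(0.5, 8, 30)[:, None], (30, n))
        mat = np.vstack([flat, bursty, filler])
        hvg = select_hvg_vst(make_counts(mat), 1)
        assert hvg.loc[1, "selected"]  # the bursty gene wins
        assert (hvg.loc[1, "variance_standardized"]
                > hvg.loc[0, "variance_standardized"])

    def test_n_hvg_exceeding_genes_selects_all(self, caplog):
        mat = np.random.default_rng(4).poisson(2.0, size=(5, 50))
        with caplog.at_level("WARNING", logger="growthplate"):
            hvg = select_hvg_vst(make_counts(mat), 100)
        assert hvg["selected"].all()

    def test_selection_invariant_to_gene_order(self):
        rng = np.random.default_rng(6)
        mat = rng.poisson(np.linspace(0.5, 10, 40)[:, None], (40, 300))
        cm = make_counts(mat)
        hvg = select_hvg_vst(cm, 10)
        perm = rng.permutation(40)
        hvg_p = select_hvg_vst(make_counts(mat[perm],
                                           gene_ids=[f"g{i}" for i in perm]), 10)
        sel = set(hvg.loc[hvg["selected"], "gene_id"])
        sel_p = set(hvg_p.loc[hvg_p["selected"], "gene_id"])
        assert sel == sel_p


class TestPCA:
    @staticmethod
    def _norm(mat):
        from growthplate import log_normalize
        return log_normalize(make_counts(mat), 1e4)

    def test_rank_one_explains_everything(self):
        u = np.arange(1, 11, dtype=float)
        mat = np.outer([2, 4, 6], u).astype(int)
        X = scale_matrix(mat.T.astype(float))
        scores = pca_scores(X, 2)
        var = scores.var(axis=0, ddof=1)
        assert var[0] / var.sum() > 0.999

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 10))
        Xc = X - X.mean(axis=0)
        scores = pca_scores(X, 5)
        # oracle: eigendecomposition of the covariance matrix
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (len(X) - 1))
        order = np.argsort(evals)[::-1]
        oracle = Xc @ evecs[:, order[:5]]
        for k in range(5):
            assert np.allclose(np.abs(scores[:, k]), np.abs(oracle[:, k]), atol=1e-8)
        assert np.allclose(scores.var(axis=0, ddof=1), evals[order[:5]], rtol=1e-10)

    def test_sign_convention_bit_identical(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(15, 6))
        a, b = pca_scores(X.copy(), 4), pca_scores(X.copy(), 4)
        assert np.array_equal(a, b)

    def test_too_many_components_rejected(self):
        with pytest.raises(DataError):
            pca_scores(np.ones((3, 2)), 5)

    def test_run_pca_uses_selected_genes(self, small_synth):
        counts, _, _ = small_synth
        from growthplate import log_normalize, select_hvg_vst
        norm = log_normalize(counts, 1e4)
        hvg = select_hvg_vst(counts, 30)
        scores = run_pca(norm, hvg, n_components=10)
        assert scores.shape == (counts.n_cells, 10)
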