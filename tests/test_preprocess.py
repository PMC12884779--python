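import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.nonparametric.smoothers_lowess import lowess

from scper.preprocess import (
    GeneByCellCounts,
    PreprocessConfig,
    PreprocessError,
    filter_cells_genes,
    impute_diffusion,
    intersect_genes,
    library_normalize,
    select_hvgs,
    stratified_subsample,
    _largest_remainder,
)


def _toy(counts, **kw):
    g, n = counts.shape
    return GeneByCellCounts(
        gene_ids=np.array([f"g{i}" for i in range(g)], dtype=object),
        cell_ids=np.array([f"c{j}" for j in range(n)], dtype=object),
        counts=np.asarray(counts, dtype=float),
        cell_type=kw.get("cell_type", np.array(["t"] * n, dtype=object)),
        batch=kw.get("batch", np.array(["b"] * n, dtype=object)),
    )


class TestFilterCellsGenes:
    def test_low_complexity_cell_removed(self):
        # one cell detects 150 genes (below the 200 threshold), others 250
        counts = np.zeros((300, 5))
        counts[:250, 1:] = 1.0
        counts[:150, 0] = 1.0
        filtered, _ = filter_cells_genes(_toy(counts), PreprocessConfig(min_cells_per_gene=1))
        assert "c0" not in filtered.cell_ids
        assert filtered.n_cells == 4

    def test_rare_gene_removed_after_cell_filter(self):
        counts = np.ones((250, 6))
        counts[0, :] = [1, 1, 0, 0, 0, 0]  # gene g0 detected in exactly 2 cells
        cfg = PreprocessConfig(min_detected_genes=100)
        filtered, stats = filter_cells_genes(_toy(counts), cfg)
        assert "g0" not in filtered.gene_ids
        assert stats.n_genes_removed == 1

    def test_degenerate_detection_distribution_keeps_all_cells(self):
        counts = np.ones((500, 50))  # every cell detects exactly 500 genes
        filtered, stats = filter_cells_genes(_toy(counts))
        assert filtered.n_cells == 50
        assert stats.n_cells_removed_quantile == 0

    def test_idempotent(self, tiny_counts):
        cfg = PreprocessConfig(min_detected_genes=5, min_cells_per_gene=2)
        once, _ = filter_cells_genes(tiny_counts, cfg)
        twice, _ = filter_cells_genes(once, cfg)
        assert np.array_equal(once.counts, twice.counts)
        assert np.array_equal(once.cell_ids, twice.cell_ids)

    def test_empty_result_raises(self):
        counts = np.ones((10, 4))  # only 10 detected genes << 200
        with pytest.raises(PreprocessError):
            filter_cells_genes(_toy(counts))


class TestLibraryNormalize:
    def test_direct_arithmetic(self):
        norm = library_normalize(np.array([[1.0], [1.0], [2.0]]))
        assert np.allclose(norm.cp10k[:, 0], [2500, 2500, 5000])
        assert np.allclose(norm.log1p[:, 0], np.log([2501, 2501, 5001]))

    def test_zero_stays_zero_and_sums_conserved(self, tiny_counts):
        norm = library_normalize(tiny_counts.counts)
        assert np.all(norm.cp10k[tiny_counts.counts == 0] == 0)
        sums = norm.cp10k.sum(axis=0)
        assert np.allclose(sums, 1e4, atol=1e-6)

    def test_zero_library_column_flagged(self):
        mat = np.array([[1.0, 0.0], [1.0, 0.0]])
        norm = library_normalize(mat)
        assert list(norm.zero_library_columns) == [1]
        assert np.all(norm.cp10k[:, 1] == 0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            library_normalize(np.array([[-1.0], [2.0]]))


class TestSelectHVGs:
    def test_high_variance_gene_ranks_first(self):
        # means spread so the trend is locally supported; one mid-range gene
        # has variance far above it
        rng = np.random.default_rng(0)
        means = rng.uniform(2.0, 8.0, size=200)
        expr = rng.normal(means[:, None], 0.3, size=(200, 300))
        expr[37] = rng.normal(5.0, 3.0, size=300)
        norm = library_normalize(np.abs(expr))
        panel, stats = select_hvgs(norm, 10)
        assert panel.gene_ids[0] == "g37"
        assert stats.rank[37] == 0

    def test_ranking_matches_brute_force_dispersion(self, small_sc):
        norm = library_normalize(small_sc.counts, gene_ids=small_sc.gene_ids)
        keep = norm.log1p.var(axis=1, ddof=1) > 0
        panel, stats = select_hvgs(norm, int(keep.sum()))
        # independent recomputation of delta_g = log var - f(log mean)
        mu = norm.log1p[keep].mean(axis=1)
        va = norm.log1p[keep].var(axis=1, ddof=1)
        frac = min(1.0, max(0.3, 30.0 / keep.sum()))
        trend = lowess(np.log(va), np.log(mu), frac=frac, it=1, return_sorted=False)
        delta = np.log(va) - trend
        ids = norm.gene_ids[keep]
        expected = ids[np.lexsort((ids.astype(str), -delta))]
        assert list(panel.gene_ids) == list(expected)

    def test_requesting_more_than_available_warns_and_clamps(self):
        rng = np.random.default_rng(1)
        norm = library_normalize(rng.poisson(3.0, size=(50, 30)).astype(float))
        with pytest.warns(UserWarning):
            panel, _ = select_hvgs(norm, 5000)
        assert len(panel) <= 50

    def test_constant_matrix_rejected(self):
        norm = library_normalize(np.ones((20, 10)))
        with pytest.raises(ValueError):
            select_hvgs(norm, 5)


class TestIntersectGenes:
    def test_shared_subset_in_reference_order(self, small_bulk, small_sc):
        sub = small_sc.subset_genes(np.arange(0, 200))
        bulk = small_bulk.reindex_genes(small_sc.gene_ids[100:250])
        panel = intersect_genes(sub, bulk)
        assert list(panel.gene_ids) == list(small_sc.gene_ids[100:200])

    def test_identical_sets_full_order(self, small_sc, small_bulk):
        panel = intersect_genes(small_sc, small_bulk)
        assert list(panel.gene_ids) == list(small_sc.gene_ids)

    def test_disjoint_sets_error_names_examples(self, small_sc, small_bulk):
        bulk = small_bulk
        bulk.gene_ids = np.array([f"ENS{i}" for i in range(len(bulk.gene_ids))], dtype=object)
        with pytest.raises(ValueError, match="ENS0"):
            intersect_genes(small_sc, bulk)


class TestStratifiedSubsample:
    def test_equal_quota_largest_remainder(self):
        counts = np.ones((250, 6000))
        types = np.repeat(["a", "b", "c"], 2000).astype(object)
        sc = _toy(counts, cell_type=types)
        sub = stratified_subsample(sc, 5000, seed=0)
        _, got = np.unique(sub.cell_type.astype(str), return_counts=True)
        assert sorted(got, reverse=True) == [1667, 1667, 1666]

    def test_deficit_redistributed(self):
        counts = np.ones((250, 4100))
        types = np.array(["rare"] * 100 + ["x"] * 2000 + ["y"] * 2000, dtype=object)
        sc = _toy(counts, cell_type=types)
        sub = stratified_subsample(sc, 3000, seed=0)
        tally = dict(zip(*np.unique(sub.cell_type.astype(str), return_counts=True)))
        assert tally["rare"] == 100
        assert tally["x"] + tally["y"] == 2900
        assert abs(tally["x"] - tally["y"]) <= 1

    def test_seed_reproducible(self, small_sc):
        a = stratified_subsample(small_sc, 150, seed=42)
        b = stratified_subsample(small_sc, 150, seed=42)
        assert list(a.cell_ids) == list(b.cell_ids)

    def test_too_few_cells_requested(self, small_sc):
        with pytest.raises(ValueError):
            stratified_subsample(small_sc, 2, seed=0)

    @given(st.integers(2, 8), st.integers(0, 500))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_largest_remainder_sums_exactly(self, k, extra):
        rng = np.random.default_rng(extra)
        f = rng.dirichlet(np.ones(k))
        total = k + extra
        quota = _largest_remainder(f, total)
        assert quota.sum() == total
        assert (quota >= 0).all()


class TestImputeDiffusion:
    def test_zero_steps_identity(self, small_sc):
        norm = library_normalize(small_sc.counts[:, :100])
        out = impute_diffusion(norm, k_neighbors=10, diffusion_steps=0)
        assert out is norm

    def test_duplicate_cells_get_equal_imputations(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(4.0, size=(60, 30)).astype(float)
        counts[:, 1] = counts[:, 0]  # exact duplicate pair
        norm = library_normalize(counts)
        out = impute_diffusion(norm, k_neighbors=5, diffusion_steps=3)
        assert np.allclose(out.log1p[:, 0], out.log1p[:, 1])

    def test_diffusion_reduces_per_gene_variance(self, small_sc):
        norm = library_normalize(small_sc.counts[:, :200])
        out = impute_diffusion(norm, k_neighbors=10, diffusion_steps=3)
        before = norm.cp10k.var(axis=1).mean()
        after = out.cp10k.var(axis=1).mean()
        assert after <= before

    def test_too_many_neighbors_rejected(self, small_sc):
        norm = library_normalize(small_sc.counts[:, :10])
        with pytest.raises(ValueError):
            impute_diffusion(norm, k_neighbors=10, diffusion_steps=1)
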