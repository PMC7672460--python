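import numpy as np
import pandas as pd
import pytest

from ifcseq.io_formats import CountMatrix, ExpressionMatrix
from ifcseq.sct_preprocess import (PreprocessConfig, filter_cells_min_genes,
                                   filter_genes_min_cells, log_transform,
                                   preprocess, rank_marker_genes,
                                   select_highly_variable_genes,
                                   select_species_cells)


def _cm(values, prefix="g"):
    values = np.asarray(values)
    return CountMatrix(values,
                       [f"{prefix}{i}" for i in range(values.shape[0])],
                       [f"c{j}" for j in range(values.shape[1])])


class TestSpeciesSelection:
    def _mixed(self, values):
        values = np.asarray(values)
        half = values.shape[0] // 2
        genes = [f"HUMAN_g{i}" for i in range(half)] + \
                [f"MOUSE_g{i}" for i in range(values.shape[0] - half)]
        return CountMatrix(values, genes, [f"c{j}" for j in range(values.shape[1])])

    def test_majority_human_cell_kept(self):
        # 3 human genes expressed vs 1 mouse gene
        cm = self._mixed([[1], [1], [1], [1], [0], [0]])
        out = select_species_cells(cm)
        assert out.n_cells == 1
        assert all(g.startswith("HUMAN_") for g in out.gene_ids)

    def test_tie_is_dropped(self):
        cm = self._mixed([[1], [1], [0], [1], [1], [0]])
        assert select_species_cells(cm).n_cells == 0

    def test_unprefixed_gene_is_error(self):
        cm = CountMatrix([[1]], ["RAT_x"], ["c0"])
        with pytest.raises(ValueError, match="prefix"):
            select_species_cells(cm)

    def test_matches_bruteforce_on_random_binary(self, rng):
        values = (rng.random((6, 5)) < 0.5).astype(int)
        cm = self._mixed(values)
        out = select_species_cells(cm)
        expected = [j for j in range(5)
                    if (values[:3, j] > 0).sum() > (values[3:, j] > 0).sum()]
        assert out.cell_ids.tolist() == [f"c{j}" for j in expected]


class TestCountFilters:
    @pytest.mark.parametrize("n_expressed,kept", [(19, False), (20, True), (21, True)])
    def test_min_cells_boundary(self, n_expressed, kept):
        row = np.zeros(30, dtype=int)
        row[:n_expressed] = 3
        cm = _cm(np.vstack([row, np.ones(30, dtype=int)]))
        out = filter_genes_min_cells(cm, 20)
        assert ("g0" in out.gene_ids.tolist()) is kept

    @pytest.mark.parametrize("n_genes_expr,kept", [(199, False), (200, True)])
    def test_min_genes_boundary(self, n_genes_expr, kept):
        col = np.zeros(250, dtype=int)
        col[:n_genes_expr] = 1
        cm = _cm(np.column_stack([col, np.ones(250, dtype=int)]))
        out = filter_cells_min_genes(cm, 200)
        assert ("c0" in out.cell_ids.tolist()) is kept

    def test_min_genes_zero_is_identity(self, random_counts):
        out = filter_cells_min_genes(random_counts, 0)
        assert np.array_equal(out.values, random_counts.values)

    def test_filters_match_bruteforce(self, random_counts):
        out = filter_genes_min_cells(random_counts, 10)
        expected = [i for i in range(random_counts.n_genes)
                    if (random_counts.values[i] > 0).sum() >= 10]
        assert out.gene_ids.tolist() == [f"g{i}" for i in expected]
        out2 = filter_cells_min_genes(random_counts, 15)
        expected2 = [j for j in range(random_counts.n_cells)
                     if (random_counts.values[:, j] > 0).sum() >= 15]
        assert out2.cell_ids.tolist() == [f"c{j}" for j in expected2]

    def test_filters_idempotent(self, random_counts):
        once = filter_genes_min_cells(random_counts, 10)
        twice = filter_genes_min_cells(once, 10)
        assert np.array_equal(once.values, twice.values)


def _hvg_oracle(counts, min_mean, max_mean, min_disp, library_normalize=True):
    """Step-by-step 20-bin dispersion recipe, independent of the implementation."""
    x = counts.values.T.astype(float)  # cells x genes
    if library_normalize:
        lib = x.sum(axis=1)
        x = x / lib[:, None] * np.median(lib)
    x_log = np.log1p(x)
    x = np.expm1(x_log)  # de-logged normalized values
    n = x.shape[0]
    mean = x.mean(axis=0)
    var = (np.mean(x * x, axis=0) - mean ** 2) * n / (n - 1)
    mean_safe = np.where(mean == 0, 1e-12, mean)
    disp = var / mean_safe
    disp = np.where(disp == 0, np.nan, disp)
    disp = np.log(disp)
    log_mean = np.log1p(mean)
    df = pd.DataFrame({"mean": log_mean, "disp": disp})
    df["bin"] = pd.cut(df["mean"], bins=20)
    grouped = df.groupby("bin", observed=True)["disp"]
    avg = grouped.transform("mean")
    dev = grouped.transform("std")
    one_gene_bin = grouped.transform("size") == 1
    dev = dev.mask(one_gene_bin, avg)
    avg = avg.mask(one_gene_bin, 0.0)
    disp_norm = np.nan_to_num(((df["disp"] - avg) / dev).to_numpy())
    keep = (log_mean > min_mean) & (log_mean < max_mean) & (disp_norm > min_disp)
    # constant genes are by definition not variable (tolerance for roundoff)
    x_log_var = x_log.var(axis=0)
    return keep & (x_log_var > 1e-12)


class TestHighlyVariableGenes:
    def test_constant_matrix_rejected(self):
        cm = _cm(np.full((5, 30), 4))
        with pytest.raises(ValueError, match="relax"):
            select_highly_variable_genes(cm)

    def test_mean_gate_excludes_high_mean_gene(self, rng):
        # gene 0: moderate mean, bursty; gene 1: huge mean everywhere
        g0 = rng.integers(0, 2, 200) * rng.integers(1, 10, 200)
        g1 = np.full(200, 500) + rng.integers(0, 3, 200)
        filler = rng.poisson(1.0, size=(30, 200))
        cm = _cm(np.vstack([g0, g1, filler]))
        out = select_highly_variable_genes(cm, 0.0125, 3, -0.5,
                                           library_normalize=False)
        kept = out.gene_ids.tolist()
        assert "g1" not in kept

    @pytest.mark.parametrize("library_normalize", [True, False])
    def test_matches_independent_recipe(self, library_normalize, truth):
        from ifcseq.synthetic_data import generate_sct
        counts, _, _ = generate_sct(truth, n_cells=300, n_genes=200, seed=9)
        counts = filter_genes_min_cells(counts, 1)  # avoid all-zero genes
        out = select_highly_variable_genes(counts, 0.0125, 3, -0.15,
                                           library_normalize=library_normalize)
        expected = _hvg_oracle(counts, 0.0125, 3, -0.15, library_normalize)
        assert out.gene_ids.tolist() == counts.gene_ids[expected].tolist()


class TestLogTransform:
    def test_known_values(self):
        cm = _cm(np.array([[0, 3]]))
        expr = log_transform(cm)
        assert expr.values[0, 0] == 0.0
        e = log_transform(np.array([[np.e - 1]]), ["c0"], ["t0"])
        assert np.isclose(e.values[0, 0], 1.0)

    def test_elementwise_oracle(self, random_counts):
        expr = log_transform(random_counts)
        assert np.allclose(expr.values, np.log(1 + random_counts.values.T),
                           atol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            log_transform(np.array([[-0.5]]), ["c0"], ["t0"])


class TestRankMarkerGenes:
    def _expr(self, values):
        values = np.asarray(values, float)
        return ExpressionMatrix(values,
                                [f"c{i}" for i in range(values.shape[0])],
                                [f"g{j}" for j in range(values.shape[1])])

    def test_clearly_differential_gene_ranks_first(self, rng):
        base = rng.normal(1.0, 0.1, size=(20, 5))
        base[:10, 0] = 2.0
        base[10:, 0] = 0.0
        labels = ["A"] * 10 + ["B"] * 10
        ranking = rank_marker_genes(self._expr(base), labels, 3)
        assert ranking.top_genes("A")[0] == "g0"

    def test_exchangeable_gene_never_beats_differential(self, rng):
        values = rng.normal(0.0, 1.0, size=(40, 4))
        values[:20, 1] += 3.0  # g1 differential for A
        labels = ["A"] * 20 + ["B"] * 20
        ranking = rank_marker_genes(self._expr(values), labels, 4)
        top = ranking.top_genes("A")
        assert top.index("g1") < top.index("g0")

    def test_planted_markers_occupy_top_slots(self, rng):
        n_per, n_genes = 15, 20
        values = rng.normal(0.0, 0.5, size=(3 * n_per, n_genes))
        labels = sum([[p] * n_per for p in ("A", "B", "C")], [])
        planted = {"A": [0, 1, 2], "B": [5, 6, 7], "C": [10, 11, 12]}
        for k, pop in enumerate(("A", "B", "C")):
            for g in planted[pop]:
                values[k * n_per:(k + 1) * n_per, g] += 4.0
        ranking = rank_marker_genes(self._expr(values), labels, 3)
        for pop in ("A", "B", "C"):
            assert set(ranking.top_genes(pop)) == {f"g{i}" for i in planted[pop]}

    def test_label_permutation_equivariance(self, rng):
        values = rng.normal(size=(30, 8))
        values[:15, 2] += 2
        labels = np.array(["A"] * 15 + ["B"] * 15, dtype=object)
        r1 = rank_marker_genes(self._expr(values), labels, 5)
        swapped = np.where(labels == "A", "B", "A")
        r2 = rank_marker_genes(self._expr(values), swapped, 5)
        assert r1.rankings["A"] == r2.rankings["B"]
        assert r1.rankings["B"] == r2.rankings["A"]

    def test_small_population_is_error(self):
        expr = self._expr(np.ones((4, 5)))
        with pytest.raises(ValueError, match="2 cells"):
            rank_marker_genes(expr, ["A", "B", "B", "B"], 2)

    def test_agrees_with_scanpy_argmax(self, rng):
        """Independent route: scanpy's t-test ranking finds the same top gene."""
        import anndata as ad
        import scanpy as sc
        values = rng.normal(1.0, 0.3, size=(60, 10))
        values[:30, 4] += 2.5
        labels = ["A"] * 30 + ["B"] * 30
        ranking = rank_marker_genes(self._expr(values), labels, 1)
        adata = ad.AnnData(values)
        adata.var_names = [f"g{j}" for j in range(10)]
        adata.obs["pop"] = pd.Categorical(labels)
        sc.tl.rank_genes_groups(adata, "pop", method="t-test", n_genes=1)
        assert ranking.top_genes("A")[0] == adata.uns["rank_genes_groups"]["names"]["A"][0]


class TestPipelineOrder:
    def test_preprocess_composes_filters_and_log(self, small_sct):
        counts, _, _ = small_sct
        cfg = PreprocessConfig(apply_hvg=False, min_cells_per_gene=20)
        expr = preprocess(counts, cfg)
        manual = log_transform(filter_genes_min_cells(counts, 20))
        assert np.array_equal(expr.values, manual.values)
        assert expr.target_names.tolist() == manual.target_names.tolist()
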