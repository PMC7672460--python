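import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ifcseq import evaluation as ev
from ifcseq.io_formats import ExpressionMatrix


def _em(values, prefix="g"):
    values = np.asarray(values, float)
    return ExpressionMatrix(values, [f"c{i}" for i in range(values.shape[0])],
                            [f"{prefix}{j}" for j in range(values.shape[1])])


class TestPerCellMetrics:
    def test_perfect_prediction(self, rng):
        t = _em(rng.normal(size=(6, 5)))
        rep = ev.per_cell_metrics(t, t)
        assert np.allclose(rep.per_cell_pearson, 1.0)
        assert np.allclose(rep.per_cell_rmse, 0.0)
        assert rep.medians["pearson"] == 1.0

    def test_anticorrelated_prediction(self, rng):
        t = _em(rng.normal(size=(4, 6)))
        p = _em(-t.values + 3.0)
        rep = ev.per_cell_metrics(t, p)
        assert np.allclose(rep.per_cell_pearson, -1.0)

    def test_matches_textbook_formulas(self, rng):
        t = _em(rng.normal(size=(5, 4)))
        p = _em(rng.normal(size=(5, 4)))
        rep = ev.per_cell_metrics(t, p)
        pearson = [stats.pearsonr(t.values[i], p.values[i])[0] for i in range(5)]
        spearman = [stats.spearmanr(t.values[i], p.values[i])[0] for i in range(5)]
        rmse = [np.sqrt(np.mean((t.values[i] - p.values[i]) ** 2)) for i in range(5)]
        assert np.allclose(rep.per_cell_pearson, pearson, atol=1e-12)
        assert np.allclose(rep.per_cell_spearman, spearman, atol=1e-12)
        assert np.allclose(rep.per_cell_rmse, rmse, atol=1e-12)
        assert rep.medians["pearson"] == pytest.approx(np.median(pearson))

    def test_zero_variance_cell_excluded_from_median(self, rng):
        t_vals = rng.normal(size=(4, 5))
        t_vals[0] = 2.0  # constant truth vector -> undefined correlation
        t, p = _em(t_vals), _em(rng.normal(size=(4, 5)))
        rep = ev.per_cell_metrics(t, p)
        assert np.isnan(rep.per_cell_pearson[0])
        assert rep.n_cells_excluded == 1
        assert not np.isnan(rep.medians["pearson"])

    def test_too_few_genes_rejected(self, rng):
        t = _em(rng.normal(size=(4, 2)))
        with pytest.raises(ValueError, match="3 genes"):
            ev.per_cell_metrics(t, t)

    def test_gene_subset_restricts_metrics(self, rng):
        t, p = _em(rng.normal(size=(5, 8))), _em(rng.normal(size=(5, 8)))
        sub = ["g1", "g4", "g6"]
        rep = ev.per_cell_metrics(t, p, gene_subset=sub)
        assert rep.gene_subset == sub
        manual = stats.pearsonr(t.values[0, [1, 4, 6]], p.values[0, [1, 4, 6]])[0]
        assert rep.per_cell_pearson[0] == pytest.approx(manual)


class TestPerGeneMetrics:
    def test_identity_and_anticorrelation(self, rng):
        t = _em(rng.normal(size=(10, 4)))
        assert np.allclose(ev.per_gene_metrics(t, t)["pearson"], 1.0)
        p = _em(-2.0 * t.values + 1.0)
        assert np.allclose(ev.per_gene_metrics(t, p)["pearson"], -1.0)

    def test_matches_bruteforce(self, rng):
        t, p = _em(rng.normal(size=(12, 6))), _em(rng.normal(size=(12, 6)))
        out = ev.per_gene_metrics(t, p)
        expected = [stats.pearsonr(t.values[:, j], p.values[:, j])[0] for j in range(6)]
        assert np.allclose(out["pearson"], expected, atol=1e-12)

    def test_affine_invariance(self, rng):
        t, p = _em(rng.normal(size=(12, 6))), _em(rng.normal(size=(12, 6)))
        p2 = _em(4.2 * p.values + 0.3)
        assert np.allclose(ev.per_gene_metrics(t, p)["pearson"],
                           ev.per_gene_metrics(t, p2)["pearson"], atol=1e-9)


class TestPerTreeUncertainty:
    def test_identical_trees_zero_std(self, rng):
        true = _em(rng.normal(size=(8, 3)))
        pred = rng.normal(size=(8, 3))
        stack = np.stack([pred] * 5)
        out = ev.per_tree_uncertainty(stack, true)
        assert np.allclose(out["std"], 0.0, atol=1e-12)

    def test_two_tree_hand_computation(self):
        true = _em([[0.0], [1.0], [2.0], [3.0]])
        t1 = np.array([[0.1], [0.9], [2.1], [2.9]])
        t2 = np.array([[3.0], [2.0], [1.0], [0.0]])
        out = ev.per_tree_uncertainty(np.stack([t1, t2]), true)
        r1 = stats.pearsonr(true.values[:, 0], t1[:, 0])[0]
        r2 = stats.pearsonr(true.values[:, 0], t2[:, 0])[0]
        expected = np.std([r1, r2], ddof=0)  # population std, n = n_trees
        assert out["std"][0] == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_tree_reordering(self, rng):
        true = _em(rng.normal(size=(10, 4)))
        stack = rng.normal(size=(6, 10, 4))
        a = ev.per_tree_uncertainty(stack, true)["std"]
        b = ev.per_tree_uncertainty(stack[::-1], true)["std"]
        assert np.allclose(a, b, atol=1e-12)


class TestPopulationProfiles:
    def test_single_population_is_column_means(self, rng):
        expr = _em(rng.normal(size=(7, 4)))
        prof = ev.population_profiles(expr, ["A"] * 7, ["g0", "g1", "g2", "g3"])
        assert np.allclose(prof.loc["A"], expr.values.mean(axis=0), atol=1e-12)

    def test_planted_means_recovered(self):
        values = np.vstack([np.zeros((5, 3)), np.full((5, 3), 2.0)])
        expr = _em(values)
        prof = ev.population_profiles(expr, ["lo"] * 5 + ["hi"] * 5,
                                      ["g0", "g1", "g2"])
        assert np.allclose(prof.loc["lo"], 0.0)
        assert np.allclose(prof.loc["hi"], 2.0)

    def test_matches_groupby_mean(self, rng):
        expr = _em(rng.normal(size=(30, 5)))
        labels = rng.choice(["A", "B", "C"], size=30).tolist()
        prof = ev.population_profiles(expr, labels, [f"g{j}" for j in range(5)])
        expected = pd.DataFrame(expr.values, columns=prof.columns) \
            .groupby(np.asarray(labels)).mean()
        assert np.allclose(prof.to_numpy(), expected.loc[prof.index].to_numpy(),
                           atol=1e-12)


class TestPopulationSimilarity:
    def test_identical_rows_correlate_one(self, rng):
        row = rng.normal(size=10)
        prof = pd.DataFrame([row, row], index=["A", "B"])
        sim = ev.population_similarity(prof, with_ci=False)
        assert sim.entry("A", "B") == pytest.approx(1.0)

    def test_orthogonal_centered_rows(self):
        prof = pd.DataFrame([[1, -1, 1, -1], [1, 1, -1, -1]], index=["A", "B"],
                            dtype=float)
        sim = ev.population_similarity(prof, with_ci=False)
        assert sim.entry("A", "B") == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_pairwise(self, rng):
        prof = pd.DataFrame(rng.normal(size=(3, 10)), index=["A", "B", "C"])
        sim = ev.population_similarity(prof)
        for a in "ABC":
            for b in "ABC":
                expected = 1.0 if a == b else stats.pearsonr(prof.loc[a], prof.loc[b])[0]
                assert sim.entry(a, b) == pytest.approx(expected, abs=1e-12)
        assert np.allclose(sim.values, sim.values.T)
        # CI brackets the estimate
        lo, hi = sim.ci("A", "B")
        assert lo <= sim.entry("A", "B") <= hi

    def test_significantly_more_similar_uses_ci_bounds(self):
        sim = ev.SimilarityMatrix(
            values=np.array([[1.0, 0.99, 0.9], [0.99, 1.0, 0.8], [0.9, 0.8, 1.0]]),
            populations=["cyto", "helper", "other"],
            ci_low=np.array([[1, 0.979, 0.85], [0.979, 1, 0.7], [0.85, 0.7, 1]]),
            ci_high=np.array([[1, 0.995, 0.975], [0.995, 1, 0.9], [0.975, 0.9, 1]]),
        )
        # lower CI of (cyto, helper) = 0.979 > upper CI of (cyto, other) = 0.975
        assert ev.significantly_more_similar(sim, "cyto", "helper", "other")
        # overlapping intervals: 0.85 (low of other,cyto) < 0.9 (high of other,helper)
        assert not ev.significantly_more_similar(sim, "other", "cyto", "helper")


class TestFisherCI:
    def test_closed_form_r0(self):
        lo, hi = ev.fisher_ci(0.0, 103)
        z = stats.norm.ppf(0.975)
        expected = np.tanh(z / 10.0)
        assert lo == pytest.approx(-expected, abs=1e-9)
        assert hi == pytest.approx(expected, abs=1e-9)
        assert hi == pytest.approx(0.1935, abs=5e-4)

    def test_closed_form_r05(self):
        lo, hi = ev.fisher_ci(0.5, 100)
        assert lo == pytest.approx(0.337, abs=1e-3)
        assert hi == pytest.approx(0.634, abs=1e-3)

    def test_confidence_to_zero_collapses(self):
        lo, hi = ev.fisher_ci(0.4, 50, confidence=1e-12)
        assert lo == pytest.approx(0.4, abs=1e-6)
        assert hi == pytest.approx(0.4, abs=1e-6)

    def test_width_decreases_in_n_increases_in_confidence(self):
        widths = [np.diff(ev.fisher_ci(0.3, n))[0] for n in (10, 50, 200, 1000)]
        assert all(a > b for a, b in zip(widths, widths[1:]))
        w90 = np.diff(ev.fisher_ci(0.3, 50, 0.90))[0]
        w99 = np.diff(ev.fisher_ci(0.3, 50, 0.99))[0]
        assert w99 > w90

    def test_degenerate_and_invalid_inputs(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert ev.fisher_ci(1.0, 20) == (1.0, 1.0)
        with pytest.raises(ValueError, match="n >= 4"):
            ev.fisher_ci(0.5, 3)


class TestBootstrap:
    def test_exact_affine_relation_zero_std(self, rng):
        x = rng.normal(size=50)
        y = 2.0 * x + 1.0
        assert ev.bootstrap_corr_std(x, y, n_boot=200, seed=0) == pytest.approx(0.0, abs=1e-12)

    def test_seeded_determinism(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        a = ev.bootstrap_corr_std(x, y, n_boot=500, seed=3)
        b = ev.bootstrap_corr_std(x, y, n_boot=500, seed=3)
        assert a == b

    def test_within_monte_carlo_error_of_reference(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=60)
        y = x + rng.normal(scale=1.0, size=60)
        ref = ev.bootstrap_corr_std(x, y, n_boot=100_000, seed=99)
        small = ev.bootstrap_corr_std(x, y, n_boot=200, seed=7)
        # std of a bootstrap-std estimate scales ~ ref / sqrt(2 * (n_boot - 1))
        mc_err = ref / np.sqrt(2 * 199)
        assert abs(small - ref) <= 3 * mc_err
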