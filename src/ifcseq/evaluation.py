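"""Validation statistics for predicted expression.

Covers per-cell and per-gene Pearson/Spearman correlations and RMSE
(medians reported across cells, as in the result tables), per-tree ensemble
uncertainty, population-average expression profiles and their pairwise
transcriptional similarity, Fisher-transform confidence intervals for
correlations, and bootstrap standard deviations.

Cells or genes whose truth or prediction vector has zero variance have an
undefined correlation; these are excluded from medians (never coerced to 0)
and the exclusion counts are surfaced in the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

__all__ = [
    "MetricReport", "SimilarityMatrix",
    "per_cell_metrics", "per_gene_metrics", "per_tree_uncertainty",
    "population_profiles", "population_similarity",
    "fisher_ci", "bootstrap_corr_std", "significantly_more_similar",
]


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of corresponding rows; NaN where undefined."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a ** 2).sum(axis=1) * (b ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def _rowwise_spearman(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ra = stats.rankdata(a, axis=1)  # ties get average ranks
    rb = stats.rankdata(b, axis=1)
    return _rowwise_pearson(ra, rb)


@dataclass
class MetricReport:
    per_cell_pearson: np.ndarray
    per_cell_spearman: np.ndarray
    per_cell_rmse: np.ndarray
    gene_subset: list
    n_cells_excluded: int
    per_gene_pearson: np.ndarray | None = None
    per_gene_spearman: np.ndarray | None = None
    gene_names: list | None = None
    n_genes_excluded: int = 0

    @property
    def medians(self) -> dict:
        return {
            "pearson": float(np.nanmedian(self.per_cell_pearson)),
            "spearman": float(np.nanmedian(self.per_cell_spearman)),
            "rmse": float(np.median(self.per_cell_rmse)),
        }

    def to_json(self, path) -> None:
        payload = {
            "medians": self.medians,
            "n_cells": int(len(self.per_cell_pearson)),
            "n_cells_excluded": int(self.n_cells_excluded),
            "n_genes_excluded": int(self.n_genes_excluded),
            "gene_subset": [str(g) for g in self.gene_subset],
        }
        if self.per_gene_pearson is not None:
            payload["median_per_gene_pearson"] = float(np.nanmedian(self.per_gene_pearson))
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class SimilarityMatrix:
    values: np.ndarray  # (n_pops, n_pops) Pearson correlations
    populations: list
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    n_genes: int | None = None

    def entry(self, a: str, b: str) -> float:
        i, j = self.populations.index(a), self.populations.index(b)
        return float(self.values[i, j])

    def ci(self, a: str, b: str) -> tuple:
        i, j = self.populations.index(a), self.populations.index(b)
        return float(self.ci_low[i, j]), float(self.ci_high[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations, columns=self.populations)


def _aligned(true: ExpressionMatrix, pred: ExpressionMatrix, gene_subset):
    if not np.array_equal(true.cell_ids, pred.cell_ids):
        raise ValueError("true and predicted matrices must be aligned on cells")
    if gene_subset is not None:
        genes = [g for g in gene_subset]
        true = true.subset_targets(genes)
        pred = pred.subset_targets(genes)
    return true, pred


def per_cell_metrics(true: ExpressionMatrix, pred: ExpressionMatrix,
                     gene_subset=None, compute_per_gene: bool = True) -> MetricReport:
    """Per-cell Pearson/Spearman/RMSE across a gene subset, medians over cells.

    The gene subset is typically the union of the per-population top marker
    genes; restricting to it (rather than all genes) is where prediction
    quality concentrates.
    """
    true, pred = _aligned(true, pred, gene_subset)
    if true.values.shape[1] < 3:
        raise ValueError("need at least 3 genes for per-cell correlations")
    t, p = true.values, pred.values
    pearson = _rowwise_pearson(t, p)
    spearman = _rowwise_spearman(t, p)
    rmse = np.sqrt(np.mean((t - p) ** 2, axis=1))
    report = MetricReport(
        per_cell_pearson=pearson,
        per_cell_spearman=spearman,
        per_cell_rmse=rmse,
        gene_subset=true.target_names.tolist(),
        n_cells_excluded=int(np.isnan(pearson).sum()),
    )
    if compute_per_gene:
        gp = _rowwise_pearson(t.T, p.T)
        gs = _rowwise_spearman(t.T, p.T)
        report.per_gene_pearson = gp
        report.per_gene_spearman = gs
        report.gene_names = true.target_names.tolist()
        report.n_genes_excluded = int(np.isnan(gp).sum())
    return report


def per_gene_metrics(true: ExpressionMatrix, pred: ExpressionMatrix,
                     cell_subset=None) -> dict:
    """Per-gene Pearson/Spearman across cells; zero-variance genes are NaN."""
    if not np.array_equal(true.cell_ids, pred.cell_ids):
        raise ValueError("true and predicted matrices must be aligned on cells")
    if cell_subset is not None:
        pos = {c: i for i, c in enumerate(true.cell_ids.tolist())}
        idx = np.array([pos[c] for c in cell_subset])
        t, p = true.values[idx], pred.values[idx]
    else:
        t, p = true.values, pred.values
    pearson = _rowwise_pearson(t.T, p.T)
    spearman = _rowwise_spearman(t.T, p.T)
    return {
        "gene_names": true.target_names.tolist(),
        "pearson": pearson,
        "spearman": spearman,
        "n_genes_excluded": int(np.isnan(pearson).sum()),
    }


def per_tree_uncertainty(per_tree_preds: np.ndarray, true: ExpressionMatrix,
                         gene_subset=None) -> dict:
    """Std over ensemble members of each gene's prediction-truth correlation.

    ``per_tree_preds`` has shape (n_trees, n_cells, n_targets). For each
    gene, the Pearson correlation between every tree's prediction and the
    truth is computed across cells; the population standard deviation over
    trees (ddof=0, n = n_trees) is reported.
    """
    per_tree_preds = np.asarray(per_tree_preds, dtype=float)
    if per_tree_preds.ndim != 3:
        raise ValueError("per-tree stack must be (n_trees, n_cells, n_targets)")
    names = true.target_names.tolist()
    t = true.values
    if gene_subset is not None:
        pos = {g: i for i, g in enumerate(names)}
        cols = np.array([pos[g] for g in gene_subset])
        t = t[:, cols]
        per_tree_preds = per_tree_preds[:, :, cols]
        names = list(gene_subset)
    n_trees = per_tree_preds.shape[0]
    corr = np.empty((n_trees, t.shape[1]))
    for k in range(n_trees):
        corr[k] = _rowwise_pearson(t.T, per_tree_preds[k].T)
    with np.errstate(invalid="ignore"):
        std = np.nanstd(corr, axis=0, ddof=0)
    return {"gene_names": names, "per_tree_corr": corr, "std": std}


def population_profiles(expr: ExpressionMatrix, labels, marker_genes) -> pd.DataFrame:
    """Population-by-gene matrix of mean expression (rows: populations)."""
    sub = expr.subset_targets(marker_genes)
    lab = np.asarray(labels.labels if hasattr(labels, "labels") else labels, dtype=object)
    if len(lab) != expr.n_cells:
        raise ValueError("labels and expression matrix differ in cell count")
    pops = sorted(set(lab.tolist()))
    rows = []
    for pop in pops:
        mask = lab == pop
        if not mask.any():
            raise ValueError(f"population {pop!r} is empty")
        rows.append(sub.values[mask].mean(axis=0))
    return pd.DataFrame(np.vstack(rows), index=pops, columns=sub.target_names.tolist())


def population_similarity(profiles: pd.DataFrame, with_ci: bool = True,
                          confidence: float = 0.95) -> SimilarityMatrix:
    """Pairwise Pearson correlation between population profile rows.

    The confidence interval for each off-diagonal entry uses the Fisher
    transformation with n = number of genes in the profiles.
    """
    mat = profiles.to_numpy(dtype=float)
    pops = [str(p) for p in profiles.index]
    n_pop, n_genes = mat.shape
    sim = np.ones((n_pop, n_pop))
    for i in range(n_pop):
        for j in range(i + 1, n_pop):
            r = _rowwise_pearson(mat[i][None, :], mat[j][None, :])[0]
            sim[i, j] = sim[j, i] = r
    result = SimilarityMatrix(sim, pops, n_genes=n_genes)
    if with_ci:
        lo = np.ones((n_pop, n_pop))
        hi = np.ones((n_pop, n_pop))
        for i in range(n_pop):
            for j in range(n_pop):
                if i == j:
                    continue
                lo[i, j], hi[i, j] = fisher_ci(sim[i, j], n_genes, confidence)
        result.ci_low, result.ci_high = lo, hi
    return result


def fisher_ci(r: float, n: int, confidence: float = 0.95) -> tuple:
    """Fisher-transform confidence interval for a Pearson correlation.

    (low, high) = tanh(atanh(r) -/+ z * 1/sqrt(n - 3)) with z the two-sided
    normal quantile for the requested confidence.
    """
    if n < 4:
        raise ValueError("Fisher CI requires n >= 4")
    r = float(r)
    if abs(r) >= 1.0:
        if abs(r) > 1.0:
            raise ValueError("|r| must be <= 1")
        import warnings
        warnings.warn("|r| = 1: degenerate confidence interval", stacklevel=2)
        return (r, r)
    z = stats.norm.ppf((1.0 + confidence) / 2.0)
    se = 1.0 / np.sqrt(n - 3)
    zr = np.arctanh(r)
    return (float(np.tanh(zr - z * se)), float(np.tanh(zr + z * se)))


def significantly_more_similar(sim: SimilarityMatrix, a: str, b: str, c: str) -> bool:
    """True iff (a,b) are significantly more similar than (a,c).

    The criterion is non-overlap of the Fisher confidence intervals in the
    favorable direction: the lower bound of r(a,b) exceeds the upper bound
    of r(a,c).
    """
    if sim.ci_low is None:
        raise ValueError("similarity matrix carries no confidence intervals")
    return sim.ci(a, b)[0] > sim.ci(a, c)[1]


def bootstrap_corr_std(true_vec, pred_vec, n_boot: int = 10000, seed: int = 0) -> float:
    """Bootstrap standard deviation of the Pearson correlation of two vectors.

    Cells are resampled with replacement ``n_boot`` times; resamples where
    either vector is constant are skipped (counted but excluded).
    """
    x = np.asarray(true_vec, dtype=float)
    y = np.asarray(pred_vec, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 observations to bootstrap")
    rng = np.random.default_rng(seed)
    rs = np.empty(n_boot)
    chunk = max(1, min(n_boot, int(5e6 // max(n, 1))))
    for start in range(0, n_boot, chunk):
        k = min(chunk, n_boot - start)
        idx = rng.integers(0, n, size=(k, n))
        xs, ys = x[idx], y[idx]
        rs[start:start + k] = _rowwise_pearson(xs, ys)
    valid = ~np.isnan(rs)
    return float(np.std(rs[valid], ddof=0))
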