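"""Preprocessing of the single-cell transcriptomics (SCT) experiment.

The raw input is a gene-by-cell UMI count matrix plus a per-cell table of
surface-marker intensities (an antibody-tag readout in CITE-seq-style data).
Preprocessing turns this into the filtered, natural-log-transformed
expression matrix used for regression, and ranks per-population marker genes
that later serve as the evaluation gene set.

Pipeline order (asserted by :func:`preprocess`):

1. species selection (mixed-species experiments only): keep cells expressing
   strictly more prefix-1 than prefix-2 genes, drop prefix-2 gene rows;
2. minimum-genes-per-cell filter (default 200; mixed-species data only);
3. highly-variable-gene selection by the 20-bin dispersion recipe
   (defaults min_mean 0.0125, max_mean 3, min_disp -0.15);
4. minimum-cells-per-gene filter (default 20);
5. natural-log transform x -> ln(1 + x).

"Expressed" always means a non-zero count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import CountMatrix, ExpressionMatrix

__all__ = [
    "PreprocessConfig",
    "MarkerGeneRanking",
    "select_species_cells",
    "filter_genes_min_cells",
    "filter_cells_min_genes",
    "select_highly_variable_genes",
    "log_transform",
    "rank_marker_genes",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    min_cells_per_gene: int = 20
    min_genes_per_cell: int = 200          # mixed-species (human) data only
    hvg_min_mean: float = 0.0125
    hvg_max_mean: float = 3.0
    hvg_min_disp: float = -0.15
    species_prefixes: tuple = ("HUMAN_", "MOUSE_")
    n_top_markers: int = 100
    apply_species_filter: bool = False     # True for mixed-species input
    apply_hvg: bool = True
    hvg_library_normalize: bool = True     # per-cell scaling inside HVG only
    de_method: str = "t-test"              # or "wilcoxon"

    def __post_init__(self) -> None:
        if self.min_cells_per_gene < 0 or self.min_genes_per_cell < 0:
            raise ValueError("count thresholds must be non-negative")
        if self.n_top_markers < 1:
            raise ValueError("n_top_markers must be >= 1")


@dataclass
class MarkerGeneRanking:
    """Per-population ordered (gene_id, score) lists, best first."""

    rankings: dict  # population -> list[(gene_id, score)]

    @property
    def populations(self) -> list:
        return list(self.rankings)

    def top_genes(self, population: str, n: int | None = None) -> list:
        pairs = self.rankings[population]
        return [g for g, _ in (pairs if n is None else pairs[:n])]

    def all_top_genes(self) -> list:
        """Union of every population's list, first-seen order preserved."""
        seen, out = set(), []
        for pop in self.rankings:
            for g, _ in self.rankings[pop]:
                if g not in seen:
                    seen.add(g)
                    out.append(g)
        return out


def select_species_cells(counts: CountMatrix, prefixes=("HUMAN_", "MOUSE_")) -> CountMatrix:
    """Keep cells expressing strictly more prefix-1 than prefix-2 genes.

    Mixed-species barnyard experiments tag each gene with a species prefix;
    a cell with at least as many expressed genes of the second species as of
    the first is an ambiguous doublet candidate and is dropped (ties drop).
    Gene rows of the second species are removed from the output.
    """
    p1, p2 = prefixes
    gene_list = counts.gene_ids.tolist()
    is1 = np.array([g.startswith(p1) for g in gene_list])
    is2 = np.array([g.startswith(p2) for g in gene_list])
    neither = ~(is1 | is2)
    if neither.any():
        bad = counts.gene_ids[neither][0]
        raise ValueError(f"gene {bad!r} has neither prefix {p1!r} nor {p2!r}")
    expressed = counts.values > 0
    n1 = expressed[is1].sum(axis=0)
    n2 = expressed[is2].sum(axis=0)
    return counts.select_cells(n1 > n2).select_genes(is1)


def filter_genes_min_cells(counts: CountMatrix, min_cells: int) -> CountMatrix:
    """Keep genes expressed (non-zero) in at least ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be non-negative")
    n_cells_expr = (counts.values > 0).sum(axis=1)
    return counts.select_genes(n_cells_expr >= min_cells)


def filter_cells_min_genes(counts: CountMatrix, min_genes: int) -> CountMatrix:
    """Keep cells expressing (non-zero) at least ``min_genes`` genes."""
    if min_genes < 0:
        raise ValueError("min_genes must be non-negative")
    n_genes_expr = (counts.values > 0).sum(axis=0)
    return counts.select_cells(n_genes_expr >= min_genes)


def select_highly_variable_genes(
    counts: CountMatrix,
    min_mean: float = 0.0125,
    max_mean: float = 3.0,
    min_disp: float = -0.15,
    library_normalize: bool = True,
) -> CountMatrix:
    """Dispersion-based highly-variable-gene filter (20-bin recipe).

    Counts are (optionally) scaled per cell to the median library size and
    log1p-transformed; per-gene mean and dispersion (variance/mean of the
    de-logged values) are computed, genes are binned into 20 mean bins and
    dispersions z-scored within each bin. Kept genes satisfy
    ``min_mean < mean < max_mean`` and normalized dispersion ``> min_disp``.
    """
    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(counts.values.T.astype(np.float64))
    adata.var_names = [str(g) for g in counts.gene_ids.tolist()]
    adata.obs_names = [str(c) for c in counts.cell_ids.tolist()]
    if library_normalize:
        sc.pp.normalize_total(adata)  # scale to median library size
    sc.pp.log1p(adata)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(
            adata,
            flavor="seurat",
            min_mean=min_mean,
            max_mean=max_mean,
            min_disp=min_disp,
            n_bins=20,
        )
    keep = adata.var["highly_variable"].to_numpy()
    # a zero-variance gene has no dispersion and can never be highly variable
    keep &= np.asarray(adata.X).var(axis=0) > 1e-12
    if keep.sum() < 1:
        raise ValueError(
            "no gene passes the dispersion filter; relax min_mean/max_mean/min_disp"
        )
    return counts.select_genes(keep)


def log_transform(values, cell_ids=None, target_names=None) -> ExpressionMatrix:
    """Elementwise natural-log transform x -> ln(1 + x); zeros stay zero.

    Accepts a :class:`CountMatrix` (transposed to cells x genes) or a raw
    cells-by-targets array with explicit ids.
    """
    if isinstance(values, CountMatrix):
        mat = values.values.T.astype(float)
        cell_ids = values.cell_ids
        target_names = values.gene_ids
    else:
        mat = np.asarray(values, dtype=float)
    if mat.size and mat.min() < 0:
        raise ValueError("log transform requires non-negative input")
    return ExpressionMatrix(np.log1p(mat), cell_ids, target_names)


def _welch_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Welch t statistic per gene (columns), group x vs group y."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = stats.ttest_ind(x, y, axis=0, equal_var=False).statistic
    return np.nan_to_num(t, nan=0.0)


def _wilcoxon_z(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Normal-approximation z of the rank-sum statistic per gene (columns)."""
    nx, ny = x.shape[0], y.shape[0]
    ranks = stats.rankdata(np.vstack([x, y]), axis=0)
    rx = ranks[:nx].sum(axis=0)
    mu = nx * (nx + ny + 1) / 2.0
    sigma = np.sqrt(nx * ny * (nx + ny + 1) / 12.0)
    with np.errstate(invalid="ignore"):
        z = (rx - mu) / sigma
    return np.nan_to_num(z, nan=0.0)


def rank_marker_genes(expr: ExpressionMatrix, labels, n_top: int = 100,
                      method: str = "t-test") -> MarkerGeneRanking:
    """Rank differentially expressed genes per population, one-vs-rest.

    The default statistic is the Welch t-test on log expression; a
    rank-sum ("wilcoxon") alternative is available. Ties in the statistic
    break by gene id so rankings are deterministic.
    """
    label_arr = np.asarray(labels.labels if hasattr(labels, "labels") else labels,
                           dtype=object)
    if len(label_arr) != expr.n_cells:
        raise ValueError("labels and expression matrix differ in cell count")
    pops = sorted(set(label_arr.tolist()))
    if len(pops) < 2:
        raise ValueError("need at least 2 populations to rank marker genes")
    stat_fn = {"t-test": _welch_t, "wilcoxon": _wilcoxon_z}.get(method)
    if stat_fn is None:
        raise ValueError(f"unknown DE method {method!r}")
    gene_names = expr.target_names.tolist()
    rankings = {}
    for pop in pops:
        in_pop = label_arr == pop
        if in_pop.sum() < 2 or (~in_pop).sum() < 2:
            raise ValueError(f"population {pop!r} needs >= 2 cells on both sides")
        scores = stat_fn(expr.values[in_pop], expr.values[~in_pop])
        order = sorted(range(len(gene_names)), key=lambda i: (-scores[i], gene_names[i]))
        rankings[pop] = [(gene_names[i], float(scores[i])) for i in order[:n_top]]
    return MarkerGeneRanking(rankings)


def preprocess(counts: CountMatrix, config: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Run the full filter chain in the fixed order and return log expression."""
    cfg = config or PreprocessConfig()
    if cfg.apply_species_filter:
        counts = select_species_cells(counts, cfg.species_prefixes)
        counts = filter_cells_min_genes(counts, cfg.min_genes_per_cell)
    if cfg.apply_hvg:
        counts = select_highly_variable_genes(
            counts, cfg.hvg_min_mean, cfg.hvg_max_mean, cfg.hvg_min_disp,
            library_normalize=cfg.hvg_library_normalize,
        )
    counts = filter_genes_min_cells(counts, cfg.min_cells_per_gene)
    return log_transform(counts)
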