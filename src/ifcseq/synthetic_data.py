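"""Paired-modality synthetic data with known ground truth.

Generates a matched SCT experiment (negative-binomial UMI counts plus a
2-marker surface table), an IFC experiment (marker table and optional
32x32 16-bit brightfield-like images), and the ground-truth population of
every cell, so the whole pipeline — including the label-free CNN — can be
trained and validated without any external download.

The default layout mimics the mouse myeloid-progenitor geometry: two
well-separated extreme populations and one intermediate population that
occupies a smaller range of the marker space (which is what makes it the
hardest to predict), on top of a diffuse background of "other" cells.

Expression model: every gene g has log-mean
``mu_g(cell) = base_g + effect_g[pop] + s_g1 * m1 + s_g2 * m2`` with
(m1, m2) the cell's marker coordinates; counts are negative-binomial with
that mean. Population marker genes carry a large ``effect`` in their own
population; marker-coding genes carry a large monotone slope on one marker.

Image model: a centered disk whose radius grows with marker 1 on a noisy
background, with interior speckle whose density grows with marker 2 — so
morphology alone encodes both marker values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coregistration import Gate, GateSet, PopulationLabels
from .io_formats import CountMatrix, ExpressionMatrix, ImageStack, MarkerTable

__all__ = ["SyntheticTruth", "GenePlan", "generate_sct", "generate_ifc",
           "expected_log_expression"]

_DEFAULT_POPULATIONS = {
    # name: (center_m1, center_m2, spread_sd, mixture_weight)
    "mep_like": (0.20, 0.20, 0.08, 0.30),
    "cmp_like": (0.50, 0.50, 0.05, 0.25),   # intermediate, smaller spread
    "gmp_like": (0.80, 0.80, 0.08, 0.30),
    "other": (0.50, 0.50, 0.28, 0.15),      # diffuse background
}


@dataclass
class SyntheticTruth:
    """Ground-truth generative parameters shared by both modalities."""

    populations: dict = field(default_factory=lambda: dict(_DEFAULT_POPULATIONS))
    marker_names: tuple = ("CD34like", "FcgRlike")
    n_markers_per_pop: int = 10       # planted population marker genes
    marker_effect: float = 2.5        # natural-log effect in own population
    n_link_genes_per_marker: int = 5  # strongly marker-coding genes
    link_slope: float = 2.0           # log-mean slope on the marker value
    background_slope_sd: float = 0.25
    base_log_mean: float = -1.0
    base_log_sd: float = 0.5
    nb_dispersion: float = 2.0        # NB size parameter theta
    radius_base: float = 5.0          # disk radius at marker1 = 0 (pixels)
    radius_gain: float = 6.0          # extra radius per unit of marker1
    texture_gain: float = 0.5         # speckle probability per unit of marker2
    noise_sd: float = 300.0           # background noise sd, 16-bit scale
    background_level: float = 20000.0
    disk_level: float = 35000.0
    speckle_level: float = 55000.0
    gene_seed: int = 12345            # fixes the gene plan across calls

    def __post_init__(self) -> None:
        for name, (cx, cy, sd, w) in self.populations.items():
            if not (0.0 <= cx <= 1.0 and 0.0 <= cy <= 1.0):
                raise ValueError(f"population {name!r} center outside the unit square")
            if sd < 0 or w < 0:
                raise ValueError(f"population {name!r} has negative spread or weight")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.radius_base + self.radius_gain > 15:
            raise ValueError("disk radius would exceed the 32x32 frame")

    @property
    def population_names(self) -> list:
        return [p for p in self.populations if p != "other"]

    def gates(self) -> GateSet:
        """Rectangular gates matching the default three-population layout."""
        mx, my = self.marker_names
        return GateSet({
            "mep_like": Gate(mx, my, (0.0, 0.35), (0.0, 0.35)),
            "cmp_like": Gate(mx, my, (0.35, 0.65), (0.35, 0.65)),
            "gmp_like": Gate(mx, my, (0.65, 1.0), (0.65, 1.0)),
        })

    def gene_plan(self, n_genes: int) -> "GenePlan":
        return GenePlan(self, n_genes)


class GenePlan:
    """Deterministic per-gene parameters derived from a truth object.

    The plan depends only on the truth's ``gene_seed`` and ``n_genes``, so
    the SCT and IFC modalities (and repeated calls) share identical genes.
    """

    def __init__(self, truth: SyntheticTruth, n_genes: int):
        pops = truth.population_names
        need = len(pops) * truth.n_markers_per_pop + \
            2 * truth.n_link_genes_per_marker
        if n_genes < need:
            raise ValueError(f"need at least {need} genes for the configured plan")
        rng = np.random.default_rng(truth.gene_seed)
        self.gene_ids = np.array([f"GENE{i:04d}" for i in range(n_genes)], dtype=object)
        self.base = rng.normal(truth.base_log_mean, truth.base_log_sd, size=n_genes)
        # small random marker slopes for every gene; overwritten for link genes
        self.slopes = rng.normal(0.0, truth.background_slope_sd, size=(n_genes, 2))
        self.effects = {pop: np.zeros(n_genes) for pop in pops}
        self.planted_markers = {}
        cursor = 0
        for pop in pops:
            idx = np.arange(cursor, cursor + truth.n_markers_per_pop)
            self.effects[pop][idx] = truth.marker_effect
            self.planted_markers[pop] = self.gene_ids[idx].tolist()
            cursor += truth.n_markers_per_pop
        self.link_genes = {}
        for m in range(2):
            idx = np.arange(cursor, cursor + truth.n_link_genes_per_marker)
            self.slopes[idx, :] = 0.0
            self.slopes[idx, m] = truth.link_slope
            self.link_genes[truth.marker_names[m]] = self.gene_ids[idx].tolist()
            cursor += truth.n_link_genes_per_marker

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def log_mean(self, markers: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """(n_cells, n_genes) log of the NB mean for each cell and gene."""
        mu = self.base[None, :] + markers @ self.slopes.T
        for pop, eff in self.effects.items():
            mask = labels == pop
            if mask.any():
                mu[mask] += eff[None, :]
        return mu


def _draw_cells(truth: SyntheticTruth, n_cells: int, rng: np.random.Generator):
    names = list(truth.populations)
    weights = np.array([truth.populations[p][3] for p in names], dtype=float)
    if n_cells < len(truth.population_names):
        raise ValueError("n_cells must be at least the number of populations")
    weights = weights / weights.sum()
    which = rng.choice(len(names), size=n_cells, p=weights)
    labels = np.array([names[i] for i in which], dtype=object)
    centers = np.array([truth.populations[p][:2] for p in labels.tolist()])
    spreads = np.array([truth.populations[p][2] for p in labels.tolist()])
    markers = centers + rng.normal(0.0, 1.0, size=(n_cells, 2)) * spreads[:, None]
    return np.clip(markers, 0.0, 1.0), labels


def generate_sct(truth: SyntheticTruth, n_cells: int = 2000, n_genes: int = 120,
                 seed: int = 0):
    """Synthetic SCT experiment.

    Returns ``(CountMatrix, MarkerTable, PopulationLabels)``; the marker
    table holds the true (jittered, clipped) marker coordinates and the
    labels are the ground-truth mixture components.
    """
    rng = np.random.default_rng(seed)
    markers, labels = _draw_cells(truth, n_cells, rng)
    plan = truth.gene_plan(n_genes)
    mean = np.exp(plan.log_mean(markers, labels))
    theta = truth.nb_dispersion
    p = theta / (theta + mean)
    counts = rng.negative_binomial(theta, p).T  # genes x cells
    cell_ids = np.array([f"SCT{i:05d}" for i in range(n_cells)], dtype=object)
    return (
        CountMatrix(counts, plan.gene_ids, cell_ids),
        MarkerTable(markers, cell_ids, np.asarray(truth.marker_names, dtype=object)),
        PopulationLabels(labels, cell_ids),
    )


def expected_log_expression(truth: SyntheticTruth, markers: MarkerTable,
                            n_genes: int = 120, gates: GateSet | None = None) -> ExpressionMatrix:
    """Noise-free expression as a deterministic monotone function of markers.

    The population term is resolved by gating the marker coordinates (a
    deterministic function of the marker point), and the log1p of the NB
    mean is returned — the exact quantity a perfect regressor could learn.
    """
    from .coregistration import apply_gates

    gates = gates or truth.gates()
    norm = MarkerTable(markers.values, markers.cell_ids, markers.marker_names,
                       normalized=True)
    labels = apply_gates(norm, gates)
    # map the gate labels onto the populations that carry effects
    plan = truth.gene_plan(n_genes)
    mu = plan.log_mean(np.asarray(markers.values, float), labels.labels)
    return ExpressionMatrix(np.log1p(np.exp(mu)), markers.cell_ids, plan.gene_ids)


def _render_image(m1: float, m2: float, truth: SyntheticTruth,
                  rng: np.random.Generator) -> np.ndarray:
    size = 32
    img = rng.normal(truth.background_level, truth.noise_sd, size=(size, size)) \
        if truth.noise_sd > 0 else np.full((size, size), truth.background_level)
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    radius = truth.radius_base + truth.radius_gain * m1
    disk = (xx - c) ** 2 + (yy - c) ** 2 <= radius ** 2
    img[disk] = truth.disk_level + (rng.normal(0.0, truth.noise_sd, size=int(disk.sum()))
                                    if truth.noise_sd > 0 else 0.0)
    p_speckle = np.clip(truth.texture_gain * m2, 0.0, 1.0)
    if p_speckle > 0:
        speckle = disk & (rng.random((size, size)) < p_speckle)
        img[speckle] = truth.speckle_level
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def generate_ifc(truth: SyntheticTruth, n_cells: int = 2000, seed: int = 0,
                 with_images: bool = True):
    """Synthetic IFC experiment.

    Returns ``(MarkerTable, ImageStack | None, PopulationLabels)``. Images
    encode marker 1 as disk radius and marker 2 as interior speckle density,
    quantized to 16 bits on a noisy background.
    """
    rng = np.random.default_rng(seed)
    markers, labels = _draw_cells(truth, n_cells, rng)
    cell_ids = np.array([f"IFC{i:05d}" for i in range(n_cells)], dtype=object)
    table = MarkerTable(markers, cell_ids, np.asarray(truth.marker_names, dtype=object))
    stack = None
    if with_images:
        pixels = np.stack([
            _render_image(m1, m2, truth, rng) for m1, m2 in markers
        ])
        stack = ImageStack(pixels, cell_ids)
    return table, stack, PopulationLabels(labels, cell_ids)
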