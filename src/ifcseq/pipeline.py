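"""End-to-end orchestration of the two published modes.

``run_standard`` consumes measured IFC marker intensities; ``run_labelfree``
first regresses the markers from brightfield images with the CNN (or an
injected oracle, for testing the invariant that the modes differ only in
marker provenance) and then proceeds identically:

preprocess SCT -> normalize markers (per modality) -> gate -> rank marker
genes -> 70/30 split -> fit forest (+ linear baseline) -> evaluate on the
SCT test split -> predict the IFC cells -> population profiles and
transcriptional similarity.

Every run writes a reproducibility manifest (seed, config hash, package
versions). The single global seed fans out deterministically to per-stage
seeds via a stable hash of the stage name.
"""

from __future__ import annotations

import hashlib
import json
import os
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from . import __version__
from . import coregistration as coreg
from . import evaluation as ev
from . import expression_model as em
from . import sct_preprocess as pp
from .io_formats import (CountMatrix, ExpressionMatrix, ImageStack, MarkerTable,
                         write_predictions)
from .labelfree_cnn import CNNConfig, predict_markers, train_marker_cnn
from .sct_preprocess import PreprocessConfig

__all__ = ["RunConfig", "PipelineInputs", "PipelineResult",
           "run_standard", "run_labelfree", "stage_seed", "load_run_config"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    mode: str = "standard"
    seed: int = 0
    output_dir: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: em.ModelConfig = field(default_factory=em.ModelConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    gates: coreg.GateSet | None = None
    extra_targets: list = field(default_factory=list)  # marker columns appended to targets
    log_extra_targets: bool = True   # same ln(1+x) treatment as genes
    fit_linear_baseline: bool = True
    stratify_split: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("standard", "labelfree"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.gates is None:
            raise ValueError("a GateSet is required (gates are config data)")

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, coreg.GateSet):
                return {name: {"marker_x": g.marker_x, "marker_y": g.marker_y,
                               "x": list(g.x), "y": list(g.y)}
                        for name, g in o.gates.items()} | {"precedence": o.precedence}
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)
        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineInputs:
    sct_counts: CountMatrix
    sct_markers: MarkerTable
    ifc_markers: MarkerTable | None = None
    ifc_images: ImageStack | None = None


@dataclass
class PipelineResult:
    sct_expression: ExpressionMatrix
    marker_ranking: pp.MarkerGeneRanking
    sct_labels: coreg.PopulationLabels
    ifc_labels: coreg.PopulationLabels
    model: em.ExpressionModel
    sct_test_report: ev.MetricReport
    linear_test_report: ev.MetricReport | None
    per_tree_std: dict
    ifc_predictions: ExpressionMatrix
    sct_profiles: object       # population x gene DataFrame (true SCT expression)
    ifc_profiles: object       # population x gene DataFrame (predicted IFC expression)
    sct_similarity: ev.SimilarityMatrix
    ifc_similarity: ev.SimilarityMatrix
    ifc_marker_table: MarkerTable
    cnn_log: list | None = None
    manifest: dict = field(default_factory=dict)


def _align_markers_to_cells(markers: MarkerTable, cell_ids: np.ndarray) -> MarkerTable:
    pos = {c: i for i, c in enumerate(markers.cell_ids.tolist())}
    missing = [c for c in cell_ids.tolist() if c not in pos]
    if missing:
        raise ValueError(f"marker table missing cells, e.g. {missing[:3]}")
    idx = np.array([pos[c] for c in cell_ids.tolist()])
    return markers.select_cells(idx)


def _build_targets(expr: ExpressionMatrix, sct_markers: MarkerTable,
                   cfg: RunConfig) -> ExpressionMatrix:
    """Optionally append surface channels (e.g. CD4) to the target matrix."""
    if not cfg.extra_targets:
        return expr
    cols, names = [], []
    for t in cfg.extra_targets:
        v = sct_markers.column(t)
        if cfg.log_extra_targets:
            v = np.log1p(v)
        cols.append(v[:, None])
        names.append(f"surface_{t}")
    values = np.hstack([expr.values] + cols)
    targets = np.concatenate([expr.target_names,
                              np.asarray(names, dtype=object)])
    return ExpressionMatrix(values, expr.cell_ids, targets)


def _write_artifacts(result: PipelineResult, cfg: RunConfig) -> None:
    out = cfg.output_dir
    os.makedirs(out, exist_ok=True)
    write_predictions(result.ifc_predictions, os.path.join(out, "ifc_predictions.csv"))
    result.sct_test_report.to_json(os.path.join(out, "sct_test_metrics.json"))
    result.sct_profiles.to_csv(os.path.join(out, "sct_profiles.csv"))
    result.ifc_profiles.to_csv(os.path.join(out, "ifc_profiles.csv"))
    result.sct_similarity.to_frame().to_csv(os.path.join(out, "sct_similarity.csv"))
    result.ifc_similarity.to_frame().to_csv(os.path.join(out, "ifc_similarity.csv"))
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2)


def _run_core(inputs: PipelineInputs, cfg: RunConfig,
              ifc_marker_table: MarkerTable, cnn_log=None) -> PipelineResult:
    # SCT side: filters -> log expression
    expr = pp.preprocess(inputs.sct_counts, cfg.preprocess)
    sct_markers = _align_markers_to_cells(inputs.sct_markers, expr.cell_ids)
    sct_norm = coreg.normalize_markers(sct_markers)
    sct_labels = coreg.apply_gates(sct_norm, cfg.gates)
    ranking = pp.rank_marker_genes(expr, sct_labels, cfg.preprocess.n_top_markers,
                                   method=cfg.preprocess.de_method)
    marker_genes = [g for g in ranking.all_top_genes()
                    if g in set(expr.target_names.tolist())]

    targets = _build_targets(expr, sct_markers, cfg)
    (mk_tr, tg_tr), (mk_te, tg_te) = em.split_train_test(
        targets, sct_norm, cfg.model.train_fraction,
        seed=stage_seed(cfg.seed, "split"),
        stratify_labels=sct_labels.labels if cfg.stratify_split else None,
    )
    model_cfg = em.ModelConfig(**{**asdict(cfg.model),
                                  "seed": stage_seed(cfg.seed, "forest")})
    model = em.fit(mk_tr, tg_tr, model_cfg)
    test_pred = em.predict(model, mk_te)
    report = ev.per_cell_metrics(tg_te, test_pred.mean, gene_subset=marker_genes)
    per_tree_std = ev.per_tree_uncertainty(test_pred.per_tree, tg_te,
                                           gene_subset=marker_genes) \
        if test_pred.per_tree is not None else {}

    linear_report = None
    if cfg.fit_linear_baseline:
        lin_cfg = em.ModelConfig(**{**asdict(cfg.model), "kind": "linear"})
        linear = em.fit(mk_tr, tg_tr, lin_cfg)
        lin_pred = em.predict(linear, mk_te)
        linear_report = ev.per_cell_metrics(tg_te, lin_pred.mean,
                                            gene_subset=marker_genes,
                                            compute_per_gene=False)

    # IFC side
    ifc_pred = em.predict(model, ifc_marker_table, per_tree=False)
    ifc_labels = coreg.apply_gates(ifc_marker_table, cfg.gates)
    sct_profiles = ev.population_profiles(expr, sct_labels, marker_genes)
    ifc_profiles = ev.population_profiles(ifc_pred.mean, ifc_labels, marker_genes)
    sct_sim = ev.population_similarity(sct_profiles)
    ifc_sim = ev.population_similarity(ifc_profiles)

    import sklearn
    manifest = {
        "mode": cfg.mode,
        "seed": int(cfg.seed),
        "config_hash": cfg.config_hash(),
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in ("split", "forest", "cnn")},
        "versions": {"ifcseq": __version__, "numpy": np.__version__,
                     "sklearn": sklearn.__version__},
        "n_sct_cells": int(expr.n_cells),
        "n_genes": int(len(expr.target_names)),
        "n_marker_genes": len(marker_genes),
        "marker_norm_bounds": {"sct": sct_norm.norm_bounds,
                               "ifc": ifc_marker_table.norm_bounds},
    }
    result = PipelineResult(
        sct_expression=expr, marker_ranking=ranking, sct_labels=sct_labels,
        ifc_labels=ifc_labels, model=model, sct_test_report=report,
        linear_test_report=linear_report, per_tree_std=per_tree_std,
        ifc_predictions=ifc_pred.mean, sct_profiles=sct_profiles,
        ifc_profiles=ifc_profiles, sct_similarity=sct_sim, ifc_similarity=ifc_sim,
        ifc_marker_table=ifc_marker_table, cnn_log=cnn_log, manifest=manifest,
    )
    if cfg.output_dir:
        _write_artifacts(result, cfg)
    return result


def run_standard(inputs: PipelineInputs, cfg: RunConfig) -> PipelineResult:
    """Standard mode: measured IFC marker intensities drive the prediction."""
    if inputs.ifc_markers is None:
        raise ValueError("standard mode requires an IFC marker table")
    ifc_norm = inputs.ifc_markers if inputs.ifc_markers.normalized \
        else coreg.normalize_markers(inputs.ifc_markers)
    return _run_core(inputs, cfg, ifc_norm)


def run_labelfree(inputs: PipelineInputs, cfg: RunConfig,
                  marker_oracle: MarkerTable | None = None) -> PipelineResult:
    """Label-free mode: markers come from the brightfield CNN.

    ``marker_oracle`` injects a precomputed marker table in place of the CNN
    prediction (used to verify that the two modes differ only in marker
    provenance).
    """
    cnn_log = None
    if marker_oracle is not None:
        predicted = marker_oracle if marker_oracle.normalized \
            else coreg.normalize_markers(marker_oracle)
    else:
        if inputs.ifc_images is None:
            raise ValueError("label-free mode requires brightfield images")
        if inputs.ifc_markers is None:
            raise ValueError("label-free mode trains the CNN on measured markers")
        measured = inputs.ifc_markers if inputs.ifc_markers.normalized \
            else coreg.normalize_markers(inputs.ifc_markers)
        cnn_cfg = CNNConfig(**{**asdict(cfg.cnn), "seed": stage_seed(cfg.seed, "cnn")})
        model, cnn_log = train_marker_cnn(inputs.ifc_images, measured, cnn_cfg)
        predicted = predict_markers(model, inputs.ifc_images)
    return _run_core(inputs, cfg, predicted, cnn_log=cnn_log)


def load_run_config(path) -> tuple:
    """Parse the YAML run config; returns ``(RunConfig, input_paths)``."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    gates = coreg.GateSet.from_dict(raw["gates"])
    cfg = RunConfig(
        mode=raw.get("mode", "standard"),
        seed=int(raw.get("seed", 0)),
        output_dir=raw.get("output_dir"),
        preprocess=PreprocessConfig(**raw.get("preprocess", {})),
        model=em.ModelConfig(**raw.get("model", {})),
        cnn=CNNConfig(**raw.get("cnn", {})),
        gates=gates,
        extra_targets=list(raw.get("extra_targets", [])),
        log_extra_targets=bool(raw.get("log_extra_targets", True)),
        stratify_split=bool(raw.get("stratify_split", False)),
    )
    paths = raw.get("inputs", {})
    required = ["sct_counts", "sct_markers"]
    if cfg.mode == "labelfree":
        required.append("ifc_images_dir")
    for key in required:
        if key not in paths:
            raise ValueError(f"run config missing inputs.{key}")
        if not os.path.exists(str(paths[key])):
            raise FileNotFoundError(f"inputs.{key}: {paths[key]} does not exist")
    return cfg, paths
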