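"""Marker-to-expression regression: random forest and linear baseline.

A single multi-output model maps the (normalized) shared surface markers of
a cell to its full expression profile. The forest follows the published
configuration — 50 trees, mean-absolute-error split criterion, sqrt
max-features — with no hyperparameter tuning and hence no validation split;
the SCT experiment is split 70/30 into train and test. An ordinary
least-squares model serves as the linear baseline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression

from .io_formats import ExpressionMatrix, MarkerTable

__all__ = ["ModelConfig", "ExpressionModel", "PredictionResult",
           "split_train_test", "fit", "predict", "save_model", "load_model"]


@dataclass
class ModelConfig:
    n_trees: int = 50
    split_criterion: str = "absolute_error"
    max_features: str = "sqrt"
    train_fraction: float = 0.7
    seed: int = 0
    kind: str = "forest"  # or "linear"
    stratify: bool = False

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.kind not in ("forest", "linear"):
            raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass
class ExpressionModel:
    kind: str
    marker_names: np.ndarray
    target_names: np.ndarray
    estimator: object
    config: ModelConfig

    @property
    def n_trees(self) -> int:
        if self.kind != "forest":
            raise AttributeError("linear model has no trees")
        return len(self.estimator.estimators_)


@dataclass
class PredictionResult:
    mean: ExpressionMatrix
    per_tree: np.ndarray | None = None  # (n_trees, n_cells, n_targets)


def split_train_test(expr: ExpressionMatrix, markers: MarkerTable,
                     train_fraction: float = 0.7, seed: int = 0,
                     stratify_labels=None):
    """Split cells into disjoint train/test sets; train size = round(f * n).

    Returns ``((markers_train, expr_train), (markers_test, expr_test))``.
    Deterministic for a fixed seed. Optional stratification keeps the
    per-population proportions of ``stratify_labels`` approximately equal in
    both halves.
    """
    if not np.array_equal(expr.cell_ids, markers.cell_ids):
        raise ValueError("expression and marker tables must be aligned on cell ids")
    n = expr.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells to split")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    if stratify_labels is not None:
        lab = np.asarray(stratify_labels, dtype=object)
        train_idx = []
        for pop in sorted(set(lab.tolist())):
            idx = np.flatnonzero(lab == pop)
            rng.shuffle(idx)
            k = int(round(train_fraction * len(idx)))
            train_idx.extend(idx[:k].tolist())
        train_mask = np.zeros(n, dtype=bool)
        train_mask[train_idx] = True
    else:
        perm = rng.permutation(n)
        train_mask = np.zeros(n, dtype=bool)
        train_mask[perm[:n_train]] = True
    train = (markers.select_cells(train_mask),
             ExpressionMatrix(expr.values[train_mask], expr.cell_ids[train_mask],
                              expr.target_names))
    test = (markers.select_cells(~train_mask),
            ExpressionMatrix(expr.values[~train_mask], expr.cell_ids[~train_mask],
                             expr.target_names))
    return train, test


def fit(markers_train: MarkerTable, targets_train: ExpressionMatrix,
        config: ModelConfig | None = None) -> ExpressionModel:
    """Fit a multi-output regressor from markers to all targets jointly."""
    cfg = config or ModelConfig()
    if not np.array_equal(markers_train.cell_ids, targets_train.cell_ids):
        raise ValueError("training markers and targets must be aligned on cell ids")
    X = markers_train.values
    Y = targets_train.values
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training cells")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("NaNs in training data")
    if np.any(X.max(axis=0) - X.min(axis=0) <= 0):
        bad = markers_train.marker_names[X.max(axis=0) - X.min(axis=0) <= 0][0]
        raise ValueError(f"input marker {bad!r} is constant in the training set")
    if cfg.kind == "forest":
        est = RandomForestRegressor(
            n_estimators=cfg.n_trees,
            criterion=cfg.split_criterion,
            max_features=cfg.max_features,
            random_state=cfg.seed,
            n_jobs=1,
        )
    else:
        est = LinearRegression()
    # sklearn handles single-target y as 1-D; keep 2-D for a uniform surface
    est.fit(X, Y)
    return ExpressionModel(cfg.kind, markers_train.marker_names.copy(),
                           targets_train.target_names.copy(), est, cfg)


def predict(model: ExpressionModel, markers: MarkerTable,
            per_tree: bool = True) -> PredictionResult:
    """Predict expression for each cell; forests also expose per-tree outputs.

    Marker values are expected in [0,1]; values outside that range (possible
    after independent per-modality normalization) trigger a warning but are
    passed through unmodified.
    """
    if list(markers.marker_names) != list(model.marker_names):
        raise ValueError(
            f"marker names {markers.marker_names.tolist()} do not match "
            f"training markers {model.marker_names.tolist()}"
        )
    X = markers.values
    if X.size and (X.min() < 0.0 or X.max() > 1.0):
        warnings.warn("marker values outside [0,1]; predicting on them unmodified",
                      stacklevel=2)
    mean = np.asarray(model.estimator.predict(X), dtype=float)
    if mean.ndim == 1:
        mean = mean[:, None]
    result = PredictionResult(
        ExpressionMatrix(mean, markers.cell_ids, model.target_names.copy())
    )
    if per_tree and model.kind == "forest":
        stacks = []
        for tree in model.estimator.estimators_:
            p = np.asarray(tree.predict(X), dtype=float)
            stacks.append(p[:, None] if p.ndim == 1 else p)
        result.per_tree = np.stack(stacks)
    return result


def save_model(model: ExpressionModel, path) -> None:
    """Persist the fitted estimator plus a JSON manifest next to it."""
    joblib.dump(model.estimator, path)
    manifest = {
        "kind": model.kind,
        "marker_names": model.marker_names.tolist(),
        "target_names": model.target_names.tolist(),
        "config": asdict(model.config),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_model(path) -> ExpressionModel:
    with open(str(path) + ".json") as fh:
        manifest = json.load(fh)
    est = joblib.load(path)
    return ExpressionModel(
        manifest["kind"],
        np.asarray(manifest["marker_names"], dtype=object),
        np.asarray(manifest["target_names"], dtype=object),
        est,
        ModelConfig(**manifest["config"]),
    )
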