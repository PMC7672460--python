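"""Label-free surface-marker regression from 32x32 brightfield images.

In label-free mode the shared surface markers are not measured but
predicted from each cell's morphology with a residual convolutional
network, after which expression prediction proceeds exactly as in standard
mode. The network maps a 32x32 single-channel brightfield image to the
normalized marker values in [0,1].

Architecture: a convolutional input stem followed by four stages of two
residual blocks each (two 3x3 convolutions per block), for 17 convolutional
layers in total and roughly 0.69 million parameters. Every convolution uses
zero padding, so spatial dimensions shrink only through the 2x2 max-pooling
steps between stages; every activation except the final one is preceded by
batch normalization, and the output head is a sigmoid so predictions are
bounded in [0,1]. Channel widths per stage are (16, 32, 64, 128).

Training uses Adam with mean-squared-error loss, a held-out validation
split, best-validation-weight selection and early stopping, and on-the-fly
flip augmentation (vertical, horizontal, or both axes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .io_formats import ImageStack, MarkerTable, IMAGE_SHAPE

__all__ = ["CNNConfig", "MarkerCNN", "build_marker_cnn", "augment_flips",
           "train_marker_cnn", "predict_markers", "FLIP_MODES", "flip_images"]

FLIP_MODES = ("identity", "vflip", "hflip", "vhflip")
STAGE_CHANNELS = (16, 32, 64, 128)
BLOCKS_PER_STAGE = 2


@dataclass
class CNNConfig:
    epochs: int = 50
    batch_size: int = 64
    validation_fraction: float = 0.1
    early_stop_patience: int = 5
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    seed: int = 0
    augment: bool = True
    loss: str = "mse"

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss != "mse":
            raise ValueError("only mse loss is supported")


class MarkerCNN:
    """Residual CNN regressing ``n_markers`` values in [0,1] from one image."""

    def __init__(self, n_markers: int = 2, marker_names=None, seed: int = 0):
        if n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        rng = np.random.default_rng(seed)
        self.n_markers = n_markers
        self.marker_names = list(marker_names) if marker_names is not None else [
            f"marker{i + 1}" for i in range(n_markers)
        ]
        self.stem_conv = _nn.Conv3x3(1, STAGE_CHANNELS[0], rng)
        self.stem_bn = _nn.BatchNorm2d(STAGE_CHANNELS[0])
        self.stem_relu = _nn.ReLU()
        self.stages = []  # list of (pool or None, [blocks])
        cin = STAGE_CHANNELS[0]
        for si, cout in enumerate(STAGE_CHANNELS):
            pool = _nn.MaxPool2() if si > 0 else None
            blocks = []
            for bi in range(BLOCKS_PER_STAGE):
                blocks.append(_nn.ResidualBlock(cin if bi == 0 else cout, cout, rng))
            self.stages.append((pool, blocks))
            cin = cout
        self.gap = _nn.GlobalAvgPool()
        self.head = _nn.Dense(STAGE_CHANNELS[-1], n_markers, rng)
        self.out_act = _nn.Sigmoid()

    # -- introspection -----------------------------------------------------
    @property
    def conv_layers(self) -> list:
        convs = [self.stem_conv]
        for _, blocks in self.stages:
            for b in blocks:
                convs.extend(b.conv_layers)
        return convs

    @property
    def n_conv_layers(self) -> int:
        return len(self.conv_layers)

    def params(self) -> list:
        out = self.stem_conv.params() + self.stem_bn.params()
        for _, blocks in self.stages:
            for b in blocks:
                out.extend(b.params())
        out.extend(self.head.params())
        return out

    @property
    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def get_weights(self) -> list:
        """Copies of all trainable parameters plus BN running statistics."""
        state = [p.value.copy() for p in self.params()]
        for bn in self._batchnorms():
            state.append(bn.running_mean.copy())
            state.append(bn.running_var.copy())
        return state

    def set_weights(self, state: list) -> None:
        params = self.params()
        for p, v in zip(params, state[:len(params)]):
            p.value[...] = v
        rest = state[len(params):]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = rest[2 * i]
            bn.running_var[...] = rest[2 * i + 1]

    def _batchnorms(self) -> list:
        bns = [self.stem_bn]
        for _, blocks in self.stages:
            for b in blocks:
                bns.extend([b.bn1, b.bn2])
        return bns

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (n, 1, 32, 32) float32 in [0,1] -> (n, n_markers) in [0,1]."""
        h = self.stem_conv.forward(x, train)
        h = self.stem_bn.forward(h, train)
        h = self.stem_relu.forward(h, train)
        for pool, blocks in self.stages:
            if pool is not None:
                h = pool.forward(h, train)
            for b in blocks:
                h = b.forward(h, train)
        h = self.gap.forward(h, train)
        h = self.head.forward(h, train)
        return self.out_act.forward(h, train)

    def backward(self, gloss: np.ndarray) -> None:
        g = self.out_act.backward(gloss)
        g = self.head.backward(g)
        g = self.gap.backward(g)
        for pool, blocks in reversed(self.stages):
            for b in reversed(blocks):
                g = b.backward(g)
            if pool is not None:
                g = pool.backward(g)
        g = self.stem_relu.backward(g)
        g = self.stem_bn.backward(g)
        self.stem_conv.backward(g)

    def predict(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference on a (n, 1, 32, 32) float array, batched, eval mode."""
        outs = []
        for i in range(0, images.shape[0], batch_size):
            outs.append(self.forward(images[i:i + batch_size].astype(_nn.F32), train=False))
        return np.concatenate(outs) if outs else np.zeros((0, self.n_markers))


def build_marker_cnn(image_shape=(32, 32, 1), n_markers: int = 2,
                     marker_names=None, seed: int = 0) -> MarkerCNN:
    """Build the residual marker-regression network for 32x32x1 input."""
    shape = tuple(image_shape)
    if shape not in ((32, 32), (32, 32, 1)):
        raise ValueError(f"unsupported input shape {shape}; expected 32x32x1")
    return MarkerCNN(n_markers=n_markers, marker_names=marker_names, seed=seed)


def _images_to_float(stack) -> np.ndarray:
    """Pixel preprocessing: scale 16-bit intensities into [0,1]."""
    pixels = stack.pixels if isinstance(stack, ImageStack) else np.asarray(stack)
    if pixels.ndim != 3 or pixels.shape[1:] != IMAGE_SHAPE:
        raise ValueError(f"expected images of shape n x {IMAGE_SHAPE}, got {pixels.shape}")
    return (pixels.astype(_nn.F32) / _nn.F32(65535.0))[:, None, :, :]


def flip_images(pixels: np.ndarray, mode: str) -> np.ndarray:
    """Apply one named flip to a (n, h, w) or (n, c, h, w) batch."""
    if mode == "identity":
        return pixels
    if mode == "vflip":      # flip along the vertical axis (rows reversed)
        return pixels[..., ::-1, :]
    if mode == "hflip":      # flip along the horizontal axis (columns reversed)
        return pixels[..., :, ::-1]
    if mode == "vhflip":
        return pixels[..., ::-1, ::-1]
    raise ValueError(f"unknown flip mode {mode!r}")


def augment_flips(batch: ImageStack, rng) -> ImageStack:
    """Randomly flip each image along the vertical, horizontal, or both axes.

    Each image is independently mapped to one of the four orientations
    (including identity). Marker targets are orientation-free and unchanged.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    choice = rng.integers(0, 4, size=batch.n_images)
    out = batch.pixels.copy()
    for k, mode in enumerate(FLIP_MODES):
        sel = choice == k
        if sel.any():
            out[sel] = flip_images(batch.pixels[sel], mode)
    return ImageStack(out, batch.cell_ids)


def _augment_float_batch(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    choice = rng.integers(0, 4, size=x.shape[0])
    out = x.copy()
    for k, mode in enumerate(FLIP_MODES):
        sel = choice == k
        if sel.any():
            out[sel] = flip_images(x[sel], mode)
    return out


def train_marker_cnn(images, markers: MarkerTable, config: CNNConfig | None = None,
                     model: MarkerCNN | None = None):
    """Train the marker CNN; returns ``(model, log)``.

    A ``validation_fraction`` of the data is held out; after each epoch the
    validation loss is evaluated, the best-validation weights are retained,
    and training stops early once the loss has not improved for
    ``early_stop_patience`` consecutive epochs. The log is a list of
    per-epoch dicts with train/validation loss.
    """
    cfg = config or CNNConfig()
    if not markers.normalized:
        raise ValueError("markers must be normalized to [0,1] before CNN training")
    x = _images_to_float(images)
    y = np.asarray(markers.values, dtype=_nn.F32)
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"{x.shape[0]} images but {y.shape[0]} marker rows")
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = build_marker_cnn(n_markers=y.shape[1],
                                 marker_names=markers.marker_names.tolist(),
                                 seed=int(rng.integers(2 ** 31)))
    n = x.shape[0]
    n_val = max(1, int(round(cfg.validation_fraction * n)))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    x_tr, y_tr = x[train_idx], y[train_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    batch_size = cfg.batch_size
    if len(train_idx) < batch_size:
        warnings.warn(
            f"only {len(train_idx)} training images; reducing batch size from "
            f"{batch_size}", stacklevel=2)
        batch_size = max(1, len(train_idx))

    opt = _nn.Adam(model.params(), lr=cfg.learning_rate)
    best_val = np.inf
    best_state = model.get_weights()
    patience_left = cfg.early_stop_patience
    log = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_idx))
        losses = []
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            xb = x_tr[idx]
            if cfg.augment:
                xb = _augment_float_batch(xb, rng)
            pred = model.forward(xb, train=True)
            loss, grad = _nn.mse_loss(pred, y_tr[idx])
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        val_pred = model.predict(x_val)
        val_loss = float(np.mean((val_pred - y_val) ** 2))
        log.append({"epoch": epoch + 1,
                    "train_loss": float(np.mean(losses)),
                    "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.get_weights()
            patience_left = cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    model.set_weights(best_state)
    return model, log


def predict_markers(model: MarkerCNN, images) -> MarkerTable:
    """Predict normalized marker values for each image, one row per cell."""
    x = _images_to_float(images)
    pred = model.predict(x)
    cell_ids = (images.cell_ids if isinstance(images, ImageStack)
                else np.array([f"cell{i}" for i in range(x.shape[0])], dtype=object))
    return MarkerTable(pred.astype(float), cell_ids,
                       np.asarray(model.marker_names, dtype=object), normalized=True)
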