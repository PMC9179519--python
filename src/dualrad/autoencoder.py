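"""Dual-purpose convolutional autoencoder for ultrasound lesion analysis.

A single network performs two tasks at once: it segments the breast lesion
(the decoder emits a per-pixel probability map trained against the ground
truth mask with a soft Dice objective) and it produces a low-dimensional
"deep radiomic" descriptor — the activation of its dense bottleneck, 16 wide
by default.  The encoder halves the spatial dimensions block by block; the
bottleneck flattens the final feature volume through a hierarchy of dense
layers down to the latent vector and mirrors back; the decoder upsamples to
the input resolution.  There are no skip connections, so everything the
decoder knows passes through the latent vector.

Implementation is pure NumPy (see :mod:`dualrad._nn`), sized so the ``desk``
preset trains in minutes on one CPU core.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _nn
from .phantom import UltrasoundSample


class AutoencoderError(ValueError):
    """Raised for invalid model configuration or inputs."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The first conv block keeps full resolution; each of the remaining
    ``n_blocks - 1`` blocks halves it, so the encoder output is
    ``input_size / 2**(n_blocks-1)`` square.  Channel widths double per block,
    capped at ``max_channels``.
    """

    input_size: int = 512
    n_blocks: int = 5
    base_filters: int = 32
    max_channels: int = 256
    dense_hidden: int = 256
    latent_dim: int = 16
    kernel_size: int = 3
    pool_size: int = 2
    use_skip_connections: bool = False

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise AutoencoderError("latent_dim must be >= 1")
        if self.use_skip_connections:
            raise AutoencoderError("skip connections are not part of this model")
        if self.input_size % (self.pool_size ** (self.n_blocks - 1)) != 0:
            raise AutoencoderError(
                f"input_size {self.input_size} not divisible by "
                f"pool_size^(n_blocks-1) = {self.pool_size ** (self.n_blocks - 1)}")

    @classmethod
    def paper(cls) -> "ModelConfig":
        """Full-scale preset: 512x512 input, 32 base filters, 16-d latent."""
        return cls()

    @classmethod
    def desk(cls) -> "ModelConfig":
        """CPU-sized preset: 64x64 input, 8 base filters, 16-d latent."""
        return cls(input_size=64, base_filters=8, dense_hidden=64)

    @property
    def channels(self) -> List[int]:
        return [min(self.base_filters * 2 ** i, self.max_channels)
                for i in range(self.n_blocks)]

    @property
    def bottleneck_size(self) -> int:
        return self.input_size // self.pool_size ** (self.n_blocks - 1)

    @property
    def flatten_features(self) -> int:
        return self.bottleneck_size ** 2 * self.channels[-1]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 150
    batch_size: int = 8
    lr_start: float = 2e-4
    lr_end: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise AutoencoderError("epochs must be >= 1")
        if not (0 < self.lr_end <= self.lr_start):
            raise AutoencoderError("need 0 < lr_end <= lr_start")

    def replace(self, **kw) -> "TrainConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class DualOutput:
    """Joint result of one forward pass: segmentation + deep radiomics."""

    prob_map: np.ndarray  # (H, W) in [0, 1]
    latent: np.ndarray    # (latent_dim,)


class DualAutoencoder:
    """Model handle: layer stack with a tap at the latent dense layer."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        k = cfg.kernel_size
        ch = cfg.channels
        layers: List[_nn.Layer] = []
        # encoder: stem block at full resolution, then halving blocks
        layers += [_nn.Conv2D(1, ch[0], k, rng), _nn.BatchNorm2D(ch[0]), _nn.ReLU()]
        for i in range(1, cfg.n_blocks):
            layers += [_nn.Conv2D(ch[i - 1], ch[i], k, rng),
                       _nn.BatchNorm2D(ch[i]), _nn.ReLU(), _nn.MaxPool2()]
        # dense bottleneck hierarchy down to the latent vector
        flat = cfg.flatten_features
        layers += [_nn.Flatten(),
                   _nn.Dense(flat, cfg.dense_hidden, rng), _nn.ReLU(),
                   _nn.Dense(cfg.dense_hidden, cfg.latent_dim, rng)]
        self._latent_index = len(layers)  # output of layers[:_latent_index] is latent
        s = cfg.bottleneck_size
        layers += [_nn.Dense(cfg.latent_dim, cfg.dense_hidden, rng), _nn.ReLU(),
                   _nn.Dense(cfg.dense_hidden, flat, rng), _nn.ReLU(),
                   _nn.Reshape((s, s, ch[-1]))]
        # decoder: mirrored upsampling blocks, then 1-channel sigmoid head
        for i in range(cfg.n_blocks - 1, 0, -1):
            layers += [_nn.Upsample2(), _nn.Conv2D(ch[i], ch[i - 1], k, rng),
                       _nn.BatchNorm2D(ch[i - 1]), _nn.ReLU()]
        layers += [_nn.Conv2D(ch[0], 1, k, rng), _nn.Sigmoid()]
        self.layers = layers

    @property
    def n_params(self) -> int:
        return sum(p.size for l in self.layers for p in l.params)

    def forward(self, x: np.ndarray, train: bool = False
                ) -> Tuple[np.ndarray, np.ndarray]:
        """x: (N, H, W, 1) -> (prob maps (N, H, W, 1), latents (N, latent_dim))."""
        h = x
        latent = None
        for i, layer in enumerate(self.layers):
            h = layer.forward(h, train)
            if i == self._latent_index - 1:
                latent = h
        return h, latent

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Run the encoder alone up to the latent layer."""
        h = x
        for layer in self.layers[:self._latent_index]:
            h = layer.forward(h, train=False)
        return h

    def backward(self, dout: np.ndarray) -> None:
        g = dout
        for layer in reversed(self.layers):
            g = layer.backward(g)


def model_summary(cfg: ModelConfig) -> dict:
    """Analytic layer geometry and parameter count (no allocation)."""
    ch = cfg.channels
    k2 = cfg.kernel_size ** 2
    n = k2 * 1 * ch[0] + ch[0] + 2 * ch[0]                      # stem conv + BN
    for i in range(1, cfg.n_blocks):
        n += k2 * ch[i - 1] * ch[i] + ch[i] + 2 * ch[i]
    flat = cfg.flatten_features
    n += flat * cfg.dense_hidden + cfg.dense_hidden
    n += cfg.dense_hidden * cfg.latent_dim + cfg.latent_dim
    n += cfg.latent_dim * cfg.dense_hidden + cfg.dense_hidden
    n += cfg.dense_hidden * flat + flat
    for i in range(cfg.n_blocks - 1, 0, -1):
        n += k2 * ch[i] * ch[i - 1] + ch[i - 1] + 2 * ch[i - 1]
    n += k2 * ch[0] * 1 + 1
    return {
        "channels": ch,
        "bottleneck_size": cfg.bottleneck_size,
        "flatten_features": flat,
        "latent_dim": cfg.latent_dim,
        "n_params": n,
    }


def build_model(cfg: ModelConfig, seed: int = 0) -> DualAutoencoder:
    """Instantiate the model with He-initialized weights."""
    return DualAutoencoder(cfg, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Dice similarity
# ---------------------------------------------------------------------------

def dice_coefficient(p: np.ndarray, g: np.ndarray, smooth: float = 0.0) -> float:
    """Soft Dice similarity with squared denominator terms:

        DSC = 2 * sum(p_i * g_i) / (sum(p_i^2) + sum(g_i^2))

    ``p`` is a probability raster/vector in [0, 1]; ``g`` is binary.  When both
    are identically zero the similarity is defined as 1.0 (perfect agreement
    on "no lesion").
    """
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise AutoencoderError(f"shape mismatch {p.shape} vs {g.shape}")
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise AutoencoderError("p must lie in [0, 1]")
    if not np.all((g == 0) | (g == 1)):
        raise AutoencoderError("g must be binary")
    num = 2.0 * float((p * g).sum()) + smooth
    den = float((p * p).sum() + (g * g).sum()) + smooth
    if den == 0.0:
        return 1.0
    return num / den


def dice_loss(p: np.ndarray, g: np.ndarray, smooth: float = 1.0) -> float:
    """Per-sample Dice loss 1 - DSC with a smoothing term for stability."""
    return 1.0 - dice_coefficient(p, g, smooth=smooth)


def _batch_dice_loss_grad(p: np.ndarray, g: np.ndarray, smooth: float = 1.0
                          ) -> Tuple[float, np.ndarray]:
    """Mean Dice loss over the batch and its gradient wrt p.

    p, g: (N, H, W, 1).  The loss is computed per sample then averaged.
    """
    n = p.shape[0]
    pf = p.reshape(n, -1).astype(np.float64)
    gf = g.reshape(n, -1).astype(np.float64)
    num = 2.0 * (pf * gf).sum(axis=1) + smooth
    den = (pf * pf).sum(axis=1) + (gf * gf).sum(axis=1) + smooth
    dice = num / den
    loss = float(np.mean(1.0 - dice))
    # d(1-dice)/dp = -(2 g den - 2 p num) / den^2, averaged over the batch
    grad = -(2.0 * gf * den[:, None] - 2.0 * pf * num[:, None]) / (den ** 2)[:, None]
    grad /= n
    return loss, grad.reshape(p.shape).astype(np.float32)


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------

def _stack(samples: Sequence[UltrasoundSample]) -> Tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.image for s in samples]).astype(np.float32)[..., None]
    g = np.stack([s.mask for s in samples]).astype(np.float32)[..., None]
    return x, g


def _soft_dice_eval(model: DualAutoencoder, x: np.ndarray, g: np.ndarray,
                    batch: int = 8) -> float:
    vals = []
    for i in range(0, x.shape[0], batch):
        y, _ = model.forward(x[i:i + batch], train=False)
        pf = y.reshape(y.shape[0], -1).astype(np.float64)
        gf = g[i:i + batch].reshape(y.shape[0], -1).astype(np.float64)
        num = 2.0 * (pf * gf).sum(axis=1) + 1.0
        den = (pf * pf).sum(axis=1) + (gf * gf).sum(axis=1) + 1.0
        vals.extend(num / den)
    return float(np.mean(vals))


def train(model: DualAutoencoder,
          train_samples: Sequence[UltrasoundSample],
          val_samples: Optional[Sequence[UltrasoundSample]] = None,
          tcfg: TrainConfig = TrainConfig(),
          include_normal: bool = False,
          ) -> Tuple[DualAutoencoder, pd.DataFrame]:
    """Minimize the batch-averaged Dice loss with Adam + cosine LR decay.

    Normal (lesion-free) images are excluded by default: an empty ground
    truth makes the Dice target degenerate.  Returns the model and a history
    table (epoch, train_dice, val_dice) of soft Dice values.
    """
    data = [s for s in train_samples if include_normal or s.label != "normal"]
    if not data:
        raise AutoencoderError("no (abnormal) training samples provided")
    x, g = _stack(data)
    size = model.cfg.input_size
    if x.shape[1] != size or x.shape[2] != size:
        raise AutoencoderError(
            f"training images are {x.shape[1]}x{x.shape[2]}, model wants {size}")
    xv = gv = None
    if val_samples:
        val = [s for s in val_samples if include_normal or s.label != "normal"]
        if val:
            xv, gv = _stack(val)

    rng = np.random.default_rng(tcfg.seed)
    n = x.shape[0]
    steps_per_epoch = int(np.ceil(n / tcfg.batch_size))
    opt = _nn.Adam(model.layers, tcfg.lr_start, tcfg.lr_end,
                   total_steps=tcfg.epochs * steps_per_epoch)
    history = []
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        losses = []
        for b in range(steps_per_epoch):
            idx = order[b * tcfg.batch_size:(b + 1) * tcfg.batch_size]
            y, _ = model.forward(x[idx], train=True)
            loss, dy = _batch_dice_loss_grad(y, g[idx])
            model.backward(dy)
            opt.step()
            losses.append(loss)
        row = {"epoch": epoch + 1, "train_dice": 1.0 - float(np.mean(losses))}
        row["val_dice"] = (_soft_dice_eval(model, xv, gv)
                           if xv is not None else np.nan)
        history.append(row)
    return model, pd.DataFrame(history)


def predict(model: DualAutoencoder, image: np.ndarray) -> DualOutput:
    """Segmentation probability map and latent descriptor from one forward pass."""
    image = np.asarray(image, dtype=np.float32)
    size = model.cfg.input_size
    if image.shape != (size, size):
        raise AutoencoderError(
            f"image shape {image.shape} does not match model input {size}x{size}")
    y, latent = model.forward(image[None, :, :, None], train=False)
    return DualOutput(prob_map=y[0, :, :, 0], latent=latent[0].astype(np.float64))


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard mask from the probability map."""
    return (np.asarray(prob_map) >= threshold).astype(np.uint8)


def evaluate_dice(model: DualAutoencoder, samples: Sequence[UltrasoundSample],
                  threshold: float = 0.5) -> float:
    """Mean Dice of binarized predictions against ground-truth masks."""
    vals = []
    for s in samples:
        out = predict(model, s.image)
        vals.append(dice_coefficient(binarize(out.prob_map, threshold), s.mask,
                                     smooth=1e-12))
    return float(np.mean(vals))


def latent_matrix(model: DualAutoencoder, samples: Sequence[UltrasoundSample],
                  batch: int = 16) -> np.ndarray:
    """Latent descriptors for a list of samples, cases x latent_dim."""
    x, _ = _stack(samples)
    outs = []
    for i in range(0, x.shape[0], batch):
        _, lat = model.forward(x[i:i + batch], train=False)
        outs.append(lat.astype(np.float64))
    return np.vstack(outs)


def filter_latent(latent: np.ndarray, k: int = 4
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Keep the k highest-variance latent columns, discarding the rest.

    Columns that are exactly zero across all cases are dropped first; of the
    remainder the k with the largest variance are kept (ties broken toward
    the lower column index).  Returns (selected indices ascending, reduced
    matrix).  Mirrors the post-training step where most latent units are
    constant or dead and only a handful carry the signal.
    """
    L = np.asarray(latent, dtype=np.float64)
    if L.ndim != 2 or L.shape[0] < 2:
        raise AutoencoderError("latent matrix must be 2-D with >= 2 rows")
    nonzero = np.where(~np.all(L == 0.0, axis=0))[0]
    if len(nonzero) < k:
        warnings.warn(
            f"only {len(nonzero)} nonzero latent columns; keeping all of them",
            stacklevel=2)
        sel = np.sort(nonzero)
        return sel, L[:, sel]
    var = L[:, nonzero].var(axis=0)
    order = sorted(range(len(nonzero)), key=lambda i: (-var[i], nonzero[i]))
    sel = np.sort(nonzero[order[:k]])
    return sel, L[:, sel]


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_model(model: DualAutoencoder, path: str) -> None:
    """Serialize config, weights, and batch-norm statistics to an .npz file."""
    arrays = {"config_json": np.frombuffer(
        json.dumps(dataclasses.asdict(model.cfg)).encode(), dtype=np.uint8)}
    for i, layer in enumerate(model.layers):
        for j, p in enumerate(layer.params):
            arrays[f"p_{i}_{j}"] = p
        if isinstance(layer, _nn.BatchNorm2D):
            arrays[f"rm_{i}"] = layer.running_mean
            arrays[f"rv_{i}"] = layer.running_var
    np.savez_compressed(path, **arrays)


def load_model(path: str) -> DualAutoencoder:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["config_json"]).decode()))
        model = build_model(cfg, seed=0)
        for i, layer in enumerate(model.layers):
            for j in range(len(layer.params)):
                layer.params[j][...] = data[f"p_{i}_{j}"]
            if isinstance(layer, _nn.BatchNorm2D):
                layer.running_mean[...] = data[f"rm_{i}"]
                layer.running_var[...] = data[f"rv_{i}"]
    return model
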