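"""Phase-1 probability-map providers.

The level set engine only requires a per-pixel kidney probability U_K in
[0, 1]; where that map comes from is pluggable:

* ``oracle_corrupted`` — the phantom truth with planted CNN-style errors
  (the standard provider for controlled experiments);
* ``intensity_bayes`` — posterior of a two-class Gaussian intensity model
  with equal class priors, a classical non-deep baseline;
* ``cnn`` — a trained encoder–decoder network (see :mod:`unls.nn`) whose
  sigmoid output is U_K.

Also here: the 12-fold augmentation recipe used to enlarge training pairs
(random translation; rotations of -90/-45/+45/+90/180 degrees; vertical and
horizontal flips; Gaussian noise at variances 0.01/0.02/0.05; one combined
translation+flip), and toy-scale CNN training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import ImageGrid, LabelMask, ProbabilityMap
from .io import normalize_intensity
from .phantom import CorruptionConfig, corrupt_probability_map
from . import nn

__all__ = ["ProviderConfig", "CnnConfig", "provide_probability_map",
           "augment_pair", "build_model", "train_provider", "ModelDescription",
           "TrainedCnnProvider"]

NOISE_VARIANCES = (0.01, 0.02, 0.05)
ROTATION_ANGLES = (-90, -45, 45, 90, 180)


@dataclass(frozen=True)
class CnnConfig:
    """Architecture and training hyper-parameters of the CNN provider.

    Defaults mirror the full-scale configuration (depth-4 encoder, 64 base
    filters, dropout 0.5, BCE loss, Adam with initial learning rate 1e-4
    decayed by 10% after 10 stale epochs, 200 epochs); toy-scale runs pass
    much smaller values.
    """

    architecture: str = "bcd_unt"    # {"unt", "bcd_unt"}
    depth: int = 4
    base_filters: int = 64
    dense_blocks: int = 3            # bcd_unt deepest-encoder dense stages
    dropout: float = 0.5
    loss: str = "bce"                # {"bce", "ds_bce"}
    initial_learning_rate: float = 1e-4
    lr_decay_factor: float = 0.9
    lr_patience: int = 10
    epochs: int = 200
    batch_size: int = 8
    rng_seed: int = 0

    def __post_init__(self):
        if self.architecture not in ("unt", "bcd_unt"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if self.initial_learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class ProviderConfig:
    """Selects exactly one probability-map provider and its parameters."""

    provider: str = "oracle_corrupted"
    corruption: CorruptionConfig = field(default_factory=CorruptionConfig)
    bayes_means: tuple[float, float] | None = None      # (kidney, background)
    bayes_variances: tuple[float, float] | None = None
    variance_floor: float = 1e-4
    model: "TrainedCnnProvider | None" = None

    def __post_init__(self):
        if self.provider not in ("oracle_corrupted", "intensity_bayes", "cnn"):
            raise ValueError(f"unknown provider {self.provider!r}")


def _gaussian_posterior(x: np.ndarray, means, variances) -> np.ndarray:
    mu_k, mu_b = means
    var_k, var_b = variances
    log_k = -0.5 * np.log(2 * np.pi * var_k) - (x - mu_k) ** 2 / (2 * var_k)
    log_b = -0.5 * np.log(2 * np.pi * var_b) - (x - mu_b) ** 2 / (2 * var_b)
    m = np.maximum(log_k, log_b)
    ek, eb = np.exp(log_k - m), np.exp(log_b - m)
    return ek / (ek + eb)


def provide_probability_map(image: ImageGrid, cfg: ProviderConfig,
                            truth: LabelMask | None = None) -> ProbabilityMap:
    """Produce U_K for ``image`` with the configured provider.

    ``oracle_corrupted`` requires ``truth``; ``intensity_bayes`` fits its
    class-conditional Gaussians from the truth regions when explicit
    means/variances are not supplied (variances floored at
    ``variance_floor``); ``cnn`` requires a trained model in the config.
    """
    if cfg.provider == "oracle_corrupted":
        if truth is None:
            raise ValueError("oracle provider requires a truth mask")
        return corrupt_probability_map(truth, cfg.corruption)

    if cfg.provider == "intensity_bayes":
        x = normalize_intensity(image).pixels
        if cfg.bayes_means is not None:
            means = cfg.bayes_means
            variances = cfg.bayes_variances or (1.0, 1.0)
            if min(variances) < 1e-12:
                raise ValueError("class variance below 1e-12")
        else:
            if truth is None:
                raise ValueError(
                    "intensity_bayes needs explicit class parameters or a "
                    "truth mask to fit them from")
            kid = truth.as_bool()
            means = (float(x[kid].mean()), float(x[~kid].mean()))
            variances = (max(float(x[kid].var()), cfg.variance_floor),
                         max(float(x[~kid].var()), cfg.variance_floor))
        return ProbabilityMap(_gaussian_posterior(x, means, variances),
                              image.spacing)

    if cfg.model is None:
        raise ValueError("cnn provider requires a trained model")
    return cfg.model.predict(image)


# -- augmentation -------------------------------------------------------------

def _translate(img, mask, dy, dx):
    im = ndimage.shift(img, (dy, dx), order=1, mode="constant", cval=0.0)
    mk = ndimage.shift(mask, (dy, dx), order=0, mode="constant", cval=0)
    return im, mk


def _rotate(img, mask, angle):
    if angle % 90 == 0:
        k = (angle // 90) % 4
        return np.rot90(img, k), np.rot90(mask, k)
    im = ndimage.rotate(img, angle, reshape=False, order=1,
                        mode="constant", cval=0.0)
    mk = ndimage.rotate(mask, angle, reshape=False, order=0,
                        mode="constant", cval=0)
    return im, mk


def augment_pair(image: ImageGrid, mask: LabelMask, seed: int = 0,
                 max_shift_frac: float = 0.1,
                 ) -> list[tuple[ImageGrid, LabelMask]]:
    """Produce exactly 12 augmented (image, mask) pairs.

    1 random translation + 5 rotations + 2 flips + 3 noise levels + 1
    combined random translation-and-flip. Geometric operations are applied
    identically to image and mask (mask by nearest neighbour); noise touches
    only the image (on its [0,1]-normalised intensities). Deterministic per
    seed.
    """
    rng = np.random.default_rng(seed)
    img, msk = image.pixels, mask.labels
    rows, cols = img.shape
    max_dy = max(1, int(rows * max_shift_frac))
    max_dx = max(1, int(cols * max_shift_frac))
    out: list[tuple[np.ndarray, np.ndarray]] = []

    dy, dx = rng.integers(-max_dy, max_dy + 1, size=2)
    out.append(_translate(img, msk, dy, dx))
    for angle in ROTATION_ANGLES:
        out.append(_rotate(img, msk, angle))
    out.append((img[::-1].copy(), msk[::-1].copy()))        # vertical flip
    out.append((img[:, ::-1].copy(), msk[:, ::-1].copy()))  # horizontal flip
    norm = normalize_intensity(image).pixels
    for var in NOISE_VARIANCES:
        noisy = norm + rng.normal(0.0, np.sqrt(var), size=norm.shape)
        out.append((noisy, msk.copy()))
    dy, dx = rng.integers(-max_dy, max_dy + 1, size=2)
    im, mk = _translate(img, msk, dy, dx)
    axis = int(rng.integers(0, 2))
    im = im[::-1].copy() if axis == 0 else im[:, ::-1].copy()
    mk = mk[::-1].copy() if axis == 0 else mk[:, ::-1].copy()
    out.append((im, mk))

    return [(ImageGrid(np.ascontiguousarray(i, dtype=np.float64), image.spacing),
             LabelMask(np.ascontiguousarray(m).astype(np.uint8), mask.spacing))
            for i, m in out]


# -- architecture description -------------------------------------------------

@dataclass
class ModelDescription:
    """Inspectable layer list of a configured architecture."""

    architecture: str
    input_size: tuple[int, int]
    layers: list = field(default_factory=list)

    @property
    def output_shape(self) -> tuple[int, int, int]:
        return self.layers[-1]["output_shape"]


def build_model(cfg: CnnConfig,
                input_size: tuple[int, int] = (256, 256)) -> ModelDescription:
    """Describe the configured encoder–decoder architecture layer by layer.

    Both architectures keep the output spatial size equal to the input and
    end in a 1x1 convolution + sigmoid, so the per-pixel output lies in
    (0, 1). ``bcd_unt`` replaces the deepest encoder block with
    ``dense_blocks`` densely connected convolution stages and fuses each
    skip connection with a bidirectional convolutional LSTM.
    """
    h, w = input_size
    if h % 2 ** cfg.depth or w % 2 ** cfg.depth:
        raise ValueError(
            f"input size {h}x{w} not divisible by 2^{cfg.depth}")
    desc = ModelDescription(cfg.architecture, input_size)
    layers = desc.layers

    def add(name, output_shape, **extra):
        layers.append({"name": name, "output_shape": output_shape, **extra})

    ch = cfg.base_filters
    sh, sw = h, w
    for d in range(cfg.depth):
        deepest = d == cfg.depth - 1
        if cfg.architecture == "bcd_unt" and deepest:
            for s in range(cfg.dense_blocks):
                add(f"enc{d}_dense_conv{s}", (sh, sw, ch),
                    kernel=(3, 3), dense=True)
        else:
            add(f"enc{d}_conv1", (sh, sw, ch), kernel=(3, 3))
            add(f"enc{d}_conv2", (sh, sw, ch), kernel=(3, 3))
            add(f"enc{d}_dropout", (sh, sw, ch), rate=cfg.dropout)
        add(f"enc{d}_maxpool", (sh // 2, sw // 2, ch), kernel=(2, 2))
        sh, sw, ch = sh // 2, sw // 2, ch * 2
    add("bottleneck_conv1", (sh, sw, ch), kernel=(3, 3))
    add("bottleneck_conv2", (sh, sw, ch), kernel=(3, 3))
    for d in reversed(range(cfg.depth)):
        sh, sw, ch = sh * 2, sw * 2, ch // 2
        add(f"dec{d}_upconv", (sh, sw, ch), kernel=(2, 2))
        if cfg.architecture == "bcd_unt":
            add(f"dec{d}_bconvlstm_fuse", (sh, sw, ch * 2))
        else:
            add(f"dec{d}_concat", (sh, sw, ch * 2))
        add(f"dec{d}_conv1", (sh, sw, ch), kernel=(3, 3))
        add(f"dec{d}_conv2", (sh, sw, ch), kernel=(3, 3))
    add("head_conv1x1_sigmoid", (h, w, 1), kernel=(1, 1), activation="sigmoid")
    return desc


# -- toy-scale training -------------------------------------------------------

@dataclass
class TrainedCnnProvider:
    """A trained network plus the normalisation convention it expects."""

    model: nn.TinyUNet
    config: CnnConfig

    def predict(self, image: ImageGrid) -> ProbabilityMap:
        x = normalize_intensity(image).pixels[None, None]
        p = self.model.predict(x)[0, 0]
        return ProbabilityMap(np.clip(p, 0.0, 1.0), image.spacing)


def _stack(pairs):
    xs = np.stack([normalize_intensity(img).pixels for img, _ in pairs])
    ys = np.stack([m.labels.astype(np.float64) for _, m in pairs])
    return xs[:, None], ys[:, None]


def train_provider(train_pairs: list, val_pairs: list, cfg: CnnConfig,
                   ) -> tuple[TrainedCnnProvider, nn.TrainingCurves]:
    """Train the CNN provider on (image, mask) pairs; returns the trained
    provider and per-epoch loss/accuracy curves (epoch 0 = untrained).

    The NumPy backend trains the ``unt`` architecture (dropout omitted at
    this scale); ``bcd_unt`` is available as a description only.
    """
    if not train_pairs or not val_pairs:
        raise ValueError("training and validation sets must be non-empty")
    if cfg.architecture != "unt":
        raise NotImplementedError(
            "the NumPy backend trains the 'unt' architecture only")
    x_tr, y_tr = _stack(train_pairs)
    x_va, y_va = _stack(val_pairs)
    model = nn.TinyUNet(depth=cfg.depth, base=cfg.base_filters,
                        seed=cfg.rng_seed)
    curves = nn.train(model, x_tr, y_tr, x_va, y_va, epochs=cfg.epochs,
                      batch_size=cfg.batch_size,
                      lr=cfg.initial_learning_rate,
                      lr_decay_factor=cfg.lr_decay_factor,
                      patience=cfg.lr_patience, seed=cfg.rng_seed + 1)
    return TrainedCnnProvider(model, cfg), curves
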