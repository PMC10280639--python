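"""The base 2D CNN family for recurrence prediction.

One architecture, parameterized by the convolutional kernel size, maps any
100 x 100 single-channel patch to a recurrence probability:

    [conv(k) -> maxpool(3) -> PReLU -> BN] x 2
    [conv(k) -> maxpool(2) -> PReLU]
    GAP -> FC(c3 -> h) -> FC(h -> 1) -> PReLU -> sigmoid

Convolutions are stride-1 with same-padding, so the feature-map ladder
100 -> 33 -> 11 -> 5 is identical for every kernel size in {2,...,6} and the
kernel variants ("multi-kernel networks") are drop-in interchangeable.  The
default widths (32, 64, 128) with an 8-unit hidden dense layer give 93,909
trainable parameters for the 3 x 3 reference model (~94K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

ALLOWED_KERNELS = (2, 3, 4, 5, 6)
DEFAULT_CHANNELS = (32, 64, 128)
DEFAULT_FC_HIDDEN = 8
POOL_SIZES = (3, 3, 2)
INPUT_SIZE = 100


@dataclass(frozen=True)
class ModelConfig:
    """Hyper-structure of one base CNN."""

    kernel: int = 3
    channels: tuple[int, int, int] = DEFAULT_CHANNELS
    fc_hidden: int = DEFAULT_FC_HIDDEN
    pool_sizes: tuple[int, int, int] = POOL_SIZES
    input_size: int = INPUT_SIZE

    def __post_init__(self) -> None:
        if self.kernel not in ALLOWED_KERNELS:
            raise ValueError(f"kernel must be one of {ALLOWED_KERNELS}, got {self.kernel}")
        if len(self.channels) != 3 or any(c <= 0 for c in self.channels):
            raise ValueError(f"channels must be three positive widths, got {self.channels}")
        if self.fc_hidden <= 0:
            raise ValueError("fc_hidden must be positive")
        if tuple(self.pool_sizes) != POOL_SIZES:
            raise ValueError(f"pool_sizes are fixed at {POOL_SIZES}")


@dataclass
class BaseCNN:
    """A built (possibly trained) base network."""

    net: nn.Sequential
    config: ModelConfig
    feature_layer: int  # index whose output feeds Grad-CAM (last conv block's PReLU)
    frozen: bool = False
    loss_history: list = field(default_factory=list)

    @property
    def trainable_parameter_count(self) -> int:
        return self.net.count_parameters()

    def freeze(self) -> None:
        """Mark the model inference-only; gradient-based introspection refuses it."""
        self.frozen = True


def build_cnn(config: ModelConfig, seed: int) -> BaseCNN:
    """Construct a base CNN with weights drawn deterministically from ``seed``."""
    rng = np.random.default_rng(seed)
    c1, c2, c3 = config.channels
    k = config.kernel
    p1, p2, p3 = config.pool_sizes
    layers: list[nn.Layer] = [
        nn.Conv2d(1, c1, k, rng, needs_input_grad=False),
        nn.MaxPool2d(p1),
        nn.PReLU(),
        nn.BatchNorm2d(c1),
        nn.Conv2d(c1, c2, k, rng),
        nn.MaxPool2d(p2),
        nn.PReLU(),
        nn.BatchNorm2d(c2),
        nn.Conv2d(c2, c3, k, rng),
        nn.MaxPool2d(p3),
        nn.PReLU(),
        nn.GlobalAvgPool(),
        nn.Linear(c3, config.fc_hidden, rng),
        nn.Linear(config.fc_hidden, 1, rng),
        nn.PReLU(),
    ]
    return BaseCNN(net=nn.Sequential(layers), config=config, feature_layer=10)


def count_parameters(model: BaseCNN) -> int:
    """Total number of trainable scalars (conv/FC weights and biases, BN affine
    pairs, PReLU slopes)."""
    return model.net.count_parameters()


def _as_batch(patch: np.ndarray, input_size: int) -> np.ndarray:
    patch = np.asarray(patch, dtype=np.float32)
    if patch.ndim == 2:
        patch = patch[None]
    if patch.ndim != 3 or patch.shape[-2:] != (input_size, input_size):
        raise ValueError(
            f"expected {input_size}x{input_size} patch(es), got shape {patch.shape}")
    return patch[:, :, :, None]


def predict(model: BaseCNN, patch: np.ndarray) -> np.ndarray | float:
    """Recurrence probability for one patch or a batch of patches.

    Inference mode: batch normalization uses its running statistics, so the
    output is a deterministic function of the weights and the input.
    """
    single = np.asarray(patch).ndim == 2
    x = _as_batch(patch, model.config.input_size) / np.float32(255.0)
    logits = model.net.forward(x, train=False).ravel()
    probs = nn.sigmoid(logits)
    return float(probs[0]) if single else probs


def train_cnn(model: BaseCNN, patches: np.ndarray, labels: np.ndarray,
              hp=None, seed: int = 0, epochs: int | None = None,
              augment: bool = True) -> BaseCNN:
    """Train in place with mini-batch SGD (momentum + step-decayed LR) on BCE.

    ``patches``: (n, 100, 100) in [0, 255]; intensities are scaled to [0, 1]
    internally. Random horizontal/vertical flips are applied on the fly when
    ``augment`` is set.
    """
    from .evaluate import Hyperparams, lr_schedule
    from .preprocess import augment_flip

    if hp is None:
        hp = Hyperparams()
    if model.frozen:
        raise RuntimeError("model is frozen; cannot train")
    n_epochs = hp.epochs_base if epochs is None else epochs
    x_all = _as_batch(patches, model.config.input_size) / np.float32(255.0)
    y_all = np.asarray(labels, dtype=np.float32).ravel()
    if x_all.shape[0] != y_all.size:
        raise ValueError("patches and labels disagree in length")
    rng = np.random.default_rng(seed)
    opt = nn.SGD(model.net.params(), momentum=hp.momentum)
    n = x_all.shape[0]
    for epoch in range(n_epochs):
        lr = lr_schedule(epoch, hp)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            xb = x_all[idx]
            if augment:
                xb = augment_flip(xb, rng)
            logits = model.net.forward(xb, train=True)
            loss, dlogits = nn.bce_with_logits(logits, y_all[idx])
            model.net.backward(dlogits)
            opt.step(lr)
            epoch_loss += loss * idx.size
        model.loss_history.append(epoch_loss / n)
    return model
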