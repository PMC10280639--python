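"""Grad-CAM saliency over the final convolutional block of a base CNN.

The recurrence logit's gradient is backpropagated to the last convolutional
block's activation (128 maps of 5 x 5 after the final pooling). Each channel
is weighted by the spatial mean of its gradient, the weighted sum is
rectified, bicubically upsampled to the 100 x 100 input frame, and
max-normalized to [0, 1]. Batch normalization runs in inference mode
throughout, so the map explains exactly the probability that
:func:`ctrecur.models.predict` reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from skimage.transform import resize as _sk_resize

from .models import BaseCNN, _as_batch
from .preprocess import PATCH_SIZE


@dataclass
class SaliencyMap:
    """Heatmap in [0, 1], co-registered with the 100 x 100 input patch."""

    heat: np.ndarray

    def __post_init__(self) -> None:
        self.heat = np.asarray(self.heat, dtype=np.float32)
        if self.heat.min() < 0 or self.heat.max() > 1:
            raise ValueError("saliency values must lie in [0, 1]")


def grad_cam(model: BaseCNN, patch: np.ndarray) -> SaliencyMap:
    """Gradient-weighted class activation map for one patch.

    Channel weights are the global average of the logit's gradient over the
    final conv block's feature maps; the rectified weighted sum is upsampled
    and normalized so the maximum is exactly 1 (an all-zero map stays zero).
    """
    if model.frozen:
        raise RuntimeError("model is frozen for inference; gradients are "
                           "unavailable for Grad-CAM")
    x = _as_batch(patch, model.config.input_size)
    if x.shape[0] != 1:
        raise ValueError("grad_cam explains one patch at a time")
    net = model.net
    fl = model.feature_layer
    feats = net.forward_upto(x / np.float32(255.0), stop=fl + 1, cache=True)
    net.forward_from(feats, start=fl + 1, cache=True)
    dlogit = np.ones((1, 1), dtype=np.float32)
    dfeats = net.backward(dlogit, stop_at=fl + 1)

    weights = dfeats.mean(axis=(1, 2))[0]          # (C,)
    cam = np.maximum((feats[0] * weights).sum(axis=-1), 0.0)
    heat = _sk_resize(cam.astype(np.float64), (PATCH_SIZE, PATCH_SIZE), order=3,
                      mode="edge", anti_aliasing=False, preserve_range=True,
                      clip=False)
    heat = np.maximum(heat, 0.0)
    peak = float(heat.max())
    if peak > 0:
        heat = heat / peak
    return SaliencyMap(heat=heat.astype(np.float32))


def overlay(patch: np.ndarray, saliency: SaliencyMap, path=None, alpha: float = 0.4,
            ax=None):
    """Render the heatmap over the grayscale patch with a red-to-blue colormap;
    optionally save to ``path`` (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(np.asarray(patch), cmap="gray", vmin=0, vmax=255)
    ax.imshow(saliency.heat, cmap="jet", vmin=0, vmax=1, alpha=alpha)
    ax.set_axis_off()
    if own_fig:
        if path is not None:
            fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)
    return ax
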