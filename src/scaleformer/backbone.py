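"""Frozen convolutional patch-feature extractor.

The pipeline trains only the transformer stages; patch embeddings come from
a *frozen* CNN and can therefore be precomputed once per dataset. The default
extractor here is a seeded random-weight convolutional network (three strided
conv/ReLU stages followed by global average pooling) in the spirit of
random-feature methods: random convolution banks respond differently to
different texture frequencies and contrasts, which is exactly the signal the
synthetic slides carry. Any callable mapping an RGB patch batch to fixed-width
vectors can be plugged in instead (e.g. a pretrained ImageNet CNN).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.util import img_as_float


def bilinear_resize_batch(patches: np.ndarray, size: int) -> np.ndarray:
    """Resize a (B, h, w, ch) float batch to (B, size, size, ch) bilinearly.

    All patches in a grid share one shape, so the interpolation weights are
    computed once and applied to the whole stack.
    """
    b, h, w, ch = patches.shape
    if (h, w) == (size, size):
        return patches
    ys = (np.arange(size) + 0.5) * h / size - 0.5
    xs = (np.arange(size) + 0.5) * w / size - 0.5
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 1)
    y1 = np.clip(y0 + 1, 0, h - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    wy = np.clip(ys - y0, 0.0, 1.0)[None, :, None, None]
    wx = np.clip(xs - x0, 0.0, 1.0)[None, None, :, None]
    p00 = patches[:, y0][:, :, x0]
    p01 = patches[:, y0][:, :, x1]
    p10 = patches[:, y1][:, :, x0]
    p11 = patches[:, y1][:, :, x1]
    top = p00 * (1 - wx) + p01 * wx
    bot = p10 * (1 - wx) + p11 * wx
    return top * (1 - wy) + bot * wy


def _conv2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray, stride: int) -> np.ndarray:
    """Valid-mode strided convolution. x: (B,H,W,Cin), weight: (k,k,Cin,Cout)."""
    k = weight.shape[0]
    windows = sliding_window_view(x, (k, k), axis=(1, 2))  # (B,H-k+1,W-k+1,Cin,k,k)
    windows = windows[:, ::stride, ::stride]
    b, oh, ow = windows.shape[:3]
    cols = windows.transpose(0, 1, 2, 4, 5, 3).reshape(b, oh, ow, -1)
    w2 = weight.reshape(-1, weight.shape[-1])
    return cols @ w2 + bias


class RandomConvBackbone:
    """Seeded frozen random CNN: three strided conv/ReLU stages + global pool.

    Parameters
    ----------
    feature_dim:
        Width of the pooled output embedding (channel count of stage 3).
    input_size:
        Side length every patch is bilinearly resized to before stage 1.
    seed:
        Seed for the (He-initialized) random filter bank; the extractor is a
        pure function of its seed.
    """

    def __init__(self, feature_dim: int = 192, input_size: int = 48, seed: int = 0):
        self.feature_dim = feature_dim
        self.input_size = input_size
        self.seed = seed
        rng = np.random.default_rng(seed)
        channels = [3, 24, 48, feature_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for cin, cout in zip(channels[:-1], channels[1:]):
            std = np.sqrt(2.0 / (9 * cin))
            self.weights.append(rng.normal(0.0, std, size=(3, 3, cin, cout)))
            self.biases.append(np.zeros(cout))

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        """Map a (B, h, w, 3) patch batch to (B, feature_dim) embeddings."""
        x = img_as_float(patches).astype(np.float64)
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[-1] == 1:
            x = np.repeat(x, 3, axis=-1)
        x = bilinear_resize_batch(x, self.input_size)
        x = x - 0.5  # center intensities
        for w, b in zip(self.weights, self.biases):
            x = np.maximum(_conv2d(x, w, b, stride=2), 0.0)
        return x.mean(axis=(1, 2))

    def parameter_checksum(self) -> float:
        """Sum of all frozen parameters; used to assert the frozen contract."""
        return float(sum(w.sum() for w in self.weights) + sum(b.sum() for b in self.biases))
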