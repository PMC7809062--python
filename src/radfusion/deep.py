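"""Deep-feature extraction: an 8-layer CNN and its Conv_5 feature bank.

The network follows the fixed architecture contract: a 32x32 grayscale
input, four 3x3 stride-1 zero-padded convolutions each followed by 2x2
max pooling (spatial trace 32 -> 16 -> 8 -> 4 -> 2), a fifth convolution
with a 2x2 kernel and no padding that collapses the map to 1x1 with 64
channels, and a head of two hidden dense layers ending in a 2-class
output.  Transfer-learning features are the 64 flattened Conv_5
activations; channels constant across a cohort (zero variance) are
dropped before modelling.

The network is implemented directly on numpy (forward and backward), so
training is deterministic for a fixed seed in single-threaded BLAS.
Per-layer channel widths 8/16/32/64 for Conv_1..Conv_4 are the package's
choice (monotone doubling); only the Conv_5 width (64) is fixed by the
feature-bank contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize

logger = logging.getLogger(__name__)

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "LungStyleCNN",
    "preprocess_roi",
    "select_largest_roi_slice",
    "extract_deep_features",
    "filter_zero_variance",
    "pretrain",
]

INPUT_SIZE = 32
N_DEEP_FEATURES = 64


@dataclass(frozen=True)
class ArchitectureSpec:
    input_size: int = INPUT_SIZE
    conv_channels: tuple[int, ...] = (8, 16, 32, 64)  # Conv_1..Conv_4, 3x3 pad 1 + 2x2 pool
    conv5_channels: int = 64                          # 2x2 kernel, no padding -> 1x1
    dense_units: tuple[int, ...] = (32, 16)
    n_classes: int = 2

    @property
    def n_features(self) -> int:
        """Flattened Conv_5 dimension: 1 x 1 x conv5_channels."""
        size = self.input_size
        for _ in self.conv_channels:
            size //= 2          # each conv keeps size (pad 1), pooling halves it
        # Conv_5: 2x2 valid kernel on the remaining (size x size) map
        final = size - 1
        if final != 1:
            raise ValueError(f"architecture trace broken: Conv_5 output {final}x{final}")
        return final * final * self.conv5_channels


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    learning_rate: float = 0.001
    epochs: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


# ------------------------------------------------------------------ layers

def _conv_forward(x, w, b, pad):
    n, _, h, wd = x.shape
    o, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho, wo = h + 2 * pad - kh + 1, wd + 2 * pad - kw + 1
    y = np.tile(b[None, :, None, None], (n, 1, ho, wo))
    for di in range(kh):
        for dj in range(kw):
            y += np.einsum("nchw,oc->nohw", xp[:, :, di:di + ho, dj:dj + wo], w[:, :, di, dj])
    return y, xp


def _conv_backward(dy, xp, w, pad, x_shape):
    o, _, kh, kw = w.shape
    _, _, ho, wo = dy.shape
    dw = np.zeros_like(w)
    db = dy.sum(axis=(0, 2, 3))
    dxp = np.zeros_like(xp)
    for di in range(kh):
        for dj in range(kw):
            xs = xp[:, :, di:di + ho, dj:dj + wo]
            dw[:, :, di, dj] = np.einsum("nohw,nchw->oc", dy, xs)
            dxp[:, :, di:di + ho, dj:dj + wo] += np.einsum("nohw,oc->nchw", dy, w[:, :, di, dj])
    if pad:
        return dw, db, dxp[:, :, pad:-pad, pad:-pad]
    return dw, db, dxp


def _pool_forward(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    y = xr.max(axis=(3, 5))
    mask = xr == y[:, :, :, None, :, None]
    return y, mask


def _pool_backward(dy, mask):
    n, c, ho, _, wo, _ = mask.shape
    dxr = mask * dy[:, :, :, None, :, None]
    return dxr.reshape(n, c, ho * 2, wo * 2)


class LungStyleCNN:
    """The 8-layer network: 5 conv layers + 2 hidden dense + 2-class output."""

    def __init__(self, spec: ArchitectureSpec = ArchitectureSpec(), seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 1
        for i, c_out in enumerate(spec.conv_channels, start=1):
            self.params[f"wc{i}"] = rng.normal(0, np.sqrt(2.0 / (c_in * 9)), (c_out, c_in, 3, 3))
            self.params[f"bc{i}"] = np.zeros(c_out)
            c_in = c_out
        self.params["wc5"] = rng.normal(0, np.sqrt(2.0 / (c_in * 4)), (spec.conv5_channels, c_in, 2, 2))
        self.params["bc5"] = np.zeros(spec.conv5_channels)
        d_in = spec.n_features
        for i, d_out in enumerate(spec.dense_units, start=1):
            self.params[f"wd{i}"] = rng.normal(0, np.sqrt(2.0 / d_in), (d_in, d_out))
            self.params[f"bd{i}"] = np.zeros(d_out)
            d_in = d_out
        self.params["wout"] = rng.normal(0, np.sqrt(2.0 / d_in), (d_in, spec.n_classes))
        self.params["bout"] = np.zeros(spec.n_classes)

    # ---------------------------------------------------------- forward

    def _check_input(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float)
        if x.ndim == 2:
            x = x[None]
        s = self.spec.input_size
        if x.ndim != 3 or x.shape[1:] != (s, s):
            raise ValueError(f"inputs must be {s}x{s} grayscale images, got {x.shape}")
        return x[:, None]  # (N, 1, H, W)

    def features(self, images) -> np.ndarray:
        """Flattened rectified Conv_5 activations, one row per image."""
        x = self._check_input(images)
        p = self.params
        for i in range(1, 5):
            x, _ = _conv_forward(x, p[f"wc{i}"], p[f"bc{i}"], pad=1)
            x = np.maximum(x, 0.0)
            x, _ = _pool_forward(x)
        x, _ = _conv_forward(x, p["wc5"], p["bc5"], pad=0)
        x = np.maximum(x, 0.0)
        return x.reshape(x.shape[0], -1)

    def _forward_full(self, images):
        """Forward pass through the head, keeping caches for backprop."""
        x = self._check_input(images)
        p = self.params
        caches = []
        for i in range(1, 5):
            y, xp = _conv_forward(x, p[f"wc{i}"], p[f"bc{i}"], pad=1)
            relu_mask = y > 0
            y = y * relu_mask
            pooled, pool_mask = _pool_forward(y)
            caches.append(("conv", i, xp, relu_mask, pool_mask, x.shape))
            x = pooled
        y, xp = _conv_forward(x, p["wc5"], p["bc5"], pad=0)
        relu_mask = y > 0
        y = y * relu_mask
        caches.append(("conv5", 5, xp, relu_mask, None, x.shape))
        h = y.reshape(y.shape[0], -1)
        for i in (1, 2):
            z = h @ p[f"wd{i}"] + p[f"bd{i}"]
            m = z > 0
            caches.append(("dense", i, h, m, None, None))
            h = z * m
        logits = h @ p["wout"] + p["bout"]
        caches.append(("out", 0, h, None, None, None))
        return logits, caches

    def _backward_full(self, dlogits, caches):
        p = self.params
        grads = {}
        kind, _, h, _, _, _ = caches[-1]
        grads["wout"] = h.T @ dlogits
        grads["bout"] = dlogits.sum(axis=0)
        dh = dlogits @ p["wout"].T
        for kind, i, h, m, _, _ in reversed(caches[5:7]):
            dz = dh * m
            grads[f"wd{i}"] = h.T @ dz
            grads[f"bd{i}"] = dz.sum(axis=0)
            dh = dz @ p[f"wd{i}"].T
        _, _, xp, relu_mask, _, x_shape = caches[4]
        dy = dh.reshape(relu_mask.shape) * relu_mask
        grads["wc5"], grads["bc5"], dx = _conv_backward(dy, xp, p["wc5"], 0, x_shape)
        for kind, i, xp, relu_mask, pool_mask, x_shape in reversed(caches[:4]):
            dy = _pool_backward(dx, pool_mask) * relu_mask
            grads[f"wc{i}"], grads[f"bc{i}"], dx = _conv_backward(dy, xp, p[f"wc{i}"], 1, x_shape)
        return grads

    def predict_proba(self, images) -> np.ndarray:
        logits, _ = self._forward_full(images)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def save(self, path) -> None:
        np.savez(path, **self.params)

    def load(self, path) -> "LungStyleCNN":
        data = np.load(path)
        for k in self.params:
            self.params[k] = data[k]
        return self


# ------------------------------------------------------------- preprocessing

def select_largest_roi_slice(volume: np.ndarray, mask: np.ndarray):
    """Axial slice with the largest in-slice mask area (ties: lowest index)."""
    volume = np.asarray(volume)
    mask = np.asarray(mask).astype(bool)
    if volume.shape != mask.shape or mask.ndim != 3:
        raise ValueError("volume and mask must be aligned 3-D arrays")
    areas = mask.sum(axis=(1, 2))
    if areas.sum() == 0:
        raise ValueError("mask is empty")
    k = int(np.argmax(areas))  # argmax returns the first (lowest) maximizer
    return volume[k], mask[k]


def preprocess_roi(image: np.ndarray, mask: np.ndarray,
                   out_size: int = INPUT_SIZE) -> np.ndarray:
    """Crop to the mask bounding box, black out non-ROI pixels, resize.

    In-ROI intensities are min-max scaled to [0, 1] (a constant ROI maps
    to mid-gray 0.5); the output is exactly ``out_size`` square.  Bilinear
    resampling may leave small nonzero values just outside the ROI
    boundary — masking happens before resizing, as the contract states.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if image.shape != mask.shape or image.ndim != 2:
        raise ValueError("image and mask must be aligned 2-D arrays")
    if not mask.any():
        raise ValueError("mask is empty")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    img = image[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    m = mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    vals = img[m]
    lo, hi = vals.min(), vals.max()
    scaled = np.zeros_like(img)
    if hi > lo:
        scaled[m] = (img[m] - lo) / (hi - lo)
    else:
        scaled[m] = 0.5
    return resize(scaled, (out_size, out_size), order=1, mode="constant",
                  anti_aliasing=False, preserve_range=True)


# ------------------------------------------------------------------ features

def extract_deep_features(model: LungStyleCNN, images) -> pd.DataFrame:
    """One row per image; columns are the 64 flattened Conv_5 activations."""
    x = np.stack([np.asarray(im, dtype=float) for im in images])
    feats = model.features(x)
    cols = [f"deep_{j:02d}" for j in range(feats.shape[1])]
    return pd.DataFrame(feats, columns=cols)


def filter_zero_variance(table: pd.DataFrame, tol: float = 1e-12) -> pd.DataFrame:
    """Drop columns whose values are constant to machine tolerance."""
    if len(table) < 2:
        raise ValueError("need at least 2 rows to assess variance")
    keep = [c for c in table.columns if np.ptp(table[c].to_numpy()) > tol]
    if not keep:
        raise ValueError("all columns have zero variance")
    dropped = table.shape[1] - len(keep)
    if dropped:
        logger.info("filter_zero_variance: dropped %d constant columns", dropped)
    return table[keep]


# ------------------------------------------------------------------ training

def pretrain(model: LungStyleCNN, images, labels, config: TrainConfig = TrainConfig()):
    """Train the network with softmax cross-entropy and Adam.

    The stated batch size and learning rate are used as given; Adam is
    the update rule (with lr = 0 the weights are provably unchanged).
    Returns the per-epoch mean loss history.
    """
    x = np.stack([np.asarray(im, dtype=float) for im in images])
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("training labels must contain both classes")
    rng = np.random.default_rng(config.seed)
    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(y))
        losses = []
        for start in range(0, len(y), config.batch_size):
            idx = order[start:start + config.batch_size]
            logits, caches = model._forward_full(x[idx])
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            proba = e / e.sum(axis=1, keepdims=True)
            loss = -np.mean(np.log(proba[np.arange(len(idx)), y[idx]] + 1e-12))
            losses.append(loss)
            dlogits = proba.copy()
            dlogits[np.arange(len(idx)), y[idx]] -= 1.0
            dlogits /= len(idx)
            grads = model._backward_full(dlogits, caches)
            t += 1
            for k, g in grads.items():
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * g
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * g * g
                mhat = m_state[k] / (1 - beta1 ** t)
                vhat = v_state[k] / (1 - beta2 ** t)
                model.params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        history.append(float(np.mean(losses)))
        logger.info("epoch %d: loss %.4f", epoch + 1, history[-1])
    return history
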