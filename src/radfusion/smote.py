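"""SMOTE class balancing with DMwR-style over/under-sampling percentages.

The convention follows the R implementation the settings were printed
for: ``perc_over`` is the percentage of *new* synthetic minority cases
relative to the minority count (200 -> two synthetic points per minority
sample), and ``perc_under`` is the percentage of majority cases sampled
relative to the number of synthetic cases just created.  With the
default (k=5, perc_over=200, perc_under=200) a 3-vs-20 problem yields
3 + 6 minority and 12 majority samples.

Synthetic points are drawn on the segment between a minority point and
one of its k nearest minority neighbours; neighbour search runs on
z-scored features so that no single high-scale column dominates the
Euclidean metric, and the interpolated points are mapped back to the
original scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = ["SmoteConfig", "smote_balance"]


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    perc_over: int = 200
    perc_under: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.perc_over < 100 or self.perc_over % 100:
            raise ValueError("perc_over must be a positive multiple of 100")
        if self.perc_under < 100:
            raise ValueError("perc_under must be >= 100")


def smote_balance(features, labels, config: SmoteConfig = SmoteConfig()):
    """Balance a binary problem; returns (features', labels').

    The output keeps every original minority point, appends
    ``perc_over/100 * n_minority`` synthetic minority points, and keeps a
    without-replacement subsample of ``perc_under/100 * n_synthetic``
    majority points (all of them, with replacement for the remainder,
    only if the majority class is smaller than that).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("features must be 2-D and aligned with labels")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("smote_balance requires exactly two classes present")
    minority = classes[np.argmin(counts)]
    x_min = x[y == minority]
    x_maj = x[y != minority]
    n_min = x_min.shape[0]
    if n_min < 2:
        raise ValueError("minority class must have at least 2 samples")

    rng = np.random.default_rng(config.seed)
    k = config.k_neighbors
    if k > n_min - 1:
        logger.warning("k_neighbors=%d clamped to %d (minority size %d)", k, n_min - 1, n_min)
        k = n_min - 1

    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z_min = (x_min - mu) / sd
    nn = NearestNeighbors(n_neighbors=k + 1).fit(z_min)
    neigh = nn.kneighbors(z_min, return_distance=False)[:, 1:]  # drop self

    per_point = config.perc_over // 100
    synth = np.empty((n_min * per_point, x.shape[1]))
    row = 0
    for i in range(n_min):
        for _ in range(per_point):
            j = neigh[i, rng.integers(k)]
            u = rng.uniform()
            synth[row] = x_min[i] + u * (x_min[j] - x_min[i])
            row += 1

    n_keep = (config.perc_under * synth.shape[0]) // 100
    if n_keep <= x_maj.shape[0]:
        keep = rng.choice(x_maj.shape[0], size=n_keep, replace=False)
    else:
        logger.warning("majority class (%d) smaller than requested %d; sampling with replacement",
                       x_maj.shape[0], n_keep)
        keep = rng.choice(x_maj.shape[0], size=n_keep, replace=True)

    out_x = np.vstack([x_min, synth, x_maj[keep]])
    out_y = np.concatenate([
        np.full(n_min + synth.shape[0], minority),
        np.full(n_keep, classes[classes != minority][0]),
    ])
    logger.info("SMOTE: %d/%d -> %d/%d (minority/majority)",
                n_min, x_maj.shape[0], n_min + synth.shape[0], n_keep)
    return out_x, out_y
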