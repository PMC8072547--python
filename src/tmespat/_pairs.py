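"""Shared pair-counting machinery behind K, pcf and their cross variants.

All second-order estimators reduce to sums over ordered close pairs
(subject point i, target point j) of a weight

    w_ij = e_ij            (homogeneous)
    w_ij = e_ij / (λ̂_i λ̂_j)   (inhomogeneous)

with ``e_ij = |W| / |W ∩ (W + x_j − x_i)|`` the translation edge-correction
factor. The estimators differ only in how the weights are binned over the
distance grid (cumulatively for K, through a ring kernel for the pcf) and in
the normalising divisor D. Keeping the per-subject rows of the binned sums
is what makes Loh's subject bootstrap cheap: the global estimate is the row
mean of the local-contribution matrix divided by D/n_subjects.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .grid import RGrid
from .window import Window

__all__ = [
    "ordered_close_pairs",
    "translation_weights",
    "k_contributions",
    "pcf_contributions",
]


def ordered_close_pairs(coords_from, coords_to, r_max: float, same_pattern: bool):
    """Ordered pairs (i, j) with ``d(from_i, to_j) <= r_max``.

    When ``same_pattern`` is true, self-pairs ``i == j`` are excluded (but
    duplicate points at distance zero still pair with each other).
    Returns ``(i, j, d, dx, dy)`` arrays.
    """
    tree_from = cKDTree(coords_from)
    tree_to = cKDTree(coords_to)
    neighbours = tree_from.query_ball_tree(tree_to, r_max)
    counts = np.fromiter((len(nb) for nb in neighbours), dtype=np.int64, count=len(neighbours))
    i = np.repeat(np.arange(len(neighbours)), counts)
    j = np.concatenate([np.asarray(nb, dtype=np.int64) for nb in neighbours]) if counts.sum() else np.zeros(0, dtype=np.int64)
    if same_pattern and len(i):
        keep = i != j
        i, j = i[keep], j[keep]
    dx = coords_to[j, 0] - coords_from[i, 0]
    dy = coords_to[j, 1] - coords_from[i, 1]
    d = np.hypot(dx, dy)
    return i, j, d, dx, dy


def translation_weights(window: Window, dx, dy):
    """``e_ij = |W| / |W ∩ (W + (dx, dy))|`` per pair."""
    overlap = np.asarray(window.translation_overlap(dx, dy), dtype=float)
    if np.any(overlap <= 0):
        raise ValueError("translation overlap vanished inside the analysis range")
    return window.area / overlap


def k_contributions(i, d, w, n_subjects: int, r: RGrid) -> np.ndarray:
    """Per-subject cumulative weighted pair counts.

    ``T[s, k] = Σ_{pairs with subject s, d <= r_k} w`` — the raw material of
    both the K estimate and its Loh decomposition.
    """
    rv = r.values
    T = np.zeros((n_subjects, len(rv)))
    if len(i):
        bins = np.searchsorted(rv, d, side="left")
        inside = bins < len(rv)
        np.add.at(T, (i[inside], bins[inside]), w[inside])
        np.cumsum(T, axis=1, out=T)
    return T


def pcf_contributions(i, d, w, n_subjects: int, r: RGrid, h: float) -> np.ndarray:
    """Per-subject Epanechnikov ring-kernel sums.

    ``T[s, k] = Σ_{pairs with subject s} κ_h(r_k − d) · w`` with
    ``κ_h(t) = 0.75 (1 − (t/h)²)/h`` on ``|t| < h``. Division by ``2πr`` and
    the estimator divisor happens in the caller.
    """
    rv = r.values
    nr = len(rv)
    T = np.zeros((n_subjects, nr))
    if not len(i):
        return T
    dr = rv[1] - rv[0]
    m = int(np.ceil(2.0 * h / dr)) + 2
    lo = np.searchsorted(rv, d - h, side="left")
    cols = lo[:, None] + np.arange(m)[None, :]
    valid = cols < nr
    cols_c = np.where(valid, cols, 0)
    t = (rv[cols_c] - d[:, None]) / h
    kern = 0.75 * (1.0 - t**2) / h
    kern = np.where((np.abs(t) < 1.0) & valid, kern, 0.0)
    vals = kern * w[:, None]
    rows = np.broadcast_to(i[:, None], cols.shape)
    np.add.at(T, (rows.ravel(), cols_c.ravel()), vals.ravel())
    return T
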