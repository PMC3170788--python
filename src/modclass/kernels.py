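"""Distances, mean-distance normalization and joint-kernel fusion.

For every feature m the pairwise sample distances S_m (chi-square, L1 or L2)
are turned into an RBF kernel

    K_m[i, j] = exp(-S_m[i, j] / gamma_m),

where gamma_m is the mean of S_m over all N^2 ordered training pairs
(diagonal included). Dividing by the training mean puts every feature's
distances on the same scale, so averaging the per-feature kernels

    K = (1/M) * sum_m K_m

gives each feature an equal contribution to the fused kernel regardless of
its dimensionality or raw scale (joint kernel equal contribution). Test-time
kernels reuse the training gamma_m so train and test live on one scale.

The chi-square distance is sum_l (x_l - y_l)^2 / (x_l + y_l) with
zero-denominator terms (x_l = y_l = 0 on nonnegative vectors) contributing 0,
the standard continuous extension. No 1/2 factor is applied; the gamma
normalization cancels any constant factor anyway.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.distance import cdist

METRICS = ("L1", "L2", "chi2")

_CHUNK = 64  # row-chunk size for the chi-square broadcast, bounds peak memory


def _check_metric(metric: str) -> str:
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    return metric


def _as_matrix(x, name: str = "features") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[None]
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 1-D or 2-D")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def _chi2_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.empty((a.shape[0], b.shape[0]))
    for i0 in range(0, a.shape[0], _CHUNK):
        blk = a[i0 : i0 + _CHUNK, None, :]
        diff2 = (blk - b[None]) ** 2
        denom = blk + b[None]
        terms = np.divide(diff2, denom, out=np.zeros_like(diff2), where=denom > 0)
        out[i0 : i0 + _CHUNK] = terms.sum(axis=-1)
    return out


def feature_distance(x, y, metric: str = "chi2") -> float:
    """Distance between two feature vectors under L1, L2 or chi2."""
    _check_metric(metric)
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError(f"vectors must be 1-D of equal length, got {xv.shape} vs {yv.shape}")
    if metric == "L1":
        return float(np.abs(xv - yv).sum())
    if metric == "L2":
        return float(np.sqrt(((xv - yv) ** 2).sum()))
    if np.any(xv < 0) or np.any(yv < 0):
        raise ValueError("chi2 distance requires nonnegative entries")
    denom = xv + yv
    terms = np.divide((xv - yv) ** 2, denom, out=np.zeros_like(denom), where=denom > 0)
    return float(terms.sum())


def cross_distances(a, b, metric: str = "chi2") -> np.ndarray:
    """Rectangular distance matrix between the rows of *a* and of *b*."""
    _check_metric(metric)
    am = _as_matrix(a, "a")
    bm = _as_matrix(b, "b")
    if am.shape[1] != bm.shape[1]:
        raise ValueError(f"dimension mismatch: {am.shape[1]} vs {bm.shape[1]}")
    if metric == "L1":
        return cdist(am, bm, metric="cityblock")
    if metric == "L2":
        return cdist(am, bm, metric="euclidean")
    if np.any(am < 0) or np.any(bm < 0):
        raise ValueError("chi2 distance requires nonnegative entries")
    return _chi2_cross(am, bm)


def pairwise_distances(features, metric: str = "chi2") -> np.ndarray:
    """Symmetric zero-diagonal distance matrix over a sample-by-dimension array."""
    fm = _as_matrix(features)
    if fm.shape[0] < 1:
        raise ValueError("need at least one sample")
    d = cross_distances(fm, fm, metric)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float round-off
    np.fill_diagonal(d, 0.0)
    return d


def compute_gamma(distances: np.ndarray) -> float:
    """Mean pairwise distance over all N^2 ordered pairs, diagonal included.

    A degenerate all-zero distance matrix (all samples identical) falls back
    to gamma = 1 with a warning so toy inputs remain runnable.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"distance matrix must be square, got {d.shape}")
    n = d.shape[0]
    gamma = float(d.sum()) / (n * n)
    if gamma <= 0.0:
        warnings.warn("zero mean distance; falling back to gamma = 1", stacklevel=2)
        return 1.0
    return gamma


def rbf_kernel(distances: np.ndarray, gamma: float) -> np.ndarray:
    """Elementwise exp(-S/gamma); accepts square or rectangular distance input."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    return np.exp(-d / gamma)


def jkec_combine(kernels, weights=None) -> np.ndarray:
    """Fuse per-feature kernels by elementwise mean (or an explicit weighted sum).

    The default, unweighted mean is the equal-contribution rule. The optional
    *weights* (nonnegative, summing to 1) are an extension hook for weighted
    fusion; no particular weighting is recommended.
    """
    mats = [np.asarray(k, dtype=float) for k in kernels]
    if len(mats) < 1:
        raise ValueError("need at least one kernel")
    shape = mats[0].shape
    for k in mats[1:]:
        if k.shape != shape:
            raise ValueError(f"kernel shape mismatch: {k.shape} vs {shape}")
    if weights is None:
        return np.mean(mats, axis=0)
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(mats),) or np.any(w < 0):
        raise ValueError("weights must be one nonnegative value per kernel")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum()}")
    return np.tensordot(w, np.stack(mats), axes=1)
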