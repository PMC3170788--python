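"""Global visual descriptors: gray, color, edge-orientation and variance histograms.

All extractors accept raster images as numpy arrays of shape ``(H, W)``
(grayscale) or ``(H, W, 3)`` (RGB) holding integer intensities in ``[0, 255]``.
Every histogram is normalized to sum to 1 by :func:`normalize_histogram`; a
histogram whose raw counts sum to zero (e.g. the edge histogram of a constant
image) is returned as the all-zero vector of the right length so that flat
images remain processable, and the chi-square kernel downstream treats the
zero coordinates gracefully.

Binning is half-open everywhere — value ``v`` falls in bin ``floor(v / width)``
— with the last bin closed (overflow clamped into it), so bin assignment is
total on the declared range.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

#: ITU-R BT.601 luminance weights used for RGB -> grayscale conversion.
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Largest possible variance of values bounded in [0, 255]: (255/2)^2.
MAX_PATCH_VARIANCE = 255.0**2 / 4.0


def validate_image(image: np.ndarray) -> np.ndarray:
    """Check that *image* is a valid raster image and return it as an array.

    Valid means: 2-D (1 channel) or 3-D with 3 planes, integer intensities in
    [0, 255], positive height and width.
    """
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim not in (2, 3):
        raise ValueError(f"image must be 2-D or 3-D, got shape {arr.shape}")
    if arr.ndim == 3 and arr.shape[2] != 3:
        raise ValueError(f"3-D image must have 3 channels, got {arr.shape[2]}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have positive height and width")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
            raise ValueError("image intensities must be integers")
        arr = arr.astype(np.int64)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("image intensities must lie in [0, 255]")
    return arr


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Return a 1-channel view of *image*, converting RGB by luminance.

    RGB pixels are mapped to round(0.299 R + 0.587 G + 0.114 B).
    """
    arr = validate_image(image)
    if arr.ndim == 2:
        return arr
    gray = np.rint(arr.astype(float) @ GRAY_WEIGHTS)
    return np.clip(gray, 0, 255).astype(np.int64)


def standardize(image: np.ndarray, size: int = 256) -> np.ndarray:
    """Resize *image* to ``size x size`` with bilinear interpolation.

    All feature extraction assumes images share one size so block grids and
    histogram scales are comparable; this is the canonical rescaling step.
    """
    arr = validate_image(image)
    if arr.shape[0] == size and arr.shape[1] == size:
        return arr
    pil = Image.fromarray(arr.astype(np.uint8))
    resized = pil.resize((size, size), Image.BILINEAR)
    return np.asarray(resized).astype(np.int64)


def normalize_histogram(counts) -> np.ndarray:
    """Normalize nonnegative counts to a unit-sum frequency histogram.

    Each entry is divided by the total count. A zero total yields the all-zero
    vector of the same length rather than an error.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("counts must be 1-D")
    if not np.all(np.isfinite(arr)):
        raise ValueError("counts must be finite")
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    total = arr.sum()
    if total == 0:
        return np.zeros_like(arr)
    return arr / total


def gray_histogram(image: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Normalized intensity histogram of the (grayscale-converted) image."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    gray = to_grayscale(image)
    idx = np.minimum(gray.ravel() * n_bins // 256, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return normalize_histogram(counts)


def color_histogram(image: np.ndarray, bins: tuple[int, int, int] = (4, 4, 4)) -> np.ndarray:
    """Joint quantized RGB histogram with k x m x l bins, red-major flattening.

    Each pixel maps to the joint bin (floor(r*k/256), floor(g*m/256),
    floor(b*l/256)); the output has length k*m*l and sums to 1.
    """
    k, m, l = (int(b) for b in bins)
    if k < 1 or m < 1 or l < 1:
        raise ValueError("all bin counts must be >= 1")
    arr = validate_image(image)
    if arr.ndim != 3:
        raise ValueError("color_histogram requires a 3-channel image")
    r = np.minimum(arr[:, :, 0].ravel() * k // 256, k - 1)
    g = np.minimum(arr[:, :, 1].ravel() * m // 256, m - 1)
    b = np.minimum(arr[:, :, 2].ravel() * l // 256, l - 1)
    joint = (r * m + g) * l + b
    counts = np.bincount(joint, minlength=k * m * l).astype(float)
    return normalize_histogram(counts)


def _gradients(gray: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradients with replicate-border padding."""
    p = np.pad(gray.astype(float), 1, mode="edge")
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    return gx, gy


def _block_bounds(extent: int, n: int) -> list[tuple[int, int]]:
    """Half-open ranges tiling [0, extent) into n contiguous blocks."""
    edges = [extent * i // n for i in range(n + 1)]
    return [(edges[i], edges[i + 1]) for i in range(n)]


def edge_histogram(
    image: np.ndarray,
    grid: tuple[int, int] = (4, 4),
    n_bins: int = 20,
) -> np.ndarray:
    """Block-based gradient-orientation histogram weighted by gradient magnitude.

    The image is tiled into ``grid`` blocks; inside each block per-pixel
    gradient magnitudes are accumulated into ``n_bins`` equal-width orientation
    bins over [0, 360) degrees, and each block's histogram is normalized to sum
    to 1 independently (all-zero if the block has no gradient energy). Blocks
    are concatenated row-major, giving ``rows * cols * n_bins`` entries — 320
    with the 4x4 grid and 20 bins.
    """
    rows, cols = (int(g) for g in grid)
    if rows < 1 or cols < 1 or n_bins < 1:
        raise ValueError("grid dimensions and n_bins must be >= 1")
    gray = to_grayscale(image)
    h, w = gray.shape
    if h < rows or w < cols:
        raise ValueError(f"image {h}x{w} smaller than grid {rows}x{cols}")
    gx, gy = _gradients(gray)
    mag = np.hypot(gx, gy)
    orient = np.degrees(np.arctan2(gy, gx)) % 360.0
    obin = np.minimum((orient * n_bins / 360.0).astype(int), n_bins - 1)

    out = np.zeros(rows * cols * n_bins)
    for bi, (r0, r1) in enumerate(_block_bounds(h, rows)):
        for bj, (c0, c1) in enumerate(_block_bounds(w, cols)):
            counts = np.bincount(
                obin[r0:r1, c0:c1].ravel(),
                weights=mag[r0:r1, c0:c1].ravel(),
                minlength=n_bins,
            )
            start = (bi * cols + bj) * n_bins
            out[start : start + n_bins] = normalize_histogram(counts)
    return out


def variance_histogram(
    image: np.ndarray,
    patch_radius: int = 2,
    n_bins: int = 32,
) -> np.ndarray:
    """Histogram of local patch variances over all interior pixels.

    For every pixel whose (2r+1)x(2r+1) neighborhood fits inside the image the
    population variance of that patch is computed; variances are binned into
    ``n_bins`` equal-width bins over [0, 255^2/4] (the maximum variance of
    values bounded in [0, 255]), last bin absorbing overflow, and normalized.
    """
    if patch_radius < 1:
        raise ValueError("patch_radius must be >= 1")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    gray = to_grayscale(image).astype(float)
    side = 2 * patch_radius + 1
    if gray.shape[0] < side or gray.shape[1] < side:
        raise ValueError(f"image too small for a {side}x{side} patch")
    windows = np.lib.stride_tricks.sliding_window_view(gray, (side, side))
    variances = windows.var(axis=(-2, -1)).ravel()
    width = MAX_PATCH_VARIANCE / n_bins
    idx = np.minimum((variances / width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return normalize_histogram(counts)
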