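"""Bag-of-visual-words: dense patch sampling, SIFT descriptors, codebook, histogram.

Local appearance is captured by sampling square patches on a regular grid,
describing each patch with a 128-dimensional SIFT-style gradient-orientation
histogram (8 orientation planes over a 4x4 spatial grid, Gaussian-windowed,
unit L2 norm), quantizing descriptors against a k-means codebook learned on
training descriptors only, and counting codeword frequencies:

    h_c = (1/L) * #{patches whose nearest center is c}

Nearest-center assignment uses squared Euclidean distance with ties broken
toward the lowest center index so histograms are deterministic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from modclass.features_global import to_grayscale

SIFT_SPATIAL_CELLS = 4
SIFT_ORIENT_BINS = 8
SIFT_DIM = SIFT_SPATIAL_CELLS * SIFT_SPATIAL_CELLS * SIFT_ORIENT_BINS


@dataclass
class Codebook:
    """k-means cluster centers in descriptor space plus training metadata."""

    centers: np.ndarray  # (C, dim)
    seed: int
    n_iter: int = 0
    objective: float = 0.0  # within-cluster sum of squared distances

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[0] < 1:
            raise ValueError("centers must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("centers must be finite")

    @property
    def size(self) -> int:
        return self.centers.shape[0]

    @property
    def dim(self) -> int:
        return self.centers.shape[1]

    def save(self, path: str | Path) -> None:
        """Write the codebook as text: header `C<TAB>dim<TAB>seed`, one center per line."""
        with open(path, "w") as fh:
            fh.write(f"{self.size}\t{self.dim}\t{self.seed}\n")
            for row in self.centers:
                fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Codebook":
        with open(path) as fh:
            header = fh.readline().split("\t")
            if len(header) != 3:
                raise ValueError("malformed codebook header")
            c, dim, seed = (int(v) for v in header)
            centers = np.loadtxt(io.StringIO(fh.read()), ndmin=2)
        if centers.shape != (c, dim):
            raise ValueError(f"codebook body {centers.shape} does not match header ({c}, {dim})")
        return cls(centers=centers, seed=seed)


def sample_grid_patches(image: np.ndarray, patch_size: int = 16, stride: int = 8) -> np.ndarray:
    """Extract square patches on a regular grid, row-major, as an (n, p, p) array.

    Patches are anchored at rows/cols 0, stride, 2*stride, ... as long as the
    whole patch fits inside the image.
    """
    if patch_size < 1 or stride < 1:
        raise ValueError("patch_size and stride must be >= 1")
    gray = to_grayscale(image)
    h, w = gray.shape
    if patch_size > h or patch_size > w:
        raise ValueError(f"patch_size {patch_size} exceeds image extent {h}x{w}")
    windows = np.lib.stride_tricks.sliding_window_view(gray, (patch_size, patch_size))
    patches = windows[::stride, ::stride]
    return patches.reshape(-1, patch_size, patch_size)


def _sift_geometry(side: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (cell index, Gaussian weight) for a side x side patch."""
    yy, xx = np.mgrid[0:side, 0:side]
    cell_r = np.minimum(yy * SIFT_SPATIAL_CELLS // side, SIFT_SPATIAL_CELLS - 1)
    cell_c = np.minimum(xx * SIFT_SPATIAL_CELLS // side, SIFT_SPATIAL_CELLS - 1)
    cell = cell_r * SIFT_SPATIAL_CELLS + cell_c
    center = (side - 1) / 2.0
    sigma = side / 2.0
    gauss = np.exp(-(((yy - center) ** 2 + (xx - center) ** 2) / (2.0 * sigma**2)))
    return cell, gauss


def sift_descriptors(patches: np.ndarray) -> np.ndarray:
    """Vectorized SIFT descriptors for a batch of square patches -> (n, 128).

    Per patch: central-difference gradients (replicate border), orientation
    quantized into 8 bins over [0, 360), contributions weighted by gradient
    magnitude times a Gaussian window (sigma = side/2) centered on the patch,
    accumulated into 4x4 spatial cells, flattened cell-major, L2-normalized.
    An all-zero-gradient patch yields the all-zero descriptor.
    """
    arr = np.asarray(patches, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError("patches must be square (n, side, side)")
    n, side, _ = arr.shape
    if side < SIFT_SPATIAL_CELLS:
        raise ValueError(f"patch side must be >= {SIFT_SPATIAL_CELLS}")

    p = np.pad(arr, ((0, 0), (1, 1), (1, 1)), mode="edge")
    gx = (p[:, 1:-1, 2:] - p[:, 1:-1, :-2]) / 2.0
    gy = (p[:, 2:, 1:-1] - p[:, :-2, 1:-1]) / 2.0
    mag = np.hypot(gx, gy)
    orient = np.degrees(np.arctan2(gy, gx)) % 360.0
    obin = np.minimum((orient * SIFT_ORIENT_BINS / 360.0).astype(int), SIFT_ORIENT_BINS - 1)

    cell, gauss = _sift_geometry(side)
    weights = mag * gauss
    idx = cell[None] * SIFT_ORIENT_BINS + obin
    idx = idx + np.arange(n)[:, None, None] * SIFT_DIM
    desc = np.bincount(idx.ravel(), weights=weights.ravel(), minlength=n * SIFT_DIM)
    desc = desc.reshape(n, SIFT_DIM)
    norms = np.linalg.norm(desc, axis=1)
    nonzero = norms > 0
    desc[nonzero] /= norms[nonzero, None]
    return desc


def sift_descriptor(patch: np.ndarray) -> np.ndarray:
    """SIFT descriptor of a single square patch -> 128-vector."""
    return sift_descriptors(np.asarray(patch)[None])[0]


def image_descriptors(image: np.ndarray, patch_size: int = 16, stride: int = 8) -> np.ndarray:
    """Dense-grid SIFT descriptors of an image -> (L, 128)."""
    return sift_descriptors(sample_grid_patches(image, patch_size, stride))


def build_codebook(
    descriptors: np.ndarray,
    n_centers: int,
    seed: int,
    max_iter: int = 100,
) -> Codebook:
    """Cluster descriptors with seeded k-means (Euclidean) into a codebook."""
    arr = np.asarray(descriptors, dtype=float)
    if arr.ndim != 2:
        raise ValueError("descriptors must be 2-D (n, dim)")
    if n_centers < 1:
        raise ValueError("n_centers must be >= 1")
    if arr.shape[0] < n_centers:
        raise ValueError(f"need at least {n_centers} descriptors, got {arr.shape[0]}")
    km = KMeans(
        n_clusters=n_centers,
        init="k-means++",
        n_init=1,
        max_iter=max_iter,
        random_state=seed,
        algorithm="lloyd",
    ).fit(arr)
    return Codebook(
        centers=km.cluster_centers_,
        seed=seed,
        n_iter=int(km.n_iter_),
        objective=float(km.inertia_),
    )


def assign_centers(descriptors: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Index of the Euclidean-nearest center per descriptor (ties -> lowest index)."""
    arr = np.asarray(descriptors, dtype=float)
    if arr.ndim != 2:
        raise ValueError("descriptors must be 2-D (n, dim)")
    if arr.shape[1] != codebook.dim:
        raise ValueError(f"descriptor dim {arr.shape[1]} != codebook dim {codebook.dim}")
    d2 = cdist(arr, codebook.centers, metric="sqeuclidean")
    return np.argmin(d2, axis=1)  # argmin returns the first (lowest) index on ties


def bow_histogram(descriptors: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Codeword frequency histogram: counts of nearest-center assignments / L."""
    arr = np.asarray(descriptors, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need at least one descriptor")
    assignments = assign_centers(arr, codebook)
    counts = np.bincount(assignments, minlength=codebook.size).astype(float)
    return counts / arr.shape[0]
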