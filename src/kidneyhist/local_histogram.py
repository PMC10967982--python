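"""Local normalized histograms with asymmetric bin edges.

The descriptor of one image: the image is partitioned into a 10x10 grid of
non-overlapping windows; for every window an 8-bin normalized histogram is
computed twice — once on the intensity image and once on its Sobel
gradient-magnitude image — using unequal (asymmetric) bin edges that
concentrate resolution near zero, where CT pixel mass is densest. The
two 100x8 matrices are merged into a single 1x1600 feature vector.

Bin convention: with edges ``e0 < e1 < ... < e8`` (``e0 = 0``, ``e8 = 255``),
bin k (k = 0..6) covers the half-open interval ``[e_k, e_{k+1})`` and the
last bin covers the closed interval ``[e7, 255]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "INTENSITY_EDGES",
    "GRADIENT_EDGES",
    "SYMMETRIC_EDGES",
    "BinEdges",
    "WindowGrid",
    "make_window_grid",
    "asymmetric_bin_counts",
    "asymmetric_histogram",
    "gradient_magnitude",
    "local_histograms",
    "extract_features",
]

#: Optimised unequal edges for the intensity histogram (shipped defaults).
INTENSITY_EDGES = (0, 8, 16, 32, 48, 80, 100, 130, 255)
#: Optimised unequal edges for the gradient-magnitude histogram.
GRADIENT_EDGES = (0, 4, 8, 12, 16, 24, 48, 96, 255)
#: Conventional equal-width edges, kept for the symmetric-bin ablation.
SYMMETRIC_EDGES = (0, 32, 64, 96, 128, 159, 191, 223, 255)

N_WINDOWS = 100
N_BINS = 8
FEATURE_LENGTH = 2 * N_WINDOWS * N_BINS  # 1600


@dataclass(frozen=True)
class BinEdges:
    """Nine ascending integer boundaries defining 8 asymmetric intervals."""

    edges: tuple[int, ...]

    def __post_init__(self) -> None:
        e = tuple(int(v) for v in self.edges)
        if len(e) != 9:
            raise ValueError("exactly 9 edges are required")
        if any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("edges must be strictly increasing")
        if e[0] != 0 or e[-1] != 255:
            raise ValueError("edges must start at 0 and end at 255")
        object.__setattr__(self, "edges", e)

    @classmethod
    def from_interior(cls, interior: "np.ndarray | tuple[int, ...]") -> "BinEdges":
        return cls((0, *(int(v) for v in interior), 255))

    @property
    def interior(self) -> tuple[int, ...]:
        return self.edges[1:-1]


@dataclass(frozen=True)
class WindowGrid:
    """Partition of an image into an ``n x n`` grid of rectangular windows."""

    row_bounds: tuple[int, ...]
    col_bounds: tuple[int, ...]

    @property
    def n_rows(self) -> int:
        return len(self.row_bounds) - 1

    @property
    def n_cols(self) -> int:
        return len(self.col_bounds) - 1

    def windows(self, img: np.ndarray):
        """Yield window pixel blocks in row-major window order."""
        for i in range(self.n_rows):
            r0, r1 = self.row_bounds[i], self.row_bounds[i + 1]
            for j in range(self.n_cols):
                c0, c1 = self.col_bounds[j], self.col_bounds[j + 1]
                yield img[r0:r1, c0:c1]


def make_window_grid(height: int, width: int, n: int = 10) -> WindowGrid:
    """Tile an ``height x width`` image with ``n x n`` non-overlapping windows.

    Bounds are ``floor(i*dim/n)``, so windows tile the image exactly; when a
    dimension is not divisible by ``n`` adjacent windows differ by at most
    one pixel in that dimension.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if height < n or width < n:
        raise ValueError(f"image {height}x{width} too small for a {n}x{n} window grid")
    rb = tuple(i * height // n for i in range(n + 1))
    cb = tuple(j * width // n for j in range(n + 1))
    return WindowGrid(rb, cb)


def _bin_indices(values: np.ndarray, edges: BinEdges) -> np.ndarray:
    # searchsorted(side='right') on the interior edges maps v in [e_k, e_{k+1})
    # to k and 255 to the last bin, realising the half-open/closed convention.
    return np.searchsorted(np.asarray(edges.edges[1:-1]), values, side="right")


def asymmetric_bin_counts(pixels: np.ndarray, edges: BinEdges) -> np.ndarray:
    """Raw per-bin counts of ``pixels`` under the asymmetric edge convention."""
    vals = np.asarray(pixels).ravel()
    if vals.size == 0:
        raise ValueError("empty pixel collection")
    if vals.min() < 0 or vals.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    return np.bincount(_bin_indices(vals, edges), minlength=N_BINS).astype(np.int64)


def asymmetric_histogram(pixels: np.ndarray, edges: BinEdges) -> np.ndarray:
    """Normalized 8-bin histogram; frequencies sum to 1."""
    counts = asymmetric_bin_counts(pixels, edges)
    return counts / counts.sum()


def gradient_magnitude(img: np.ndarray) -> np.ndarray:
    """Per-pixel Sobel gradient magnitude, clipped to [0, 255].

    3x3 Sobel kernels with replicate borders; sqrt(Gx^2 + Gy^2) is clipped
    (not rescaled) to the 8-bit range and rounded to the nearest integer, so
    the gradient image shares the intensity image's value range and can be
    binned with the same machinery.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("image must be at least 3x3 for the Sobel operator")
    f = img.astype(np.float64)
    gx = ndimage.sobel(f, axis=1, mode="nearest")
    gy = ndimage.sobel(f, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    return np.rint(np.clip(mag, 0, 255)).astype(np.uint8)


def local_histograms(img: np.ndarray, edges: BinEdges, n: int = 10) -> np.ndarray:
    """Per-window normalized histograms: a ``(n*n, 8)`` row-stochastic matrix.

    Windows appear in row-major order (left-to-right, top-to-bottom).
    """
    img = np.asarray(img)
    grid = make_window_grid(img.shape[0], img.shape[1], n)
    out = np.empty((grid.n_rows * grid.n_cols, N_BINS))
    for w, block in enumerate(grid.windows(img)):
        out[w] = asymmetric_histogram(block, edges)
    return out


def extract_features(
    img: np.ndarray,
    intensity_edges: BinEdges | None = None,
    gradient_edges: BinEdges | None = None,
) -> np.ndarray:
    """Merged 1x1600 descriptor of one (already border-cropped) image.

    Layout: for each window w = 0..99 in row-major order, the 8 intensity
    frequencies followed by the 8 gradient frequencies. The vector sums to
    200 (100 windows x 2 unit-mass histograms).
    """
    intensity_edges = intensity_edges or BinEdges(INTENSITY_EDGES)
    gradient_edges = gradient_edges or BinEdges(GRADIENT_EDGES)
    hi = local_histograms(img, intensity_edges)
    hg = local_histograms(gradient_magnitude(img), gradient_edges)
    return np.concatenate([hi, hg], axis=1).ravel()
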