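"""Loading of grayscale CT slices and removal of the uninformative black margin.

Abdominal CT exports carry a wide near-zero border around the body. Cropping
it before feature extraction shrinks the image and removes the dark-pixel
mass that would otherwise dominate every local histogram.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "CLASS_NAMES",
    "load_gray_image",
    "crop_black_border",
    "discover_dataset",
]

#: Fixed class order used everywhere (labels, confusion matrices, softmax).
CLASS_NAMES = ("cyst", "normal", "stone", "tumour")

#: Folder-name spellings accepted when scanning a dataset root.
_CLASS_ALIASES = {
    "cyst": "cyst",
    "normal": "normal",
    "stone": "stone",
    "tumour": "tumour",
    "tumor": "tumour",
}

_IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png"}


def _validate_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2D array")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    return img


def load_gray_image(path: str | Path) -> np.ndarray:
    """Read a JPEG/PNG file as an 8-bit grayscale array.

    Color inputs are converted to single-channel luminance (ITU-R 601
    weights, Pillow's ``L`` mode). Returns a ``uint8`` array of shape
    ``(height, width)``.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode != "L":
                im = im.convert("L")
            arr = np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot read image file: {path}") from exc
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"zero-sized or non-grayscale image: {path}")
    return arr


def crop_black_border(img: np.ndarray, threshold: int = 10) -> np.ndarray:
    """Crop to the bounding box of all pixels strictly brighter than ``threshold``.

    The margin of a CT export is nominally black but JPEG compression leaves
    low non-zero values in it, so the default threshold is 10 rather than 0.
    A degenerate all-dark image is returned unchanged with a warning so that
    batch runs survive outlier files.
    """
    img = _validate_image(img)
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    mask = img > threshold
    if not mask.any():
        warnings.warn("no pixel exceeds the crop threshold; returning image unchanged",
                      stacklevel=2)
        return img
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return img[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]


def discover_dataset(root: str | Path) -> list[tuple[str, Path]]:
    """Scan ``root/<class_name>/*.{jpg,png}`` and return (label, path) pairs.

    Class folders are matched case-insensitively; both "tumor" and "tumour"
    spellings are accepted. Pairs are sorted (by class, then filename) so the
    listing order is reproducible across filesystems.
    """
    root = Path(root)
    if not root.is_dir():
        raise IOError(f"dataset root is not a directory: {root}")
    pairs: list[tuple[str, Path]] = []
    for sub in sorted(root.iterdir()):
        if not sub.is_dir():
            continue
        label = _CLASS_ALIASES.get(sub.name.lower())
        if label is None:
            continue
        for f in sorted(sub.iterdir()):
            if f.suffix.lower() in _IMAGE_SUFFIXES:
                pairs.append((label, f))
    if not pairs:
        raise IOError(f"no class folders with images found under {root}")
    return pairs
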