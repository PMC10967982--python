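"""Synthetic CT-like phantom images for end-to-end pipeline testing.

Phantoms are statistical look-alikes of abdominal CT exports, not
anatomical renderings: a near-zero margin frames an elliptical,
Gaussian-textured "body", and each disease class inserts a local structure
chosen so the classes separate in exactly the statistics the pipeline
measures —

* ``cyst``   : a smooth dark blob — a soft local depression of the mean
  that preserves the body's noise texture, so it is plain in the intensity
  histogram but invisible to the gradient one,
* ``stone``  : a small sharp near-saturated bright disc (top intensity bin
  plus a strong gradient ring),
* ``tumour`` : an irregular blob with high-variance texture (strong local
  gradients over a wide area),
* ``normal`` : the bare textured body.

Neither channel alone separates all four classes; their combination does.

Every image is reproducible from the dataset seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .image_prep import CLASS_NAMES

__all__ = ["PhantomConfig", "generate_phantom", "generate_dataset", "write_dataset"]


@dataclass(frozen=True)
class PhantomConfig:
    image_size: int = 128
    margin_width: int = 12
    body_mean: float = 120.0
    body_std: float = 15.0
    #: Gaussian smoothing sigma (pixels) of the body texture. Tissue in CT is
    #: locally smooth, so body gradients concentrate near zero; lesion edges
    #: and the tumour's rough interior then dominate the gradient histogram.
    body_smoothness: float = 3.0
    cyst_intensity: float = 40.0
    cyst_radius: int = 10
    #: Width (pixels) of the cyst's soft boundary ramp. Renal cysts are
    #: thin-walled and homogeneous, so their margin is a gentle intensity
    #: transition rather than a sharp edge; a wide taper keeps the cyst's
    #: gradient response within the body-texture range, leaving the cyst
    #: visible to the intensity histogram but not to the gradient one.
    cyst_taper: float = 16.0
    stone_intensity: float = 250.0
    stone_radius: int = 4
    tumour_intensity: float = 150.0
    tumour_texture_std: float = 60.0
    tumour_radius: int = 12
    n_per_class: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin_width >= self.image_size / 4:
            raise ValueError("margin_width must be < image_size/4")
        for r in (self.cyst_radius, self.stone_radius, self.tumour_radius):
            if r >= self.image_size / 4:
                raise ValueError("lesion radii must be < image_size/4")
        for v in (self.body_mean, self.cyst_intensity, self.stone_intensity,
                  self.tumour_intensity):
            if not 0 <= v <= 255:
                raise ValueError("intensities must lie in [0, 255]")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")


def _disc_mask(size: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[:size, :size]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def generate_phantom(cls: str, cfg: PhantomConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """One labelled phantom image as a ``uint8`` array, deterministic in ``rng``."""
    if cls not in CLASS_NAMES:
        raise ValueError(f"unknown class: {cls!r}")
    s = cfg.image_size
    m = cfg.margin_width
    # near-zero margin noise (<= 5), as left by lossy export of a black frame
    img = rng.integers(0, 4, size=(s, s)).astype(np.float64)

    # elliptical body spanning [m, s-m] in both dimensions
    cy = cx = (s - 1) / 2
    ay = ax = (s - 2 * m) / 2
    yy, xx = np.ogrid[:s, :s]
    body = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    noise = rng.normal(0.0, 1.0, size=(s, s))
    if cfg.body_smoothness > 0:
        noise = ndimage.gaussian_filter(noise, cfg.body_smoothness)
        noise /= noise.std()  # restore unit variance after smoothing
    img[body] = (cfg.body_mean + cfg.body_std * noise)[body]

    if cls != "normal":
        radius = {"cyst": cfg.cyst_radius, "stone": cfg.stone_radius,
                  "tumour": cfg.tumour_radius}[cls]
        # jittered insertion point, kept well inside the body
        max_off = max(1.0, 0.5 * min(ay, ax) - radius)
        ly = cy + rng.uniform(-max_off, max_off)
        lx = cx + rng.uniform(-max_off, max_off)
        blob = _disc_mask(s, ly, lx, radius)
        if cls == "cyst":
            # smooth hypodense blob: the local mean drops to cyst_intensity
            # over a soft ramp while the body's noise texture is preserved —
            # CT noise is acquisition noise and is present in fluid too, so
            # a cyst darkens the image without changing its gradient texture
            dist = np.sqrt((yy - ly) ** 2 + (xx - lx) ** 2)
            w = np.clip((radius + cfg.cyst_taper - dist) / cfg.cyst_taper, 0.0, 1.0)
            img = img - w * (cfg.body_mean - cfg.cyst_intensity)
        elif cls == "stone":
            img[blob] = cfg.stone_intensity + rng.normal(0, 2, size=int(blob.sum()))
            img[blob] = np.maximum(img[blob], 240)  # calcification stays near-saturated
        else:  # tumour: irregular outline, violently textured interior
            angle = np.arctan2(np.asarray(yy - ly, dtype=float),
                               np.asarray(xx - lx, dtype=float))
            wobble = 1.0 + 0.3 * np.sin(3 * angle + rng.uniform(0, 2 * np.pi)) \
                         + 0.2 * np.sin(7 * angle + rng.uniform(0, 2 * np.pi))
            rr = np.sqrt((yy - ly) ** 2 + (xx - lx) ** 2)
            blob = rr <= radius * wobble
            img[blob] = cfg.tumour_intensity + rng.normal(
                0, cfg.tumour_texture_std, size=int(blob.sum()))

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_dataset(cfg: PhantomConfig) -> list[tuple[str, np.ndarray]]:
    """``n_per_class`` phantoms per class, reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    out: list[tuple[str, np.ndarray]] = []
    for cls in CLASS_NAMES:
        for _ in range(cfg.n_per_class):
            out.append((cls, generate_phantom(cls, cfg, rng)))
    return out


def write_dataset(cfg: PhantomConfig, root: str | Path) -> list[tuple[str, Path]]:
    """Materialise a phantom dataset in the class-foldered PNG layout."""
    root = Path(root)
    written: list[tuple[str, Path]] = []
    counters: dict[str, int] = {}
    for cls, img in generate_dataset(cfg):
        k = counters.get(cls, 0)
        counters[cls] = k + 1
        d = root / cls
        d.mkdir(parents=True, exist_ok=True)
        path = d / f"{cls}_{k:04d}.png"
        Image.fromarray(img, mode="L").save(path)
        written.append((cls, path))
    return written
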