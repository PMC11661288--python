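"""Synthetic natural-image surrogates and the patch pipeline.

The package's fixtures are generated, not downloaded: Gaussian random-phase
images with a 1/f amplitude spectrum (the canonical natural-image power
law), optionally overlaid with sparse oriented Gabor splats so that
whitened patch marginals become heavy-tailed — the statistical regime
sparse coding assumes. Images are whitened with the standard
frequency-domain filter ``R(f) = f · exp(−(f/f0)⁴)`` (low-pass-windowed
whitening), contrast-normalized per image, and tiled into 16×16 patches
flattened row-major to length-256 vectors.

User-supplied grayscale image arrays can be pushed through the same
whitening/patch pipeline via :func:`whiten_contrast_normalize` and
:func:`extract_patches`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from ._rng import as_generator
from .errors import ConfigError, ContractError

__all__ = ["PatchDataset", "generate_pink_images", "whiten_contrast_normalize",
           "extract_patches", "make_patch_dataset", "load_images"]

logger = logging.getLogger(__name__)


@dataclass
class PatchDataset:
    """Whitened, contrast-normalized flat patches with a train/val split."""

    patches: np.ndarray                 # (N, patch_size²)
    split: np.ndarray                   # (N,) array of {"train", "val"}
    metadata: dict = field(default_factory=dict)

    @property
    def train(self) -> np.ndarray:
        return self.patches[self.split == "train"]

    @property
    def val(self) -> np.ndarray:
        return self.patches[self.split == "val"]

    def save(self, path: str) -> None:
        np.savez(path, patches=self.patches, split=self.split)
        with open(str(path) + ".json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)

    @classmethod
    def load(cls, path: str) -> "PatchDataset":
        with np.load(path, allow_pickle=False) as data:
            patches, split = data["patches"], data["split"]
        try:
            with open(str(path) + ".json") as fh:
                metadata = json.load(fh)
        except FileNotFoundError:
            metadata = {}
        return cls(patches=patches, split=split, metadata=metadata)


def load_images(paths) -> np.ndarray:
    """Load user-supplied grayscale images (PNG/PGM/TIFF) as a stack.

    Color images are averaged to grayscale; all images must share one
    square size. Feed the result to :func:`whiten_contrast_normalize` and
    :func:`extract_patches` for the standard pipeline.
    """
    import imageio.v3 as iio

    imgs = []
    for p in paths:
        a = np.asarray(iio.imread(p), dtype=np.float64)
        if a.ndim == 3:
            a = a.mean(axis=-1)
        imgs.append(a)
    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise ContractError(f"images differ in size: {sorted(shapes)}")
    return np.stack(imgs)


def _gabor_splat(size: int, cx: float, cy: float, theta: float, freq: float,
                 sigma: float) -> np.ndarray:
    """A single oriented Gabor patch on a size×size canvas."""
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    xr = (x - cx) * np.cos(theta) + (y - cy) * np.sin(theta)
    yr = -(x - cx) * np.sin(theta) + (y - cy) * np.cos(theta)
    return np.exp(-(xr ** 2 + yr ** 2) / (2 * sigma ** 2)) * \
        np.cos(2 * np.pi * freq * xr)


def generate_pink_images(n_images: int, size: int = 128, exponent: float = 1.0,
                         rng=None, edge_overlays: int = 12) -> np.ndarray:
    """Random-phase images with amplitude spectrum ∝ 1/f^exponent.

    ``edge_overlays`` sparse Gabor splats per image add oriented structure
    so that whitened-patch marginals are heavy-tailed (kurtosis > 3);
    set to 0 for pure Gaussian 1/f noise. ``exponent=0`` gives white noise.
    """
    if size < 32:
        raise ConfigError("size must be >= 32")
    if exponent < 0 or exponent > 3:
        raise ConfigError("exponent outside the sensible range [0, 3]")
    rng = as_generator(rng)
    fx = np.fft.fftfreq(size)
    fy = np.fft.fftfreq(size)
    f = np.sqrt(fx[None, :] ** 2 + fy[:, None] ** 2)
    amp = np.zeros_like(f)
    nonzero = f > 0
    amp[nonzero] = f[nonzero] ** (-exponent)
    images = np.empty((n_images, size, size))
    for i in range(n_images):
        phase = rng.standard_normal((size, size)) + \
            1j * rng.standard_normal((size, size))
        img = np.fft.ifft2(amp * phase).real
        img /= max(img.std(), 1e-12)
        for _ in range(edge_overlays):
            cx, cy = rng.uniform(0, size, size=2)
            splat = _gabor_splat(size, cx, cy, theta=rng.uniform(0, np.pi),
                                 freq=rng.uniform(0.05, 0.25),
                                 sigma=rng.uniform(2.0, 6.0))
            img += rng.choice([-1.0, 1.0]) * rng.uniform(1.0, 3.0) * splat
        images[i] = img
    return images


def whiten_contrast_normalize(images: np.ndarray, cutoff: float = 0.4,
                              order: int = 4) -> np.ndarray:
    """Frequency-domain whitening with a low-pass window, then per-image
    contrast normalization.

    The filter is ``R(f) = f · exp(−(f/f0)^order)`` with ``f0 = cutoff ×
    Nyquist`` — the convention of the classical sparse-coding literature.
    After filtering, each image is normalized to zero mean and unit pixel
    variance. Constant (zero-variance) images are skipped with a warning.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    size = images.shape[1]
    if images.shape[1] != images.shape[2]:
        raise ContractError("images must be square")
    fx = np.fft.fftfreq(size)
    f = np.sqrt(fx[None, :] ** 2 + fx[:, None] ** 2)
    f0 = cutoff * 0.5  # Nyquist frequency is 0.5 cycles/pixel
    R = f * np.exp(-((f / f0) ** order))
    out = []
    for i, img in enumerate(images):
        if img.std() < 1e-12:
            logger.warning("image %d is constant; skipping", i)
            continue
        white = np.fft.ifft2(np.fft.fft2(img) * R).real
        white -= white.mean()
        white /= max(white.std(), 1e-12)
        out.append(white)
    if not out:
        raise ContractError("all images were degenerate")
    return np.stack(out)


def extract_patches(images: np.ndarray, patch_size: int = 16,
                    max_patches: int | None = None, rng=None,
                    random_crops: bool = False,
                    val_fraction: float = 0.1) -> PatchDataset:
    """Tile images into non-overlapping patches (or random crops) and split.

    Patches are flattened row-major (origin top-left, image-scan order) and
    split 90/10 into train/val by a seeded shuffle.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    size = images.shape[1]
    if patch_size > size:
        raise ConfigError("patch_size larger than image")
    rng = as_generator(rng)
    patches = []
    if random_crops:
        n = max_patches or 1000
        for _ in range(n):
            i = rng.integers(0, images.shape[0])
            r = rng.integers(0, size - patch_size + 1)
            c = rng.integers(0, size - patch_size + 1)
            patches.append(images[i, r:r + patch_size, c:c + patch_size].ravel())
    else:
        per_side = size // patch_size
        for img in images:
            for r in range(per_side):
                for c in range(per_side):
                    patches.append(
                        img[r * patch_size:(r + 1) * patch_size,
                            c * patch_size:(c + 1) * patch_size].ravel())
        if max_patches is not None and len(patches) > max_patches:
            keep = rng.choice(len(patches), size=max_patches, replace=False)
            patches = [patches[k] for k in sorted(keep)]
    patches = np.stack(patches)
    n = patches.shape[0]
    order = rng.permutation(n)
    n_val = int(round(val_fraction * n))
    split = np.full(n, "train", dtype=object)
    split[order[:n_val]] = "val"
    return PatchDataset(patches=patches, split=split.astype(str),
                        metadata={"patch_size": patch_size,
                                  "n_patches": int(n),
                                  "val_fraction": val_fraction})


def make_patch_dataset(n_images: int = 30, size: int = 128,
                       exponent: float = 1.0, patch_size: int = 16,
                       edge_overlays: int = 12, cutoff: float = 0.4,
                       order: int = 4, max_patches: int | None = None,
                       seed: int = 0) -> PatchDataset:
    """End-to-end fixture: generate, whiten, normalize, tile, split.

    Fully determined by ``seed``; the generation parameters are recorded in
    the dataset metadata.
    """
    rng = np.random.default_rng(seed)
    images = generate_pink_images(n_images, size=size, exponent=exponent,
                                  rng=rng, edge_overlays=edge_overlays)
    white = whiten_contrast_normalize(images, cutoff=cutoff, order=order)
    ds = extract_patches(white, patch_size=patch_size, max_patches=max_patches,
                         rng=rng)
    ds.metadata.update({"n_images": n_images, "size": size,
                        "exponent": exponent, "edge_overlays": edge_overlays,
                        "cutoff": cutoff, "order": order, "seed": seed})
    return ds
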