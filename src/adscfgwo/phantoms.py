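"""Synthetic brain-like phantoms and label-preserving image augmentation.

Real MRI data cannot ship with the package, so the tuning and metrics
machinery is exercised on generated phantoms: grayscale images of a
smooth elliptical "brain" on a dark background, where positive images
(label 1, tumor) additionally contain one to three bright elliptical
lesion blobs inside the brain mask and negative images (label 0, normal)
do not.  The appearance model is deliberately simple — its job is to give
a controlled, separable binary classification task, not to mimic MRI
physics.

The augmentation pipeline mirrors the standard label-preserving
transforms for this kind of data: random shift, horizontal/vertical
flips, rotation in [0, 360] degrees and zoom in [0.9, 1.1], applied in
that fixed order, always preserving the input dimensions and filling
out-of-frame pixels with a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.transform import AffineTransform, rotate, warp

__all__ = [
    "PhantomConfig",
    "AugmentationConfig",
    "ImageDataset",
    "generate_phantom_dataset",
    "augment_image",
    "augment_dataset",
    "save_dataset",
    "load_dataset",
]


@dataclass
class PhantomConfig:
    """Generative settings for a phantom dataset.

    Intensities are arranged so that, at ``noise_sd == 0``, every lesion
    pixel is strictly brighter than any pixel of a lesion-free image:
    brain level ± texture stays below ``background_level + texture_amp``
    while lesions add ``lesion_offset`` on top.
    """

    n_images: int = 100
    image_size: int = 64
    tumor_fraction: float = 0.5
    background_level: float = 0.45
    brain_margin: int = 4
    texture_amp: float = 0.05
    lesion_radius: tuple[int, int] = (3, 8)
    lesion_offset: float = 0.35
    max_lesions: int = 3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.lesion_radius
        if not 0 < lo <= hi:
            raise ValueError("lesion radius range must be positive and ordered")
        if hi >= self.image_size // 2 - self.brain_margin:
            raise ValueError("lesion radius exceeds the brain mask")


@dataclass
class AugmentationConfig:
    """Label-preserving transform settings (shift, flip, rotate, zoom)."""

    shift_frac: float = 0.1
    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotation_range: tuple[float, float] = (0.0, 360.0)
    zoom_range: tuple[float, float] = (0.9, 1.1)
    interpolation: str = "bilinear"  # or "nearest"
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        if self.zoom_range[0] <= 0 or self.zoom_range[1] < self.zoom_range[0]:
            raise ValueError("zoom range must be positive and ordered")
        lo, hi = self.rotation_range
        if not (0.0 <= lo <= hi <= 360.0):
            raise ValueError("rotation range must lie within [0, 360]")
        if self.interpolation not in ("bilinear", "nearest"):
            raise ValueError("interpolation must be 'bilinear' or 'nearest'")

    @property
    def order(self) -> int:
        return 1 if self.interpolation == "bilinear" else 0


@dataclass
class ImageDataset:
    """In-memory labeled image set: float images in [0, 1] with binary labels."""

    images: np.ndarray  # (n, h, w)
    labels: np.ndarray  # (n,), values in {0, 1}
    filenames: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.images.ndim != 3 or len(self.labels) != len(self.images):
            raise ValueError("images must be (n, h, w) with one label per image")
        if not self.filenames:
            self.filenames = [f"img_{i:05d}.png" for i in range(len(self.labels))]

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "ImageDataset":
        idx = np.asarray(idx)
        return ImageDataset(
            self.images[idx], self.labels[idx], [self.filenames[i] for i in idx]
        )


def _brain_mask(size: int, margin: int) -> np.ndarray:
    c = (size - 1) / 2.0
    ax_r = size / 2.0 - margin
    ax_c = ax_r * 0.85  # brains are a little narrower than tall
    rr, cc = np.mgrid[0:size, 0:size]
    return ((rr - c) / ax_r) ** 2 + ((cc - c) / ax_c) ** 2 <= 1.0


def _single_phantom(
    cfg: PhantomConfig, positive: bool, rng: np.random.Generator
) -> np.ndarray:
    size = cfg.image_size
    mask = _brain_mask(size, cfg.brain_margin)
    # smooth internal texture, bounded by texture_amp
    tex = gaussian_filter(rng.standard_normal((size, size)), sigma=size / 8.0)
    peak = np.abs(tex).max()
    if peak > 0:
        tex = tex / peak * cfg.texture_amp
    img = np.where(mask, cfg.background_level + tex, 0.0)

    if positive:
        n_lesions = int(rng.integers(1, cfg.max_lesions + 1))
        rr, cc = np.mgrid[0:size, 0:size]
        for _ in range(n_lesions):
            r = float(rng.uniform(cfg.lesion_radius[0], cfg.lesion_radius[1]))
            # rejection-sample a center whose lesion stays inside the brain
            for _attempt in range(200):
                cy, cx = rng.uniform(0, size, size=2)
                probe = ((rr - cy) ** 2 + (cc - cx) ** 2) <= (r + 1.0) ** 2
                if np.all(mask[probe]):
                    break
            ratio = float(rng.uniform(0.7, 1.0))
            blob = ((rr - cy) / r) ** 2 + ((cc - cx) / (r * ratio)) ** 2 <= 1.0
            img = np.where(blob, img + cfg.lesion_offset, img)

    if cfg.noise_sd > 0:
        img = img + cfg.noise_sd * rng.standard_normal((size, size))
    return np.clip(img, 0.0, 1.0)


def generate_phantom_dataset(cfg: PhantomConfig) -> ImageDataset:
    """Generate a labeled phantom set with exactly round(n * tumor_fraction) positives.

    Fully determined by ``cfg`` (including its seed).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_images
    n_pos = int(np.floor(n * cfg.tumor_fraction + 0.5))
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_pos]] = 1
    images = np.stack([_single_phantom(cfg, bool(lab), rng) for lab in labels])
    return ImageDataset(images=images, labels=labels)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _zoom_about_center(img: np.ndarray, factor: float, order: int, fill: float) -> np.ndarray:
    c = (np.array(img.shape[::-1]) - 1) / 2.0  # (x, y)
    # warp expects the output->input map: o -> (o - c)/factor + c
    tform = (
        AffineTransform(translation=-c)
        + AffineTransform(scale=1.0 / factor)
        + AffineTransform(translation=c)
    )
    return warp(img, tform, order=order, cval=fill, preserve_range=True)


def augment_image(
    image: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    """One random shift → flip → rotate → zoom pass over a square grayscale image.

    Output shape equals input shape; pixels are clipped back to [0, 1].
    Identity draws short-circuit the interpolating warps so a zero
    transform is bit-exact.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("expected a square grayscale image")
    size = img.shape[0]
    order, fill = cfg.order, cfg.fill_value

    dx, dy = rng.uniform(-cfg.shift_frac, cfg.shift_frac, size=2) * size
    if dx != 0.0 or dy != 0.0:
        tform = AffineTransform(translation=(-dx, -dy))  # output->input map
        img = warp(img, tform, order=order, cval=fill, preserve_range=True)

    if cfg.horizontal_flip and rng.random() < 0.5:
        img = img[:, ::-1]
    if cfg.vertical_flip and rng.random() < 0.5:
        img = img[::-1, :]

    angle = float(rng.uniform(*cfg.rotation_range))
    if angle % 360.0 != 0.0:
        img = rotate(img, angle, resize=False, order=order, cval=fill, preserve_range=True)

    factor = float(rng.uniform(*cfg.zoom_range))
    if factor != 1.0:
        img = _zoom_about_center(img, factor, order, fill)

    return np.clip(np.ascontiguousarray(img), 0.0, 1.0)


def augment_dataset(
    dataset: ImageDataset,
    cfg: AugmentationConfig,
    multiplier: int,
    rng: np.random.Generator,
) -> ImageDataset:
    """Enlarge a dataset: each image contributes (multiplier - 1) augmented copies.

    Labels are copied verbatim; output size is multiplier × input size.
    """
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    if multiplier == 1:
        return dataset
    images = [dataset.images]
    labels = [dataset.labels]
    names = list(dataset.filenames)
    for m in range(1, multiplier):
        aug = np.stack([augment_image(img, cfg, rng) for img in dataset.images])
        images.append(aug)
        labels.append(dataset.labels)
        names.extend(f"aug{m}_{fn}" for fn in dataset.filenames)
    return ImageDataset(np.concatenate(images), np.concatenate(labels), names)


# ---------------------------------------------------------------------------
# disk layout: PNG directory + labels.csv
# ---------------------------------------------------------------------------


def save_dataset(dataset: ImageDataset, directory: str | Path) -> Path:
    """Write 8-bit grayscale PNGs plus a labels.csv (filename, label)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for img, fn in zip(dataset.images, dataset.filenames):
        arr = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(directory / fn)
    pd.DataFrame({"filename": dataset.filenames, "label": dataset.labels}).to_csv(
        directory / "labels.csv", index=False
    )
    return directory


def load_dataset(directory: str | Path) -> ImageDataset:
    """Read a PNG directory + labels.csv back into memory (images in [0, 1])."""
    directory = Path(directory)
    table = pd.read_csv(directory / "labels.csv")
    images = np.stack(
        [
            np.asarray(Image.open(directory / fn).convert("L"), dtype=float) / 255.0
            for fn in table["filename"]
        ]
    )
    return ImageDataset(images, table["label"].to_numpy(), list(table["filename"]))
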