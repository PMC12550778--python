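"""Standardization and seeded geometric augmentation.

Images are standardized with the mean and standard deviation pooled over
all pixels of the *training* images only: ``S' = (S - mu) / sigma``.

Augmentation draws rotation, scale, horizontal flip, translation and shear
from uniform laws within configured ranges and composes them in a fixed
order (flip -> rotate -> scale -> shear -> translate).  The continuous
transforms are applied about the image center as a single composed affine
warp with bilinear interpolation and constant fill (0, i.e. the dataset
mean in standardized space); the horizontal flip is an exact index
reversal so that flipping twice is bit-identical to the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform

__all__ = [
    "NormalizationStats",
    "AugmentationConfig",
    "fit_normalization",
    "standardize",
    "geometric_transform",
    "random_augment",
]

KINDS = ("rotate", "scale", "hflip", "translate", "shear")


@dataclass(frozen=True)
class NormalizationStats:
    mu: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class AugmentationConfig:
    """Uniform sampling ranges for the five geometric transforms."""

    rotation_max_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    hflip_prob: float = 0.5
    translate_max_frac: float = 0.1
    shear_max_deg: float = 5.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError(f"scale_range must satisfy 0 < lo <= hi, got {self.scale_range}")
        if self.rotation_max_deg < 0 or self.shear_max_deg < 0:
            raise ValueError("angle ranges must be nonnegative")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError(f"hflip_prob must be in [0, 1], got {self.hflip_prob}")
        if not 0.0 <= self.translate_max_frac < 1.0:
            raise ValueError(
                f"translate_max_frac must be in [0, 1), got {self.translate_max_frac}"
            )

    @property
    def is_identity(self) -> bool:
        return (
            self.rotation_max_deg == 0
            and self.scale_range == (1.0, 1.0)
            and self.hflip_prob == 0
            and self.translate_max_frac == 0
            and self.shear_max_deg == 0
        )


def fit_normalization(train_images) -> NormalizationStats:
    """Pooled mean/sd over every pixel of the training images only."""
    if len(train_images) == 0:
        raise ValueError("need at least one training image")
    flat = np.concatenate([np.asarray(im, dtype=np.float64).ravel() for im in train_images])
    mu = float(flat.mean())
    sigma = float(flat.std())
    if sigma == 0.0:
        raise ValueError("degenerate dataset: pixel variance is zero")
    return NormalizationStats(mu=mu, sigma=sigma)


def standardize(image: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    return (np.asarray(image, dtype=np.float64) - stats.mu) / stats.sigma


def _affine_matrix(kind: str, params) -> np.ndarray:
    """2x3 forward map on (row, col) coordinates, origin at the image center."""
    if kind == "rotate":
        t = np.deg2rad(float(params))
        lin = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        off = np.zeros(2)
    elif kind == "scale":
        a = float(params)
        if a <= 0:
            raise ValueError(f"scale factor must be positive, got {a}")
        lin = np.eye(2) * a
        off = np.zeros(2)
    elif kind == "shear":
        s = np.tan(np.deg2rad(float(params)))
        lin = np.array([[1.0, s], [0.0, 1.0]])
        off = np.zeros(2)
    elif kind == "translate":
        dy, dx = params if np.ndim(params) else (float(params), float(params))
        lin = np.eye(2)
        off = np.array([float(dy), float(dx)])
    else:
        raise ValueError(f"unknown transform kind {kind!r}; expected one of {KINDS}")
    return lin, off


def _apply_affine(image: np.ndarray, lin: np.ndarray, off: np.ndarray, cval: float):
    """Warp about the image center: out(x) = in(lin^-1 (x - c - off) + c)."""
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape[:2]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    inv = np.linalg.inv(lin)
    offset = center - inv @ (center + off)
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        out[:, :, c] = affine_transform(
            img[:, :, c], inv, offset=offset, order=1, mode="constant", cval=cval
        )
    return out


def geometric_transform(
    image: np.ndarray, kind: str, params=None, fill_value: float = 0.0
) -> np.ndarray:
    """Apply one named transform; output shape equals input shape.

    ``params``: angle in degrees (rotate/shear), factor (scale),
    (dy, dx) pixels (translate), unused for hflip.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3:
        raise ValueError(f"expected an (H, W, C) image, got shape {img.shape}")
    if kind == "hflip":
        return img[:, ::-1, :].copy()
    lin, off = _affine_matrix(kind, params)
    if np.allclose(lin, np.eye(2)) and np.allclose(off, 0):
        return img.copy()
    return _apply_affine(img, lin, off, fill_value)


def random_augment(
    image: np.ndarray,
    config: AugmentationConfig,
    rng: np.random.Generator,
    fill_value: float = 0.0,
) -> np.ndarray:
    """Sample one composed augmentation; deterministic under ``rng`` state.

    Draws (in fixed order): flip ~ Bernoulli(hflip_prob), rotation angle,
    scale factor, shear angle, translation — each uniform in its range —
    and applies flip first, then the single composed affine warp.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape[:2]
    do_flip = rng.random() < config.hflip_prob
    theta = rng.uniform(-config.rotation_max_deg, config.rotation_max_deg)
    alpha = rng.uniform(*config.scale_range)
    shear = rng.uniform(-config.shear_max_deg, config.shear_max_deg)
    ty = rng.uniform(-config.translate_max_frac, config.translate_max_frac) * h
    tx = rng.uniform(-config.translate_max_frac, config.translate_max_frac) * w

    if do_flip:
        img = img[:, ::-1, :]
    # compose translate . shear . scale . rotate (applied to the flipped image)
    lin = np.eye(2)
    off = np.zeros(2)
    for kind, p in (("rotate", theta), ("scale", alpha), ("shear", shear),
                    ("translate", (ty, tx))):
        l2, o2 = _affine_matrix(kind, p)
        lin = l2 @ lin
        off = l2 @ off + o2
    if np.allclose(lin, np.eye(2)) and np.allclose(off, 0):
        return img.copy()
    return _apply_affine(img, lin, off, fill_value)
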