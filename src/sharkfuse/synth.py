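"""Seeded synthetic 3-class scan-like image generator.

Real cervical CT/MRI collections of the kind this pipeline targets are
institutionally restricted, so experiments here run on generated images
that keep the *structure* of such data: three classes (normal / benign /
malignant), two modality profiles that differ in noise and lesion
contrast, and a stratified train/val/test split.

Class archetypes (geometric, not photorealistic):

* ``normal`` — background anatomy and texture only, no lesion.
* ``benign`` — a single smooth, soft-edged elliptical high-intensity lesion.
* ``malignant`` — an irregular, jagged-boundary lesion with internal
  speckle texture and a sharp rim, at the *same mean intensity offset* as
  benign, so that benign-vs-malignant is the hardest pair (intensity alone
  cannot separate them; boundary and texture statistics must).

``effect_size`` scales every lesion-specific signal; at 0 all three classes
are statistically identical background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

CLASS_NAMES = ("normal", "benign", "malignant")

#: Modality profiles: CT scans have lower background noise and higher lesion
#: contrast than MRI, making CT the easier modality (by design, so the
#: CT-vs-MRI accuracy ordering is a testable property of the pipeline).
MODALITY_PROFILES = {
    "CT": {"noise_mult": 1.0, "contrast": 1.0},
    "MRI": {"noise_mult": 1.8, "contrast": 0.65},
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generated dataset; identical configs yield identical data."""

    n_per_class: int = 100
    image_size: tuple[int, int] = (64, 64)
    channels: int = 1
    modality_profile: str = "CT"
    effect_size: float = 1.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError(f"n_per_class must be >= 1, got {self.n_per_class}")
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValueError(f"image_size must be at least 8x8, got {self.image_size}")
        if self.channels not in (1, 3):
            raise ValueError(f"channels must be 1 or 3, got {self.channels}")
        if self.modality_profile not in MODALITY_PROFILES:
            raise ValueError(
                f"modality_profile must be one of {sorted(MODALITY_PROFILES)}, "
                f"got {self.modality_profile!r}"
            )
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass
class LabeledDataset:
    """Images (N, H, W, C) in [0, 255], integer labels, optional split tags."""

    images: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES
    split: np.ndarray | None = None  # per-sample {"train","val","test"}

    def __post_init__(self):
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")
        k = len(self.class_names)
        if len(self.labels) and not np.isin(self.labels, np.arange(k)).all():
            raise ValueError(f"labels must be in 0..{k - 1}")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, split_name: str) -> "LabeledDataset":
        if self.split is None:
            raise ValueError("dataset has no split assignment")
        m = self.split == split_name
        return LabeledDataset(self.images[m], self.labels[m], self.class_names)


def _background(h, w, noise_sd, noise_mult, rng):
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    # soft elliptical "body" on a darker field
    q = ((yy - cy) / (0.46 * h)) ** 2 + ((xx - cx) / (0.46 * w)) ** 2
    img = 45.0 + 55.0 / (1.0 + np.exp((q - 1.0) / 0.08))
    sd = noise_sd * noise_mult
    if sd > 0:
        img += gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=3.0) * sd * 1.5
        img += rng.normal(0.0, sd, (h, w))
    return img


def render_image(
    class_label: int, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Render one (H, W, C) image in [0, 255] for the given class archetype."""
    if class_label not in (0, 1, 2):
        raise ValueError(f"class_label must be 0, 1 or 2, got {class_label!r}")
    h, w = config.image_size
    prof = MODALITY_PROFILES[config.modality_profile]
    img = _background(h, w, config.noise_sd, prof["noise_mult"], rng)

    if class_label != 0:
        amp = config.effect_size * prof["contrast"] * 70.0
        yy, xx = np.mgrid[0:h, 0:w]
        cy = (h - 1) / 2 + rng.uniform(-0.14, 0.14) * h
        cx = (w - 1) / 2 + rng.uniform(-0.14, 0.14) * w
        r0 = rng.uniform(0.16, 0.24) * min(h, w)
        phi = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = np.cos(phi) * dx + np.sin(phi) * dy
        v = -np.sin(phi) * dx + np.cos(phi) * dy
        theta = np.arctan2(v, u)
        ax_u = r0 * rng.uniform(0.85, 1.25)
        ax_v = r0 * rng.uniform(0.75, 1.05)
        if class_label == 1:
            # smooth ellipse, wide soft rim
            dist = np.sqrt((u / ax_u) ** 2 + (v / ax_v) ** 2) * r0 - r0
            mask = 1.0 / (1.0 + np.exp(dist / (0.25 * r0)))
            img += amp * mask
        else:
            # jagged radial boundary, sharp rim, internal speckle
            n_harm = rng.integers(4, 7)
            coeffs = rng.normal(0.0, 1.0, n_harm)
            phases = rng.uniform(0, 2 * np.pi, n_harm)
            jag = sum(
                c * np.cos((k + 2) * theta + p)
                for k, (c, p) in enumerate(zip(coeffs, phases))
            )
            jag = jag / (np.abs(coeffs).sum() + 1e-9)
            r_theta = r0 * (1.0 + 0.55 * jag)
            dist = np.sqrt((u / ax_u) ** 2 + (v / ax_v) ** 2) * r0 - r_theta
            mask = 1.0 / (1.0 + np.exp(dist / (0.04 * r0)))
            speckle = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=0.8)
            tex_amp = config.effect_size * prof["contrast"] * 45.0
            img += (amp + tex_amp * speckle) * mask

    # quantize to 8-bit levels (like real scan exports); keeps the PNG
    # writer/loader round-trip pixel-exact
    img = np.clip(np.round(img), 0.0, 255.0).astype(np.float32)
    return np.repeat(img[:, :, None], config.channels, axis=2)


def generate_dataset(config: SyntheticConfig) -> LabeledDataset:
    """Generate 3 * n_per_class images, n_per_class per class, fully seeded.

    Each image gets its own child random stream spawned from ``config.seed``,
    so rendering is order-independent and bit-reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(3 * config.n_per_class)
    images, labels = [], []
    for cls in range(3):
        for i in range(config.n_per_class):
            rng = np.random.default_rng(children[cls * config.n_per_class + i])
            images.append(render_image(cls, config, rng))
            labels.append(cls)
    return LabeledDataset(np.stack(images), np.asarray(labels, dtype=np.int64))


def _largest_remainder_counts(n: int, fractions: tuple[float, ...]) -> list[int]:
    exact = [f * n for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def split_dataset(
    dataset: LabeledDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> LabeledDataset:
    """Stratified train/val/test assignment with largest-remainder rounding."""
    if any(f <= 0 for f in fractions):
        raise ValueError(f"fractions must be positive, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions} (sum {sum(fractions)})")
    rng = np.random.default_rng(seed)
    split = np.empty(len(dataset), dtype=object)
    names = ("train", "val", "test")
    for cls in range(len(dataset.class_names)):
        idx = np.flatnonzero(dataset.labels == cls)
        rng.shuffle(idx)
        counts = _largest_remainder_counts(len(idx), tuple(fractions))
        pos = 0
        for name, cnt in zip(names, counts):
            if cnt == 0:
                logger.warning("split %r is empty for class %d", name, cls)
            split[idx[pos : pos + cnt]] = name
            pos += cnt
    return LabeledDataset(
        dataset.images, dataset.labels, dataset.class_names, split.astype("U5")
    )


def save_image_folder(dataset: LabeledDataset, root: str | Path) -> Path:
    """Export as ``<root>/<split>/<class_name>/img_#####.png`` + manifest.csv."""
    from PIL import Image
    import pandas as pd

    root = Path(root)
    rows = []
    split = dataset.split if dataset.split is not None else np.full(len(dataset), "all")
    for i, (img, lab, sp) in enumerate(zip(dataset.images, dataset.labels, split)):
        cname = dataset.class_names[lab]
        d = root / str(sp) / cname
        d.mkdir(parents=True, exist_ok=True)
        path = d / f"img_{i:05d}.png"
        arr = np.clip(np.round(img), 0, 255).astype(np.uint8)
        if arr.shape[2] == 1:
            Image.fromarray(arr[:, :, 0], mode="L").save(path)
        else:
            Image.fromarray(arr, mode="RGB").save(path)
        rows.append(
            {"path": str(path.relative_to(root)), "label": int(lab), "class_name": cname,
             "split": str(sp)}
        )
    pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)
    return root
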