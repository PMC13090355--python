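"""Hybrid data augmentation: geometric transforms plus adaptive noise.

The geometric part composes rotation, shifts, zoom, shear and optional
flips into a single affine warp.  The adaptive part injects zero-mean
Gaussian noise whose standard deviation follows

    sigma = k * (1 + brightness / 255) * (1 - contrast / 255)

where brightness is the image's mean intensity and contrast its standard
deviation: bright, low-contrast images — the ones most affected by sensor
noise in practice — receive more perturbation, while high-contrast images
carrying fine structure are preserved.  With the published base factor
k = 0.001 * 255 the resulting sigma is at most ~0.5, so by default it is
applied on the [0, 1] normalized intensity scale where that magnitude is
meaningful; a raw-scale mode applies it directly on [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Any

import numpy as np
from skimage import transform


@dataclass
class ImageStats:
    """Mean intensity and population standard deviation on [0, 255]."""

    brightness: float
    contrast: float


@dataclass
class NoiseConfig:
    k: float = 0.001 * 255  # base noise factor
    clip: bool = True
    normalized_scale: bool = True  # sigma applied on [0, 1] intensities

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")


@dataclass
class GeoAugParams:
    """Ranges for the sampled geometric transforms."""

    rotation_deg: float = 0.0
    width_shift: float = 0.0
    height_shift: float = 0.0
    zoom: float = 0.0
    shear: float = 0.0
    h_flip: bool = False
    v_flip: bool = False

    @classmethod
    def from_values(cls, values: dict[str, Any]) -> "GeoAugParams":
        """Build from optimizer-decoded hyperparameter values."""
        return cls(
            rotation_deg=float(values.get("rotation", 0.0)),
            width_shift=float(values.get("width_shift", 0.0)),
            height_shift=float(values.get("height_shift", 0.0)),
            zoom=float(values.get("zoom", 0.0)),
            shear=float(values.get("shear", 0.0)),
            h_flip=bool(values.get("h_flip", False)),
            v_flip=bool(values.get("v_flip", False)),
        )


def image_stats(img: np.ndarray) -> ImageStats:
    x = np.asarray(img, dtype=float)
    return ImageStats(brightness=float(x.mean()), contrast=float(x.std()))


def adaptive_sigma(stats: ImageStats, cfg: NoiseConfig) -> float:
    """Brightness/contrast-adaptive noise level; never negative."""
    contrast = min(stats.contrast, 255.0)
    return cfg.k * (1.0 + stats.brightness / 255.0) * (1.0 - contrast / 255.0)


def inject_noise(img: np.ndarray, sigma: float, rng: np.random.Generator,
                 cfg: NoiseConfig | None = None) -> np.ndarray:
    """Add zero-mean Gaussian noise of the given sigma; output stays uint8.

    ``sigma`` is interpreted on the scale selected by the config: on the
    normalized scale it is multiplied by 255 before being applied to the
    stored 8-bit intensities.
    """
    cfg = NoiseConfig() if cfg is None else cfg
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    img = np.asarray(img)
    if sigma == 0:
        return img.copy()
    scale = sigma * 255.0 if cfg.normalized_scale else sigma
    noisy = img.astype(float) + rng.normal(0.0, scale, size=img.shape)
    if cfg.clip:
        noisy = np.clip(noisy, 0, 255)
    return np.rint(noisy).astype(np.uint8)


def _affine_params(params: GeoAugParams, rng: np.random.Generator) -> dict[str, float]:
    return {
        "rotation_deg": float(rng.uniform(-params.rotation_deg, params.rotation_deg)),
        "shift_cols": float(rng.uniform(-params.width_shift, params.width_shift)),
        "shift_rows": float(rng.uniform(-params.height_shift, params.height_shift)),
        "zoom": float(rng.uniform(1.0 - params.zoom, 1.0 + params.zoom)),
        "shear_deg": float(np.degrees(rng.uniform(-params.shear, params.shear))),
        "h_flip": bool(params.h_flip and rng.uniform() < 0.5),
        "v_flip": bool(params.v_flip and rng.uniform() < 0.5),
    }


def apply_affine(img: np.ndarray, sampled: dict[str, float]) -> np.ndarray:
    """Apply one sampled geometric transform (bilinear, reflective borders)."""
    img = np.asarray(img)
    h, w = img.shape[:2]
    # (x, y) pixel-center convention; (size-1)/2 keeps quarter turns exact
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    zoom = sampled["zoom"]
    tf = (
        transform.AffineTransform(translation=-center)
        + transform.AffineTransform(
            rotation=np.deg2rad(sampled["rotation_deg"]),
            shear=np.deg2rad(sampled["shear_deg"]),
            scale=(zoom, zoom),
        )
        + transform.AffineTransform(
            translation=center + np.array([sampled["shift_cols"] * w, sampled["shift_rows"] * h])
        )
    )
    out = transform.warp(
        img.astype(float), tf.inverse, order=1, mode="reflect", preserve_range=True
    )
    if sampled["h_flip"]:
        out = out[:, ::-1]
    if sampled["v_flip"]:
        out = out[::-1]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def geometric_transform(
    img: np.ndarray, params: GeoAugParams, rng: np.random.Generator
) -> np.ndarray:
    """Sample and apply one geometric augmentation."""
    return apply_affine(img, _affine_params(params, rng))


@dataclass
class AugmentedSet:
    """Balanced image set plus a provenance manifest for synthetic items."""

    images: list[np.ndarray]
    labels: np.ndarray
    manifest: list[dict[str, Any]]  # one entry per synthetic image

    @property
    def n_synthetic(self) -> int:
        return len(self.manifest)


def augment_to_balance(
    images_by_class: dict[int, list[np.ndarray]],
    geo: GeoAugParams,
    noise: NoiseConfig,
    rng: np.random.Generator,
) -> AugmentedSet:
    """Augment minority classes up to the majority count.

    Each synthetic image is a geometric transform of a cycled source image
    followed by adaptive Gaussian noise, and is tagged in the manifest with
    its source index, class and sampled parameters.
    """
    for cls, imgs in images_by_class.items():
        if not imgs:
            raise ValueError(f"class {cls} has no images")
    target = max(len(v) for v in images_by_class.values())
    images: list[np.ndarray] = []
    labels: list[int] = []
    manifest: list[dict[str, Any]] = []
    for cls in sorted(images_by_class):
        originals = images_by_class[cls]
        images.extend(originals)
        labels.extend([cls] * len(originals))
        deficit = target - len(originals)
        for i in range(deficit):
            src_idx = i % len(originals)
            src = originals[src_idx]
            sampled = _affine_params(geo, rng)
            aug = apply_affine(src, sampled)
            sigma = adaptive_sigma(image_stats(aug), noise)
            aug = inject_noise(aug, sigma, rng, noise)
            images.append(aug)
            labels.append(cls)
            manifest.append(
                {"class": cls, "source_index": src_idx, "sigma": sigma, **sampled}
            )
    return AugmentedSet(images, np.array(labels), manifest)
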