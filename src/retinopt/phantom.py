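"""Synthetic fundus phantoms with exact disc/cup ground truth.

A phantom imitates the statistical structure a fundus pipeline relies on —
a dark reddish retina under a smooth illumination gradient, a bright
elliptical optic disc containing a brighter concentric cup, a few dark
vessels, sensor noise and the black circular padding of a fundus camera —
without attempting photorealism.  The class label follows the clinical
cup-to-disc-ratio (CDR) heuristic: an enlarged cup relative to the disc
marks glaucoma.  Truth masks are rasterized analytically (a pixel belongs
to a mask iff its center lies inside the generating ellipse), so
segmentation accuracy can be scored without annotation ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import bezier_curve

DEFAULT_LABEL_THRESHOLD = 0.6

# Base colours (R, G, B) on the 0-255 scale.
_BACKGROUND = np.array([150.0, 55.0, 30.0])
_DISC = np.array([235.0, 190.0, 110.0])
_CUP = np.array([255.0, 235.0, 170.0])
_VESSEL = np.array([90.0, 20.0, 15.0])


@dataclass
class PhantomSpec:
    """Geometry and noise settings for one phantom."""

    image_size: tuple[int, int] = (256, 256)
    disc_center: tuple[float, float] | None = None  # (row, col); None = jittered center
    disc_radii: tuple[float, float] = (42.0, 38.0)  # (row, col) semi-axes
    cdr: float = 0.4
    vessel_count: int = 4
    vessel_width: int = 3
    illumination_strength: float = 25.0
    noise_sigma: float = 4.0
    padding_margin: int = 12
    label_threshold: float = DEFAULT_LABEL_THRESHOLD

    def __post_init__(self) -> None:
        if not 0.0 < self.cdr < 1.0:
            raise ValueError("CDR must lie strictly between 0 and 1")
        if min(self.disc_radii) * self.cdr >= min(self.disc_radii):
            raise ValueError("cup must be strictly inside the disc")

    @property
    def label(self) -> int:
        """1 = glaucoma, 0 = normal, by the CDR rule."""
        return int(self.cdr > self.label_threshold)


@dataclass
class PhantomDataset:
    images: list[np.ndarray]
    disc_masks: list[np.ndarray]
    cup_masks: list[np.ndarray]
    labels: np.ndarray
    manifest: list[dict[str, Any]]

    def __len__(self) -> int:
        return len(self.images)


def _ellipse_mask(shape: tuple[int, int], center, radii) -> np.ndarray:
    rr, cc = np.indices(shape)
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def _vessel_mask(shape, center, rng, count, width) -> np.ndarray:
    """A few dark curves radiating past the disc, thickened by dilation."""
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for _ in range(count):
        theta = rng.uniform(0, 2 * np.pi)
        r_end = 0.48 * min(h, w)
        end = (
            int(np.clip(center[0] + r_end * np.sin(theta), 0, h - 1)),
            int(np.clip(center[1] + r_end * np.cos(theta), 0, w - 1)),
        )
        mid = (
            int(np.clip(center[0] + 0.5 * r_end * np.sin(theta) + rng.normal(0, 12), 0, h - 1)),
            int(np.clip(center[1] + 0.5 * r_end * np.cos(theta) + rng.normal(0, 12), 0, w - 1)),
        )
        rr, cc = bezier_curve(int(center[0]), int(center[1]), mid[0], mid[1], end[0], end[1], 2)
        mask[rr, cc] = True
    if width > 1:
        mask = ndi.binary_dilation(mask, iterations=width // 2)
    return mask


def generate_phantom(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Render one phantom; returns (image uint8 HxWx3, disc mask, cup mask, label)."""
    h, w = spec.image_size
    if spec.disc_center is None:
        center = (
            h / 2 + rng.uniform(-0.08, 0.08) * h,
            w / 2 + rng.uniform(-0.08, 0.08) * w,
        )
    else:
        center = spec.disc_center
    cup_radii = (spec.disc_radii[0] * spec.cdr, spec.disc_radii[1] * spec.cdr)

    disc_mask = _ellipse_mask((h, w), center, spec.disc_radii)
    cup_mask = _ellipse_mask((h, w), center, cup_radii)

    img = np.ones((h, w, 3)) * _BACKGROUND
    # smooth diagonal illumination gradient
    rr, cc = np.indices((h, w))
    ramp = (rr / h + cc / w) / 2.0 - 0.5
    img += spec.illumination_strength * ramp[..., None]

    vessels = _vessel_mask((h, w), center, rng, spec.vessel_count, spec.vessel_width)
    img[vessels] = _VESSEL
    img[disc_mask] = _DISC
    img[cup_mask] = _CUP

    img += rng.normal(0.0, spec.noise_sigma, size=img.shape)

    # black circular camera aperture
    radius = min(h, w) / 2.0 - spec.padding_margin
    aperture = ((rr - h / 2) ** 2 + (cc - w / 2) ** 2) <= radius**2
    img[~aperture] = 0.0

    return np.clip(img, 0, 255).astype(np.uint8), disc_mask, cup_mask, spec.label


def generate_dataset(
    n_per_class: int,
    seed: int = 0,
    image_size: tuple[int, int] = (256, 256),
    normal_cdr: tuple[float, float] = (0.2, 0.5),
    glaucoma_cdr: tuple[float, float] = (0.65, 0.9),
    label_threshold: float = DEFAULT_LABEL_THRESHOLD,
    **spec_overrides: Any,
) -> PhantomDataset:
    """Balanced phantom dataset with class-conditional CDR ranges.

    The default ranges sit on either side of the labelling threshold, so the
    classes are separable by construction; overlapping ranges are accepted
    with a warning since they break that guarantee.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if normal_cdr[1] > label_threshold or glaucoma_cdr[0] <= label_threshold:
        import warnings

        warnings.warn("CDR ranges straddle the label threshold; classes may overlap")
    rng = np.random.default_rng(seed)
    images, discs, cups, labels, manifest = [], [], [], [], []
    for label, (lo, hi) in ((0, normal_cdr), (1, glaucoma_cdr)):
        for i in range(n_per_class):
            spec = PhantomSpec(
                image_size=image_size,
                cdr=float(rng.uniform(lo, hi)),
                label_threshold=label_threshold,
                **spec_overrides,
            )
            img, disc, cup, lab = generate_phantom(spec, rng)
            assert lab == label
            images.append(img)
            discs.append(disc)
            cups.append(cup)
            labels.append(lab)
            manifest.append({"index": len(images) - 1, "label": lab, **asdict(spec)})
    return PhantomDataset(images, discs, cups, np.array(labels), manifest)
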