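"""Fundus preprocessing: denoise, gamma, CLAHE, padding removal,
intensity-cluster disc/cup segmentation, ROI crop.

The stages run in a fixed order.  Early stages normalize illumination and
contrast (Gaussian blur, power-law gamma correction with the brightening
default γ = 0.4, contrast-limited adaptive histogram equalization), then the
black camera padding is cropped away, the optic disc and cup are segmented
by intensity K-means (k = 6) with morphological cleanup — the disc and cup
are the brightest structures in a fundus photograph — and finally the disc
region of interest is cropped and resized to the classifier input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, morphology, transform
from sklearn.cluster import KMeans


class PipelineStageError(RuntimeError):
    """A preprocessing stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PreprocessConfig:
    blur_kernel: int = 5
    gamma: float = 0.4
    clahe_clip: float = 2.0          # OpenCV-style clip limit; /100 on skimage's scale
    clahe_tiles: tuple[int, int] = (8, 8)
    padding_threshold: float = 10.0
    kmeans_k: int = 6
    morph_kernel: int = 5
    crop_margin: float = 0.25        # fraction of the disc box added on each side
    out_size: tuple[int, int] = (224, 224)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.kmeans_k < 2:
            raise ValueError("kmeans_k must be >= 2")
        for k in (self.blur_kernel, self.morph_kernel):
            if k < 1 or k % 2 == 0:
                raise ValueError("kernels must be odd and positive")


@dataclass
class RoiBox:
    """0-based, half-open crop box."""

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValueError("empty box")

    def slice(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)


@dataclass
class ClusterMap:
    """Per-pixel intensity-cluster labels, ids ordered by descending mean."""

    labels: np.ndarray
    means: np.ndarray


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    return img


def to_gray(img: np.ndarray) -> np.ndarray:
    """Luminance (ITU-R 601) on the [0, 255] scale."""
    img = _check_image(img).astype(float)
    return 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]


def gaussian_denoise(img: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Gaussian low-pass per channel with a (blur_kernel x blur_kernel) support."""
    img = _check_image(img)
    k = cfg.blur_kernel
    if k % 2 == 0:
        raise ValueError("blur kernel must be odd")
    if k == 1:
        return img.copy()
    sigma = 0.3 * ((k - 1) * 0.5 - 1) + 0.8  # kernel-size -> sigma convention
    radius = (k - 1) // 2
    out = np.empty_like(img, dtype=float)
    for c in range(3):
        out[..., c] = ndi.gaussian_filter(
            img[..., c].astype(float), sigma, truncate=radius / sigma
        )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def gamma_correct(img: np.ndarray, gamma: float) -> np.ndarray:
    """Power-law intensity map v -> 255 * (v / 255) ** gamma."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    img = _check_image(img)
    lut = np.clip(np.rint(255.0 * (np.arange(256) / 255.0) ** gamma), 0, 255).astype(np.uint8)
    return lut[img]


def clahe_enhance(img: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Default mode equalizes the luminance and rescales the colour channels;
    per-channel mode applies CLAHE to each RGB channel independently.
    """
    img = _check_image(img).astype(float)
    h, w = img.shape[:2]
    kernel = (max(h // cfg.clahe_tiles[0], 1), max(w // cfg.clahe_tiles[1], 1))
    clip = cfg.clahe_clip / 100.0

    gray = to_gray(img)
    if gray.std() < 1e-9:
        return img.astype(np.uint8)
    eq = exposure.equalize_adapthist(gray / 255.0, kernel_size=kernel, clip_limit=clip)
    gain = np.where(gray > 0, (eq * 255.0) / np.maximum(gray, 1e-9), 1.0)
    out = img * gain[..., None]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def clahe_enhance_per_channel(img: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    img = _check_image(img)
    h, w = img.shape[:2]
    kernel = (max(h // cfg.clahe_tiles[0], 1), max(w // cfg.clahe_tiles[1], 1))
    out = np.empty_like(img, dtype=float)
    for c in range(3):
        ch = img[..., c].astype(float)
        if ch.std() < 1e-9:
            out[..., c] = ch
            continue
        out[..., c] = 255.0 * exposure.equalize_adapthist(
            ch / 255.0, kernel_size=kernel, clip_limit=cfg.clahe_clip / 100.0
        )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def remove_black_padding(
    img: np.ndarray, threshold: float = 10.0
) -> tuple[np.ndarray, RoiBox]:
    """Crop to the bounding box of the largest above-threshold component.

    An all-dark image is returned unchanged with a warning.
    """
    img = _check_image(img)
    fg = to_gray(img) > threshold
    labels, n = ndi.label(fg)
    if n == 0:
        import warnings

        warnings.warn("no foreground above threshold; image returned unchanged")
        h, w = img.shape[:2]
        return img.copy(), RoiBox(0, h, 0, w)
    sizes = ndi.sum_labels(fg, labels, index=np.arange(1, n + 1))
    comp = labels == (1 + int(np.argmax(sizes)))
    rows = np.flatnonzero(comp.any(axis=1))
    cols = np.flatnonzero(comp.any(axis=0))
    box = RoiBox(int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)
    return img[box.slice()].copy(), box


def kmeans_cluster(img: np.ndarray, k: int = 6, seed: int = 0) -> ClusterMap:
    """K-means on grayscale intensity; labels ordered by descending mean.

    Deterministic under a fixed seed.  If the image has fewer distinct
    intensities than k, k is reduced with a warning.
    """
    gray = to_gray(img)
    values = gray.reshape(-1, 1)
    n_distinct = np.unique(np.rint(gray)).size
    if n_distinct < k:
        import warnings

        warnings.warn(f"only {n_distinct} distinct intensities; reducing k from {k}")
        k = max(int(n_distinct), 1)
    if k == 1:
        return ClusterMap(np.zeros(gray.shape, dtype=int), np.array([gray.mean()]))
    km = KMeans(n_clusters=k, random_state=seed, n_init=4)
    raw = km.fit_predict(values).reshape(gray.shape)
    means = km.cluster_centers_.ravel()
    order = np.argsort(-means)  # brightest first
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return ClusterMap(relabel[raw], means[order])


def _open_close(mask: np.ndarray, selem: np.ndarray) -> np.ndarray:
    out = ndi.binary_opening(mask, structure=selem)
    return ndi.binary_closing(out, structure=selem)


def _largest_component(mask: np.ndarray) -> np.ndarray | None:
    labels, n = ndi.label(mask)
    if n == 0:
        return None
    sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _brightest_component(
    mask: np.ndarray, gray: np.ndarray, min_size: int
) -> np.ndarray | None:
    """The component with the highest mean intensity among those of at
    least ``min_size`` pixels (largest component as fallback)."""
    labels, n = ndi.label(mask)
    if n == 0:
        return None
    ids = np.arange(1, n + 1)
    sizes = ndi.sum_labels(mask, labels, index=ids)
    keep = sizes >= min_size
    if not keep.any():
        return labels == ids[int(np.argmax(sizes))]
    means = ndi.mean(gray, labels, index=ids[keep])
    return labels == ids[keep][int(np.argmax(means))]


def refine_and_mask(
    cmap: ClusterMap, cfg: PreprocessConfig, gray: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Disc and cup masks from the ordered cluster map.

    Bright clusters are accumulated in descending-mean order while they stay
    small — a cluster covering a large image fraction is retinal background,
    not disc tissue — and the disc is the largest connected component of the
    accumulated set.  The cup is the brightest cluster inside the disc; when
    the brightest cluster already spans essentially the whole disc (cup and
    neuroretinal rim merged into one intensity cluster), the disc interior
    is re-split into two intensity groups and the brighter one is the cup.
    Both masks are opened then closed, and cup ⊆ disc is enforced.
    Raises :class:`PipelineStageError` when no disc is found.
    """
    selem = morphology.disk(max(cfg.morph_kernel // 2, 1))
    labels = cmap.labels
    k = len(cmap.means)
    if k < 2:
        raise PipelineStageError(
            "segmentation", "too few intensity clusters to isolate a disc"
        )
    npix = labels.size
    selected = [0]
    for i in range(1, k):
        if np.sum(labels == i) / npix > 0.12:  # background-sized cluster
            break
        selected.append(i)
    disc = _largest_component(np.isin(labels, selected))
    if disc is None:
        raise PipelineStageError("segmentation", "no bright region found for the disc")
    disc = _open_close(disc, selem)
    disc = ndi.binary_fill_holes(disc)
    if not disc.any():
        raise PipelineStageError("segmentation", "disc mask empty after morphology")
    if disc.sum() > 0.5 * npix:
        raise PipelineStageError(
            "segmentation", "no distinct bright region: candidate disc spans the image"
        )

    if gray is None:
        gray = cmap.means[labels]  # cluster-mean intensities as fallback
    cup = (labels == 0) & disc
    if cup.sum() > 0.85 * disc.sum():
        # cup and rim merged into the brightest cluster: split by intensity
        thresh = _two_means_threshold(gray[disc])
        cup = disc & (gray > thresh)
    min_size = max(25, int(0.02 * disc.sum()))
    cup = _brightest_component(cup, gray, min_size)
    cup = np.zeros_like(disc) if cup is None else cup
    cup = _open_close(cup, selem)
    cup = ndi.binary_fill_holes(cup) & disc
    return disc, cup


def _two_means_threshold(values: np.ndarray) -> float:
    """1-D 2-means threshold (midpoint fixed-point iteration)."""
    t = float(values.mean())
    for _ in range(100):
        lo, hi = values[values <= t], values[values > t]
        if lo.size == 0 or hi.size == 0:
            break
        t_new = (lo.mean() + hi.mean()) / 2.0
        if abs(t_new - t) < 1e-6:
            break
        t = t_new
    return t


def crop_and_resize(
    img: np.ndarray,
    disc: np.ndarray,
    out_size: tuple[int, int] = (224, 224),
    margin: float = 0.25,
) -> np.ndarray:
    """Crop the disc bounding box (with a relative margin) and resize."""
    img = _check_image(img)
    if not disc.any():
        raise ValueError("empty disc mask")
    rows = np.flatnonzero(disc.any(axis=1))
    cols = np.flatnonzero(disc.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    mr = int(round((r1 - r0) * margin))
    mc = int(round((c1 - c0) * margin))
    h, w = img.shape[:2]
    box = RoiBox(max(r0 - mr, 0), min(r1 + mr, h), max(c0 - mc, 0), min(c1 + mc, w))
    crop = img[box.slice()].astype(float)
    out = transform.resize(crop, out_size, order=1, preserve_range=True, anti_aliasing=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def preprocess_pipeline(
    img: np.ndarray, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, Any]]:
    """Full pipeline; returns (224x224 image, masks, provenance record).

    Stage order: denoise → gamma → CLAHE → padding removal → K-means
    disc/cup segmentation → ROI crop and resize.  Stage failures are
    re-raised as :class:`PipelineStageError` naming the stage.
    """
    cfg = PreprocessConfig() if cfg is None else cfg
    provenance: dict[str, Any] = {"config": asdict(cfg), "stages": []}

    def stage(name: str, fn, *args):
        try:
            out = fn(*args)
        except PipelineStageError:
            raise
        except Exception as exc:  # attach stage identity
            raise PipelineStageError(name, str(exc)) from exc
        provenance["stages"].append(name)
        return out

    x = stage("denoise", gaussian_denoise, img, cfg)
    x = stage("gamma", gamma_correct, x, cfg.gamma)
    x = stage("clahe", clahe_enhance, x, cfg)
    x, box = stage("padding_removal", remove_black_padding, x, cfg.padding_threshold)
    provenance["padding_box"] = asdict(box)
    cmap = stage("segmentation", kmeans_cluster, x, cfg.kmeans_k, cfg.seed)
    disc, cup = stage("segmentation", refine_and_mask, cmap, cfg, to_gray(x))
    out = stage("crop_resize", crop_and_resize, x, disc, cfg.out_size, cfg.crop_margin)
    return out, {"disc": disc, "cup": cup}, provenance
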