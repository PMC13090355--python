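import numpy as np
import pytest

from retinopt.phantom import PhantomSpec, generate_phantom
from retinopt.preprocess import (
    PreprocessConfig,
    clahe_enhance,
    gamma_correct,
    gaussian_denoise,
    kmeans_cluster,
    refine_and_mask,
    remove_black_padding,
    to_gray,
)


@pytest.fixture(scope="session")
def phantom_batch():
    """20 seeded phantoms spanning both label classes, with truth masks."""
    out = []
    for s in range(20):
        rng = np.random.default_rng(s)
        cdr = float(np.random.default_rng(s + 100).uniform(0.25, 0.85))
        spec = PhantomSpec(cdr=cdr)
        img, disc, cup, label = generate_phantom(spec, rng)
        out.append({"spec": spec, "image": img, "disc": disc, "cup": cup, "label": label})
    return out


@pytest.fixture(scope="session")
def segmented_batch(phantom_batch):
    """The phantom batch pushed through preprocessing up to segmentation,
    with truth masks mapped into the cropped frame."""
    cfg = PreprocessConfig()
    results = []
    for item in phantom_batch:
        x = gaussian_denoise(item["image"], cfg)
        x = gamma_correct(x, cfg.gamma)
        x = clahe_enhance(x, cfg)
        x, box = remove_black_padding(x, cfg.padding_threshold)
        cmap = kmeans_cluster(x, cfg.kmeans_k, cfg.seed)
        disc, cup = refine_and_mask(cmap, cfg, to_gray(x))
        results.append(
            {
                "disc": disc,
                "cup": cup,
                "true_disc": item["disc"][box.slice()],
                "true_cup": item["cup"][box.slice()],
            }
        )
    return results


def iou(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0
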