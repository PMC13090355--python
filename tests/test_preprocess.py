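"""Preprocessing stages: intensity maps, padding crop, segmentation."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from conftest import iou
from retinopt.preprocess import (
    ClusterMap,
    PipelineStageError,
    PreprocessConfig,
    clahe_enhance,
    crop_and_resize,
    gamma_correct,
    gaussian_denoise,
    kmeans_cluster,
    preprocess_pipeline,
    refine_and_mask,
    remove_black_padding,
)


def _flat(value, shape=(64, 64, 3)):
    return np.full(shape, value, dtype=np.uint8)


class TestGamma:
    def test_endpoints_fixed(self):
        img = np.zeros((4, 4, 3), np.uint8)
        img[0] = 255
        out = gamma_correct(img, 0.4)
        assert out[0].min() == 255 and out[1].max() == 0

    def test_identity_at_one(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        assert np.array_equal(gamma_correct(img, 1.0), img)

    def test_midtone_value(self):
        out = gamma_correct(_flat(128), 0.4)
        assert out[0, 0, 0] == round(255 * (128 / 255) ** 0.4)  # ~194

    def test_brightens_midtones_below_one(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)[..., None].repeat(3, -1)
        out = gamma_correct(img, 0.4)
        assert np.all(out.astype(int) >= img.astype(int))

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            gamma_correct(_flat(10), 0.0)


class TestDenoise:
    def test_constant_unchanged(self):
        img = _flat(77)
        assert np.array_equal(gaussian_denoise(img, PreprocessConfig()), img)

    def test_variance_never_increases(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
        out = gaussian_denoise(img, PreprocessConfig())
        assert out.astype(float).var() <= img.astype(float).var()

    def test_impulse_response_matches_direct_convolution(self):
        cfg = PreprocessConfig(blur_kernel=5)
        img = np.zeros((31, 31, 3), np.uint8)
        img[15, 15] = 255
        out = gaussian_denoise(img, cfg).astype(float)
        sigma = 0.3 * ((5 - 1) * 0.5 - 1) + 0.8
        ref = ndi.gaussian_filter(img[..., 0].astype(float), sigma, truncate=2 / sigma)
        assert np.allclose(out[..., 0], np.clip(np.rint(ref), 0, 255), atol=1)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(blur_kernel=4)


class TestClahe:
    def test_constant_image_unchanged(self):
        img = _flat(120)
        out = clahe_enhance(img, PreprocessConfig())
        assert np.array_equal(out, img)

    def test_output_range(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
        out = clahe_enhance(img, PreprocessConfig())
        assert out.min() >= 0 and out.max() <= 255

    def test_boosts_low_contrast_gradient(self):
        ramp = np.linspace(100, 140, 64).astype(np.uint8)
        img = np.tile(ramp[None, :, None], (64, 1, 3))
        out = clahe_enhance(img, PreprocessConfig())
        assert out.astype(float).std() > img.astype(float).std()


class TestPaddingRemoval:
    def test_known_box_recovered(self):
        img = np.zeros((200, 200, 3), np.uint8)
        img[70:120, 60:120] = 200  # 50 x 60 bright rectangle
        crop, box = remove_black_padding(img, threshold=10)
        assert (box.row0, box.row1, box.col0, box.col1) == (70, 120, 60, 120)
        assert crop.shape == (50, 60, 3)

    def test_no_padding_is_identity(self):
        img = _flat(90)
        crop, box = remove_black_padding(img, threshold=10)
        assert crop.shape == img.shape

    def test_idempotent(self):
        img = np.zeros((100, 100, 3), np.uint8)
        img[20:80, 30:90] = 150
        crop1, _ = remove_black_padding(img, 10)
        crop2, box2 = remove_black_padding(crop1, 10)
        assert crop2.shape == crop1.shape

    def test_all_dark_returns_unchanged_with_warning(self):
        img = np.zeros((40, 40, 3), np.uint8)
        with pytest.warns(UserWarning):
            crop, box = remove_black_padding(img, 10)
        assert crop.shape == img.shape


class TestKmeans:
    def test_recovers_six_flat_regions(self):
        img = np.zeros((60, 60, 3), np.uint8)
        levels = [20, 60, 100, 140, 180, 240]
        for i, v in enumerate(levels):
            img[:, i * 10 : (i + 1) * 10] = v
        cmap = kmeans_cluster(img, k=6, seed=0)
        # each 10-column band maps to exactly one label, brightest band = 0
        for i in range(6):
            band = cmap.labels[:, i * 10 : (i + 1) * 10]
            assert np.unique(band).size == 1
        assert cmap.labels[0, 59] == 0  # brightest region first after ordering
        assert np.all(np.diff(cmap.means) <= 0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, size=(48, 48, 3), dtype=np.uint8)
        a = kmeans_cluster(img, 6, seed=3)
        b = kmeans_cluster(img, 6, seed=3)
        assert np.array_equal(a.labels, b.labels)

    def test_two_tone_threshold_matches_exhaustive_oracle(self):
        img = np.zeros((20, 20, 3), np.uint8)
        img[:, 10:] = 200
        cmap = kmeans_cluster(img, k=2, seed=0)
        # exhaustive 1-D 2-means on {0, 200}: clusters are the two tones
        assert np.unique(cmap.labels[:, :10]).size == 1
        assert np.unique(cmap.labels[:, 10:]).size == 1
        assert cmap.labels[0, 15] == 0  # brighter tone is cluster 0

    def test_fewer_intensities_than_k_reduces_k(self):
        img = np.zeros((20, 20, 3), np.uint8)
        img[:, 10:] = 200
        with pytest.warns(UserWarning):
            cmap = kmeans_cluster(img, k=6, seed=0)
        assert len(cmap.means) <= 2


class TestSegmentation:
    def test_phantom_disc_and_cup_recovery(self, segmented_batch):
        disc_ious = [iou(r["disc"], r["true_disc"]) for r in segmented_batch]
        cup_ious = [iou(r["cup"], r["true_cup"]) for r in segmented_batch]
        assert np.mean(disc_ious) >= 0.8
        assert np.mean(cup_ious) >= 0.7

    def test_cup_subset_of_disc(self, segmented_batch):
        for r in segmented_batch:
            assert not (r["cup"] & ~r["disc"]).any()

    def test_empty_cluster_map_fails_loudly(self):
        cmap = ClusterMap(labels=np.ones((10, 10), int), means=np.array([50.0, 10.0]))
        with pytest.raises(PipelineStageError):
            refine_and_mask(cmap, PreprocessConfig())


class TestCropResize:
    def test_output_is_224(self):
        img = _flat(100, (120, 130, 3))
        disc = np.zeros((120, 130), bool)
        disc[40:80, 50:90] = True
        out = crop_and_resize(img, disc)
        assert out.shape == (224, 224, 3)

    def test_full_mask_is_pure_resize(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(100, 100, 3), dtype=np.uint8)
        out = crop_and_resize(img, np.ones((100, 100), bool), out_size=(50, 50), margin=0.0)
        assert out.shape == (50, 50, 3)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            crop_and_resize(_flat(10), np.zeros((64, 64), bool))


class TestPipeline:
    def test_deterministic(self, phantom_batch):
        img = phantom_batch[0]["image"]
        out1, _, _ = preprocess_pipeline(img)
        out2, _, _ = preprocess_pipeline(img)
        assert np.array_equal(out1, out2)

    def test_output_shape_and_provenance(self, phantom_batch):
        out, masks, prov = preprocess_pipeline(phantom_batch[1]["image"])
        assert out.shape == (224, 224, 3)
        assert prov["stages"] == [
            "denoise", "gamma", "clahe", "padding_removal",
            "segmentation", "segmentation", "crop_resize",
        ]
        assert not (masks["cup"] & ~masks["disc"]).any()

    def test_segmentation_failure_names_stage(self):
        flat = np.full((128, 128, 3), 0, dtype=np.uint8)  # nothing to segment
        with pytest.raises(PipelineStageError):
            preprocess_pipeline(flat)
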