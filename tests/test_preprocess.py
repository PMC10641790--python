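"""Preprocessing chain: normalization, resampling, elastic warps, patches."""

import numpy as np
import pytest

from mslesionseg import (
    ElasticParams,
    LabelGrid,
    PatchSamplingConfig,
    VolumeGrid,
    build_training_patches,
    elastic_augment,
    resample_isotropic,
    resample_label_isotropic,
    sample_patches,
    znormalize,
)
from mslesionseg.preprocess import DegenerateVolumeError


def _vol(arr, spacing=(1.0, 1.0, 1.0)):
    return VolumeGrid(np.asarray(arr, dtype=float), spacing)


class TestZnormalize:
    def test_three_values(self):
        """{1,2,3} -> {-1.2247, 0, +1.2247} with population SD."""
        arr = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1) * np.ones((3, 2, 2))
        out = znormalize(_vol(arr))
        expected = np.array([-1.22474487, 0.0, 1.22474487])
        assert np.allclose(np.unique(np.round(out.intensities, 8)), np.round(expected, 8))
        assert abs(out.intensities.mean()) < 1e-6
        assert abs(out.intensities.std() - 1) < 1e-6

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        v = _vol(rng.standard_normal((6, 6, 6)))
        once = znormalize(v)
        twice = znormalize(once)
        assert np.allclose(once.intensities, twice.intensities, atol=1e-6)

    def test_constant_volume_raises(self):
        with pytest.raises(DegenerateVolumeError):
            znormalize(_vol(np.full((4, 4, 4), 3.0)))


class TestResample:
    def test_identity_at_target_spacing(self):
        rng = np.random.default_rng(1)
        v = _vol(rng.standard_normal((8, 8, 8)))
        out = resample_isotropic(v, 1.0)
        assert np.array_equal(out.intensities, v.intensities)

    def test_shape_formula(self):
        v = _vol(np.zeros((8, 8, 8)), spacing=(2.0, 2.0, 2.0))
        out = resample_isotropic(v, 1.0)
        assert out.shape == (16, 16, 16)
        assert out.spacing_mm == (1.0, 1.0, 1.0)

    def test_linear_ramp_oracle(self):
        """Trilinear resampling of a linear ramp is exact away from borders."""
        n = 10
        ramp = np.arange(n)[:, None, None] * 2.0 * np.ones((n, n, n))  # f(x)=2x at 2mm spacing
        v = _vol(ramp, spacing=(2.0, 2.0, 2.0))
        out = resample_isotropic(v, 1.0)
        x_phys = np.arange(out.shape[0]) * 1.0
        expected = x_phys  # f = 2 * (x_phys / 2)
        interior = slice(0, 2 * (n - 1))  # beyond the last input voxel is extrapolated
        assert np.allclose(out.intensities[interior, 5, 5], expected[interior], atol=1e-6)

    def test_label_nearest_stays_binary(self):
        lab = LabelGrid((np.arange(6**3).reshape(6, 6, 6) % 2).astype(np.int16), (2.0, 2.0, 2.0))
        out = resample_label_isotropic(lab, 1.0)
        assert out.shape == (12, 12, 12)
        assert set(np.unique(out.labels)) <= {0, 1}

    def test_bad_target(self):
        with pytest.raises(ValueError):
            resample_isotropic(_vol(np.zeros((4, 4, 4))), -1.0)


class TestElastic:
    def test_zero_displacement_is_identity(self, ms_study):
        img, lab = ms_study.image, ms_study.lesion_mask
        out_img, out_lab = elastic_augment(img, lab, ElasticParams(displacement_sd_mm=0.0), seed=0)
        assert np.array_equal(out_img.intensities, img.intensities)
        assert np.array_equal(out_lab.labels, lab.labels)

    def test_label_stays_binary_and_deterministic(self, ms_study):
        params = ElasticParams(displacement_sd_mm=1.5)
        _, lab1 = elastic_augment(ms_study.image, ms_study.lesion_mask, params, seed=3)
        _, lab2 = elastic_augment(ms_study.image, ms_study.lesion_mask, params, seed=3)
        assert set(np.unique(lab1.labels)) <= {0, 1}
        assert np.array_equal(lab1.labels, lab2.labels)

    def test_volume_approximately_conserved(self):
        """A smooth 1mm-SD warp changes a 5mm sphere's voxel count < 30%."""
        shape = (24, 24, 24)
        X, Y, Z = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
        sphere = ((X - 12) ** 2 + (Y - 12) ** 2 + (Z - 12) ** 2 <= 25).astype(np.int16)
        img = VolumeGrid(sphere.astype(float))
        lab = LabelGrid(sphere)
        n0 = sphere.sum()
        params = ElasticParams(displacement_sd_mm=1.0)
        for seed in range(20):
            _, warped = elastic_augment(img, lab, params, seed)
            assert abs(int(warped.labels.sum()) - n0) <= 0.3 * n0


class TestSamplePatches:
    def test_stratified_counts(self, ms_study):
        img, lab = znormalize(ms_study.image), ms_study.lesion_mask
        cfg = PatchSamplingConfig(16, 12, 8, 1)
        patches = sample_patches(img, lab, cfg, seed=0)
        assert len(patches) == 20
        n_lesion = sum(p.label_patch.sum() > 0 for p in patches)
        assert n_lesion == 12
        assert sum(p.label_patch.sum() == 0 for p in patches) == 8

    def test_empty_label_raises(self, ms_study):
        empty = ms_study.lesion_mask.copy(labels=np.zeros_like(ms_study.lesion_mask.labels))
        with pytest.raises(ValueError):
            sample_patches(znormalize(ms_study.image), empty, PatchSamplingConfig(16, 1, 0, 1), 0)

    def test_bounds(self, ms_study):
        img, lab = znormalize(ms_study.image), ms_study.lesion_mask
        cfg = PatchSamplingConfig(16, 10, 10, 1)
        for p in sample_patches(img, lab, cfg, seed=1):
            start = [min(max(c - 8, 0), n - 16) for c, n in zip(p.center_voxel, img.shape)]
            assert all(0 <= s and s + 16 <= n for s, n in zip(start, img.shape))
            assert p.image_patch.shape == (16, 16, 16)

    def test_patch_too_large(self, ms_study):
        with pytest.raises(ValueError):
            sample_patches(
                znormalize(ms_study.image), ms_study.lesion_mask, PatchSamplingConfig(64, 1, 1, 1), 0
            )


class TestBuildTrainingPatches:
    def test_patch_count_scaling(self, ms_study):
        img, lab = znormalize(ms_study.image), ms_study.lesion_mask
        cfg = PatchSamplingConfig(16, 5, 5, 3)
        one = build_training_patches([(img, lab)], cfg, ElasticParams(), 0)
        assert len(one) == 30  # (5+5) * 3
        two = build_training_patches([(img, lab), (img, lab)], cfg, ElasticParams(), 0)
        assert len(two) == 60

    def test_no_augmentation_collapses_to_sampled(self, ms_study):
        img, lab = znormalize(ms_study.image), ms_study.lesion_mask
        cfg = PatchSamplingConfig(16, 5, 5, 1)
        out = build_training_patches([(img, lab)], cfg, ElasticParams(), 0)
        assert len(out) == 10
        assert {p.augmentation_id for p in out} == {0}

    def test_identity_augmentation_stratification_exact(self, ms_study):
        img, lab = znormalize(ms_study.image), ms_study.lesion_mask
        cfg = PatchSamplingConfig(16, 7, 5, 3)
        out = build_training_patches([(img, lab)], cfg, ElasticParams(), 2)
        aug0 = [p for p in out if p.augmentation_id == 0]
        assert sum(p.label_patch.sum() > 0 for p in aug0) == 7

    def test_warped_copies_mostly_keep_lesions(self, ms_study):
        img, lab = znormalize(ms_study.image), ms_study.lesion_mask
        cfg = PatchSamplingConfig(16, 10, 0, 3)
        hits = total = 0
        for seed in range(5):
            out = build_training_patches([(img, lab)], cfg, ElasticParams(), seed)
            warped = [p for p in out if p.augmentation_id > 0]
            hits += sum(p.label_patch.sum() > 0 for p in warped)
            total += len(warped)
        assert hits / total >= 0.95

    def test_multichannel_patches(self, ms_study):
        img, lab = znormalize(ms_study.image), ms_study.lesion_mask
        cfg = PatchSamplingConfig(16, 3, 3, 2)
        out = build_training_patches([([img, img], lab)], cfg, ElasticParams(), 0)
        assert len(out) == 12
        assert out[0].image_patch.shape == (2, 16, 16, 16)

    def test_empty_study_list(self):
        with pytest.raises(ValueError):
            build_training_patches([], PatchSamplingConfig(16, 1, 1, 1), ElasticParams(), 0)
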