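"""Phantom generator: determinism, exact ground truth, domain structure."""

import numpy as np
import pytest

from mslesionseg import (
    LabelGrid,
    PhantomConfig,
    benchmark_config,
    generate_contrast_pair,
    generate_longitudinal_pair,
    generate_study,
    write_study,
)
from mslesionseg.grids import load_label, load_volume
from mslesionseg.phantom import PlacementError, read_sidecar
from mslesionseg.transforms import apply_to_label


def flood_fill_components(mask):
    """Independent 26-connectivity component counter (BFS flood fill)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    count = 0
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    for idx in zip(*np.nonzero(mask)):
        if seen[idx]:
            continue
        count += 1
        stack = [idx]
        seen[idx] = True
        while stack:
            p = stack.pop()
            for o in offsets:
                q = tuple(a + b for a, b in zip(p, o))
                if all(0 <= v < n for v, n in zip(q, mask.shape)) and mask[q] and not seen[q]:
                    seen[q] = True
                    stack.append(q)
    return count


class TestGenerateStudy:
    def test_deterministic(self, ms_config):
        a = generate_study(ms_config, 3)
        b = generate_study(ms_config, 3)
        assert np.array_equal(a.image.intensities, b.image.intensities)
        assert np.array_equal(a.lesion_mask.labels, b.lesion_mask.labels)

    def test_zero_lesions(self, ms_config):
        import dataclasses

        cfg = dataclasses.replace(ms_config, lesion_count_range=(0, 0))
        s = generate_study(cfg, 1)
        assert s.lesion_mask.labels.sum() == 0

    @pytest.mark.parametrize("n", [1, 5])
    def test_component_count_matches_flood_fill_oracle(self, ms_config, n):
        import dataclasses

        cfg = dataclasses.replace(ms_config, lesion_count_range=(n, n))
        s = generate_study(cfg, 11)
        assert flood_fill_components(s.lesion_mask.labels) == n
        assert len(s.lesion_centers) == n

    def test_count_drawn_from_range(self, ms_config):
        counts = {flood_fill_components(generate_study(ms_config, s).lesion_mask.labels) for s in range(8)}
        lo, hi = ms_config.lesion_count_range
        assert all(lo <= c <= hi for c in counts)

    def test_placement_failure_is_explicit(self):
        cfg = benchmark_config("ms_focal", lesion_count_range=(60, 60), max_placement_attempts=20)
        with pytest.raises(PlacementError):
            generate_study(cfg, 0)

    def test_geographic_blobs_are_large(self, source_config):
        from mslesionseg.phantom import _ellipsoid_mask

        s = generate_study(source_config, 4)
        brain = _ellipsoid_mask(source_config, source_config.brain_axes_mm)
        assert s.lesion_mask.labels.sum() >= 0.05 * brain.sum()
        assert 1 <= flood_fill_components(s.lesion_mask.labels) <= 2

    def test_separability(self, ms_config):
        """Threshold at tissue_mean + contrast/2 recovers >= 90% of lesion voxels."""
        recoveries = []
        thr = ms_config.tissue_mean + ms_config.lesion_contrast / 2
        for s in range(5):
            st = generate_study(ms_config, s)
            les = st.lesion_mask.labels > 0
            recoveries.append((st.image.intensities[les] > thr).mean())
        assert min(recoveries) >= 0.90


class TestLongitudinalPair:
    def test_null_change_pair(self, ms_config):
        import dataclasses

        cfg = dataclasses.replace(ms_config, rigid_jitter=(0.0, 0.0))
        pair = generate_longitudinal_pair(cfg, 0, 21)
        # identical anatomy and lesions; only the noise realization differs
        assert np.array_equal(pair.baseline.lesion_mask.labels, pair.follow_up.lesion_mask.labels)
        diff = pair.follow_up.image.intensities - pair.baseline.image.intensities
        assert abs(diff.mean()) < 4 * cfg.noise_sd / np.sqrt(diff.size) * 2
        assert diff.std() == pytest.approx(np.sqrt(2) * cfg.noise_sd, rel=0.1)

    def test_new_lesions_disjoint_from_baseline(self, ms_config):
        pair = generate_longitudinal_pair(ms_config, 3, 22)
        assert flood_fill_components(pair.new_lesion_mask.labels) == 3
        base_in_follow = apply_to_label(pair.baseline.lesion_mask, pair.applied_transform)
        overlap = (base_in_follow.labels > 0) & (pair.new_lesion_mask.labels > 0)
        assert overlap.sum() == 0

    def test_applied_transform_recorded(self, ms_config):
        pair = generate_longitudinal_pair(ms_config, 1, 23)
        t = pair.applied_transform
        tmax, rmax = ms_config.rigid_jitter
        assert all(abs(v) <= tmax for v in t.translation_mm)
        assert all(abs(v) <= rmax for v in t.rotation_deg)
        # the follow-up is the transformed scene: mapping all-lesion mask back
        # into baseline space must recover the baseline lesions
        all_back = apply_to_label(pair.follow_up.lesion_mask, t.inverse())
        base = pair.baseline.lesion_mask.labels > 0
        recovered = (all_back.labels > 0) & base
        assert recovered.sum() >= 0.8 * base.sum()

    def test_follow_up_is_union_of_persistent_and_new(self, ms_config):
        pair = generate_longitudinal_pair(ms_config, 2, 24)
        follow = pair.follow_up.lesion_mask.labels > 0
        new = pair.new_lesion_mask.labels > 0
        assert (new & ~follow).sum() == 0  # new lesions are part of the follow-up set


class TestContrastPair:
    def test_null_pair_difference(self, ms_config):
        import dataclasses

        cfg = dataclasses.replace(ms_config, distractor_on=False)
        pair = generate_contrast_pair(cfg, 0, 31)
        diff = pair.post.intensities - pair.pre.intensities
        assert abs(diff.mean()) < 3 * cfg.noise_sd / np.sqrt(diff.size)

    def test_enhancing_component_count(self, ms_config):
        pair = generate_contrast_pair(ms_config, 2, 32)
        assert flood_fill_components(pair.enhancing_mask.labels) == 2

    def test_distractor_bright_and_excluded(self):
        cfg = benchmark_config("source_enhancing_foci", distractor_on=True)
        pair = generate_contrast_pair(cfg, 3, 33)
        d = pair.distractor_mask.labels > 0
        e = pair.enhancing_mask.labels > 0
        assert d.sum() > 0
        assert (d & e).sum() == 0
        diff = pair.post.intensities - pair.pre.intensities
        assert diff[d].mean() > cfg.distractor_contrast / 2
        assert diff[e].mean() > cfg.lesion_contrast / 2


class TestWriteStudy:
    def test_round_trip(self, tmp_path, ms_study):
        paths = write_study(ms_study, tmp_path)
        img = load_volume(paths["image"])
        msk = load_label(paths["lesion_mask"])
        assert np.allclose(img.intensities, ms_study.image.intensities, atol=1e-6)
        assert np.array_equal(msk.labels, ms_study.lesion_mask.labels)
        assert img.spacing_mm == ms_study.image.spacing_mm
        assert set(np.unique(msk.labels)) <= {0, 1}
        meta = read_sidecar(tmp_path)
        assert meta["seed"] == ms_study.seed

    def test_affine_diagonal_is_spacing(self, tmp_path, ms_study):
        import nibabel as nib

        paths = write_study(ms_study, tmp_path)
        aff = nib.load(paths["image"]).affine
        assert np.allclose(np.diag(aff)[:3], ms_study.image.spacing_mm)


def test_config_validation():
    with pytest.raises(ValueError):
        PhantomConfig(grid_shape=(8, 64, 64))
    with pytest.raises(ValueError):
        PhantomConfig(lesion_count_range=(3, 1))
    with pytest.raises(ValueError):
        PhantomConfig(lesion_radius_range_mm=(0, 2))
    with pytest.raises(ValueError):
        PhantomConfig(lesion_radius_range_mm=(2, 40))
    with pytest.raises(ValueError):
        PhantomConfig(domain="unknown")
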