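"""Reference thresholds and lesion extraction against brute-force oracles."""

import numpy as np
import pytest

from psmaquant import (
    NoMeasurableLesionError,
    SUVVolume,
    generate_phantom,
    hottest_lesion,
    liver_reference,
    aorta_reference,
    segment_lesions,
)
from psmaquant.segmentation import Lesion

from conftest import flood_fill_components


def _uniform_volume(value=5.0, shape=(26, 26, 26), spacing=(4.0, 4.0, 4.0)):
    return SUVVolume(np.full(shape, value), voxel_size_mm=spacing)


class TestReferenceRegions:
    def test_uniform_liver_threshold(self):
        # SUV 5 everywhere: mean 5, SD 0, threshold 1.5·5 + 2·0 = 7.5
        ref = liver_reference(_uniform_volume(5.0), (52.0, 52.0, 52.0))
        assert ref.mean_suv == pytest.approx(5.0)
        assert ref.sd_suv == 0.0
        assert ref.threshold_suv == pytest.approx(7.5)
        assert ref.region_kind == "liver_sphere"

    def test_uniform_aorta_threshold(self):
        # SUV 2 everywhere: threshold 2·2 + 2·0 = 4.0
        vol = _uniform_volume(2.0, shape=(30, 30, 30), spacing=(2.0, 2.0, 2.0))
        ref = aorta_reference(vol, (30.0, 30.0, 30.0))
        assert ref.threshold_suv == pytest.approx(4.0)
        assert ref.region_kind == "aorta_cylinder"

    def test_liver_statistics_match_voxel_enumeration(self, two_sphere_phantom):
        vol, _ = two_sphere_phantom
        center = (96.0, 96.0, 96.0)
        ref = liver_reference(vol, center)
        # brute force: loop over voxel centres, collect those inside the sphere
        vals = []
        for i in range(vol.shape[0]):
            for j in range(vol.shape[1]):
                for k in range(vol.shape[2]):
                    c = ((i + 0.5) * 4.0, (j + 0.5) * 4.0, (k + 0.5) * 4.0)
                    if sum((a - b) ** 2 for a, b in zip(c, center)) <= 15.0**2:
                        vals.append(vol.data[i, j, k])
        vals = np.array(vals)
        assert ref.n_voxels == vals.size
        assert ref.mean_suv == pytest.approx(vals.mean(), rel=1e-12)
        assert ref.sd_suv == pytest.approx(vals.std(ddof=1), rel=1e-12)
        assert ref.threshold_suv == pytest.approx(1.5 * vals.mean() + 2 * vals.std(ddof=1))

    def test_aorta_statistics_match_voxel_enumeration(self):
        rng = np.random.default_rng(21)
        vol = SUVVolume(rng.uniform(1.5, 2.5, (40, 40, 40)), voxel_size_mm=(2.0,) * 3)
        center = (40.0, 40.0, 40.0)
        ref = aorta_reference(vol, center)
        vals = []
        for i in range(40):
            for j in range(40):
                for k in range(40):
                    x, y, z = (i + 0.5) * 2, (j + 0.5) * 2, (k + 0.5) * 2
                    if (x - 40) ** 2 + (y - 40) ** 2 <= 5.0**2 and abs(z - 40) <= 10.0:
                        vals.append(vol.data[i, j, k])
        vals = np.array(vals)
        assert ref.n_voxels == vals.size
        assert ref.mean_suv == pytest.approx(vals.mean(), rel=1e-12)
        assert ref.threshold_suv == pytest.approx(2 * vals.mean() + 2 * vals.std(ddof=1))

    def test_reference_sphere_must_fit_inside_volume(self):
        vol = _uniform_volume(5.0, shape=(10, 10, 10))
        with pytest.raises(ValueError, match="outside"):
            liver_reference(vol, (8.0, 20.0, 20.0))


class TestSegmentLesions:
    def test_empty_when_nothing_above_threshold(self):
        assert segment_lesions(_uniform_volume(1.0), threshold_suv=5.0) == []

    def test_single_cube_lesion_metrics(self, box_lesion_spec):
        vol, _ = generate_phantom(box_lesion_spec)
        (lesion,) = segment_lesions(vol, threshold_suv=9.5)
        assert lesion.voxel_count == 27
        assert lesion.volume_cm3 == pytest.approx(1.728)
        assert lesion.suv_mean == pytest.approx(10.0)
        assert lesion.suv_max == pytest.approx(10.0)
        assert lesion.centroid_mm == pytest.approx((30.0, 30.0, 30.0))

    def test_threshold_is_inclusive(self):
        data = np.full((5, 5, 5), 1.0)
        data[2, 2, 2] = 4.0
        vol = SUVVolume(data, voxel_size_mm=(2.0,) * 3)
        (lesion,) = segment_lesions(vol, threshold_suv=4.0)
        assert lesion.voxel_count == 1

    def test_components_match_flood_fill_oracle(self, two_sphere_phantom):
        vol, truths = two_sphere_phantom
        threshold = 9.0  # above liver and background, below both lesion peaks
        lesions = segment_lesions(vol, threshold)
        oracle = flood_fill_components(vol.data >= threshold)
        assert sorted(l.voxel_count for l in lesions) == sorted(len(c) for c in oracle)
        assert len(lesions) == len(truths) == 2

    def test_noise_free_recovery_is_exact(self, two_sphere_phantom):
        vol, truths = two_sphere_phantom
        lesions = segment_lesions(vol, threshold_suv=9.0)
        # hotter lesion sorts first
        assert [l.voxel_count for l in lesions] == [t.voxel_count for t in truths]
        assert [l.volume_cm3 for l in lesions] == pytest.approx(
            [t.volume_cm3 for t in truths])

    def test_exclusion_mask_removes_physiological_uptake(self, two_sphere_phantom):
        vol, _ = two_sphere_phantom
        exclude = np.zeros(vol.shape, dtype=bool)
        hot = segment_lesions(vol, 9.0)[0]
        idx = tuple(int(c / s) for c, s in zip(hot.centroid_mm, vol.voxel_size_mm))
        exclude[idx[0] - 5:idx[0] + 6, idx[1] - 5:idx[1] + 6, idx[2] - 5:idx[2] + 6] = True
        remaining = segment_lesions(vol, 9.0, exclude=exclude)
        assert len(remaining) == 1
        assert remaining[0].suv_max < hot.suv_max

    def test_min_voxels_drops_specks(self):
        data = np.full((10, 10, 10), 1.0)
        data[1, 1, 1] = 9.0                 # single-voxel speck
        data[5:8, 5:8, 5:8] = 9.0           # 27-voxel lesion
        vol = SUVVolume(data, voxel_size_mm=(4.0,) * 3)
        assert len(segment_lesions(vol, 8.0)) == 2
        lesions = segment_lesions(vol, 8.0, min_voxels=2)
        assert [l.voxel_count for l in lesions] == [27]

    def test_volume_conservation(self, two_sphere_phantom):
        vol, _ = two_sphere_phantom
        threshold = 4.0  # liver also supra-threshold: three components
        lesions = segment_lesions(vol, threshold)
        assert sum(l.voxel_count for l in lesions) == int((vol.data >= threshold).sum())

    def test_threshold_monotonicity(self, two_sphere_phantom):
        vol, _ = two_sphere_phantom
        totals = []
        for threshold in np.linspace(1.0, 16.0, 16):
            lesions = segment_lesions(vol, threshold)
            totals.append(sum(l.volume_cm3 for l in lesions))
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_deterministic_ordering_by_suvmax_then_centroid(self):
        data = np.full((12, 12, 12), 0.1)
        data[1, 1, 1] = 5.0
        data[8, 8, 8] = 5.0
        data[4, 4, 4] = 7.0
        vol = SUVVolume(data, voxel_size_mm=(4.0,) * 3)
        lesions = segment_lesions(vol, 4.0)
        assert [l.suv_max for l in lesions] == [7.0, 5.0, 5.0]
        # tie broken by ascending centroid
        assert lesions[1].centroid_mm < lesions[2].centroid_mm
        assert [l.lesion_id for l in lesions] == [1, 2, 3]

    def test_blurred_noisy_phantom_recovery_within_tolerance(self, two_sphere_spec):
        # psf 2 mm, noise SD 0.1: total recovered volume within 15% of truth
        from dataclasses import replace
        spec = replace(two_sphere_spec, psf_sigma_mm=2.0, noise_sd=0.1, seed=42)
        vol, truths = generate_phantom(spec)
        ref = liver_reference(vol, spec.liver_center_mm)
        lesions = segment_lesions(vol, ref.threshold_suv, min_voxels=2)
        recovered = sum(l.volume_cm3 for l in lesions)
        true_total = sum(t.volume_cm3 for t in truths)
        assert recovered == pytest.approx(true_total, rel=0.15)


class TestHottestLesion:
    def _lesion(self, lesion_id, suv_max):
        return Lesion(lesion_id, 10, 0.64, suv_max / 2, suv_max, (0.0, 0.0, 0.0))

    def test_singleton(self):
        l = self._lesion(1, 8.0)
        assert hottest_lesion([l]) is l

    def test_picks_maximum(self):
        lesions = [self._lesion(i, s) for i, s in enumerate((8.0, 12.0, 9.0), 1)]
        assert hottest_lesion(lesions).suv_max == 12.0

    def test_tie_broken_by_lowest_id(self):
        lesions = [self._lesion(2, 9.0), self._lesion(1, 9.0)]
        assert hottest_lesion(lesions).lesion_id == 1

    def test_agrees_with_linear_scan(self):
        rng = np.random.default_rng(33)
        lesions = [self._lesion(i, float(s))
                   for i, s in enumerate(rng.uniform(2, 30, 100), 1)]
        best = max(lesions, key=lambda l: l.suv_max)
        assert hottest_lesion(lesions) is best

    def test_empty_list_raises(self):
        with pytest.raises(NoMeasurableLesionError):
            hottest_lesion([])
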