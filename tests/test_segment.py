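"""Background subtraction and nucleus segmentation."""

import numpy as np
import pytest

from gammahq import (
    LabelMap,
    SegmentationParams,
    filter_labels,
    generate_field,
    segment_nuclei,
    subtract_background,
)


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestSubtractBackground:
    def test_constant_background_fully_removed(self):
        img = np.full((64, 64), 7, dtype=np.uint8)
        out = subtract_background(img, "median", radius=5)
        assert np.all(out == 0)

    def test_none_is_identity(self):
        img = np.arange(64, dtype=np.uint8).reshape(8, 8)
        out = subtract_background(img, "none")
        assert np.array_equal(out, img)
        assert out.dtype == float

    def test_rolling_ball_preserves_disk_excess_over_ramp(self):
        # planar ramp + a small bright disk; the disk should keep >= 90% of
        # its excess over the local (analytically known) ramp
        shape = (128, 128)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        ramp = 20.0 + 0.1 * cc
        disk = disk_mask(shape, (64, 64), 5)
        img = ramp + 100.0 * disk
        out = subtract_background(img, "rolling_ball", radius=30)
        excess = out[disk]
        assert np.all(excess >= 0.9 * 100.0)

    def test_output_non_negative(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (64, 64)).astype(np.uint8)
        for method in ("median", "rolling_ball"):
            assert subtract_background(img, method, radius=5).min() >= 0

    def test_radius_exceeding_image_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            subtract_background(np.zeros((20, 20)), "median", radius=15)


class TestSegmentNuclei:
    def test_recovers_noise_free_disks_exactly(self, quiet_field):
        params, pair, truth = quiet_field
        lm = segment_nuclei(pair.dapi)
        assert lm.n_labels == len(truth.cells)

    def test_all_background_image_yields_empty_map(self):
        lm = segment_nuclei(np.zeros((64, 64), dtype=np.uint8))
        assert lm.n_labels == 0
        assert np.all(lm.labels == 0)

    def test_split_touching_separates_merged_disks(self):
        # two disks merged into one blob, centers ~1.5 radii apart
        shape = (96, 96)
        radius = 10
        blob = disk_mask(shape, (48, 40), radius) | disk_mask(shape, (48, 55), radius)
        img = (100 * blob).astype(np.uint8) + 5
        merged = segment_nuclei(
            img, SegmentationParams(split_touching=False, exclude_border=False)
        )
        assert merged.n_labels == 1
        split = segment_nuclei(
            img,
            SegmentationParams(
                split_touching=True, split_min_distance=5, exclude_border=False
            ),
        )
        assert split.n_labels == 2

    def test_labels_pairwise_disjoint_and_consecutive(self, field_params):
        pair, _ = generate_field(field_params(rng_seed=13))
        lm = segment_nuclei(pair.dapi)
        present = np.unique(lm.labels)
        assert np.array_equal(present[present > 0], np.arange(1, lm.n_labels + 1))
        # disjointness is structural for a single label image: each pixel has
        # exactly one label; verify areas sum to the foreground pixel count
        areas = np.bincount(lm.labels.ravel())[1:]
        assert areas.sum() == (lm.labels > 0).sum()

    def test_border_touching_nuclei_excluded(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        img[disk_mask(img.shape, (0, 32), 8)] = 100  # clipped at the top edge
        img[disk_mask(img.shape, (32, 32), 8)] = 100
        keep = SegmentationParams(exclude_border=False, min_area=10)
        drop = SegmentationParams(exclude_border=True, min_area=10)
        assert segment_nuclei(img, keep).n_labels == 2
        assert segment_nuclei(img, drop).n_labels == 1


class TestFilterLabels:
    def make_map(self, areas):
        lbl = np.zeros((40, 120), dtype=np.int32)
        col = 0
        for i, area in enumerate(areas, start=1):
            w = max(1, area // 10)
            h = int(np.ceil(area / w))
            lbl[1 : 1 + h, col : col + w].flat[:area] = i
            col += w + 2
        return LabelMap.from_labels(lbl)

    def test_min_area_larger_than_everything_empties_map(self):
        lm = self.make_map([10, 50])
        assert filter_labels(lm, min_area=1000).n_labels == 0

    def test_identity_filter_preserves_count(self):
        lm = self.make_map([10, 50, 500])
        assert filter_labels(lm, min_area=1).n_labels == 3

    def test_area_window_keeps_single_region(self):
        lm = self.make_map([10, 50, 500])
        out = filter_labels(lm, min_area=20, max_area=100)
        assert out.n_labels == 1
        assert (np.bincount(out.labels.ravel())[1:] == [50]).all()

    @pytest.mark.parametrize("min_area", [1, 20, 60, 1000])
    def test_raising_min_area_never_increases_count(self, min_area):
        lm = self.make_map([10, 50, 500])
        assert filter_labels(lm, min_area=min_area).n_labels <= lm.n_labels

    def test_survivors_relabeled_consecutively(self):
        lm = self.make_map([10, 50, 500])
        out = filter_labels(lm, min_area=20)
        present = np.unique(out.labels)
        assert np.array_equal(present, [0, 1, 2])
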