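"""Still-image counting: preprocessing, filtering, and declumping."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from flowcount import StillCountParams, StillSceneSpec, \
    apply_intensity_filter, count_fluorescent_objects, generate_bead_image, \
    naive_connected_count, preprocess_fluorescence


def _isolated_extrema(img, margin=40):
    """Single pixels exceeding every 8-neighbour by more than ``margin``."""
    img = img.astype(int)
    ring = np.ones((3, 3), bool)
    ring[1, 1] = False
    nb_max = ndi.maximum_filter(img, footprint=ring)
    nb_min = ndi.minimum_filter(img, footprint=ring)
    hi = img - nb_max > margin
    lo = nb_min - img > margin
    return int(hi.sum() + lo.sum())


class TestPreprocess:
    def test_constant_image_stays_uniform(self):
        img = np.full((128, 128), 77, np.uint8)
        out = preprocess_fluorescence(img)
        assert out.shape == img.shape
        assert len(np.unique(out)) == 1

    def test_levels_illumination_gradient(self):
        """A 40-level background ramp is flattened by the top-hat."""
        spec = StillSceneSpec(n_objects=30, background_gradient=40.0, seed=8)
        img, _ = generate_bead_image(spec)
        out = preprocess_fluorescence(img)
        w = img.shape[1]
        thirds = [np.s_[:, :w // 3], np.s_[:, w // 3:2 * w // 3],
                  np.s_[:, 2 * w // 3:]]
        med_in = [np.median(img[s]) for s in thirds]
        med_out = [np.median(out[s]) for s in thirds]
        assert max(med_in) - min(med_in) > 20   # ramp visible before
        assert max(med_out) - min(med_out) < 5  # levelled after

    def test_median_removes_salt_and_pepper(self):
        rng = np.random.default_rng(0)
        img = np.full((256, 256), 100, np.uint8)
        idx = rng.choice(img.size, size=int(0.01 * img.size), replace=False)
        img.flat[idx[: len(idx) // 2]] = 255
        img.flat[idx[len(idx) // 2:]] = 0
        assert _isolated_extrema(img) > 100
        out = preprocess_fluorescence(img)
        assert _isolated_extrema(out) == 0

    def test_rejects_image_smaller_than_kernel(self):
        with pytest.raises(ValueError, match="smaller than"):
            preprocess_fluorescence(np.zeros((10, 10), np.uint8))

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            preprocess_fluorescence(np.zeros((64, 64), np.uint8),
                                    StillCountParams(median_kernel=4))


class TestIntensityFilter:
    @pytest.mark.parametrize("img,rng_,expected", [
        (np.array([[50, 100, 150]], np.uint8), (40, 200),
         np.array([[50, 100, 150]], np.uint8)),      # all in range
        (np.array([[10, 20, 30]], np.uint8), (40, 200),
         np.zeros((1, 3), np.uint8)),                # all below
        (np.array([[255, 180, 90]], np.uint8), (100, 220),
         np.array([[0, 180, 0]], np.uint8)),         # hot pixel zeroed
    ])
    def test_windowing(self, img, rng_, expected):
        assert np.array_equal(apply_intensity_filter(img, rng_), expected)

    def test_rejects_inverted_range(self):
        with pytest.raises(ValueError):
            apply_intensity_filter(np.zeros((2, 2), np.uint8), (200, 100))

    def test_hot_pixels_removed_from_count(self):
        """Saturated speckle is excluded by the expected-intensity window."""
        spec = StillSceneSpec(n_objects=20, peak_intensity=180, seed=6)
        img, _ = generate_bead_image(spec)
        rng = np.random.default_rng(1)
        hot = img.copy()
        rr = rng.integers(20, hot.shape[0] - 20, 40)
        cc = rng.integers(20, hot.shape[1] - 20, 40)
        for r, c in zip(rr, cc):
            hot[r:r + 9, c:c + 9] = 255
        params = StillCountParams(intensity_range=(100, 220))
        assert count_fluorescent_objects(hot, params).count == 20
        # without the window the saturated speckle inflates the count
        assert count_fluorescent_objects(hot).count > 20


class TestCounting:
    def test_blank_image_counts_zero(self):
        img, _ = generate_bead_image(StillSceneSpec(n_objects=0, seed=2))
        assert count_fluorescent_objects(img).count == 0

    def test_disjoint_scene_counts_exact(self):
        spec = StillSceneSpec(n_objects=50, clump_fraction=0.0, seed=12)
        img, _ = generate_bead_image(spec)
        res = count_fluorescent_objects(img)
        assert res.count == 50
        assert res.centroids.shape == (50, 2)

    def test_centroids_near_truth_on_disjoint_scene(self):
        spec = StillSceneSpec(n_objects=30, clump_fraction=0.0, seed=14)
        img, gt = generate_bead_image(spec)
        res = count_fluorescent_objects(img)
        truth = gt.centers(0)
        d = np.linalg.norm(res.centroids[:, None] - truth[None], axis=2)
        assert (d.min(axis=1) < 3.0).all()

    def test_overlapping_pair_split_where_naive_merges(self):
        """Two disks at 40% center separation: the distance-transform
        declumping counts 2 while plain connected components sees 1."""
        spec = StillSceneSpec(n_objects=2, clump_fraction=1.0,
                              overlap_fraction=0.4, radius_mean=12.0,
                              radius_sd=0.0, image_width=256,
                              image_height=256, seed=21)
        img, _ = generate_bead_image(spec)
        assert naive_connected_count(img) == 1
        assert count_fluorescent_objects(img).count == 2

    def test_count_invariant_under_global_intensity_shift(self):
        spec = StillSceneSpec(n_objects=40, background_level=10,
                              peak_intensity=180, seed=31)
        img, _ = generate_bead_image(spec)
        shifted = (img.astype(int) + 20).clip(0, 255).astype(np.uint8)
        assert count_fluorescent_objects(img).count == \
            count_fluorescent_objects(shifted).count

    def test_count_monotone_in_min_object_area(self):
        spec = StillSceneSpec(n_objects=40, seed=33)
        img, _ = generate_bead_image(spec)
        counts = [count_fluorescent_objects(
            img, StillCountParams(min_object_area=a)).count
            for a in (10, 100, 300, 400, 1000)]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 40
        assert counts[-1] == 0
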