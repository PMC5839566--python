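"""Generator contracts: reproducibility, ground-truth geometry, contrast."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from flowcount import FlowSceneSpec, StillSceneSpec, generate_bead_image, \
    generate_flow_video
from flowcount.synthetic import noiseless_bead_mask, object_silhouette


class TestStillScenes:
    def test_reproducible_for_fixed_seed(self):
        a, _ = generate_bead_image(StillSceneSpec(n_objects=30, seed=5))
        b, _ = generate_bead_image(StillSceneSpec(n_objects=30, seed=5))
        c, _ = generate_bead_image(StillSceneSpec(n_objects=30, seed=6))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_empty_scene_is_noise_only(self):
        spec = StillSceneSpec(n_objects=0, seed=1)
        img, gt = generate_bead_image(spec)
        assert gt.n_true_objects == 0
        assert img.shape == (spec.image_height, spec.image_width)
        # nothing brighter than background + noise tail
        assert img.max() < spec.background_level + 6 * spec.noise_sd

    @pytest.mark.parametrize("n", [1, 50])
    def test_ground_truth_lists_all_centers(self, n):
        img, gt = generate_bead_image(StillSceneSpec(n_objects=n, seed=2))
        centers = gt.centers(0)
        assert centers.shape == (n, 2)
        assert (centers >= 0).all()
        assert (centers[:, 0] < img.shape[0]).all()
        assert (centers[:, 1] < img.shape[1]).all()

    def test_disjoint_scene_component_oracle(self):
        """clump_fraction=0 scenes have one connected region per object."""
        spec = StillSceneSpec(n_objects=40, clump_fraction=0.0, seed=3)
        mask = noiseless_bead_mask(spec)
        assert ndi.label(mask)[1] == 40

    def test_full_clump_forms_single_region_with_all_centers(self):
        """Three fully clumped disks merge into one bright region."""
        spec = StillSceneSpec(n_objects=3, clump_fraction=1.0,
                              overlap_fraction=0.6, seed=4)
        mask = noiseless_bead_mask(spec)
        _, n = ndi.label(mask)
        assert n == 1
        _, gt = generate_bead_image(spec)
        assert gt.n_true_objects == 3

    def test_rejects_unplaceable_spec(self):
        spec = StillSceneSpec(n_objects=5, image_width=64, image_height=64,
                              radius_mean=30.0, seed=0)
        with pytest.raises(ValueError):
            generate_bead_image(spec)

    def test_rejects_bad_intensities(self):
        with pytest.raises(ValueError):
            generate_bead_image(StillSceneSpec(peak_intensity=20,
                                               background_level=30))


class TestFlowScenes:
    def test_reproducible_for_fixed_seed(self):
        spec = FlowSceneSpec(n_objects=2, n_frames=30, seed=9)
        a, _ = generate_flow_video(spec)
        b, _ = generate_flow_video(FlowSceneSpec(n_objects=2, n_frames=30,
                                                 seed=9))
        assert np.array_equal(a, b)

    def test_crossing_frame_from_constant_velocity(self):
        """An object starting at column 0 moving 5 px/frame crosses
        column 200 at frame 40."""
        spec = FlowSceneSpec(n_objects=1, velocity=5.0, velocity_jitter=0.0,
                            entry_frames=[0], start_columns=[0.0],
                            reference_column=200.0, n_frames=200, seed=0)
        _, gt = generate_flow_video(spec)
        assert gt.targets[0].crossing_frame == 40

    def test_staggered_entries_give_one_crossing_each(self):
        spec = FlowSceneSpec(n_objects=10, seed=13)
        _, gt = generate_flow_video(spec)
        crossings = gt.crossing_frames()
        assert len(crossings) == 10
        assert len(set(crossings.values())) == 10  # unique per object

    def test_debris_areas_below_bound(self):
        spec = FlowSceneSpec(n_objects=2, n_debris=20, debris_max_area=30.0,
                             seed=17)
        _, gt = generate_flow_video(spec)
        debris = [r for r in gt.object_records if r.is_debris]
        assert len(debris) == 20
        assert all(0 < r.area_px < 30.0 for r in debris)

    def test_low_contrast_mode_reduces_luminance_gap(self):
        lo_spec = FlowSceneSpec(n_objects=1, contrast_mode="low", seed=3)
        hi_spec = FlowSceneSpec(n_objects=1, contrast_mode="high", seed=3)
        gaps = {}
        for name, spec in (("low", lo_spec), ("high", hi_spec)):
            frames, gt = generate_flow_video(spec)
            f = gt.targets[0].crossing_frame
            sil = object_silhouette(spec, gt, f)
            gray = frames[f].astype(float) @ [0.2125, 0.7154, 0.0721]
            bg = np.full(sil.shape, False)
            bg[spec.channel_top + 5:spec.channel_bottom - 5] = True
            bg &= ~sil
            gaps[name] = abs(gray[sil].mean() - gray[bg].mean())
        assert gaps["low"] < gaps["high"]
        assert gaps["low"] < 15

    def test_silhouette_matches_rendered_pixels(self):
        spec = FlowSceneSpec(n_objects=1, contrast_mode="high", seed=5,
                             noise_sd=0.0)
        frames, gt = generate_flow_video(spec)
        f = gt.targets[0].crossing_frame
        sil = object_silhouette(spec, gt, f)
        dark = frames[f, ..., 0] < 120
        dark[:spec.channel_top] = False   # exclude channel walls
        dark[spec.channel_bottom:] = False
        inter = (sil & dark).sum()
        union = (sil | dark).sum()
        assert inter / union > 0.9

    def test_rejects_object_that_never_enters(self):
        spec = FlowSceneSpec(n_objects=1, n_frames=5, entry_frames=[0],
                             velocity=1.0, velocity_jitter=0.0, seed=0)
        with pytest.raises(ValueError, match="never fully enters"):
            generate_flow_video(spec)

    def test_frame_zero_is_object_free_by_default(self):
        spec = FlowSceneSpec(n_objects=4, seed=19)
        _, gt = generate_flow_video(spec)
        assert all(rec.entry_frame >= 1 for rec in gt.targets)
        assert object_silhouette(spec, gt, 0).sum() == 0
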