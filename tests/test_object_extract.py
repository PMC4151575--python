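"""Color segmentation, object selection and 3D primitive construction."""

import numpy as np
import pytest

from fesgrasp.camera_geometry import TableFrame
from fesgrasp.hand_track import HandState
from fesgrasp.object_extract import (
    ColorSegConfig,
    FlatObjectError,
    build_primitive,
    build_primitive_2d,
    extract_primitive,
    segment_objects,
    select_object,
    table_color_template,
)
from fesgrasp.scene_sim import NoiseSpec, ObjectSpec, SceneSpec, render_scene

STUDY_NOISE = NoiseSpec(3.0, True)


class TestColorTemplate:
    def test_uniform_frame(self):
        img = np.full((20, 30, 3), 128, dtype=np.uint8)
        np.testing.assert_array_equal(table_color_template(img), [128, 128, 128])

    def test_majority_color_recovered(self, rng):
        """60% brown + 40% assorted colors -> the brown median, exactly
        (channel-wise median oracle on the constructed image)."""
        img = np.empty((100, 100, 3), dtype=np.uint8)
        img[:60] = (150, 110, 80)
        img[60:] = rng.integers(0, 255, (40, 100, 3))
        tmpl = table_color_template(img)
        oracle = np.median(img.reshape(-1, 3), axis=0)
        np.testing.assert_array_equal(tmpl, oracle)
        np.testing.assert_array_equal(tmpl, [150, 110, 80])

    def test_pixel_permutation_invariant(self, rng):
        img = rng.integers(0, 255, (40, 40, 3)).astype(np.uint8)
        flat = img.reshape(-1, 3)
        shuffled = flat[rng.permutation(len(flat))].reshape(img.shape)
        np.testing.assert_array_equal(table_color_template(img), table_color_template(shuffled))


class TestSegmentation:
    def test_table_only_frame_yields_nothing(self, cam):
        _, rgb, _ = render_scene(SceneSpec(noise=STUDY_NOISE, seed=1), cam)
        assert segment_objects(rgb, table_color_template(rgb)) == []

    def test_thin_pen_segmented_with_good_iou(self, cam):
        spec = SceneSpec(
            objects=[ObjectSpec("thin_box", {"length": 150, "width": 8, "height": 8}, (50, 1000), yaw=25)],
            noise=STUDY_NOISE,
            seed=2,
        )
        _, rgb, gt = render_scene(spec, cam)
        masks = segment_objects(rgb, table_color_template(rgb))
        assert len(masks) == 1
        inter = (masks[0] & gt.object_mask(0)).sum()
        union = (masks[0] | gt.object_mask(0)).sum()
        assert inter / union >= 0.8

    def test_table_colored_object_is_invisible(self, cam):
        spec = SceneSpec(
            objects=[ObjectSpec("box", {"length": 100, "width": 60, "height": 50}, (0, 1000),
                                color=(150, 110, 80))],  # same as the table
            noise=STUDY_NOISE,
            seed=3,
        )
        _, rgb, _ = render_scene(spec, cam)
        assert segment_objects(rgb, table_color_template(rgb)) == []

    def test_segmentation_idempotent(self, cam):
        spec = SceneSpec(
            objects=[ObjectSpec("sphere", {"radius": 35}, (0, 900))], noise=STUDY_NOISE, seed=4
        )
        _, rgb, _ = render_scene(spec, cam)
        tmpl = table_color_template(rgb)
        a = segment_objects(rgb, tmpl)
        b = segment_objects(rgb, tmpl)
        assert len(a) == len(b)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma, mb)


class TestSelectObject:
    @staticmethod
    def _mask(shape, r0, c0, size):
        m = np.zeros(shape, dtype=bool)
        m[r0 : r0 + size, c0 : c0 + size] = True
        return m

    def test_largest_policy(self):
        small = self._mask((100, 100), 10, 10, 22)  # ~500 px
        large = self._mask((100, 100), 50, 50, 30)  # 900 px
        chosen = select_object([small, large], "largest")
        np.testing.assert_array_equal(chosen, large)

    def test_single_mask_any_policy(self):
        only = self._mask((50, 50), 5, 5, 10)
        np.testing.assert_array_equal(select_object([only], "largest"), only)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError, match="no object"):
            select_object([], "largest")

    def test_closest_to_hand_overrides_size(self, cam, noisy_table):
        """A small object near the hand beats a larger distant one."""
        spec = SceneSpec(
            objects=[
                ObjectSpec("box", {"length": 120, "width": 90, "height": 60}, (-300, 1100), color=(40, 80, 200)),
                ObjectSpec("box", {"length": 60, "width": 45, "height": 50}, (250, 900), color=(200, 40, 40)),
            ],
            noise=STUDY_NOISE,
            seed=5,
        )
        depth, rgb, gt = render_scene(spec, cam)
        masks = segment_objects(rgb, table_color_template(rgb))
        assert len(masks) == 2
        small_prim = extract_primitive(select_object(masks, "largest"), depth, cam, noisy_table)
        # hand reference placed at the small object's centroid
        small_mask = min(masks, key=lambda m: m.sum())
        small_centroid = extract_primitive(small_mask, depth, cam, noisy_table).centroid
        hand = HandState(
            arm_mask=None, hand_mask=None, start_point=None, fingertip=None,
            reference_point=small_centroid + np.array([50.0, 0, 40.0]),
            hand_plane=None, spatial_angle=0.0, pronation=0.0, flexion=0.0,
            frame=noisy_table.frame,
        )
        chosen = select_object(masks, "closest_to_hand", hand=hand, depth=depth, cam=cam, table=noisy_table)
        np.testing.assert_array_equal(chosen, small_mask)
        assert small_prim.footprint_major > 100  # sanity: largest picked the big one


class TestBuildPrimitive:
    def _primitive(self, cam, table, obj, seed=6, cfg=None):
        spec = SceneSpec(objects=[obj], noise=STUDY_NOISE, seed=seed)
        depth, rgb, gt = render_scene(spec, cam)
        masks = segment_objects(rgb, table_color_template(rgb), cfg)
        return extract_primitive(select_object(masks, "largest"), depth, cam, table, cfg), gt

    def test_sphere_height(self, cam, noisy_table):
        prim, _ = self._primitive(cam, noisy_table, ObjectSpec("sphere", {"radius": 35}, (0, 900)))
        assert prim.height == pytest.approx(70.0, abs=5.0)

    def test_upright_cylinder_footprint(self, cam, noisy_table):
        """Footprint axes of an upright cylinder read its diameter.  Modest
        noise: the footprint region is a union of cells, so its extent
        grows by roughly the transverse noise spread."""
        spec = SceneSpec(
            objects=[ObjectSpec("cylinder", {"radius": 35, "height": 100}, (0, 900))],
            noise=NoiseSpec(1.0, True), seed=6,
        )
        depth, rgb, _ = render_scene(spec, cam)
        prim = extract_primitive(
            select_object(segment_objects(rgb, table_color_template(rgb)), "largest"),
            depth, cam, noisy_table,
        )
        assert prim.footprint_major == pytest.approx(70.0, abs=5.0)
        assert prim.footprint_minor == pytest.approx(70.0, abs=5.0)

    def test_shadow_points_excluded(self, cam, noisy_table):
        """With a painted shadow decal the 3D primitive keeps no points at
        table level (ground-truth shadow labels stay outside)."""
        spec = SceneSpec(
            objects=[ObjectSpec("box", {"length": 90, "width": 70, "height": 100}, (0, 900), shadow=True)],
            noise=STUDY_NOISE,
            seed=7,
        )
        depth, rgb, gt = render_scene(spec, cam)
        mask = select_object(segment_objects(rgb, table_color_template(rgb)), "largest")
        assert (mask & gt.shadow_mask).any()  # segmentation did attach the shadow
        prim = build_primitive(mask, depth, cam, noisy_table)
        assert (prim.points_table[:, 2] > ColorSegConfig().shadow_margin).all()
        assert prim.footprint_major < 130  # shadow did not inflate the footprint

    def test_flat_object_falls_back_to_metric_2d(self, cam, noisy_table):
        spec = SceneSpec(
            objects=[ObjectSpec("thin_box", {"length": 150, "width": 8, "height": 7}, (0, 1000))],
            noise=NoiseSpec(2.0, True),
            seed=8,
        )
        depth, rgb, _ = render_scene(spec, cam)
        mask = select_object(segment_objects(rgb, table_color_template(rgb)), "largest")
        with pytest.raises(FlatObjectError):
            build_primitive(mask, depth, cam, noisy_table)
        prim = extract_primitive(mask, depth, cam, noisy_table)
        assert not prim.depth_model
        assert prim.footprint_major == pytest.approx(150.0 * 4 / np.sqrt(12), rel=0.1)
        assert prim.height < 40

    def test_centroid_inside_ground_truth_bounds(self, cam, noisy_table):
        from fesgrasp.scene_sim import to_scene_frame

        prim, gt = self._primitive(cam, noisy_table, ObjectSpec("sphere", {"radius": 40}, (100, 850)))
        c_scene = to_scene_frame(noisy_table.frame.to_camera(prim.centroid), cam)
        truth = gt.objects[0]
        assert abs(c_scene[0] - truth.centroid[0]) <= 40.0
        assert abs(c_scene[1] - truth.centroid[1]) <= 40.0
        assert 0.0 <= c_scene[2] <= 80.0

    def test_height_estimate_monotone_in_true_height(self, cam, noisy_table):
        heights = [20.0, 50.0, 80.0, 110.0, 140.0]
        est = []
        for i, h in enumerate(heights):
            prim, _ = self._primitive(
                cam, noisy_table,
                ObjectSpec("box", {"length": 90, "width": 70, "height": h}, (0, 900)),
                seed=20 + i,
            )
            est.append(prim.height)
        assert all(a < b for a, b in zip(est, est[1:]))  # Spearman rho == 1
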