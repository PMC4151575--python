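"""Table edges, arm-gap detection, arm/hand extraction and hand pose."""

import numpy as np
import pytest

from fesgrasp.camera_geometry import plane_basis, view_normal
from fesgrasp.hand_track import (
    ArmGap,
    TrackConfig,
    _edge_chains,
    detect_arm_gap,
    estimate_hand_orientation,
    extract_arm_primitive,
    extract_table_edges,
    locate_hand,
    track_frame,
)
from fesgrasp.plane_detect import RansacConfig, plane_depth_raster
from fesgrasp.scene_sim import (
    ArmSpec,
    NoiseSpec,
    SceneSpec,
    camera_pose,
    render_scene,
    to_scene_frame,
)

STUDY_NOISE = NoiseSpec(3.0, True)


def _project(p, cam):
    R, c = camera_pose(cam)
    q = R.T @ (np.asarray(p, float) - c)
    return np.array(
        [
            cam.principal_point[1] + cam.focal_length * q[1] / q[2],  # row
            cam.principal_point[0] + cam.focal_length * q[0] / q[2],  # col
        ]
    )


class TestTableEdges:
    def test_fitted_lines_match_projected_table_boundary(self, noisy_table, cam):
        """Both edge lines lie within 1 px RMS of the ground-truth edges
        obtained by projecting the true table boundary through the camera."""
        table_spec = SceneSpec().table
        gt_lines = []
        for pts3 in (
            [(x, table_spec.y_min, 0.0) for x in np.linspace(-400, 400, 9)],  # near edge
            [(table_spec.x_max, y, 0.0) for y in np.linspace(1050, 1600, 9)],  # right edge
        ):
            pix = np.array([_project(p, cam) for p in pts3])
            c = pix.mean(axis=0)
            d = np.linalg.svd(pix - c)[2][0]
            gt_lines.append((c, d))
        for line in noisy_table.edges.lines:
            t = np.linspace(*line.t_range, 50)
            samples = line.at(t)
            rms = []
            for c, d in gt_lines:
                rel = samples - c
                perp = rel - np.outer(rel @ d, d)
                rms.append(np.sqrt((np.linalg.norm(perp, axis=1) ** 2).mean()))
            assert min(rms) < 1.0  # each fitted line matches one true edge

    def test_borderless_plane_has_no_edges(self, cam):
        """A plane filling the whole frame yields no edge chains."""
        from fesgrasp.plane_detect import PlaneModel

        plane = PlaneModel(np.array([0.0, np.cos(np.pi / 4), np.sin(np.pi / 4)]), 600.0)
        raster = plane_depth_raster(plane, cam)
        with pytest.raises(ValueError, match="table edges not found"):
            extract_table_edges(raster)

    def test_two_longest_chains_selected(self):
        mask = np.zeros((500, 500), dtype=bool)
        mask[10, 50:450] = True  # 400 px
        mask[480, 50:400] = True  # 350 px
        mask[250, 100:160] = True  # 60 px
        chains = _edge_chains(mask)
        assert [len(c) for c in chains[:2]] == [400, 350]


class TestArmGap:
    def test_no_arm_means_no_gap(self, noisy_table, cam):
        depth, _, _ = render_scene(SceneSpec(noise=STUDY_NOISE, seed=8), cam)
        assert detect_arm_gap(depth, noisy_table) is None

    def test_gap_midpoint_matches_occlusion_oracle(self, noisy_table, cam):
        """The detected gap centre sits within 3 px of the midpoint of the
        edge stretch whose sight rays an independent ray-box oracle reports
        as blocked by the arm."""
        arm = ArmSpec()
        table_spec = SceneSpec().table
        line = max(noisy_table.edges.lines, key=lambda l: abs(l.direction[0]))  # right edge
        R, c = camera_pose(cam)

        def blocked(t):
            rc = line.at(np.array([t]))[0]
            d_cam = np.array(
                [
                    (rc[1] - cam.principal_point[0]) / cam.focal_length,
                    (rc[0] - cam.principal_point[1]) / cam.focal_length,
                    1.0,
                ]
            )
            D = R @ d_cam
            p = c + (-c[2] / D[2]) * D  # table point seen by this pixel
            x_start = table_spec.x_max + arm.overhang
            x_wrist = x_start - arm.forearm_length
            boxes = [
                (
                    np.array([x_wrist, arm.entry_y - arm.forearm_width / 2, arm.plane_height - arm.forearm_thickness / 2]),
                    np.array([x_start, arm.entry_y + arm.forearm_width / 2, arm.plane_height + arm.forearm_thickness / 2]),
                ),
                (
                    np.array([x_wrist - arm.hand_length, arm.entry_y - arm.hand_width / 2, arm.plane_height - arm.hand_thickness / 2]),
                    np.array([x_wrist, arm.entry_y + arm.hand_width / 2, arm.plane_height + arm.hand_thickness / 2]),
                ),
            ]
            seg = p - c
            for lo, hi in boxes:
                with np.errstate(divide="ignore"):
                    t1, t2 = (lo - c) / seg, (hi - c) / seg
                tmin = np.minimum(t1, t2).max()
                tmax = np.maximum(t1, t2).min()
                if tmax >= tmin and 0 < tmin < 1:
                    return True
            return False

        ts = np.arange(np.floor(line.t_range[0]), np.ceil(line.t_range[1]) + 1.0)
        occ = np.array([blocked(t) for t in ts])
        assert occ.any()
        t_mid_oracle = ts[occ].mean()
        oracle_px = line.at(np.array([t_mid_oracle]))[0]

        depth, _, _ = render_scene(SceneSpec(arm=arm, noise=STUDY_NOISE, seed=5), cam)
        gap = detect_arm_gap(depth, noisy_table)
        assert gap is not None
        assert np.hypot(*(np.array(gap.mid_rc) - oracle_px)) < 3.0


class TestArmPrimitive:
    def test_mask_matches_ground_truth_arm(self, noisy_table, cam):
        depth, _, gt = render_scene(SceneSpec(arm=ArmSpec(), noise=STUDY_NOISE, seed=5), cam)
        gap = detect_arm_gap(depth, noisy_table)
        mask = extract_arm_primitive(depth, gap)
        gt_arm = gt.arm_mask
        coverage = (mask & gt_arm).sum() / gt_arm.sum()
        spill = (mask & ~gt_arm).sum() / mask.sum()
        assert coverage >= 0.95
        assert spill <= 0.05

    def test_extraction_deterministic(self, noisy_table, cam):
        depth, _, _ = render_scene(SceneSpec(arm=ArmSpec(), noise=STUDY_NOISE, seed=5), cam)
        gap = detect_arm_gap(depth, noisy_table)
        np.testing.assert_array_equal(
            extract_arm_primitive(depth, gap), extract_arm_primitive(depth, gap)
        )

    def test_seed_on_edge_rejected(self, noisy_table, cam):
        depth, _, _ = render_scene(SceneSpec(arm=ArmSpec(), noise=STUDY_NOISE, seed=5), cam)
        from fesgrasp.hand_track import sobel_edge_mask

        em = sobel_edge_mask(depth.depth, 0.03)
        r, c = map(int, np.argwhere(em)[0])
        bad_gap = ArmGap(0, 0.0, (r, c), 0.0, 0.0, 1000.0)
        with pytest.raises(ValueError, match="edge"):
            extract_arm_primitive(depth, bad_gap)


class TestLocateHand:
    def test_arm_length_recovered(self, noisy_table, cam):
        """start -> fingertip distance matches the constructed arm length."""
        # 250 mm forearm + 150 mm hand = 400 mm; entry far enough across
        # the table that the whole arm stays inside the camera frustum
        arm = ArmSpec(entry_y=1350.0, overhang=80.0, forearm_length=250.0, hand_length=150.0)
        depth, _, _ = render_scene(SceneSpec(arm=arm, noise=NoiseSpec(1.0, False), seed=4), cam)
        gap = detect_arm_gap(depth, noisy_table)
        mask = extract_arm_primitive(depth, gap)
        state = locate_hand(mask, depth, cam, noisy_table, gap)
        length = np.linalg.norm(state.fingertip - state.start_point)
        assert abs(length - 400.0) < 10.0

    def test_hand_mask_subset_of_arm_and_reference_near_grasp_centre(self, noisy_table, cam):
        depth, _, gt = render_scene(SceneSpec(arm=ArmSpec(), noise=STUDY_NOISE, seed=6), cam)
        state = track_frame(depth, cam, noisy_table)
        assert (state.hand_mask & ~state.arm_mask).sum() == 0
        ref_scene = to_scene_frame(state.frame.to_camera(state.reference_point), cam)
        assert np.linalg.norm(ref_scene - gt.hand.reference_point) < 30.0

    def test_fingertip_is_distance_argmax(self, noisy_table, cam):
        from fesgrasp.camera_geometry import pixel_rays

        depth, _, _ = render_scene(SceneSpec(arm=ArmSpec(), noise=STUDY_NOISE, seed=6), cam)
        state = track_frame(depth, cam, noisy_table)
        rc = np.argwhere(state.arm_mask & depth.valid)
        pts = noisy_table.frame.to_table(
            pixel_rays(cam)[rc[:, 0], rc[:, 1]] * depth.depth[rc[:, 0], rc[:, 1]][:, None]
        )
        d = np.linalg.norm(pts - state.start_point, axis=1)
        assert np.linalg.norm(state.fingertip - state.start_point) == pytest.approx(d.max())


class TestHandOrientation:
    @staticmethod
    def _paddle(rng, pronation=0.0, flexion=0.0, sigma=0.0, n=1500):
        """Synthetic planar paddle point cloud in the table frame."""
        u = rng.uniform(0, 175, n)
        v = rng.uniform(-45, 45, n)
        p, f = np.deg2rad(pronation), np.deg2rad(flexion)
        Rx = np.array([[1, 0, 0], [0, np.cos(p), -np.sin(p)], [0, np.sin(p), np.cos(p)]])
        Ry = np.array([[np.cos(-f), 0, np.sin(-f)], [0, 1, 0], [-np.sin(-f), 0, np.cos(-f)]])
        Q = Ry @ Rx
        pts = (np.stack([-u, v, np.zeros(n)], axis=1)) @ Q.T + np.array([400.0, 1200.0, 80.0])
        if sigma:
            pts = pts + rng.normal(0, sigma, pts.shape)
        return pts

    def test_flat_paddle_has_zero_spatial_angle(self, rng):
        spatial, pron, _, _ = estimate_hand_orientation(self._paddle(rng, sigma=1.0))
        assert spatial < 3.0
        assert abs(pron) < 3.0

    @pytest.mark.parametrize("pronation", [-80, -40, 0, 40, 80])
    def test_pronation_recovered_within_budget(self, pronation, rng):
        pts = self._paddle(rng, pronation=pronation, sigma=3.0)
        spatial, pron, _, _ = estimate_hand_orientation(pts)
        assert abs(pron - pronation) <= 15.0
        assert abs(spatial - abs(pronation)) <= 15.0

    def test_quarter_turn_about_forearm_axis(self, rng):
        pts = self._paddle(rng, pronation=90.0, sigma=2.0)
        _, pron, _, _ = estimate_hand_orientation(pts)
        assert abs(abs(pron) - 90.0) <= 15.0

    def test_translation_invariance(self, rng):
        pts = self._paddle(rng, pronation=25.0, sigma=2.0)
        a = estimate_hand_orientation(pts)
        b = estimate_hand_orientation(pts + np.array([100.0, -250.0, 40.0]))
        assert a[0] == pytest.approx(b[0], abs=1e-6)
        assert a[1] == pytest.approx(b[1], abs=1e-6)

    def test_spatial_angle_equivariant_under_vertical_rotation(self, rng):
        pts = self._paddle(rng, pronation=30.0, sigma=1.0)
        ang = np.deg2rad(60.0)
        Rz = np.array([[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        a = estimate_hand_orientation(pts)
        b = estimate_hand_orientation(pts @ Rz.T)
        assert a[0] == pytest.approx(b[0], abs=2.0)  # spatial angle invariant

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_hand_orientation(self._paddle(rng)[:10])


class TestTrackingLoop:
    def test_reach_sequence_reference_rms(self, noisy_table, cam):
        """Over a 50-frame simulated reach the tracked reference point stays
        within 30 mm RMS of ground truth."""
        errs = []
        for k in range(50):
            arm = ArmSpec(forearm_length=200.0 + 5.0 * k)
            depth, _, gt = render_scene(SceneSpec(arm=arm, noise=STUDY_NOISE, seed=300 + k), cam)
            state = track_frame(depth, cam, noisy_table)
            assert state is not None
            ref = to_scene_frame(state.frame.to_camera(state.reference_point), cam)
            errs.append(np.linalg.norm(ref - gt.hand.reference_point) ** 2)
        assert np.sqrt(np.mean(errs)) < 30.0

    def test_flexion_recovered_in_observable_range(self, noisy_table, cam):
        """Flexion within the range where the fingertips stay clear of the
        table is recovered inside the 15-degree budget."""
        for f in (-40.0, -20.0, 0.0, 10.0):
            spec = SceneSpec(arm=ArmSpec(flexion=f, entry_y=1050.0), noise=STUDY_NOISE, seed=77)
            depth, _, _ = render_scene(spec, cam)
            state = track_frame(depth, cam, noisy_table)
            assert state is not None and state.hand_plane is not None
            assert abs(state.flexion - f) <= 15.0
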