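"""Arm/hand extraction from depth frames and hand pose estimation.

Per frame the tracker:

1. matches the table-edge line models fitted on the background image (BCG)
   against the frame's Sobel edge map and looks for a *gap* — a contiguous
   stretch of a table edge with no edge response, where the arm crosses it;
2. verifies the gap by the mean-depth test (the arm is nearer the camera
   than the table/background it occludes);
3. flood-fills the Sobel-filtered depth image from the gap centre to obtain
   the arm primitive;
4. finds the arm start point (off-table point farthest from the table
   edge), the fingertip (farthest 3D point from the start), recruits hand
   pixels around the fingertip and takes the median hand pixel as the hand
   reference point;
5. fits a plane to the hand points with RANSAC and derives the spatial
   angle (hand plane vs table plane), pronation/supination and wrist
   flexion/extension angles.

Sign conventions (fixed here, used by the FES mapping): pronation positive =
palm rotating toward the camera; flexion positive = fingertips toward the
table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from .camera_geometry import (
    CameraModel,
    DepthFrame,
    PointCloud3D,
    TableFrame,
    depth_to_points,
    pixel_rays,
)
from .plane_detect import BackgroundImage, PlaneModel, RansacConfig, ransac_plane


@dataclass
class TrackConfig:
    sobel_threshold: float = 0.03  # fraction of the max gradient magnitude;
    # must catch the ~50 mm steps of a low hand over the table while sitting
    # far above the few-mm noise floor
    hand_radius: float = 120.0  # mm around the fingertip recruited as hand
    gap_depth_margin: float = 30.0  # mm mean-depth difference verifying a gap
    min_gap_px: int = 8
    edge_match_radius: int = 2  # px tolerance when matching edges to lines
    ransac: RansacConfig = field(default_factory=lambda: RansacConfig(n_triplets=100))


@dataclass
class Line2D:
    """Image-space line (row/col coords): point + unit direction + the
    parameter range its edge chain spans."""

    point: np.ndarray  # (2,) (row, col)
    direction: np.ndarray  # (2,) unit
    t_range: tuple[float, float]
    n_pixels: int

    def at(self, t: np.ndarray) -> np.ndarray:
        return self.point + np.outer(t, self.direction)


@dataclass
class EdgeLineModel:
    lines: list[Line2D]  # the two longest table edges
    source: str = "bcg"


@dataclass
class TableModel:
    """Everything the per-frame stages need about the table: its plane, the
    BCG raster, the fitted edge lines and the table frame anchor."""

    plane: PlaneModel  # camera frame
    bcg: np.ndarray  # (H, W) mm
    edges: EdgeLineModel | None
    frame: TableFrame  # camera -> table transform (origin on the plane)
    table_mask: np.ndarray  # BCG pixels on the plane
    interior_rc: np.ndarray  # (2,) centroid pixel of the table region


@dataclass
class ArmGap:
    line_index: int
    t_mid: float
    mid_rc: tuple[int, int]
    t_lo: float
    t_hi: float
    mean_depth: float


@dataclass
class HandState:
    arm_mask: np.ndarray
    hand_mask: np.ndarray
    start_point: np.ndarray  # table frame, mm
    fingertip: np.ndarray
    reference_point: np.ndarray
    hand_plane: PlaneModel | None
    spatial_angle: float
    pronation: float
    flexion: float
    frame: TableFrame  # transform used, for converting back to camera coords


# ---------------------------------------------------------------------------
# Edges
# ---------------------------------------------------------------------------


def sobel_edge_mask(depth: np.ndarray, threshold_frac: float) -> np.ndarray:
    """Low-threshold Sobel edge mask of a depth raster (invalid = 0 included,
    so range boundaries appear as strong edges)."""
    mag = filters.sobel(depth)
    m = mag.max()
    if m <= 0:
        return np.zeros_like(depth, dtype=bool)
    return mag > threshold_frac * m


def _fit_line(rc: np.ndarray) -> Line2D:
    """Total-least-squares line through edge-chain pixels."""
    c = rc.mean(axis=0)
    _, _, vt = np.linalg.svd(rc - c, full_matrices=False)
    d = vt[0]
    if d[0] < 0 or (d[0] == 0 and d[1] < 0):
        d = -d  # deterministic orientation
    t = (rc - c) @ d
    return Line2D(point=c, direction=d, t_range=(float(t.min()), float(t.max())), n_pixels=len(rc))


def _edge_chains(edge_mask: np.ndarray) -> list[np.ndarray]:
    lab, n = ndimage.label(edge_mask, structure=np.ones((3, 3), dtype=int))
    chains = [np.argwhere(lab == i) for i in range(1, n + 1)]
    chains.sort(key=len, reverse=True)
    return chains


def extract_table_edges(bcg: BackgroundImage | np.ndarray, sobel_threshold: float = 0.03) -> EdgeLineModel:
    """Fit line models to the two longest edge chains of the BCG."""
    raster = bcg.bcg if isinstance(bcg, BackgroundImage) else bcg
    mask = sobel_edge_mask(raster, sobel_threshold)
    chains = _edge_chains(mask)
    if len(chains) < 2:
        raise ValueError("table edges not found: fewer than two edge chains in the BCG")
    lines = [_fit_line(ch.astype(np.float64)) for ch in chains[:2]]
    return EdgeLineModel(lines=lines, source="bcg")


def build_table_model(
    bg: BackgroundImage,
    cam: CameraModel,
    sobel_threshold: float = 0.03,
    with_edges: bool = True,
) -> TableModel:
    """Assemble the TableModel used by tracking and object extraction.

    The table-frame origin is the centroid of the plane's BCG inlier points
    (any table point is admissible as origin)."""
    cloud = depth_to_points(DepthFrame(bg.bcg), cam)
    d = bg.table_plane.distances(cloud.points)
    inl = d < 15.0
    table_mask = np.zeros(bg.bcg.shape, dtype=bool)
    rc = cloud.pixel_index[inl]
    table_mask[rc[:, 0], rc[:, 1]] = True
    origin = cloud.points[inl].mean(axis=0)
    # snap the origin exactly onto the plane
    n, off = bg.table_plane.normal, bg.table_plane.offset
    origin = origin - (origin @ n - off) * n
    edges = extract_table_edges(bg, sobel_threshold) if with_edges else None
    return TableModel(
        plane=bg.table_plane,
        bcg=bg.bcg,
        edges=edges,
        frame=TableFrame(origin, cam.tilt_theta),
        table_mask=table_mask,
        interior_rc=rc.mean(axis=0),
    )


# ---------------------------------------------------------------------------
# Arm gap detection
# ---------------------------------------------------------------------------


def _window_mean(depth: np.ndarray, r: int, c: int, half: int = 4) -> float:
    h, w = depth.shape
    win = depth[max(0, r - half) : r + half + 1, max(0, c - half) : c + half + 1]
    vals = win[win > 0]
    return float(vals.mean()) if len(vals) else 0.0


def detect_arm_gap(
    depth: DepthFrame, table: TableModel, cfg: TrackConfig | None = None
) -> ArmGap | None:
    """Find the arm's crossing of a table edge, or None.

    The BCG edge lines are sampled; positions with no frame edge response
    within ``edge_match_radius`` form candidate gaps, verified by requiring
    the frame to be at least ``gap_depth_margin`` nearer the camera than the
    BCG around the gap centre (the arm occludes the edge).  With gaps on
    both edges (both arms over the table) the nearer one is selected.
    """
    cfg = cfg or TrackConfig()
    if table.edges is None:
        raise ValueError("table model has no edge lines")
    edge_mask = sobel_edge_mask(depth.depth, cfg.sobel_threshold)
    matched = morphology.dilation(edge_mask, morphology.disk(cfg.edge_match_radius))
    h, w = depth.depth.shape
    candidates: list[ArmGap] = []
    for li, line in enumerate(table.edges.lines):
        t = np.arange(np.floor(line.t_range[0]), np.ceil(line.t_range[1]) + 1.0)
        pts = np.rint(line.at(t)).astype(int)
        ok = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
        t, pts = t[ok], pts[ok]
        present = matched[pts[:, 0], pts[:, 1]]
        # contiguous runs of absent edge; the arm's own silhouette edges cut
        # thin "present" slivers across the occluded stretch — close them so
        # the gap spans the whole crossing
        absent = ndimage.binary_closing(~present, structure=np.ones(9, dtype=bool))
        if not absent.any():
            continue
        edges_of_runs = np.flatnonzero(np.diff(np.concatenate(([0], absent.view(np.int8), [0]))))
        for s, e in zip(edges_of_runs[::2], edges_of_runs[1::2]):
            if e - s < cfg.min_gap_px:
                continue
            mid = (s + e) // 2
            r, c = pts[mid]
            frame_d = _window_mean(depth.depth, r, c)
            bcg_d = _window_mean(table.bcg, r, c)
            if frame_d > 0 and bcg_d - frame_d > cfg.gap_depth_margin:
                candidates.append(
                    ArmGap(
                        line_index=li,
                        t_mid=float(t[mid]),
                        mid_rc=(int(r), int(c)),
                        t_lo=float(t[s]),
                        t_hi=float(t[e - 1]),
                        mean_depth=frame_d,
                    )
                )
    if not candidates:
        return None
    return min(candidates, key=lambda g: g.mean_depth)


# ---------------------------------------------------------------------------
# Arm primitive
# ---------------------------------------------------------------------------


def extract_arm_primitive(
    depth: DepthFrame, gap: ArmGap, cfg: TrackConfig | None = None
) -> np.ndarray:
    """Flood fill (4-connectivity) bounded by Sobel edges from the gap centre."""
    cfg = cfg or TrackConfig()
    edge_mask = sobel_edge_mask(depth.depth, cfg.sobel_threshold)
    r, c = gap.mid_rc
    if edge_mask[r, c]:
        raise ValueError("flood-fill seed lies on an edge pixel")
    free = ~edge_mask
    lab, _ = ndimage.label(free, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    mask = lab == lab[r, c]
    if mask.sum() > 0.5 * mask.size:
        raise ValueError("edge leak: flood fill covered more than half the frame")
    # the fill stops one pixel short of the bounding Sobel ring, which lies on
    # the arm silhouette; grow back by one pixel
    mask = ndimage.binary_dilation(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    return mask & depth.valid


# ---------------------------------------------------------------------------
# Hand location
# ---------------------------------------------------------------------------


def _edge_line_3d(line: Line2D, table: TableModel, cam: CameraModel):
    """3D (table-frame) line model of a table edge: sample the image line,
    read the plane's analytic depth and back-project."""
    t = np.linspace(line.t_range[0], line.t_range[1], 32)
    pts = line.at(t)
    rays = pixel_rays(cam)
    h, w = table.bcg.shape
    r = np.clip(np.rint(pts[:, 0]).astype(int), 0, h - 1)
    c = np.clip(np.rint(pts[:, 1]).astype(int), 0, w - 1)
    d = rays[r, c]
    denom = d @ table.plane.normal
    good = np.abs(denom) > 1e-9
    depth_on_plane = np.where(good, table.plane.offset / np.where(good, denom, 1.0), 0.0)
    p3 = d * depth_on_plane[:, None]
    p3 = table.frame.to_table(p3[good & (depth_on_plane > 0)])
    a = p3[0]
    u = p3[-1] - p3[0]
    u = u / np.linalg.norm(u)
    return a, u


def locate_hand(
    arm_mask: np.ndarray,
    depth: DepthFrame,
    cam: CameraModel,
    table: TableModel,
    gap: ArmGap,
    cfg: TrackConfig | None = None,
) -> HandState:
    """Arm start point, fingertip, hand mask and hand reference point.

    The start point is the arm point on the off-table side of the crossed
    edge that is most distant (3D) from the edge line; the fingertip is the
    arm point farthest (3D) from the start; hand pixels are the arm points
    within ``hand_radius`` of the fingertip; the reference point is the hand
    pixel nearest the coordinate-wise median of the hand pixels.
    """
    cfg = cfg or TrackConfig()
    if not arm_mask.any():
        raise ValueError("empty arm mask")
    rc = np.argwhere(arm_mask & depth.valid)
    rays = pixel_rays(cam)
    pts_cam = rays[rc[:, 0], rc[:, 1]] * depth.depth[rc[:, 0], rc[:, 1]][:, None]
    pts = table.frame.to_table(pts_cam)

    line = table.edges.lines[gap.line_index]
    a3, u3 = _edge_line_3d(line, table, cam)

    # "not above the table": horizontal side of the 3D edge line opposite
    # the table interior (the table-frame origin is the inlier centroid)
    m = np.cross([0.0, 0.0, 1.0], u3)
    m[2] = 0.0
    m /= np.linalg.norm(m[:2])
    side = (pts - a3) @ m
    side_int = (np.zeros(3) - a3) @ m  # origin = interior point
    off_table = side * np.sign(side_int) < 0

    rel3 = pts - a3
    dist_line = np.linalg.norm(rel3 - np.outer(rel3 @ u3, u3), axis=1)
    if off_table.any():
        start_i = int(np.argmax(np.where(off_table, dist_line, -np.inf)))
        start = pts[start_i]
    else:
        warnings.warn("arm entirely above the table; using gap midpoint as start point", stacklevel=2)
        r, c = gap.mid_rc
        d = depth.depth[r, c]
        if d <= 0:
            d = gap.mean_depth
        start = table.frame.to_table((rays[r, c] * d)[None, :])[0]

    tip_i = int(np.argmax(np.linalg.norm(pts - start, axis=1)))
    fingertip = pts[tip_i]
    hand_sel = np.linalg.norm(pts - fingertip, axis=1) <= cfg.hand_radius
    hand_mask = np.zeros_like(arm_mask)
    hrc = rc[hand_sel]
    hand_mask[hrc[:, 0], hrc[:, 1]] = True
    hand_pts = pts[hand_sel]
    med = np.median(hand_pts, axis=0)
    ref = hand_pts[int(np.argmin(np.linalg.norm(hand_pts - med, axis=1)))]

    return HandState(
        arm_mask=arm_mask,
        hand_mask=hand_mask,
        start_point=start,
        fingertip=fingertip,
        reference_point=ref,
        hand_plane=None,
        spatial_angle=np.nan,
        pronation=np.nan,
        flexion=np.nan,
        frame=table.frame,
    )


# ---------------------------------------------------------------------------
# Hand orientation
# ---------------------------------------------------------------------------


def _wrap_deg(a: float) -> float:
    return float((a + 180.0) % 360.0 - 180.0)


def estimate_hand_orientation(
    hand_points: PointCloud3D | np.ndarray,
    table_plane_normal: np.ndarray = (0.0, 0.0, 1.0),
    forearm_axis: np.ndarray = (-1.0, 0.0, 0.0),
    tip_direction_hint: np.ndarray | None = None,
    cfg: RansacConfig | None = None,
) -> tuple[float, float, PlaneModel, float]:
    """(spatial_angle, pronation, hand_plane, flexion) from table-frame hand
    points.

    The hand is modelled as a plane via RANSAC.  The spatial angle is the
    angle between the hand-plane normal and the table normal.  Pronation is
    the signed angle of the hand normal's projection onto the frontal plane
    against the vertical; flexion the signed angle of the hand's principal
    axis against the forearm axis in the sagittal plane.
    """
    pts = hand_points.points if isinstance(hand_points, PointCloud3D) else np.asarray(hand_points)
    if len(pts) < 20:
        raise ValueError("too few hand points for orientation estimation")
    cfg = cfg or RansacConfig(n_triplets=100)
    plane = ransac_plane(PointCloud3D(pts, "table"), cfg)
    n = plane.normal
    zhat = np.asarray(table_plane_normal, dtype=np.float64)
    zhat = zhat / np.linalg.norm(zhat)
    if n @ zhat < 0:
        n = -n  # orient the hand normal upward
    spatial = float(np.degrees(np.arccos(np.clip(n @ zhat, -1.0, 1.0))))
    # pronation: hand normal projected onto the frontal (y-z) plane vs vertical;
    # positive when the palm normal tips toward the camera (-y)
    pronation = float(np.degrees(np.arctan2(-n[1], n[2])))

    # flexion: principal axis of the hand points vs the forearm axis, both
    # projected on the sagittal (x-z) plane; positive = fingertips down
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c, full_matrices=False)
    axis = vt[0]
    hint = tip_direction_hint if tip_direction_hint is not None else np.asarray(forearm_axis, float)
    if axis @ np.asarray(hint, float) < 0:
        axis = -axis
    fa = np.asarray(forearm_axis, dtype=np.float64)
    phi_axis = np.degrees(np.arctan2(axis[2], axis[0]))
    phi_fore = np.degrees(np.arctan2(fa[2], fa[0]))
    flexion = _wrap_deg(phi_axis - phi_fore)
    return spatial, pronation, plane, flexion


# ---------------------------------------------------------------------------
# Per-frame tracking loop
# ---------------------------------------------------------------------------


def track_frame(
    depth: DepthFrame,
    cam: CameraModel,
    table: TableModel,
    cfg: TrackConfig | None = None,
) -> HandState | None:
    """Full per-frame tracking: gap -> arm -> hand -> orientation.

    Returns None when no arm crosses a table edge in this frame.
    """
    cfg = cfg or TrackConfig()
    gap = detect_arm_gap(depth, table, cfg)
    if gap is None:
        return None
    arm_mask = extract_arm_primitive(depth, gap, cfg)
    state = locate_hand(arm_mask, depth, cam, table, gap, cfg)
    rc = np.argwhere(state.hand_mask & depth.valid)
    rays = pixel_rays(cam)
    pts_cam = rays[rc[:, 0], rc[:, 1]] * depth.depth[rc[:, 0], rc[:, 1]][:, None]
    hand_pts = table.frame.to_table(pts_cam)
    # forearm axis from the forearm points themselves (arm minus hand) so a
    # flexed hand does not drag the reference axis with it
    frc = np.argwhere(state.arm_mask & ~state.hand_mask & depth.valid)
    rough = state.reference_point - state.start_point
    if len(frc) >= 50:
        fpts = table.frame.to_table(rays[frc[:, 0], frc[:, 1]] * depth.depth[frc[:, 0], frc[:, 1]][:, None])
        _, _, vt = np.linalg.svd(fpts - fpts.mean(axis=0), full_matrices=False)
        forearm = vt[0] if vt[0] @ rough > 0 else -vt[0]
    else:
        nrm = np.linalg.norm(rough)
        forearm = rough / nrm if nrm > 0 else np.array([-1.0, 0.0, 0.0])
    tip_dir = state.fingertip - state.reference_point
    try:
        spatial, pronation, plane, flexion = estimate_hand_orientation(
            hand_pts,
            forearm_axis=forearm,
            tip_direction_hint=tip_dir,
            cfg=cfg.ransac,
        )
    except ValueError:
        return state  # positions only; orientation unavailable
    state.hand_plane = plane
    state.spatial_angle = spatial
    state.pronation = pronation
    state.flexion = flexion
    return state
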