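"""Triplet-sampling RANSAC plane detection and background (BCG) estimation.

The dominant table plane is found by sampling random point triplets,
modelling a candidate plane from each and keeping the candidate with the
most inliers.  ``ransac_plane_clustered`` adds the speed optimization of
first grouping candidate planes by the angle between their normals and
counting inliers only for members of the largest cluster — fewer inlier
evaluations with equivalent results when one plane dominates the scene.

Planes are stored in Hesse normal form ``normal . p = offset`` with the sign
canonicalized so ``offset >= 0`` (offset is then the distance of the
coordinate origin to the plane).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .camera_geometry import CameraModel, DepthFrame, PointCloud3D, depth_to_points, pixel_rays


@dataclass
class PlaneModel:
    normal: np.ndarray  # (3,) unit
    offset: float  # mm; normal . p = offset for points p on the plane
    inlier_mask: np.ndarray | None = None  # (H, W) bool, when pixel provenance known
    inlier_count: int = 0

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("degenerate plane normal")
        n = n / norm
        if self.offset < 0:
            n, self.offset = -n, -self.offset
        self.normal = n

    def distances(self, points: np.ndarray) -> np.ndarray:
        return np.abs(points @ self.normal - self.offset)

    def angle_to(self, other: "PlaneModel") -> float:
        """Unsigned angle between plane orientations, degrees (sign-blind)."""
        d = abs(float(np.dot(self.normal, other.normal)))
        return float(np.degrees(np.arccos(np.clip(d, -1.0, 1.0))))


@dataclass
class RansacConfig:
    n_triplets: int = 200
    dist_threshold: float = 10.0  # mm
    cluster_angle: float = 5.0  # degrees
    seed: int = 0
    max_score_points: int = 6000  # subsample size used when scoring candidates

    def __post_init__(self) -> None:
        if self.n_triplets < 1:
            raise ValueError("n_triplets must be >= 1")
        if self.dist_threshold <= 0:
            raise ValueError("dist_threshold must be > 0")
        if not (0 < self.cluster_angle < 90):
            raise ValueError("cluster_angle must lie in (0, 90)")


@dataclass
class RansacStats:
    """Instrumentation: how many candidate planes had their inliers counted."""

    n_candidates: int = 0
    n_inlier_evaluations: int = 0
    n_clusters: int = 0


@dataclass
class BackgroundImage:
    """Object-free depth raster of the table (BCG) plus its plane model."""

    bcg: np.ndarray  # (H, W) mm; holes inside the table region are padded
    n_frames_averaged: int
    table_plane: PlaneModel  # camera frame


# ---------------------------------------------------------------------------
# Core RANSAC
# ---------------------------------------------------------------------------


def _candidate_planes(points: np.ndarray, cfg: RansacConfig, rng: np.random.Generator):
    """(normals, offsets) of planes from random triplets; degenerate skipped."""
    n = len(points)
    idx = rng.integers(0, n, size=(cfg.n_triplets, 3))
    p0, p1, p2 = points[idx[:, 0]], points[idx[:, 1]], points[idx[:, 2]]
    nv = np.cross(p1 - p0, p2 - p0)
    norms = np.linalg.norm(nv, axis=1)
    scale = np.maximum(
        np.linalg.norm(p1 - p0, axis=1) * np.linalg.norm(p2 - p0, axis=1), 1e-12
    )
    ok = norms > 1e-9 * scale  # collinear / repeated triplets are degenerate
    nv = nv[ok] / norms[ok][:, None]
    off = np.einsum("ij,ij->i", nv, p0[ok])
    flip = off < 0
    nv[flip] = -nv[flip]
    off = np.abs(off)
    return nv, off


def refit_plane(points: np.ndarray) -> PlaneModel:
    """Least-squares plane through a point set (total least squares)."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    n = vt[-1]
    return PlaneModel(normal=n, offset=float(n @ c))


def _finish(
    plane_normal: np.ndarray,
    plane_offset: float,
    cloud: PointCloud3D,
    cfg: RansacConfig,
    shape: tuple[int, int] | None,
) -> PlaneModel:
    """Refit on full-cloud inliers and build the final inlier set/mask."""
    pts = cloud.points
    d = np.abs(pts @ plane_normal - plane_offset)
    inl = d < cfg.dist_threshold
    if inl.sum() >= 3:
        refined = refit_plane(pts[inl])
        d = refined.distances(pts)
        inl = d < cfg.dist_threshold
        normal, offset = refined.normal, refined.offset
    else:
        normal, offset = plane_normal, plane_offset
    mask = None
    if cloud.pixel_index is not None and shape is not None:
        mask = np.zeros(shape, dtype=bool)
        rc = cloud.pixel_index[inl]
        mask[rc[:, 0], rc[:, 1]] = True
    return PlaneModel(normal=normal, offset=float(offset), inlier_mask=mask, inlier_count=int(inl.sum()))


def _score_subset(points: np.ndarray, cfg: RansacConfig, rng: np.random.Generator) -> np.ndarray:
    if len(points) <= cfg.max_score_points:
        return points
    sel = rng.choice(len(points), size=cfg.max_score_points, replace=False)
    return points[sel]


def _count_inliers(
    points: np.ndarray, normals: np.ndarray, offsets: np.ndarray, thr: float
) -> np.ndarray:
    # |P n^T - offset| < thr, chunked over candidates to bound memory
    counts = np.empty(len(normals), dtype=np.int64)
    chunk = max(1, int(4e6 / max(len(points), 1)))
    for s in range(0, len(normals), chunk):
        d = np.abs(points @ normals[s : s + chunk].T - offsets[s : s + chunk])
        counts[s : s + chunk] = (d < thr).sum(axis=0)
    return counts


def _prepare(cloud: PointCloud3D, cfg: RansacConfig):
    pts = cloud.points
    if len(pts) < 3:
        raise ValueError("no plane: fewer than 3 points")
    rng = np.random.default_rng(cfg.seed)
    normals, offsets = _candidate_planes(pts, cfg, rng)
    if len(normals) == 0:
        raise ValueError("no plane: all sampled triplets degenerate")
    score_pts = _score_subset(pts, cfg, rng)
    return normals, offsets, score_pts


def ransac_plane(
    cloud: PointCloud3D,
    cfg: RansacConfig,
    image_shape: tuple[int, int] | None = None,
    return_stats: bool = False,
):
    """Plain triplet-sampling RANSAC: score every candidate plane.

    Deterministic given ``(cloud, cfg.seed)``.  Ties on the inlier count are
    broken toward the lowest candidate index.  The winning candidate is
    polished by a least-squares refit on its inliers.
    """
    normals, offsets, score_pts = _prepare(cloud, cfg)
    counts = _count_inliers(score_pts, normals, offsets, cfg.dist_threshold)
    best = int(np.argmax(counts))
    plane = _finish(normals[best], offsets[best], cloud, cfg, image_shape)
    stats = RansacStats(
        n_candidates=len(normals), n_inlier_evaluations=len(normals), n_clusters=0
    )
    return (plane, stats) if return_stats else plane


def _greedy_normal_clusters(normals: np.ndarray, cluster_angle: float) -> list[np.ndarray]:
    """Greedy angular agglomeration: each candidate joins the first cluster
    whose representative normal is within ``cluster_angle`` (sign-blind)."""
    cos_thr = np.cos(np.deg2rad(cluster_angle))
    reps: list[np.ndarray] = []
    members: list[list[int]] = []
    for i, n in enumerate(normals):
        placed = False
        for k, r in enumerate(reps):
            if abs(float(n @ r)) >= cos_thr:
                members[k].append(i)
                placed = True
                break
        if not placed:
            reps.append(n)
            members.append([i])
    return [np.array(m, dtype=np.intp) for m in members]


def ransac_plane_clustered(
    cloud: PointCloud3D,
    cfg: RansacConfig,
    image_shape: tuple[int, int] | None = None,
    return_stats: bool = False,
):
    """RANSAC with the normal-clustering optimization.

    Candidate planes are first clustered by pairwise normal angle; inliers
    are counted only for members of the largest cluster, which for a
    single-dominant-plane scene gives the same winner as scoring everything
    at a fraction of the inlier evaluations.
    """
    normals, offsets, score_pts = _prepare(cloud, cfg)
    clusters = _greedy_normal_clusters(normals, cfg.cluster_angle)
    sizes = [len(c) for c in clusters]
    largest = clusters[int(np.argmax(sizes))]
    counts = _count_inliers(score_pts, normals[largest], offsets[largest], cfg.dist_threshold)
    best = int(largest[int(np.argmax(counts))])
    plane = _finish(normals[best], offsets[best], cloud, cfg, image_shape)
    stats = RansacStats(
        n_candidates=len(normals),
        n_inlier_evaluations=len(largest),
        n_clusters=len(clusters),
    )
    return (plane, stats) if return_stats else plane


# ---------------------------------------------------------------------------
# Background estimation
# ---------------------------------------------------------------------------


def plane_depth_raster(plane: PlaneModel, cam: CameraModel) -> np.ndarray:
    """Analytic depth of the plane along every pixel ray (mm; 0 where the
    plane is behind the camera or parallel to the ray)."""
    rays = pixel_rays(cam)
    denom = rays @ plane.normal
    with np.errstate(divide="ignore", invalid="ignore"):
        t = plane.offset / denom
    return np.where(np.isfinite(t) & (t > 0), t, 0.0)


def detect_table_plane(
    depth: DepthFrame,
    cam: CameraModel,
    cfg: RansacConfig,
    clustered: bool = True,
) -> PlaneModel:
    """Dominant plane of one frame; errors if it covers <50% of valid pixels."""
    cloud = depth_to_points(depth, cam)
    fit = ransac_plane_clustered if clustered else ransac_plane
    plane = fit(cloud, cfg, image_shape=depth.depth.shape)
    if plane.inlier_count < 0.5 * len(cloud):
        raise ValueError("no dominant plane: table inliers cover <50% of valid pixels")
    return plane


def estimate_background(
    frames: list[DepthFrame],
    cam: CameraModel,
    cfg: RansacConfig,
    n_frames: int = 15,
) -> BackgroundImage:
    """Background image (BCG) from the first ``n_frames`` object-free frames.

    Per frame the table plane is detected, closed contours inside the table
    region (pixels occluded by on-table objects, or invalid) are padded with
    the plane's analytic depth, and the padded frames are averaged.  The
    final plane is refit on inliers pooled over the frames.
    """
    if n_frames > len(frames):
        raise ValueError("n_frames exceeds the number of supplied frames")
    acc = None
    pooled: list[np.ndarray] = []
    for i in range(n_frames):
        frame = frames[i]
        frame_cfg = RansacConfig(
            n_triplets=cfg.n_triplets,
            dist_threshold=cfg.dist_threshold,
            cluster_angle=cfg.cluster_angle,
            seed=cfg.seed + i,
            max_score_points=cfg.max_score_points,
        )
        plane = detect_table_plane(frame, cam, frame_cfg)
        table_mask = plane.inlier_mask
        filled = ndimage.binary_fill_holes(table_mask)
        holes = filled & ~table_mask
        padded = frame.depth.copy()
        if holes.any():
            padded[holes] = plane_depth_raster(plane, cam)[holes]
        acc = padded if acc is None else acc + padded
        rc = np.argwhere(table_mask)
        sub = rc[:: max(1, len(rc) // 2000)]
        rays = pixel_rays(cam)
        pooled.append(rays[sub[:, 0], sub[:, 1]] * frame.depth[sub[:, 0], sub[:, 1]][:, None])
    bcg = acc / n_frames
    table_plane = refit_plane(np.concatenate(pooled))
    return BackgroundImage(bcg=bcg, n_frames_averaged=n_frames, table_plane=table_plane)
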