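"""Color-template segmentation of on-table objects and 3D primitive
construction.

Because the table dominates the image (>50% of pixels), its color template
is simply the channel-wise median of the RGB frame.  Pixels deviating from
the template are object candidates; padding the closed contours of the
table template and subtracting the unpadded template yields the object
masks.  This route is insensitive to object *size* (small flat objects are
invisible to depth-based table subtraction) but requires objects to differ
in color from the table.

The selected mask is lifted to 3D: its pixels are back-projected, moved to
the table frame, and points close to the table plane are removed (large
objects cast shadows that segmentation may attach to the mask).  For
objects too flat to survive the shadow margin, a metric 2D route projects
the mask onto the table plane through the camera model instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from .camera_geometry import CameraModel, ColorFrame, DepthFrame, pixel_rays
from .hand_track import HandState, TableModel


class FlatObjectError(ValueError):
    """Raised when the shadow margin removes every 3D point of an object."""


@dataclass
class ColorSegConfig:
    deviation_threshold: int = 30  # per-channel L-inf deviation from template
    selection_policy: str = "largest"  # or "closest_to_hand"
    shadow_margin: float = 10.0  # mm above the table plane
    min_component_px: int = 20
    min_points_3d: int = 30  # fewer surviving points -> flat-object route

    def __post_init__(self) -> None:
        if not (0 < self.deviation_threshold < 255):
            raise ValueError("deviation_threshold must lie in (0, 255)")
        if self.shadow_margin <= 0:
            raise ValueError("shadow_margin must be > 0")


@dataclass
class ObjectPrimitive:
    """Extracted object: pixels, table-frame points and derived dimensions.

    ``footprint_major``/``footprint_minor`` are the axis lengths of the
    equivalent-second-moment ellipse of the transverse (horizontal)
    footprint, in mm; ``footprint_axis`` the table-frame direction of the
    major axis.  ``image_elongation`` is the eccentricity measure
    ``(major - minor) / major`` of the equivalent ellipse of the *image*
    region (used by the roundness rule, where the image silhouette of a ball
    is circular while its visible 3D surface is not).  ``depth_model`` is
    False when the object was too flat for the 3D route and the footprint
    came from projecting the mask onto the table plane.
    """

    mask: np.ndarray
    points_table: np.ndarray  # (N, 3) mm, z > shadow_margin
    height: float
    footprint_major: float
    footprint_minor: float
    footprint_axis: np.ndarray  # (2,) unit, table frame x-y
    centroid: np.ndarray  # (3,) table frame
    image_elongation: float
    silhouette_solidity: float  # filled-mask area / its convex hull area
    footprint_points: np.ndarray  # (N, 2) transverse coords used for moments
    depth_model: bool = True


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def table_color_template(rgb: ColorFrame | np.ndarray) -> np.ndarray:
    """Channel-wise median color over all pixels (valid while the table
    covers the majority of the image)."""
    img = rgb.rgb if isinstance(rgb, ColorFrame) else np.asarray(rgb)
    return np.median(img.reshape(-1, img.shape[-1]), axis=0)


def segment_objects(
    rgb: ColorFrame | np.ndarray,
    template: np.ndarray,
    cfg: ColorSegConfig | None = None,
) -> list[np.ndarray]:
    """Object masks: padded table template minus the unpadded template.

    The table template is the set of pixels within ``deviation_threshold``
    of the median color in every channel; objects appear as closed contours
    (holes) inside it.  Components smaller than ``min_component_px`` are
    dropped as noise.  An empty list is a valid outcome (no object detected).
    """
    cfg = cfg or ColorSegConfig()
    img = rgb.rgb if isinstance(rgb, ColorFrame) else np.asarray(rgb)
    dev = np.abs(img.astype(np.int16) - np.asarray(template, dtype=np.int16)).max(axis=-1)
    tmpl = dev <= cfg.deviation_threshold
    padded = ndimage.binary_fill_holes(tmpl)
    objects = padded & ~tmpl
    lab, n = ndimage.label(objects, structure=np.ones((3, 3), dtype=int))
    masks = []
    for i in range(1, n + 1):
        m = lab == i
        if m.sum() >= cfg.min_component_px:
            masks.append(m)
    return masks


def select_object(
    masks: list[np.ndarray],
    policy: str = "largest",
    hand: HandState | None = None,
    depth: DepthFrame | None = None,
    cam: CameraModel | None = None,
    table: TableModel | None = None,
) -> np.ndarray:
    """Pick the target object mask.

    ``largest`` takes the mask with the most pixels; ``closest_to_hand``
    takes the mask whose 3D centroid is nearest the hand reference point
    (requires hand, depth, cam and table).  Ties break toward the lowest
    mask index.
    """
    if not masks:
        raise ValueError("no object")
    if policy == "largest":
        return masks[int(np.argmax([m.sum() for m in masks]))]
    if policy == "closest_to_hand":
        if hand is None or depth is None or cam is None or table is None:
            raise ValueError("closest_to_hand needs hand, depth, cam and table")
        rays = pixel_rays(cam)
        dists = []
        for m in masks:
            rc = np.argwhere(m & depth.valid)
            pts = table.frame.to_table(rays[rc[:, 0], rc[:, 1]] * depth.depth[rc[:, 0], rc[:, 1]][:, None])
            dists.append(np.linalg.norm(pts.mean(axis=0) - hand.reference_point))
        return masks[int(np.argmin(dists))]
    raise ValueError(f"unknown selection policy {policy!r}")


# ---------------------------------------------------------------------------
# 3D primitive
# ---------------------------------------------------------------------------


def _equivalent_ellipse(points_2d: np.ndarray):
    """(major, minor, major-axis unit vector) of the ellipse with the same
    normalized second central moments as the point set (4 sqrt eigenvalue)."""
    from .grasp_classify import ellipse_axes  # single authoritative definition

    return ellipse_axes(points_2d, return_axis=True)


def _region_ellipse(points_2d: np.ndarray, res: float = 2.0):
    """Equivalent ellipse of the *region* covered by the points.

    The transverse projection of a visible surface oversamples silhouette
    rims (pixel density piles up where the surface turns away), which
    inflates raw point moments; rasterizing and filling first recovers the
    uniform region moments the equivalent-ellipse definition assumes.
    """
    lo = points_2d.min(axis=0) - 2 * res
    hi = points_2d.max(axis=0) + 2 * res
    shape = np.maximum(np.ceil((hi - lo) / res).astype(int), 1)
    grid = np.zeros(shape, dtype=bool)
    ij = ((points_2d - lo) / res).astype(int)
    grid[ij[:, 0], ij[:, 1]] = True
    from skimage import morphology as _morph

    grid = _morph.closing(grid, _morph.disk(1))
    grid = ndimage.binary_fill_holes(grid)
    cells = (np.argwhere(grid) + 0.5) * res + lo
    return _equivalent_ellipse(cells)


def _silhouette_metrics(mask: np.ndarray, cam: CameraModel) -> tuple[float, float]:
    """(elongation, solidity) of the mask silhouette.

    Elongation is the equivalent-ellipse axis difference measured in a
    fronto-parallel plane about the region's central viewing ray (a gnomonic
    projection removes the off-axis perspective distortion, so a ball's
    silhouette reads as a circle anywhere in the image while elongated
    objects stay elongated).  Solidity (area over convex-hull area) tells a
    convex ball silhouette apart from shapes whose second moments happen to
    be isotropic, e.g. a mug whose handle widens the silhouette by just the
    amount of its vertical elongation.
    """
    filled = ndimage.binary_fill_holes(mask)
    rc = np.argwhere(filled)
    if len(rc) < 3:
        return 0.0, 1.0
    from skimage import morphology as _morph

    hull = _morph.convex_hull_image(filled)
    solidity = float(filled.sum() / hull.sum()) if hull.any() else 1.0
    rays = pixel_rays(cam)[rc[:, 0], rc[:, 1]]
    centre = rays.mean(axis=0)
    centre = centre / np.linalg.norm(centre)
    # orthonormal basis perpendicular to the central ray
    e1 = np.cross(centre, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.array([1.0, 0.0, 0.0])
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(centre, e1)
    w = rays / (rays @ centre)[:, None]
    coords = np.stack([w @ e1, w @ e2], axis=1)
    from .grasp_classify import ellipse_axes

    major, minor = ellipse_axes(coords)
    elong = float((major - minor) / major) if major > 0 else 0.0
    return elong, solidity


def build_primitive(
    mask: np.ndarray,
    depth: DepthFrame,
    cam: CameraModel,
    table: TableModel,
    cfg: ColorSegConfig | None = None,
) -> ObjectPrimitive:
    """Lift a segmentation mask to a 3D object primitive.

    Mask pixels are back-projected and moved to the table frame; points with
    z <= ``shadow_margin`` are excluded (shadow rejection).  Raises
    :class:`FlatObjectError` when nothing survives — the caller may fall
    back to :func:`build_primitive_2d`.
    """
    cfg = cfg or ColorSegConfig()
    if not mask.any():
        raise ValueError("empty object mask")
    rc = np.argwhere(mask & depth.valid)
    if len(rc) == 0:
        raise FlatObjectError("object too flat for depth model (no valid depth)")
    rays = pixel_rays(cam)
    pts = table.frame.to_table(rays[rc[:, 0], rc[:, 1]] * depth.depth[rc[:, 0], rc[:, 1]][:, None])
    keep = pts[:, 2] > cfg.shadow_margin
    if keep.sum() < cfg.min_points_3d:
        raise FlatObjectError("object too flat for depth model")
    kept = pts[keep]
    height = float(np.percentile(kept[:, 2], 99))
    foot = kept[:, :2]
    major, minor, axis = _region_ellipse(foot)
    kept_mask = np.zeros_like(mask)
    krc = rc[keep]
    kept_mask[krc[:, 0], krc[:, 1]] = True
    elong, solidity = _silhouette_metrics(kept_mask, cam)
    return ObjectPrimitive(
        mask=mask,
        points_table=kept,
        height=height,
        footprint_major=major,
        footprint_minor=minor,
        footprint_axis=axis,
        centroid=kept.mean(axis=0),
        image_elongation=elong,
        silhouette_solidity=solidity,
        footprint_points=foot,
        depth_model=True,
    )


def build_primitive_2d(
    mask: np.ndarray,
    depth: DepthFrame,
    cam: CameraModel,
    table: TableModel,
    cfg: ColorSegConfig | None = None,
) -> ObjectPrimitive:
    """Metric 2D route for flat objects: project the mask through the camera
    onto the table plane (a homography) and measure the footprint there.

    The height estimate still uses whatever depth the mask pixels carry
    (robust upper percentile of z), so the small-object height gate remains
    meaningful.
    """
    cfg = cfg or ColorSegConfig()
    rc = np.argwhere(mask)
    rays = pixel_rays(cam)
    d = rays[rc[:, 0], rc[:, 1]]
    denom = d @ table.plane.normal
    good = np.abs(denom) > 1e-9
    t = np.where(good, table.plane.offset / np.where(good, denom, 1.0), 0.0)
    ok = good & (t > 0)
    plane_pts = table.frame.to_table(d[ok] * t[ok][:, None])
    foot = plane_pts[:, :2]
    major, minor, axis = _equivalent_ellipse(foot)

    rcv = np.argwhere(mask & depth.valid)
    if len(rcv):
        pts = table.frame.to_table(rays[rcv[:, 0], rcv[:, 1]] * depth.depth[rcv[:, 0], rcv[:, 1]][:, None])
        height = float(max(np.percentile(pts[:, 2], 98), 0.0))
    else:
        height = 0.0
    elong, solidity = _silhouette_metrics(mask, cam)
    return ObjectPrimitive(
        mask=mask,
        points_table=plane_pts,
        height=height,
        footprint_major=major,
        footprint_minor=minor,
        footprint_axis=axis,
        centroid=plane_pts.mean(axis=0),
        image_elongation=elong,
        silhouette_solidity=solidity,
        footprint_points=foot,
        depth_model=False,
    )


def extract_primitive(
    mask: np.ndarray,
    depth: DepthFrame,
    cam: CameraModel,
    table: TableModel,
    cfg: ColorSegConfig | None = None,
) -> ObjectPrimitive:
    """3D route with automatic fallback to the metric 2D route for objects
    flatter than the shadow margin."""
    try:
        return build_primitive(mask, depth, cam, table, cfg)
    except FlatObjectError:
        return build_primitive_2d(mask, depth, cam, table, cfg)
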