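"""Sequential rule-based grasp classification.

Objects are first split by height at 4 cm:

* **small** objects lie flat on the table and are grasped laterally or with
  a pinch — Rule 1: if the equivalent-ellipse axes of the footprint differ
  by more than 60% (``(major - minor)/major > 0.60``), lateral, else pinch;
* **large** objects are grasped laterally, palmarly or spherically —
  Rule 2: near-circular silhouettes (elongation < 5%) whose height matches
  the footprint diameter are round objects → spherical; otherwise
  Rule 3: a handle on the same side as the user's hand → lateral, else
  palmar, with the object's major footprint axis kept for aligning the hand
  during prehension.

The elongation readings ``(major - minor)/major`` are scale-free and bounded
in [0, 1].  Rule 2 uses the *image-plane* silhouette ellipse (a ball's
silhouette is circular; its visible 3D surface projected to the horizontal
plane is not) plus a height-vs-diameter roundness gate that keeps upright
cylinders (bottles) out of the spherical class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .object_extract import ObjectPrimitive


@dataclass
class ClassifierConfig:
    height_threshold: float = 40.0  # mm, the 4 cm small/large gate
    rule1_ratio: float = 0.60  # lateral vs pinch elongation threshold
    rule2_ratio: float = 0.05  # spherical elongation threshold
    round_height_tol: float = 0.25  # |height/diameter - 1| bound for spherical
    round_solidity: float = 0.95  # min silhouette convex-solidity for spherical
    aperture_clearance: float = 20.0  # mm added so the hand opens wider
    handle_raster_mm: float = 4.0
    handle_open_scale: float = 0.55  # opening-disc radius as a fraction of the
    # body's maximum inscribed-disc radius (from the distance transform)
    handle_min_area: float = 0.03  # handle area as fraction of body area
    handle_min_body_radius: float = 15.0  # mm; thinner bodies cannot bear a handle

    def __post_init__(self) -> None:
        if not (0 < self.rule2_ratio < self.rule1_ratio < 1):
            raise ValueError("need 0 < rule2_ratio < rule1_ratio < 1")


@dataclass
class HandleResult:
    present: bool
    side: str | None  # 'left' | 'right' | None
    relation: str  # 'hand_side' | 'opposite' | 'none'
    span: float = 0.0  # mm, handle thickness (grip opening needed)


@dataclass
class GraspDecision:
    grasp_type: str  # palmar | lateral | pinch | spherical
    aperture: float  # mm, required opening span incl. clearance
    alignment_axis: np.ndarray  # (3,) unit, table frame
    handle: HandleResult


def ellipse_axes(points_2d: np.ndarray, return_axis: bool = False):
    """Axis lengths of the equivalent-second-moment ellipse of a point set.

    For a region sampled uniformly the axes are ``4 sqrt(eigenvalues)`` of
    the coordinate covariance (a uniform disc of diameter d yields axes d).
    Collinear input returns minor = 0 (maximally elongated).
    """
    pts = np.asarray(points_2d, dtype=np.float64)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    major = 4.0 * np.sqrt(evals[1])
    minor = 4.0 * np.sqrt(evals[0])
    if return_axis:
        axis = evecs[:, 1]
        if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
            axis = -axis
        return float(major), float(minor), axis
    return float(major), float(minor)


# ---------------------------------------------------------------------------
# Handle detection
# ---------------------------------------------------------------------------


def detect_handle(
    primitive: ObjectPrimitive,
    hand_side: str = "right",
    cfg: ClassifierConfig | None = None,
) -> HandleResult:
    """Detect a handle from the transverse (horizontal) projection.

    The footprint points are rasterized, closed, and opened with a disc
    scaled to the body's maximum inscribed-disc radius; what the opening
    removes and exceeds a small area fraction is the handle.  Its side is
    the sign of the handle-centroid offset from the body centroid along the
    table-edge (x) axis, compared with the side of the user's hand.
    """
    cfg = cfg or ClassifierConfig()
    pts = primitive.footprint_points
    if len(pts) < 50:
        raise ValueError("too few footprint points for handle analysis")
    res = cfg.handle_raster_mm
    lo = pts.min(axis=0) - 2 * res
    hi = pts.max(axis=0) + 2 * res
    shape = np.maximum(np.ceil((hi - lo) / res).astype(int), 1)
    grid = np.zeros(shape, dtype=bool)
    ij = ((pts - lo) / res).astype(int)
    grid[ij[:, 0], ij[:, 1]] = True
    grid = morphology.closing(grid, morphology.disk(1))
    grid = ndimage.binary_fill_holes(grid)

    inscribed_px = float(ndimage.distance_transform_edt(grid).max())
    if inscribed_px * res < cfg.handle_min_body_radius:
        # a thin slab/strip has no graspable body; ragged rasterization must
        # not masquerade as a handle
        return HandleResult(False, None, "none")
    r_px = max(1, int(round(cfg.handle_open_scale * inscribed_px)))
    body = morphology.opening(grid, morphology.disk(r_px))
    area = grid.sum()
    body_area = body.sum()
    if body_area < 0.25 * area:
        # opening erased a thin elongated object entirely: no body, no handle
        return HandleResult(False, None, "none")
    diff = grid & ~body
    lab, n = ndimage.label(diff, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return HandleResult(False, None, "none")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < cfg.handle_min_area * body_area:
        return HandleResult(False, None, "none")
    handle_ij = np.argwhere(lab == best)
    body_ij = np.argwhere(body)
    # grid axis 0 is the table-frame x (table-edge) axis
    dx_mm = (handle_ij[:, 0].mean() - body_ij[:, 0].mean()) * res
    if abs(dx_mm) < 5.0:
        side = None
        relation = "none"
    else:
        side = "right" if dx_mm > 0 else "left"
        relation = "hand_side" if side == hand_side else "opposite"
    span = (np.ptp(handle_ij[:, 1]) + 1) * res  # tangential thickness
    span = float(min(span, (np.ptp(handle_ij[:, 0]) + 1) * res))
    return HandleResult(True, side, relation, span)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _elongation(major: float, minor: float) -> float:
    return (major - minor) / major if major > 0 else 0.0


def classify(
    primitive: ObjectPrimitive,
    hand_side: str = "right",
    cfg: ClassifierConfig | None = None,
) -> GraspDecision:
    """Map an object primitive to one of the four stimulable grasp types."""
    cfg = cfg or ClassifierConfig()
    major, minor = primitive.footprint_major, primitive.footprint_minor
    if major <= 0:
        raise ValueError("degenerate primitive: zero footprint")
    align = np.array([primitive.footprint_axis[0], primitive.footprint_axis[1], 0.0])
    elong = _elongation(major, minor)

    if primitive.height < cfg.height_threshold:
        # Rule 1: small objects -> lateral if elongated, else pinch
        grasp = "lateral" if elong > cfg.rule1_ratio else "pinch"
        return GraspDecision(
            grasp_type=grasp,
            aperture=minor + cfg.aperture_clearance,
            alignment_axis=align,
            handle=HandleResult(False, None, "none"),
        )

    # Rule 2: round large objects -> spherical
    round_elong = (
        primitive.image_elongation if primitive.image_elongation is not None else elong
    )
    diameter = major
    solidity = getattr(primitive, "silhouette_solidity", 1.0)
    if (
        round_elong < cfg.rule2_ratio
        and solidity >= cfg.round_solidity
        and abs(primitive.height / diameter - 1.0) < cfg.round_height_tol
    ):
        return GraspDecision(
            grasp_type="spherical",
            aperture=diameter + cfg.aperture_clearance,
            alignment_axis=align,
            handle=HandleResult(False, None, "none"),
        )

    # Rule 3: handle on the hand's side -> lateral, else palmar
    try:
        handle = detect_handle(primitive, hand_side, cfg)
    except ValueError:
        handle = HandleResult(False, None, "none")
    if handle.present and handle.relation == "hand_side":
        span = handle.span if handle.span > 0 else minor
        return GraspDecision(
            grasp_type="lateral",
            aperture=span + cfg.aperture_clearance,
            alignment_axis=align,
            handle=handle,
        )
    return GraspDecision(
        grasp_type="palmar",
        aperture=minor + cfg.aperture_clearance,
        alignment_axis=align,
        handle=handle,
    )
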