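"""Synthetic RGB-D scene simulator for the table-top grasping rig.

Renders registered depth/color frame pairs of a tilted table carrying rigid
colored objects and, optionally, an arm entering across a table edge — the
geometry of a depth sensor on a 0.6 m stand tilted 45 degrees at a work
table.  Rendering is exact per-pixel ray casting against analytic surfaces
(plane, sphere, oriented box, vertical cylinder), so every rendered depth
value has a closed-form ground truth; Gaussian depth noise and optional
11-bit range quantization emulate the sensor.

The simulator works in the **scene frame**: z up, origin at the foot of the
camera stand on the table plane, x parallel to the camera's image x axis, y
running away from the camera across the table.  This frame shares its axes
with the perception pipeline's table frame (both are built from the same
tilt rotation), so ground-truth angles and heights compare directly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .camera_geometry import (
    CameraModel,
    ColorFrame,
    DepthFrame,
    camera_to_table_rotation,
    pixel_rays,
)
from .plane_detect import PlaneModel

GRASP_TYPES = ("palmar", "lateral", "pinch", "spherical")

# label-image ids
LBL_BACKGROUND = 0
LBL_TABLE = 1
LBL_FOREARM = 100
LBL_HAND = 101
LBL_OBJECT0 = 10  # object i gets id LBL_OBJECT0 + i

BACKGROUND_COLOR = (25, 25, 28)
SKIN_COLOR = (205, 160, 125)

# colors distinct from the default table brown by well over the default
# segmentation threshold in at least one channel
OBJECT_PALETTE = (
    (200, 40, 40),
    (40, 80, 200),
    (50, 160, 60),
    (230, 200, 50),
    (140, 60, 170),
    (60, 185, 185),
    (240, 240, 240),
    (235, 130, 40),
)


# ---------------------------------------------------------------------------
# Scene specification
# ---------------------------------------------------------------------------


@dataclass
class TableSpec:
    """Finite table rectangle in the scene frame (z = 0)."""

    x_min: float = -1400.0
    x_max: float = 700.0
    y_min: float = 350.0
    y_max: float = 2600.0
    color: tuple[int, int, int] = (150, 110, 80)


@dataclass
class ObjectSpec:
    """A rigid object resting on the table.

    ``shape`` is one of sphere, box, thin_box, cylinder, cylinder_with_handle
    (thin_box is a box whose height is small — kept as a separate name so
    scene files read naturally).  ``dims`` in mm:

    * sphere: ``radius``
    * box / thin_box: ``length`` (local x), ``width`` (local y), ``height``
    * cylinder: ``radius``, ``height``
    * cylinder_with_handle: additionally ``handle_length`` (radial protrusion
      beyond the barrel), ``handle_width`` (tangential), ``handle_height``

    ``position`` is the (x, y) of the footprint centre, ``yaw`` the rotation
    about the vertical axis in degrees (for the mug, yaw 0 points the handle
    along +x).  ``shadow`` paints a darkened decal on the table around the
    far base of the object to exercise the shadow-exclusion rule.
    """

    shape: str
    dims: dict
    position: tuple[float, float] = (0.0, 1100.0)
    yaw: float = 0.0
    color: tuple[int, int, int] = (200, 40, 40)
    shadow: bool = False


@dataclass
class ArmSpec:
    """Arm entering across a table edge: a forearm slab ending in a thin
    planar hand paddle (the hand-plane model only requires planarity).

    The arm axis runs parallel to -x from the right-hand table edge
    (``entry_edge='right'``), crossing it at y = ``entry_y``, at height
    ``plane_height`` above the table.  ``pronation`` rotates the paddle about
    the forearm axis (positive = palm turning toward the camera);
    ``flexion`` rotates it about the wrist axis (positive = fingertips
    toward the table).
    """

    entry_edge: str = "right"
    entry_y: float = 1200.0
    overhang: float = 150.0  # how far the forearm extends beyond the edge
    forearm_length: float = 300.0
    forearm_width: float = 70.0
    forearm_thickness: float = 30.0
    hand_length: float = 175.0
    hand_width: float = 90.0
    hand_thickness: float = 6.0
    plane_height: float = 80.0  # height of the arm axis above the table
    pronation: float = 0.0
    flexion: float = 0.0


@dataclass
class NoiseSpec:
    depth_sigma: float = 0.0  # mm, Gaussian, added to exact depth
    quantize_11bit: bool = False  # uniform 2048-level quantization of the range


@dataclass
class SceneSpec:
    table: TableSpec = field(default_factory=TableSpec)
    objects: list[ObjectSpec] = field(default_factory=list)
    arm: ArmSpec | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    hand_side: str = "right"
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SceneSpec":
        raw = json.loads(text)
        spec = cls(
            table=TableSpec(**raw.get("table", {})),
            objects=[ObjectSpec(**o) for o in raw.get("objects", [])],
            arm=ArmSpec(**raw["arm"]) if raw.get("arm") else None,
            noise=NoiseSpec(**raw.get("noise", {})),
            hand_side=raw.get("hand_side", "right"),
            seed=raw.get("seed", 0),
        )
        for o in spec.objects:
            o.position = tuple(o.position)
            o.color = tuple(o.color)
        spec.table.color = tuple(spec.table.color)
        return spec


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class ObjectTruth:
    shape: str
    dims: dict
    centroid: np.ndarray  # scene frame, mm (solid centroid)
    height: float
    footprint_axes: tuple[float, float]  # physical extents (major, minor), mm
    handle_side: str | None  # 'left' | 'right' | None
    true_grasp: str | None
    label_id: int
    color: tuple[int, int, int]


@dataclass
class HandTruth:
    reference_point: np.ndarray  # paddle centre, scene frame
    fingertip: np.ndarray
    wrist: np.ndarray
    start_point: np.ndarray  # far (off-table) end of the forearm axis
    pronation: float
    flexion: float
    normal: np.ndarray  # paddle plane normal, scene frame
    forearm_axis: np.ndarray


@dataclass
class GroundTruth:
    table_plane: PlaneModel  # camera frame
    objects: list[ObjectTruth]
    hand: HandTruth | None
    hand_side: str
    label_image: np.ndarray | None = None  # (H, W) int, see LBL_* ids
    shadow_mask: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def object_mask(self, i: int = 0) -> np.ndarray:
        return self.label_image == self.objects[i].label_id

    @property
    def arm_mask(self) -> np.ndarray:
        return (self.label_image == LBL_FOREARM) | (self.label_image == LBL_HAND)

    @property
    def hand_mask(self) -> np.ndarray:
        return self.label_image == LBL_HAND


def camera_pose(cam: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    """(R, c): scene coords of a camera point q are ``R @ q + c``."""
    R = camera_to_table_rotation(cam.tilt_theta)  # camera->scene axes
    c = np.array([0.0, 0.0, cam.mount_height])
    return R, c


def to_scene_frame(points_cam: np.ndarray, cam: CameraModel) -> np.ndarray:
    R, c = camera_pose(cam)
    return np.asarray(points_cam, dtype=np.float64) @ R.T + c


# ---------------------------------------------------------------------------
# Analytic surfaces
# ---------------------------------------------------------------------------


def _rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    ca, sa = np.cos(a), np.sin(a)
    return np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    ca, sa = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, ca, -sa], [0.0, sa, ca]])


def _rot_y(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    ca, sa = np.cos(a), np.sin(a)
    return np.array([[ca, 0.0, sa], [0.0, 1.0, 0.0], [-sa, 0.0, ca]])


def _ray_table(o, D, table: TableSpec):
    t = np.full(D.shape[0], np.inf)
    dz = D[:, 2]
    m = dz < 0
    tt = -o[2] / np.where(m, dz, 1.0)
    x = o[0] + tt * D[:, 0]
    y = o[1] + tt * D[:, 1]
    ok = m & (tt > 0) & (x >= table.x_min) & (x <= table.x_max) & (y >= table.y_min) & (y <= table.y_max)
    t[ok] = tt[ok]
    return t


def _ray_sphere(o, D, centre, radius):
    oc = o - centre
    a = np.einsum("ij,ij->i", D, D)
    b = 2.0 * D @ oc
    c = oc @ oc - radius * radius
    disc = b * b - 4 * a * c
    t = np.full(D.shape[0], np.inf)
    m = disc >= 0
    sq = np.sqrt(np.where(m, disc, 0.0))
    t0 = (-b - sq) / (2 * a)
    ok = m & (t0 > 0)
    t[ok] = t0[ok]
    return t


def _ray_box(o, D, centre, rot, half):
    """Oriented box; ``rot`` maps local to scene coordinates."""
    ol = (o - centre) @ rot
    Dl = D @ rot
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / Dl
        t1 = (-half - ol) * inv
        t2 = (half - ol) * inv
    tmin = np.nanmax(np.minimum(t1, t2), axis=1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=1)
    # rays parallel to a slab axis: inv = inf, products are +-inf, fine unless
    # the origin coordinate is exactly on a face (not the case here)
    t = np.full(D.shape[0], np.inf)
    ok = (tmax >= tmin) & (tmax > 0) & (tmin > 0)
    t[ok] = tmin[ok]
    return t


def _ray_cylinder(o, D, centre_xy, radius, height):
    """Vertical solid cylinder, base on z=0."""
    ox, oy = o[0] - centre_xy[0], o[1] - centre_xy[1]
    a = D[:, 0] ** 2 + D[:, 1] ** 2
    b = 2.0 * (ox * D[:, 0] + oy * D[:, 1])
    c = ox * ox + oy * oy - radius * radius
    t = np.full(D.shape[0], np.inf)
    disc = b * b - 4 * a * c
    m = (disc >= 0) & (a > 1e-12)
    sq = np.sqrt(np.where(m, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_side = (-b - sq) / (2 * a)
    z = o[2] + t_side * D[:, 2]
    ok = m & (t_side > 0) & (z >= 0) & (z <= height)
    t[ok] = t_side[ok]
    # top cap
    dz = D[:, 2]
    mc = dz < 0
    t_cap = (height - o[2]) / np.where(mc, dz, 1.0)
    x = ox + t_cap * D[:, 0]
    y = oy + t_cap * D[:, 1]
    okc = mc & (t_cap > 0) & (x * x + y * y <= radius * radius)
    t = np.where(okc & (t_cap < t), t_cap, t)
    return t


def _object_surfaces(obj: ObjectSpec):
    """Yield (kind, params) surfaces for one object, in the scene frame."""
    x, y = obj.position
    d = obj.dims
    if obj.shape == "sphere":
        r = d["radius"]
        yield ("sphere", (np.array([x, y, r]), r))
    elif obj.shape in ("box", "thin_box"):
        half = np.array([d["length"] / 2, d["width"] / 2, d["height"] / 2])
        centre = np.array([x, y, d["height"] / 2])
        yield ("box", (centre, _rot_z(obj.yaw), half))
    elif obj.shape in ("cylinder", "cylinder_with_handle"):
        yield ("cylinder", (np.array([x, y]), d["radius"], d["height"]))
        if obj.shape == "cylinder_with_handle":
            hl = d["handle_length"]
            hw = d["handle_width"]
            hh = d.get("handle_height", 0.45 * d["height"])
            rot = _rot_z(obj.yaw)
            radial = rot @ np.array([1.0, 0.0, 0.0])
            centre = np.array([x, y, d["height"] / 2]) + radial * (d["radius"] + hl / 2)
            yield ("box", (centre, rot, np.array([hl / 2, hw / 2, hh / 2])))
    else:
        raise ValueError(f"unknown shape {obj.shape!r}")


def _cast(o, D, surfaces):
    """Smallest positive t and surface index per ray (-1 = miss)."""
    t_best = np.full(D.shape[0], np.inf)
    idx = np.full(D.shape[0], -1, dtype=np.int32)
    for i, (kind, params) in enumerate(surfaces):
        if kind == "table":
            t = _ray_table(o, D, params)
        elif kind == "sphere":
            t = _ray_sphere(o, D, *params)
        elif kind == "box":
            t = _ray_box(o, D, *params)
        elif kind == "cylinder":
            t = _ray_cylinder(o, D, *params)
        else:  # pragma: no cover
            raise ValueError(kind)
        closer = t < t_best
        t_best[closer] = t[closer]
        idx[closer] = i
    return t_best, idx


# ---------------------------------------------------------------------------
# Arm construction
# ---------------------------------------------------------------------------


def _arm_geometry(arm: ArmSpec, table: TableSpec):
    """Forearm and paddle boxes plus analytic hand ground truth."""
    if arm.entry_edge != "right":
        raise ValueError("only right-edge arm entry is modelled")
    x_edge = table.x_max
    z = arm.plane_height
    x_start = x_edge + arm.overhang
    x_wrist = x_start - arm.forearm_length
    wrist = np.array([x_wrist, arm.entry_y, z])
    forearm_centre = np.array([(x_start + x_wrist) / 2, arm.entry_y, z])
    forearm_half = np.array([arm.forearm_length / 2, arm.forearm_width / 2, arm.forearm_thickness / 2])

    # paddle pose: pronation about the forearm (x) axis, then flexion about
    # the wrist axis; positive flexion sends fingertips toward the table
    Q = _rot_y(-arm.flexion) @ _rot_x(arm.pronation)
    u = Q @ np.array([-1.0, 0.0, 0.0])  # wrist -> fingertip direction
    normal = Q @ np.array([0.0, 0.0, 1.0])
    centre = wrist + u * (arm.hand_length / 2)
    half = np.array([arm.hand_length / 2, arm.hand_width / 2, arm.hand_thickness / 2])

    # the grasp centre sits at the metacarpophalangeal region, ~60% of the
    # hand length from the wrist
    truth = HandTruth(
        reference_point=wrist + u * (0.6 * arm.hand_length),
        fingertip=wrist + u * arm.hand_length,
        wrist=wrist,
        start_point=np.array([x_start, arm.entry_y, z]),
        pronation=arm.pronation,
        flexion=arm.flexion,
        normal=normal,
        forearm_axis=np.array([-1.0, 0.0, 0.0]),
    )
    boxes = [
        (forearm_centre, np.eye(3), forearm_half),  # forearm
        (centre, Q, half),  # hand paddle
    ]
    return boxes, truth


# ---------------------------------------------------------------------------
# Ground truth from a spec (analytic, no rendering required)
# ---------------------------------------------------------------------------


def _object_truth(obj: ObjectSpec, i: int, true_grasp: str | None = None) -> ObjectTruth:
    d = obj.dims
    x, y = obj.position
    if obj.shape == "sphere":
        r = d["radius"]
        centroid = np.array([x, y, r])
        height = 2 * r
        foot = (2 * r, 2 * r)
        handle = None
    elif obj.shape in ("box", "thin_box"):
        centroid = np.array([x, y, d["height"] / 2])
        height = d["height"]
        foot = (max(d["length"], d["width"]), min(d["length"], d["width"]))
        handle = None
    else:
        centroid = np.array([x, y, d["height"] / 2])
        height = d["height"]
        if obj.shape == "cylinder_with_handle":
            foot = (2 * d["radius"] + d["handle_length"], 2 * d["radius"])
            c = np.cos(np.deg2rad(obj.yaw))
            handle = "right" if c > 0.3 else ("left" if c < -0.3 else None)
        else:
            foot = (2 * d["radius"], 2 * d["radius"])
            handle = None
    return ObjectTruth(
        shape=obj.shape,
        dims=dict(d),
        centroid=centroid,
        height=height,
        footprint_axes=foot,
        handle_side=handle,
        true_grasp=true_grasp,
        label_id=LBL_OBJECT0 + i,
        color=tuple(obj.color),
    )


def _table_plane_camera(cam: CameraModel) -> PlaneModel:
    # table normal (up) in camera coordinates; canonical form offset >= 0
    t = np.deg2rad(cam.tilt_theta)
    normal = np.array([0.0, np.cos(t), np.sin(t)])  # -up, so offset is +mount_height
    return PlaneModel(normal=normal, offset=cam.mount_height)


def ground_truth_from_spec(
    spec: SceneSpec, cam: CameraModel, labels: list[str] | None = None
) -> GroundTruth:
    objs = [
        _object_truth(o, i, labels[i] if labels else None) for i, o in enumerate(spec.objects)
    ]
    hand = _arm_geometry(spec.arm, spec.table)[1] if spec.arm else None
    return GroundTruth(
        table_plane=_table_plane_camera(cam),
        objects=objs,
        hand=hand,
        hand_side=spec.hand_side,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _quantize_11bit(depth: np.ndarray, rng_lo: float, rng_hi: float) -> np.ndarray:
    step = (rng_hi - rng_lo) / 2047.0
    q = np.where(depth > 0, rng_lo + np.round((depth - rng_lo) / step) * step, 0.0)
    return q


def render_scene(
    spec: SceneSpec,
    cam: CameraModel | None = None,
    labels: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[DepthFrame, ColorFrame, GroundTruth]:
    """Ray-cast a scene into a registered depth/color frame pair.

    Depth is the exact distance along the optical axis to the nearest
    surface, in mm, with Gaussian noise of ``spec.noise.depth_sigma`` added
    and values outside the sensor range marked invalid (0).  Color is flat
    shaded per surface.  The returned ground truth carries the per-pixel
    label image and analytic object/hand geometry.
    """
    cam = cam or CameraModel()
    gt = ground_truth_from_spec(spec, cam, labels)
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    surfaces: list[tuple[str, tuple]] = [("table", spec.table)]
    ids = [LBL_TABLE]
    for i, obj in enumerate(spec.objects):
        for surf in _object_surfaces(obj):
            surfaces.append(surf)
            ids.append(LBL_OBJECT0 + i)
    if spec.arm is not None:
        boxes, _ = _arm_geometry(spec.arm, spec.table)
        for j, box in enumerate(boxes):
            surfaces.append(("box", box))
            ids.append(LBL_FOREARM if j == 0 else LBL_HAND)

    R, c = camera_pose(cam)
    rays = pixel_rays(cam).reshape(-1, 3)
    D = rays @ R.T  # ray directions in the scene frame; t = optical-axis depth
    t, idx = _cast(c, D, surfaces)

    H, W = cam.height, cam.width
    hit = idx >= 0
    depth = np.where(hit, t, 0.0)
    label = np.where(hit, np.array(ids, dtype=np.int32)[np.clip(idx, 0, None)], LBL_BACKGROUND)
    label = label.reshape(H, W)

    # colors (independent of depth validity: the RGB camera always sees)
    color = np.empty((H * W, 3), dtype=np.uint8)
    color[:] = BACKGROUND_COLOR
    flat_label = label.reshape(-1)
    color[flat_label == LBL_TABLE] = spec.table.color
    for i, obj in enumerate(spec.objects):
        color[flat_label == LBL_OBJECT0 + i] = obj.color
    color[(flat_label == LBL_FOREARM) | (flat_label == LBL_HAND)] = SKIN_COLOR

    # shadow decals: darkened table footprint behind the object (beyond the
    # object's own occlusion border so a visible ribbon borders the mask)
    shadow = np.zeros(H * W, dtype=bool)
    hit_pts = c + D * np.where(hit, t, 1.0)[:, None]
    for i, obj in enumerate(spec.objects):
        if not obj.shadow:
            continue
        ot = gt.objects[i]
        ox, oy = obj.position
        sx = ot.footprint_axes[0] / 2 + 15.0
        sy = ot.height / 2 + 50.0
        cy = oy + ot.height / 2
        on_table = flat_label == LBL_TABLE
        ex = (hit_pts[:, 0] - ox) / sx
        ey = (hit_pts[:, 1] - cy) / sy
        inside = on_table & (ex * ex + ey * ey <= 1.0)
        shadow |= inside
    color[shadow] = (np.array(spec.table.color) * 0.55).astype(np.uint8)
    color = color.reshape(H, W, 3)

    # sensor noise / range clamp / quantization
    depth = depth.reshape(H, W)
    if spec.noise.depth_sigma > 0:
        valid = depth > 0
        depth = depth + np.where(valid, rng.normal(0.0, spec.noise.depth_sigma, depth.shape), 0.0)
    lo, hi = cam.depth_range
    depth = np.where((depth >= lo) & (depth <= hi), depth, 0.0)
    if spec.noise.quantize_11bit:
        depth = _quantize_11bit(depth, lo, hi)

    # frustum check
    for i, ot in enumerate(gt.objects):
        if not (label == ot.label_id).any():
            msg = f"object {i} ({ot.shape}) is not visible in the rendered frame"
            warnings.warn(msg, stacklevel=2)
            gt.flags.append(msg)

    gt.label_image = label
    gt.shadow_mask = shadow.reshape(H, W)
    return DepthFrame(depth), ColorFrame(color), gt


def render_background_frames(
    spec: SceneSpec, cam: CameraModel | None = None, n_frames: int = 15, seed: int | None = None
) -> list[DepthFrame]:
    """Object/arm-free frames of the scene's table for background estimation.

    The rig is static, so the exact table depth is rendered once and each
    frame is an independent noise realization of it.
    """
    cam = cam or CameraModel()
    bare = SceneSpec(table=spec.table, noise=NoiseSpec(0.0, False), seed=spec.seed)
    depth0, _, _ = render_scene(bare, cam)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    lo, hi = cam.depth_range
    out = []
    for _ in range(n_frames):
        d = depth0.depth.copy()
        if spec.noise.depth_sigma > 0:
            d += np.where(d > 0, rng.normal(0.0, spec.noise.depth_sigma, d.shape), 0.0)
        d = np.where((d >= lo) & (d <= hi), d, 0.0)
        if spec.noise.quantize_11bit:
            d = _quantize_11bit(d, lo, hi)
        out.append(DepthFrame(d))
    return out


# ---------------------------------------------------------------------------
# Test-set generation
# ---------------------------------------------------------------------------

EVALUATION_COMPOSITION = {"lateral": 42, "palmar": 17, "pinch": 19, "spherical": 6}

# sampling regions for object centres: well inside the table and the
# frustum; taller objects sit nearer the camera so their tops stay in view
_POS_X = (-350.0, 350.0)
_POS_Y_FLAT = (800.0, 1500.0)  # objects below ~5 cm
_POS_Y_MID = (750.0, 1000.0)  # mugs, vertical CD cases (<= ~14 cm)
_POS_Y_TALL = (650.0, 850.0)  # bottles (<= ~26 cm)


def _sample_object(label: str, rng: np.random.Generator, hand_side: str) -> ObjectSpec:
    """Draw one object whose analytically correct grasp is ``label``.

    Dimension ranges emulate the named household objects of the four grasp
    classes (pencil/spoon and handled mugs for lateral; bottles, vertical CD
    cases and turned-away mugs for palmar; phones/keys/flat discs for pinch;
    balls for spherical) with margins to the classifier thresholds so the
    ground-truth label is unambiguous.
    """
    color = OBJECT_PALETTE[rng.integers(len(OBJECT_PALETTE))]
    shadow = False
    sign = 1.0 if hand_side == "right" else -1.0

    if label == "lateral":
        if rng.random() < 0.6:  # pencil / spoon: thin elongated, flat
            pos = (rng.uniform(*_POS_X), rng.uniform(*_POS_Y_FLAT))
            length = rng.uniform(120, 180)
            width = rng.uniform(6, 14)
            height = rng.uniform(6, 14)
            return ObjectSpec(
                "thin_box",
                {"length": length, "width": width, "height": height},
                pos,
                yaw=rng.uniform(0, 180),
                color=color,
            )
        # mug / coffee pot with the handle toward the hand side
        pos = (rng.uniform(*_POS_X), rng.uniform(*_POS_Y_MID))
        yaw = rng.uniform(-40, 40)
        if sign < 0:
            yaw += 180.0
        return ObjectSpec(
            "cylinder_with_handle",
            {
                "radius": rng.uniform(35, 45),
                "height": rng.uniform(90, 120),
                "handle_length": rng.uniform(35, 50),
                "handle_width": rng.uniform(16, 24),
            },
            pos,
            yaw=yaw,
            color=color,
            shadow=bool(rng.random() < 0.3),
        )
    if label == "palmar":
        u = rng.random()
        if u < 0.5:  # bottle
            pos = (rng.uniform(*_POS_X), rng.uniform(*_POS_Y_TALL))
            return ObjectSpec(
                "cylinder",
                {"radius": rng.uniform(30, 45), "height": rng.uniform(180, 260)},
                pos,
                color=color,
                shadow=bool(rng.random() < 0.3),
            )
        if u < 0.75:  # CD case standing on edge
            pos = (rng.uniform(*_POS_X), rng.uniform(*_POS_Y_MID))
            return ObjectSpec(
                "box",
                {
                    "length": rng.uniform(120, 140),
                    "width": rng.uniform(8, 14),
                    "height": rng.uniform(120, 140),
                },
                pos,
                yaw=rng.uniform(0, 180),
                color=color,
            )
        # mug with the handle turned away from the hand
        pos = (rng.uniform(*_POS_X), rng.uniform(*_POS_Y_MID))
        yaw = rng.uniform(140, 220)
        if sign < 0:
            yaw += 180.0
        return ObjectSpec(
            "cylinder_with_handle",
            {
                "radius": rng.uniform(35, 45),
                "height": rng.uniform(90, 120),
                "handle_length": rng.uniform(35, 50),
                "handle_width": rng.uniform(16, 24),
            },
            pos,
            yaw=yaw,
            color=color,
        )
    if label == "pinch":
        pos = (rng.uniform(*_POS_X), rng.uniform(*_POS_Y_FLAT))
        if rng.random() < 0.7:  # phone / keys: flat, not elongated
            length = rng.uniform(90, 140)
            width = length * rng.uniform(0.5, 0.85)
            return ObjectSpec(
                "thin_box",
                {"length": length, "width": width, "height": rng.uniform(8, 18)},
                pos,
                yaw=rng.uniform(0, 180),
                color=color,
            )
        # CD lying flat: a thin disc
        return ObjectSpec(
            "cylinder",
            {"radius": rng.uniform(55, 65), "height": rng.uniform(6, 10)},
            pos,
            color=color,
        )
    if label == "spherical":
        # balls
        return ObjectSpec(
            "sphere",
            {"radius": rng.uniform(28, 42)},
            (rng.uniform(-250, 250), rng.uniform(700, 1100)),
            color=color,
            shadow=bool(rng.random() < 0.3),
        )
    raise ValueError(f"unknown grasp label {label!r}")


def generate_test_set(
    composition: dict[str, int] | None = None,
    seed: int = 0,
    depth_sigma: float = 3.0,
    quantize_11bit: bool = True,
    cam: CameraModel | None = None,
    hand_side: str = "right",
) -> list[tuple[SceneSpec, GroundTruth]]:
    """Scenes with randomized object sizes/orientations per grasp class.

    ``composition`` maps grasp label to scene count (default: the 86-image
    evaluation composition, 42 lateral / 17 palmar / 19 pinch /
    6 spherical).  Deterministic given ``seed``.
    """
    composition = dict(EVALUATION_COMPOSITION if composition is None else composition)
    if any(v < 0 for v in composition.values()):
        raise ValueError("composition counts must be >= 0")
    cam = cam or CameraModel()
    rng = np.random.default_rng(seed)
    out = []
    for label in GRASP_TYPES:
        for _ in range(composition.get(label, 0)):
            obj = _sample_object(label, rng, hand_side)
            spec = SceneSpec(
                objects=[obj],
                noise=NoiseSpec(depth_sigma=depth_sigma, quantize_11bit=quantize_11bit),
                hand_side=hand_side,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            out.append((spec, ground_truth_from_spec(spec, cam, labels=[label])))
    return out
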