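"""Camera model, depth back-projection and coordinate-frame transforms.

Conventions used throughout the package (fixed here, nowhere else):

* **Camera frame** — x right, y down, z along the optical axis, units mm.
* **Table frame** — z up (perpendicular to the table surface), x parallel to
  the camera's x axis (i.e. along the table edge nearest the camera), y
  pointing away from the camera across the table.  The rotation between the
  two frames is parameterized by the rig tilt angle ``theta`` (the angle
  between the optical axis and the table surface, 45 degrees for the default
  rig).
* **Anatomical projection views** (used by the grasp classifier) are named in
  the table frame: *transverse* = horizontal plane (normal +z), *frontal* =
  plane with normal +x, *sagittal* = plane with normal +y.

Depth rasters store the distance along the optical axis in millimetres;
``0`` marks an invalid pixel (out of sensor range).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# Camera model and frames
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera plus the table-top rig extrinsics.

    ``tilt_theta`` is the angle between the optical axis and the table
    surface; ``mount_height`` the height of the optical centre above the
    table, both describing the default rig (sensor on a 0.6 m stand tilted
    45 degrees down at the table).
    """

    width: int = 640
    height: int = 480
    focal_length: float = 525.0
    principal_point: tuple[float, float] = (319.5, 239.5)
    mount_height: float = 600.0
    tilt_theta: float = 45.0
    depth_range: tuple[float, float] = (500.0, 3000.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.tilt_theta < 90.0):
            raise ValueError("tilt_theta must lie in (0, 90) degrees")
        if self.depth_range[0] >= self.depth_range[1]:
            raise ValueError("depth_range must be (near, far) with near < far")


@dataclass
class DepthFrame:
    """Depth raster in mm; 0 marks invalid pixels."""

    depth: np.ndarray  # (H, W) float64, mm

    @property
    def valid(self) -> np.ndarray:
        return self.depth > 0


@dataclass
class ColorFrame:
    """8-bit RGB raster registered with the depth frame."""

    rgb: np.ndarray  # (H, W, 3) uint8


@dataclass
class PointCloud3D:
    """Points in mm with a frame tag and an optional pixel provenance map."""

    points: np.ndarray  # (N, 3) float64
    frame_tag: str = "camera"  # "camera" | "table"
    pixel_index: np.ndarray | None = None  # (N, 2) int (row, col)

    def __len__(self) -> int:
        return len(self.points)


_RAY_CACHE: dict[tuple, np.ndarray] = {}


def pixel_rays(cam: CameraModel) -> np.ndarray:
    """Per-pixel ray directions ``((u-cx)/f, (v-cy)/f, 1)``, shape (H, W, 3).

    With this parameterization a surface point at parameter ``t`` along the
    ray has camera-frame z coordinate exactly ``t``, i.e. ``t`` *is* the
    depth value the sensor reports.
    """
    key = (cam.width, cam.height, cam.focal_length, cam.principal_point)
    if key not in _RAY_CACHE:
        cx, cy = cam.principal_point
        u = np.arange(cam.width, dtype=np.float64)
        v = np.arange(cam.height, dtype=np.float64)
        uu, vv = np.meshgrid(u, v)
        rays = np.stack(
            [(uu - cx) / cam.focal_length, (vv - cy) / cam.focal_length, np.ones_like(uu)],
            axis=-1,
        )
        _RAY_CACHE[key] = rays
    return _RAY_CACHE[key]


def depth_to_points(depth: DepthFrame, cam: CameraModel) -> PointCloud3D:
    """Back-project every valid pixel of a depth frame into the camera frame.

    Invalid (zero) pixels are omitted.  An all-invalid frame yields an empty
    cloud and a warning.
    """
    d = depth.depth
    if d.shape != (cam.height, cam.width):
        raise ValueError("depth frame dimensions do not match the camera model")
    valid = d > 0
    if not valid.any():
        warnings.warn("depth frame contains no valid pixels", stacklevel=2)
        return PointCloud3D(np.empty((0, 3)), "camera", np.empty((0, 2), dtype=np.intp))
    rays = pixel_rays(cam)
    pts = rays[valid] * d[valid][:, None]
    rc = np.argwhere(valid)
    return PointCloud3D(pts, "camera", rc)


def camera_to_table_rotation(theta_deg: float) -> np.ndarray:
    """Rotation matrix mapping camera-frame vectors to table-frame vectors.

    Rows are the table-frame axes expressed in camera coordinates; for the
    rig geometry (camera pitched down by ``theta`` towards the table) the
    table normal in camera coordinates is (0, -cos theta, -sin theta), so the
    transform sends every table-surface point to a constant z.
    """
    if not (0.0 < theta_deg < 90.0):
        raise ValueError("theta must lie in (0, 90) degrees")
    t = np.deg2rad(theta_deg)
    s, c = np.sin(t), np.cos(t)
    return np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, -s, c],
            [0.0, -c, -s],
        ]
    )


@dataclass(frozen=True)
class TableFrame:
    """Rigid transform from the camera frame to a table-anchored frame.

    ``origin`` is a camera-frame point on the table plane (any table point is
    admissible; the pipeline uses the centroid of the detected plane's
    inliers).  z in the target frame is height above the table.
    """

    origin: np.ndarray  # (3,) camera frame, mm
    theta_deg: float
    rotation: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=np.float64))
        object.__setattr__(self, "rotation", camera_to_table_rotation(self.theta_deg))

    def to_table(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=np.float64) - self.origin) @ self.rotation.T

    def to_camera(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation + self.origin


def to_table_frame(cloud: PointCloud3D, origin: np.ndarray, theta_deg: float) -> PointCloud3D:
    """Rigidly transform a camera-frame cloud into the table frame.

    Translation by ``-origin`` followed by the tilt rotation; the output z
    axis is the vertical component (height above the table).
    """
    if cloud.frame_tag != "camera":
        raise ValueError("to_table_frame expects a camera-frame cloud")
    frame = TableFrame(origin, theta_deg)
    return PointCloud3D(frame.to_table(cloud.points), "table", cloud.pixel_index)


# ---------------------------------------------------------------------------
# Projection views (transverse / frontal / sagittal)
# ---------------------------------------------------------------------------

VIEW_ANGLES = {
    "transverse": (0.0, 90.0),
    "frontal": (90.0, 0.0),
    "sagittal": (0.0, 0.0),
}


@dataclass(frozen=True)
class ProjectionView:
    """A named anatomical projection plane given by azimuth/elevation angles."""

    az: float
    el: float
    name: str = ""

    @classmethod
    def named(cls, name: str) -> "ProjectionView":
        az, el = VIEW_ANGLES[name]
        return cls(az, el, name)


def view_normal(view: ProjectionView | str) -> np.ndarray:
    """Unit normal of a projection plane from its azimuth/elevation angles.

    Spherical construction: ``(cos el sin az, cos el cos az, sin el)``.  The
    named views map to the table-frame axes — transverse (az=0, el=90) to the
    vertical axis, frontal (az=90, el=0) and sagittal (az=0, el=0) to the two
    horizontal axes.
    """
    if isinstance(view, str):
        view = ProjectionView.named(view)
    az, el = np.deg2rad(view.az), np.deg2rad(view.el)
    n = np.array([np.cos(el) * np.sin(az), np.cos(el) * np.cos(az), np.sin(el)])
    return n / np.linalg.norm(n)


def plane_basis(normal: np.ndarray) -> np.ndarray:
    """Orthonormal in-plane basis (3, 2) for a plane with the given normal.

    Obtained from the singular decomposition of the normal (the right
    singular vectors orthogonal to it), with a deterministic sign fix so the
    basis is reproducible.
    """
    n = np.asarray(normal, dtype=np.float64)
    n = n / np.linalg.norm(n)
    _, _, vt = np.linalg.svd(n[None, :])
    basis = vt[1:].T  # (3, 2), columns orthonormal, both orthogonal to n
    # deterministic sign: make the largest-magnitude entry of each column positive
    for j in range(2):
        k = np.argmax(np.abs(basis[:, j]))
        if basis[k, j] < 0:
            basis[:, j] = -basis[:, j]
    return basis


def project_to_plane(cloud: PointCloud3D | np.ndarray, view: ProjectionView | str) -> np.ndarray:
    """Project table-frame points onto a named plane, returning (N, 2) coords.

    The in-plane coordinates are taken in an orthonormal basis of the plane,
    so the projection is an isometry for points already lying in the plane.
    """
    pts = cloud.points if isinstance(cloud, PointCloud3D) else np.asarray(cloud, dtype=np.float64)
    if isinstance(cloud, PointCloud3D) and cloud.frame_tag != "table":
        raise ValueError("project_to_plane expects a table-frame cloud")
    if len(pts) == 0:
        return np.empty((0, 2))
    basis = plane_basis(view_normal(view))
    return pts @ basis


def write_ply(points: np.ndarray, path) -> None:
    """Write an ascii PLY point cloud (debug aid)."""
    pts = np.asarray(points, dtype=np.float64)
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\nelement vertex %d\n"
            "property float x\nproperty float y\nproperty float z\nend_header\n" % len(pts)
        )
        np.savetxt(fh, pts, fmt="%.4f")
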