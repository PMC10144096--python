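"""3D localization from a 2D bounding box, a depth patch, and the observer pose.

A detector gives a pixel bounding box around the animal; the stereo camera
gives per-pixel depth.  The pipeline implemented here recovers the
world-frame 3D position in four steps:

1. contract the bounding box about its center by a scale factor ``theta``
   (the interior rectangle avoids averaging background depth near the box
   edges),
2. average the valid depth readings inside the contracted box to get the
   range ``s`` to the target,
3. back-project the box center through the pinhole model,
   ``X_C = K^-1 (s [u, v, 1]^T)``,
4. map the camera-frame point through the fixed camera-to-body transform
   and the observer's body-to-world pose.

Pixel convention: origin at the top-left corner, ``u`` rightward, ``v``
downward; ``(cx, cy)`` is the box center in the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InvalidParameterError, InvalidPoseError, NoDepthError

__all__ = [
    "BoundingBox2D",
    "ScaledROI",
    "DepthPatch",
    "CameraIntrinsics",
    "ObserverPose",
    "RigidTransform",
    "shrink_roi",
    "mean_valid_depth",
    "backproject",
    "camera_to_body",
    "body_to_world",
    "localize",
    "DEFAULT_THETA",
]

#: Default bounding-box contraction factor (interior half-box).
DEFAULT_THETA = 0.5

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class BoundingBox2D:
    """Axis-aligned pixel box given by center ``(cx, cy)`` and size ``(w, h)``."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not (np.isfinite(self.cx) and np.isfinite(self.cy)):
            raise InvalidParameterError("box center must be finite")
        if self.w <= 0 or self.h <= 0:
            raise InvalidParameterError("box width and height must be positive")


@dataclass(frozen=True)
class ScaledROI:
    """A bounding box contracted by ``theta``; same center, scaled size."""

    cx: float
    cy: float
    w: float
    h: float
    theta: float

    def pixel_indices(self, shape: tuple[int, int] | None = None):
        """Integer pixel (row, col) indices whose centers fall inside the box.

        The box is rasterized half-open, ``[x0, x1) x [y0, y1)``; a pixel
        ``(r, c)`` has its center at ``(u, v) = (c + 0.5, r + 0.5)``.
        ``shape`` optionally clips to an image/patch extent.
        """
        x0, x1 = self.cx - self.w / 2.0, self.cx + self.w / 2.0
        y0, y1 = self.cy - self.h / 2.0, self.cy + self.h / 2.0
        c0, c1 = int(np.ceil(x0 - 0.5)), int(np.ceil(x1 - 0.5))
        r0, r1 = int(np.ceil(y0 - 0.5)), int(np.ceil(y1 - 0.5))
        if shape is not None:
            r0, r1 = max(r0, 0), min(r1, shape[0])
            c0, c1 = max(c0, 0), min(c1, shape[1])
        rows = np.arange(r0, max(r1, r0))
        cols = np.arange(c0, max(c1, c0))
        return np.meshgrid(rows, cols, indexing="ij")


@dataclass(frozen=True)
class DepthPatch:
    """Grid of stereo depth readings (meters) with a validity mask.

    Unfilled stereo pixels are marked invalid and excluded from averaging.
    """

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        valid = np.asarray(self.valid, dtype=bool)
        if values.shape != valid.shape:
            raise InvalidParameterError("depth values and mask shapes differ")
        if np.any(valid & ~(np.isfinite(values) & (values > 0))):
            raise InvalidParameterError("valid depths must be finite and > 0")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid", valid)


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsic matrix K (focal lengths and principal point, pixels)."""

    K: np.ndarray

    def __post_init__(self):
        K = np.asarray(self.K, dtype=np.float64)
        if K.shape != (3, 3):
            raise InvalidParameterError("K must be 3x3")
        if abs(K[2, 2] - 1.0) > 1e-12:
            raise InvalidParameterError("K[2,2] must equal 1")
        if abs(np.linalg.det(K)) < 1e-12:
            raise InvalidParameterError("K must be invertible")
        object.__setattr__(self, "K", K)


def _rotation_from_quaternion(q_wxyz) -> np.ndarray:
    q = np.asarray(q_wxyz, dtype=np.float64)
    if q.shape != (4,):
        raise InvalidPoseError("quaternion must have 4 components (w, x, y, z)")
    norm = np.linalg.norm(q)
    if norm < 1e-12:
        raise InvalidPoseError("quaternion has zero norm")
    q = q / norm
    # scipy uses (x, y, z, w) ordering
    return Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()


@dataclass(frozen=True)
class ObserverPose:
    """Observer (UAV) attitude R and position o relative to the world frame.

    ``R`` may be given directly or via a unit quaternion ``q`` in (w, x, y, z)
    order, which is normalized on ingest and converted to a matrix.
    """

    R: np.ndarray
    o: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.R, dtype=np.float64)
        o = np.asarray(self.o, dtype=np.float64).reshape(3)
        if R.shape != (3, 3):
            raise InvalidPoseError("R must be 3x3")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-6:
            raise InvalidPoseError("R is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise InvalidPoseError("R must be a proper rotation (det +1)")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "o", o)

    @classmethod
    def from_quaternion(cls, q_wxyz, position) -> "ObserverPose":
        return cls(_rotation_from_quaternion(q_wxyz), np.asarray(position, dtype=np.float64))


@dataclass(frozen=True)
class RigidTransform:
    """4x4 homogeneous transform; rotation block orthonormal, bottom row [0,0,0,1]."""

    M: np.ndarray

    def __post_init__(self):
        M = np.asarray(self.M, dtype=np.float64)
        if M.shape != (4, 4):
            raise InvalidParameterError("rigid transform must be 4x4")
        if np.max(np.abs(M[3] - np.array([0.0, 0.0, 0.0, 1.0]))) > _ORTHO_TOL:
            raise InvalidParameterError("bottom row must be [0,0,0,1]")
        R = M[:3, :3]
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-6:
            raise InvalidParameterError("upper-left block is not a rotation")
        object.__setattr__(self, "M", M)

    def apply(self, point) -> np.ndarray:
        """Transform a 3-vector (appends the homogeneous 1)."""
        p = np.asarray(point, dtype=np.float64).reshape(3)
        return self.M[:3, :3] @ p + self.M[:3, 3]

    def inverse(self) -> "RigidTransform":
        R = self.M[:3, :3]
        t = self.M[:3, 3]
        Minv = np.eye(4)
        Minv[:3, :3] = R.T
        Minv[:3, 3] = -R.T @ t
        return RigidTransform(Minv)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.M @ other.M)


def shrink_roi(box: BoundingBox2D, theta: float) -> ScaledROI:
    """Contract ``box`` about its center by scale ``theta`` in (0, 1]."""
    if not (0.0 < theta <= 1.0):
        raise InvalidParameterError(f"theta must be in (0, 1], got {theta}")
    return ScaledROI(box.cx, box.cy, theta * box.w, theta * box.h, theta)


def mean_valid_depth(patch: DepthPatch) -> float:
    """Arithmetic mean of the valid depth readings (the target range S)."""
    if not np.any(patch.valid):
        raise NoDepthError("depth patch has no valid pixels")
    return float(patch.values[patch.valid].mean())


def backproject(u: float, v: float, s: float, intrinsics: CameraIntrinsics) -> np.ndarray:
    """Invert the pinhole projection: X_C = K^-1 (s [u, v, 1]^T)."""
    if s <= 0:
        raise InvalidParameterError("depth must be positive")
    return np.linalg.solve(intrinsics.K, s * np.array([u, v, 1.0]))


def camera_to_body() -> RigidTransform:
    """Fixed transform from the camera frame to the UAV body frame.

    Camera optical axis (+z) maps to body forward (+x); camera +x (image
    right) to body -y; camera +y (image down) to body -z.
    """
    M = np.array(
        [
            [0.0, 0.0, 1.0, 0.0],
            [-1.0, 0.0, 0.0, 0.0],
            [0.0, -1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return RigidTransform(M)


def body_to_world(pose: ObserverPose) -> RigidTransform:
    """Homogeneous transform carrying body-frame points into the world frame."""
    M = np.eye(4)
    M[:3, :3] = pose.R
    M[:3, 3] = pose.o
    return RigidTransform(M)


def localize(
    box: BoundingBox2D,
    patch: DepthPatch,
    intrinsics: CameraIntrinsics,
    pose: ObserverPose,
    theta: float = DEFAULT_THETA,
) -> np.ndarray:
    """World-frame 3D position of the target behind a detection.

    The depth ``patch`` is interpreted as covering the *original* bounding
    box (patch pixel (0, 0) at the box's top-left corner); the contracted
    ROI selects the interior pixels whose valid depths are averaged.
    Raises :class:`NoDepthError` when no valid pixel survives; at tracking
    level the caller converts that into a missing measurement.
    """
    roi = shrink_roi(box, theta)
    # ROI in patch-local pixel coordinates
    local = ScaledROI(
        roi.cx - (box.cx - box.w / 2.0),
        roi.cy - (box.cy - box.h / 2.0),
        roi.w,
        roi.h,
        theta,
    )
    rows, cols = local.pixel_indices(patch.values.shape)
    if rows.size == 0:
        raise NoDepthError("contracted ROI covers no pixels")
    sub = DepthPatch(patch.values[rows, cols], patch.valid[rows, cols])
    s = mean_valid_depth(sub)
    x_c = backproject(box.cx, box.cy, s, intrinsics)
    return (body_to_world(pose) @ camera_to_body()).apply(x_c)
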