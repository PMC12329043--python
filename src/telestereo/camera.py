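"""Telecentric (affine) camera model.

A telecentric lens images the scene as a parallel projection: all chief
rays are parallel to the optical axis, so the recorded pixel position of a
world point does not depend on its depth.  The intrinsic matrix is purely
diagonal,

    K = diag(M_x / pp,  M_y / pp,  1)

with magnification ``M`` (dimensionless) and pixel pitch ``pp`` (mm/px).
There is no principal point: pixel coordinates are *centered*, i.e. (0, 0)
is the image center, u grows rightward and v downward.  All lengths are in
millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TelecentricCamera",
    "Ray",
    "DegenerateGeometryError",
    "project",
    "backproject_ray",
    "triangulate",
    "triangulate_many",
    "rotation_matrix",
    "rotation_angle_deg",
]


class DegenerateGeometryError(ValueError):
    """Raised when rays are (nearly) parallel and cannot be intersected."""


def rotation_matrix(axis, angle_rad: float) -> np.ndarray:
    """Rotation about ``axis`` by ``angle_rad`` (Rodrigues formula)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    axis = axis / n
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1.0 - np.cos(angle_rad)) * (K @ K)


def rotation_angle_deg(Ra: np.ndarray, Rb: np.ndarray | None = None) -> float:
    """Geodesic angle (degrees) between two rotations (or of one rotation).

    Uses the atan2 form, which keeps full precision for small angles
    where the arccos-of-trace formula saturates.
    """
    R = np.asarray(Ra) if Rb is None else np.asarray(Ra).T @ np.asarray(Rb)
    s = 0.5 * np.linalg.norm(
        [R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arctan2(s, c)))


@dataclass(frozen=True)
class Ray:
    """World-space line: ``origin + s * direction`` with unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or abs(n - 1.0) > 1e-9:
            d = d / n
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)

    def point_distance(self, X) -> float:
        """Perpendicular distance from a point to the ray's line."""
        v = np.asarray(X, dtype=float) - self.origin
        return float(np.linalg.norm(v - (v @ self.direction) * self.direction))


@dataclass
class TelecentricCamera:
    """Affine camera: diagonal intrinsics plus a rigid pose (world→camera).

    Parameters
    ----------
    mag_x, mag_y:
        Dimensionless magnifications.  Anisotropy is allowed; calibrated
        systems often show a slight x/y difference.
    pixel_pitch:
        Sensor pixel pitch in mm/px.
    R, t:
        World→camera rigid transform: ``x_cam = R @ X + t`` (t in mm).
    image_size:
        (width, height) in pixels.
    """

    mag_x: float
    mag_y: float
    pixel_pitch: float
    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))
    image_size: tuple[int, int] = (256, 256)

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if not (self.mag_x > 0 and self.mag_y > 0 and self.pixel_pitch > 0):
            raise ValueError("magnifications and pixel pitch must be positive")
        if np.linalg.norm(self.R.T @ self.R - np.eye(3)) > 1e-8:
            raise ValueError("R is not orthonormal")
        if np.linalg.det(self.R) < 0:
            raise ValueError("R must be a proper rotation (det +1)")

    @property
    def K(self) -> np.ndarray:
        """Diagonal telecentric intrinsic matrix, entries in px/mm."""
        return np.diag(
            [self.mag_x / self.pixel_pitch, self.mag_y / self.pixel_pitch, 1.0]
        )

    @property
    def fx(self) -> float:
        return self.mag_x / self.pixel_pitch

    @property
    def fy(self) -> float:
        return self.mag_y / self.pixel_pitch

    @property
    def viewing_direction(self) -> np.ndarray:
        """World-space unit vector along which the camera looks (+z of cam)."""
        return self.R.T @ np.array([0.0, 0.0, 1.0])

    def pixel_footprint(self) -> tuple[float, float]:
        """World-space size (mm) of one pixel in x and y."""
        return self.pixel_pitch / self.mag_x, self.pixel_pitch / self.mag_y

    def with_pose(self, R, t) -> "TelecentricCamera":
        return TelecentricCamera(
            self.mag_x, self.mag_y, self.pixel_pitch, R, t, self.image_size
        )

    def to_dict(self) -> dict:
        return {
            "mag_x": float(self.mag_x),
            "mag_y": float(self.mag_y),
            "pixel_pitch_mm": float(self.pixel_pitch),
            "R": [float(v) for v in self.R.reshape(-1)],
            "t_mm": [float(v) for v in self.t],
            "width": int(self.image_size[0]),
            "height": int(self.image_size[1]),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TelecentricCamera":
        return cls(
            mag_x=float(d["mag_x"]),
            mag_y=float(d["mag_y"]),
            pixel_pitch=float(d["pixel_pitch_mm"]),
            R=np.asarray(d["R"], dtype=float).reshape(3, 3),
            t=np.asarray(d["t_mm"], dtype=float),
            image_size=(int(d["width"]), int(d["height"])),
        )


def project(cam: TelecentricCamera, X) -> np.ndarray:
    """Project world point(s) X (mm) to centered pixel coordinates.

    Accepts a single 3-vector or an (n, 3) array; returns (u, v) of the
    same leading shape.  The result is independent of the depth coordinate
    of ``R @ X + t`` — the defining telecentric property.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    Xc = np.atleast_2d(X) @ cam.R.T + cam.t
    uv = Xc[:, :2] * np.array([cam.fx, cam.fy])
    return uv[0] if single else uv


def backproject_ray(cam: TelecentricCamera, u: float, v: float) -> Ray:
    """World-space viewing ray of pixel (u, v).

    All points on the returned line project to exactly (u, v); the
    direction is the camera's viewing direction (parallel for all pixels).
    """
    p_cam = np.array(
        [u * cam.pixel_pitch / cam.mag_x - cam.t[0],
         v * cam.pixel_pitch / cam.mag_y - cam.t[1],
         -cam.t[2]]
    )
    return Ray(origin=cam.R.T @ p_cam, direction=cam.R.T @ np.array([0.0, 0.0, 1.0]))


def _ray_origins(cam: TelecentricCamera, uv: np.ndarray) -> np.ndarray:
    """Vectorized ray origins for an (n, 2) pixel array."""
    p = np.empty((len(uv), 3))
    p[:, 0] = uv[:, 0] * cam.pixel_pitch / cam.mag_x - cam.t[0]
    p[:, 1] = uv[:, 1] * cam.pixel_pitch / cam.mag_y - cam.t[1]
    p[:, 2] = -cam.t[2]
    return p @ cam.R


def triangulate(cam1: TelecentricCamera, cam2: TelecentricCamera, p1, p2):
    """Intersect the viewing rays of a correspondence pair.

    Returns ``(X, gap)`` where X is the midpoint of the common
    perpendicular between the two rays (mm) and gap is the minimum
    ray–ray distance, a per-point quality diagnostic.

    Raises
    ------
    DegenerateGeometryError
        If the two viewing directions are (anti-)parallel.
    """
    X, gap = triangulate_many(cam1, cam2, np.atleast_2d(p1), np.atleast_2d(p2))
    return X[0], float(gap[0])


def triangulate_many(cam1, cam2, uv1: np.ndarray, uv2: np.ndarray):
    """Vectorized two-ray triangulation for (n, 2) pixel arrays."""
    d1 = cam1.viewing_direction
    d2 = cam2.viewing_direction
    c = float(d1 @ d2)
    if abs(c) > 1.0 - 1e-12:
        raise DegenerateGeometryError(
            "viewing directions are parallel; stereo angle is degenerate"
        )
    o1 = _ray_origins(cam1, np.asarray(uv1, dtype=float))
    o2 = _ray_origins(cam2, np.asarray(uv2, dtype=float))
    b = o2 - o1
    denom = 1.0 - c * c
    bd1 = b @ d1
    bd2 = b @ d2
    s = (bd1 - bd2 * c) / denom
    u = (bd1 * c - bd2) / denom
    P1 = o1 + s[:, None] * d1
    P2 = o2 + u[:, None] * d2
    return 0.5 * (P1 + P2), np.linalg.norm(P1 - P2, axis=1)
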