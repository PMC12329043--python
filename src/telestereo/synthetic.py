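"""Synthetic scene rendering: the virtual stand-in for the physical rig.

The measurement principle needs two telecentric cameras watching a surface
while a projector throws a sequence of varying patterns onto it.  Each
surface point then carries a distinctive intensity time series, which both
cameras record identically (up to noise) — the basis of temporal
correlation matching.  This module renders that situation for analytic
surfaces (plane, sphere, line grid) with exact per-pixel ground truth, so
every downstream stage can be tested without hardware.

The projector is modeled as a *parallel* projector: the pattern is carried
along a single direction onto the scene.  This matches the strongly
stopped-down projection optics of a real rig well enough for testing and
keeps the pattern-to-surface mapping analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .camera import TelecentricCamera, rotation_matrix

__all__ = [
    "PatternStack",
    "ProjectorModel",
    "Plane",
    "Sphere",
    "GridPlane",
    "ImageStack",
    "RenderResult",
    "make_pattern_stack",
    "render_stack",
    "default_rig",
]

# Paper-scale rig constants: sensor pixel pitch (mm) and lens magnification.
SENSOR_PITCH_MM = 2.74e-3
DEFAULT_MAG = 0.69
FULL_SENSOR_PX = 2848


@dataclass
class PatternStack:
    """Temporal sequence of projected patterns, intensities in [0, 1]."""

    frames: np.ndarray  # (n_frames, H_p, W_p)
    pattern_pitch: float  # mm per pattern pixel on the projection plane
    seed: int = 0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("pattern frames must be (n_frames, H, W)")
        if self.frames.min() < -1e-9 or self.frames.max() > 1 + 1e-9:
            raise ValueError("pattern intensities must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ProjectorModel:
    """Parallel projector: pattern carried along ``direction`` onto the scene.

    ``up`` fixes the pattern's row axis; the column axis completes the
    frame.  ``pattern_pitch`` is mm per pattern pixel on the plane
    perpendicular to the direction.
    """

    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -1.0]))
    up: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    pattern_pitch: float = 0.043

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        u = np.asarray(self.up, dtype=float)
        d = d / np.linalg.norm(d)
        u = u / np.linalg.norm(u)
        if abs(d @ u) > 1e-10:
            raise ValueError("projector direction and up must be orthogonal")
        self.direction = d
        self.up = u
        if self.pattern_pitch <= 0:
            raise ValueError("pattern_pitch must be positive")

    @property
    def right(self) -> np.ndarray:
        return np.cross(self.up, self.direction)


@dataclass
class Plane:
    """Analytic plane ``normal · X = offset`` with optional micro-roughness.

    ``roughness_sigma`` (mm) perturbs each intersection point i.i.d. along
    the normal, emulating a reference flat of sub-micrometre roughness.
    """

    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    offset: float = 0.0
    roughness_sigma: float = 0.0
    albedo: float | Callable = 1.0

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)
        if self.roughness_sigma < 0:
            raise ValueError("roughness_sigma must be >= 0")


@dataclass
class Sphere:
    """Analytic sphere; the renderer sees the cap facing the camera."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 2.5
    albedo: float | Callable = 1.0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class GridPlane:
    """Plane z = offset carrying a line grid: bright lines on dark ground.

    Emulates a millimetre alignment plate used for metric scaling — high
    albedo lines every ``spacing`` mm on a strongly absorbing background.
    """

    spacing: float = 1.0
    line_width: float = 0.1
    bright: float = 0.9
    dark: float = 0.05
    offset: float = 0.0
    roughness_sigma: float = 0.0

    def __post_init__(self):
        if self.spacing <= 0 or self.line_width <= 0:
            raise ValueError("spacing and line_width must be positive")


SceneSpec = Plane | Sphere | GridPlane


@dataclass
class ImageStack:
    """Acquired frames of one camera, one frame per projected pattern."""

    frames: np.ndarray  # (n_frames, H, W), intensities in [0, 1]
    camera_id: str = "cam"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("image frames must be (n_frames, H, W)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class RenderResult:
    """Rendered stack plus exact per-pixel ground truth."""

    stack: ImageStack
    hit_mask: np.ndarray  # (H, W) bool
    points: np.ndarray  # (H, W, 3) true surface points (NaN where miss)


def make_pattern_stack(
    n_frames: int,
    size: tuple[int, int] = (256, 256),
    cutoff: float = 0.12,
    seed: int = 0,
    pattern_pitch: float = 0.043,
) -> PatternStack:
    """Band-limited pseudo-random pattern sequence.

    Each frame is white noise low-pass filtered at ``cutoff`` (cycles per
    pattern pixel, separable max-norm cutoff so 0.5 keeps everything),
    then affinely rescaled to span [0, 1].  Reproducible from ``seed``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    H, W = int(size[0]), int(size[1])
    if H <= 0 or W <= 0:
        raise ValueError("pattern size must be positive")
    if not (0.0 < cutoff <= 0.5):
        raise ValueError("cutoff must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_frames, H, W))
    fy = np.fft.fftfreq(H)[:, None]
    fx = np.fft.fftfreq(W)[None, :]
    mask = (np.abs(fx) <= cutoff) & (np.abs(fy) <= cutoff)
    spec = np.fft.fft2(noise, axes=(1, 2)) * mask
    frames = np.fft.ifft2(spec, axes=(1, 2)).real
    lo = frames.min(axis=(1, 2), keepdims=True)
    hi = frames.max(axis=(1, 2), keepdims=True)
    frames = (frames - lo) / np.where(hi > lo, hi - lo, 1.0)
    return PatternStack(frames=frames, pattern_pitch=pattern_pitch, seed=seed)


def _intersect(scene: SceneSpec, origins: np.ndarray, direction: np.ndarray, rng):
    """Ray–surface intersection for parallel rays.

    Returns (hit mask, points).  For the sphere the entry point (facing
    the camera) is taken; orthographic rays have no camera center, so
    "nearest" means smallest parameter along the viewing direction.
    """
    n_pix = len(origins)
    pts = np.full((n_pix, 3), np.nan)
    if isinstance(scene, Sphere):
        oc = origins - scene.center
        b = oc @ direction
        c = (oc * oc).sum(axis=1) - scene.radius**2
        disc = b * b - c
        hit = disc >= 0.0
        s = -b[hit] - np.sqrt(disc[hit])
        pts[hit] = origins[hit] + s[:, None] * direction
        return hit, pts
    # plane-like surfaces
    if isinstance(scene, Plane):
        normal, offset, rough = scene.normal, scene.offset, scene.roughness_sigma
    else:  # GridPlane
        normal = np.array([0.0, 0.0, 1.0])
        offset, rough = scene.offset, scene.roughness_sigma
    denom = normal @ direction
    if abs(denom) < 1e-12:
        raise ValueError("projector/viewing direction parallel to the plane")
    s = (offset - origins @ normal) / denom
    pts = origins + s[:, None] * direction
    if rough > 0:
        pts = pts + rng.normal(0.0, rough, size=n_pix)[:, None] * normal
    return np.ones(n_pix, dtype=bool), pts


def _albedo_of(scene: SceneSpec, pts: np.ndarray) -> np.ndarray:
    if isinstance(scene, GridPlane):
        half = scene.line_width / 2.0
        dx = np.abs((pts[:, 0] + scene.spacing / 2) % scene.spacing - scene.spacing / 2)
        dy = np.abs((pts[:, 1] + scene.spacing / 2) % scene.spacing - scene.spacing / 2)
        on_line = (dx <= half) | (dy <= half)
        return np.where(on_line, scene.bright, scene.dark)
    a = scene.albedo
    if callable(a):
        return np.asarray(a(pts), dtype=float)
    return np.full(len(pts), float(a))


def _bilinear(img: np.ndarray, x: np.ndarray, y: np.ndarray):
    """Bilinear sample with out-of-bounds mask (no wrapping)."""
    H, W = img.shape
    inside = (x >= 0) & (x <= W - 1) & (y >= 0) & (y <= H - 1)
    xc = np.clip(x, 0, W - 1 - 1e-9)
    yc = np.clip(y, 0, H - 1 - 1e-9)
    x0 = np.floor(xc).astype(int)
    y0 = np.floor(yc).astype(int)
    fx = xc - x0
    fy = yc - y0
    v = (
        img[y0, x0] * (1 - fx) * (1 - fy)
        + img[y0, x0 + 1] * fx * (1 - fy)
        + img[y0 + 1, x0] * (1 - fx) * fy
        + img[y0 + 1, x0 + 1] * fx * fy
    )
    return v, inside


def render_stack(
    scene: SceneSpec,
    cam: TelecentricCamera,
    proj: ProjectorModel,
    patterns: PatternStack,
    noise_sigma: float = 0.0,
    seed: int = 0,
    background: float = 0.0,
    camera_id: str = "cam",
) -> RenderResult:
    """Render the pattern sequence onto the scene as seen by ``cam``.

    Every camera pixel's parallel viewing ray is intersected with the
    surface once (the geometry is static over the sequence); the surface
    point is carried along the projector direction onto the pattern plane
    and sampled bilinearly for each frame.  Intensity is
    ``albedo * pattern + N(0, noise_sigma)``, clipped to [0, 1]; rays that
    miss the surface (or leave the pattern) record ``background`` + noise.
    """
    rng = np.random.default_rng(seed)
    if isinstance(scene, (Plane, GridPlane)):
        n = scene.normal if isinstance(scene, Plane) else np.array([0.0, 0, 1])
        if abs(n @ proj.direction) < 1e-9:
            raise ValueError("projector direction parallel to the scene "
                             "plane: the pattern never reaches the surface")
    W, H = cam.image_size
    cols = np.arange(W) - (W - 1) / 2.0
    rows = np.arange(H) - (H - 1) / 2.0
    uu, vv = np.meshgrid(cols, rows)
    uv = np.column_stack([uu.ravel(), vv.ravel()])

    # parallel viewing rays for all pixels
    wx = uv[:, 0] * cam.pixel_pitch / cam.mag_x - cam.t[0]
    wy = uv[:, 1] * cam.pixel_pitch / cam.mag_y - cam.t[1]
    origins = np.column_stack([wx, wy, np.full(len(uv), -cam.t[2])]) @ cam.R
    direction = cam.viewing_direction

    hit, pts = _intersect(scene, origins, direction, rng)
    alb = np.zeros(len(uv))
    px = np.zeros(len(uv))
    py = np.zeros(len(uv))
    if hit.any():
        alb[hit] = _albedo_of(scene, pts[hit])
        Hp, Wp = patterns.frames.shape[1:]
        px[hit] = pts[hit] @ proj.right / patterns.pattern_pitch + (Wp - 1) / 2.0
        py[hit] = pts[hit] @ proj.up / patterns.pattern_pitch + (Hp - 1) / 2.0

    frames = np.empty((patterns.n_frames, H, W))
    hit_idx = np.flatnonzero(hit)
    for k in range(patterns.n_frames):
        img = np.full(len(uv), float(background))
        if len(hit_idx):
            val, inside = _bilinear(patterns.frames[k], px[hit_idx], py[hit_idx])
            img[hit_idx] = np.where(inside, alb[hit_idx] * val, background)
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, size=img.shape)
        frames[k] = np.clip(img, 0.0, 1.0).reshape(H, W)

    pts_nan = pts.copy()
    pts_nan[~hit] = np.nan
    return RenderResult(
        stack=ImageStack(frames=frames, camera_id=camera_id,
                         meta={"seed": seed, "noise_sigma": noise_sigma}),
        hit_mask=hit.reshape(H, W),
        points=pts_nan.reshape(H, W, 3),
    )


def default_rig(
    stereo_angle_deg: float = 38.5,
    mag: float = DEFAULT_MAG,
    pixel_pitch: float = SENSOR_PITCH_MM,
    image_size: tuple[int, int] = (FULL_SENSOR_PX, FULL_SENSOR_PX),
    pattern_pitch: float | None = None,
    flip_camera2: bool = False,
    working_distance: float = 120.0,
) -> tuple[TelecentricCamera, TelecentricCamera, ProjectorModel]:
    """Symmetric stereo rig: two cameras looking down at the world origin.

    The optical axes lie in the x–z plane, intersect at the origin and
    enclose ``stereo_angle_deg``; both cameras image the origin at pixel
    (0, 0).  The projector throws its pattern straight down (−z).

    With ``flip_camera2`` the second camera is additionally rotated half
    a turn about its own optical axis (a head-down mount, common when
    the two cameras face the volume from opposite sides).  The relative
    rotation then carries that half-turn and is far from the identity —
    the regime in which the deviation-from-identity selection heuristic
    for decomposed extrinsics is meaningful.  Without the flip the
    relative rotation angle equals the stereo angle.

    ``working_distance`` (mm) places the camera centers physically on
    their optical axes; telecentric projection is insensitive to it,
    but the translation part of the pose then reflects the real
    baseline geometry (two cameras several centimetres apart) instead
    of an arbitrary convention.
    """
    if not (0.0 < stereo_angle_deg < 180.0):
        raise ValueError("stereo angle must be in (0, 180) degrees")
    half = np.radians(stereo_angle_deg) / 2.0
    # viewing direction of camera i is R_i^T  ẑ = (∓sin, 0, −cos): looking down
    R1 = rotation_matrix([0, 1, 0], np.pi - half)
    R2 = rotation_matrix([0, 1, 0], half - np.pi)
    if flip_camera2:
        R2 = rotation_matrix([0, 0, 1], np.pi) @ R2
    if pattern_pitch is None:
        pattern_pitch = pixel_pitch / mag  # match camera pixel footprint
    # camera center C sits at -working_distance along the viewing
    # direction; t = -R C = working_distance * z_cam = (0, 0, wd)
    t = np.array([0.0, 0.0, float(working_distance)])
    cam1 = TelecentricCamera(mag, mag, pixel_pitch, R1, t.copy(),
                             tuple(image_size))
    cam2 = TelecentricCamera(mag, mag, pixel_pitch, R2, t.copy(),
                             tuple(image_size))
    proj = ProjectorModel(direction=[0, 0, -1.0], up=[0, 1.0, 0],
                          pattern_pitch=pattern_pitch)
    return cam1, cam2, proj
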