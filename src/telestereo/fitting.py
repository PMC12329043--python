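"""Point-cloud validation geometry: plane and sphere fits, residual
statistics, quality filtering and polyline length.

All lengths are mm.  "Standard deviation" of a fit is the *population*
standard deviation of the signed residuals about the fitted shape; at the
cloud sizes this package produces (10^4 .. 10^6 points) the sample/
population distinction is negligible, but the convention is fixed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PointCloud",
    "ShapeFit",
    "DegenerateFitError",
    "fit_plane",
    "fit_sphere",
    "filter_by_score",
    "central_patch",
    "crop_box",
    "residual_stats",
    "polyline_length",
]


class DegenerateFitError(ValueError):
    """Point configuration cannot constrain the requested shape."""


@dataclass
class PointCloud:
    """Reconstructed 3D points (mm) with per-point quality channels.

    ``score`` is the temporal correlation of the generating pixel pair,
    the primary quality channel used for outlier thresholds.  ``gap`` is
    the ray–ray miss distance from triangulation, an additional
    diagnostic that filters do not use by default.
    """

    points: np.ndarray  # (n, 3)
    score: np.ndarray | None = None
    color: np.ndarray | None = None  # (n, 3) in [0, 1]
    gap: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.isfinite(self.points).all():
            raise ValueError("point coordinates must be finite")
        n = len(self.points)
        if self.score is None:
            self.score = np.ones(n)
        self.score = np.asarray(self.score, dtype=float).ravel()
        if len(self.score) != n:
            raise ValueError("score length mismatch")
        if np.any(self.score < -1 - 1e-9) or np.any(self.score > 1 + 1e-9):
            raise ValueError("scores must lie in [-1, 1]")
        if self.color is not None:
            self.color = np.asarray(self.color, dtype=float).reshape(n, 3)
        if self.gap is not None:
            self.gap = np.asarray(self.gap, dtype=float).ravel()
            if len(self.gap) != n:
                raise ValueError("gap length mismatch")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask) -> "PointCloud":
        return PointCloud(
            self.points[mask],
            self.score[mask],
            None if self.color is None else self.color[mask],
            None if self.gap is None else self.gap[mask],
        )

    def transformed(self, R=None, t=None, scale: float = 1.0) -> "PointCloud":
        P = self.points * scale
        if R is not None:
            P = P @ np.asarray(R, dtype=float).T
        if t is not None:
            P = P + np.asarray(t, dtype=float)
        return PointCloud(P, self.score, self.color, self.gap)


@dataclass
class ShapeFit:
    """Result of a plane or sphere fit.

    ``model`` is ``"plane"`` or ``"sphere"``; parameters are stored in
    ``params`` (plane: unit normal + offset; sphere: center + radius).
    ``std`` is the population std of the signed residual distances (mm).
    """

    model: str
    params: dict
    residuals: np.ndarray
    std: float
    inlier_count: int
    radius_fixed: bool = False

    def to_report(self, threshold_used: float | None = None) -> dict:
        params_mm = {
            k: (list(map(float, v)) if np.ndim(v) else float(v))
            for k, v in self.params.items()
        }
        return {
            "model": self.model,
            "params_mm": params_mm,
            "std_mm": float(self.std),
            "n": int(self.inlier_count),
            "threshold_used": threshold_used,
        }


def fit_plane(points) -> ShapeFit:
    """Total-least-squares plane through a point set.

    The normal is the smallest-eigenvalue direction of the centered
    covariance; residuals are signed point–plane distances.
    """
    P = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(P) < 3:
        raise DegenerateFitError("plane fit needs at least 3 points")
    c = P.mean(axis=0)
    Q = P - c
    cov = Q.T @ Q
    w, V = np.linalg.eigh(cov)
    if w[1] <= w[2] * 1e-12:
        raise DegenerateFitError("points are (nearly) collinear")
    normal = V[:, 0]
    if normal[2] < 0:  # deterministic orientation
        normal = -normal
    offset = float(normal @ c)
    res = Q @ normal
    return ShapeFit(
        model="plane",
        params={"normal": normal, "offset": offset},
        residuals=res,
        std=float(res.std()),
        inlier_count=len(P),
    )


def _sphere_algebraic_init(P: np.ndarray):
    A = np.hstack([2.0 * P, np.ones((len(P), 1))])
    b = (P * P).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise DegenerateFitError("points do not constrain a free-radius sphere "
                                 "(coplanar or degenerate)")
    c = sol[:3]
    r2 = sol[3] + c @ c
    if r2 <= 0:
        raise DegenerateFitError("algebraic sphere init failed")
    return c, float(np.sqrt(r2))


def fit_sphere(points, fixed_radius: float | None = None) -> ShapeFit:
    """Geometric (Gauss–Newton) sphere fit.

    Free radius: algebraic linear initialization refined on the geometric
    distance ``|X - c| - r``.  Fixed radius: center-only refinement at the
    given radius (the regime used to check a reference sphere of known
    size).  Residuals are signed radial distances.
    """
    P = np.asarray(points, dtype=float).reshape(-1, 3)
    if fixed_radius is None:
        if len(P) < 4:
            raise DegenerateFitError("free-radius sphere fit needs >= 4 points")
        c0, r0 = _sphere_algebraic_init(P)
        x0 = np.array([*c0, r0])

        def fun(x):
            return np.linalg.norm(P - x[:3], axis=1) - x[3]

        sol = least_squares(fun, x0, method="lm", xtol=1e-14, ftol=1e-14)
        c, r = sol.x[:3], float(sol.x[3])
    else:
        if fixed_radius <= 0:
            raise ValueError("fixed_radius must be positive")
        if len(P) < 3:
            raise DegenerateFitError("fixed-radius sphere fit needs >= 3 points")
        r = float(fixed_radius)
        cen = P.mean(axis=0)
        # start behind the centroid along the cloud's mean normal guess
        try:
            pl = fit_plane(P)
            n0 = pl.params["normal"]
        except DegenerateFitError:
            n0 = np.array([0.0, 0.0, 1.0])
        inits = [cen + r * n0, cen - r * n0]

        def fun(c):
            return np.linalg.norm(P - c, axis=1) - r

        best = None
        for x0 in inits:
            sol = least_squares(fun, x0, method="lm", xtol=1e-14, ftol=1e-14)
            if best is None or sol.cost < best.cost:
                best = sol
        c = best.x
    res = np.linalg.norm(P - c, axis=1) - r
    return ShapeFit(
        model="sphere",
        params={"center": c, "radius": r},
        residuals=res,
        std=float(res.std()),
        inlier_count=len(P),
        radius_fixed=fixed_radius is not None,
    )


def filter_by_score(cloud: PointCloud, min_score: float) -> PointCloud:
    """Keep exactly the points with ``score >= min_score`` (order kept)."""
    if not (-1.0 <= min_score <= 1.0):
        raise ValueError("min_score must lie in [-1, 1]")
    return cloud.select(cloud.score >= min_score)


def central_patch(cloud: PointCloud, viewing_axis, fraction: float) -> PointCloud:
    """Innermost ``fraction`` of points around the viewing axis.

    Points are ranked by radial distance from the axis through the cloud
    centroid parallel to ``viewing_axis``; the closest fraction is kept
    (ties broken by index).  This isolates the low-slope central region
    where reconstruction noise is smallest.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    axis = np.asarray(viewing_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    d = cloud.points - cloud.points.mean(axis=0)
    radial = np.linalg.norm(d - np.outer(d @ axis, axis), axis=1)
    k = max(1, int(np.ceil(fraction * len(cloud))))
    order = np.argsort(radial, kind="stable")[:k]
    return cloud.select(np.sort(order))


def crop_box(cloud: PointCloud, lo, hi) -> PointCloud:
    """Axis-aligned crop: keep points with lo <= p <= hi componentwise.

    Used to cut away support structures (e.g. a holding platform) before
    fitting a reference shape.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    m = np.all((cloud.points >= lo) & (cloud.points <= hi), axis=1)
    return cloud.select(m)


def residual_stats(fit: ShapeFit, bin_width: float | None = None):
    """Population std plus a fixed-bin-width histogram of the residuals.

    ``bin_width`` defaults to std/10, roughly the visual granularity of a
    useful residual histogram.  Returns ``(std, (counts, bin_edges))``.
    """
    res = np.asarray(fit.residuals, dtype=float)
    if len(res) < 2:
        raise ValueError("need at least 2 residuals")
    std = float(res.std())
    if bin_width is None:
        bin_width = std / 10.0 if std > 0 else 1.0
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = np.floor(res.min() / bin_width) * bin_width
    nbins = max(1, int(np.ceil((res.max() - lo) / bin_width + 1e-9)))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(res, bins=edges)
    return std, (counts, edges)


def polyline_length(vertices) -> float:
    """Total Euclidean length of an ordered polyline (mm).

    The 3D polyline length of a curved structure is the quantity a flat
    2D image systematically underestimates through foreshortening.
    """
    V = np.asarray(vertices, dtype=float).reshape(-1, 3)
    if len(V) < 2:
        raise ValueError("polyline needs at least 2 vertices")
    return float(np.linalg.norm(np.diff(V, axis=0), axis=1).sum())
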