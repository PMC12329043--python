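"""Relative orientation of a telecentric stereo pair, and its correction.

A telecentric camera is an *affine* camera, and the fundamental matrix of
an affine stereo pair has the special form

    F = [[0, 0, a],
         [0, 0, b],
         [c, d, e]],

i.e. a vanishing upper-left 2x2 block.  Feeding such an F through the
standard pinhole-style essential-matrix decomposition — what generic
multi-view libraries do — produces a candidate set of two rotations and a
sign-ambiguous translation whose members do *not* in general contain the
physical relative rotation: one candidate hugs the identity, the other is
strongly rotated (a near half-turn).  This module reproduces that
candidate set faithfully (it is what a user of a standard library sees),
provides the two selection rules used to pick from it, and then resolves
the deeper problem:

The affine epipolar geometry fixes the epipolar directions in both images
and the in-plane baseline component, but *not* the turn angle about the
epipolar axis — varying that angle rescales reconstructed depth while
leaving every image observation unchanged (the classical bas-relief
ambiguity of parallel projection).  The rotations consistent with a given
affine F therefore form a one-parameter family.  ``correct_extrinsics``
recovers the missing angle by reconstructing a *reference object of known
shape* (a sphere of known radius) for each trial angle and minimizing the
deviation from that shape, then resolves the remaining depth-reversal
twin by requiring the camera to see the convex side of the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .camera import (
    DegenerateGeometryError,
    TelecentricCamera,
    rotation_matrix,
    triangulate_many,
)
from .correspondence import CorrespondenceSet
from .fitting import DegenerateFitError, PointCloud, fit_plane, fit_sphere

__all__ = [
    "AffineFundamental",
    "ExtrinsicCandidateSet",
    "ScaleResult",
    "ExtrinsicSolution",
    "AmbiguousSelectionError",
    "estimate_affine_fundamental",
    "affine_fundamental_from_cameras",
    "essential_from_pose",
    "candidate_extrinsics",
    "candidates_from_essential",
    "select_by_identity_rule",
    "select_by_reference",
    "TurnAngleFamily",
    "correct_extrinsics",
    "estimate_scale",
]


class AmbiguousSelectionError(ValueError):
    """The identity rule cannot separate the two candidate rotations."""


@dataclass
class AffineFundamental:
    """Affine fundamental matrix, normalized to unit Frobenius norm."""

    F: np.ndarray

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float).reshape(3, 3)
        if np.abs(F[:2, :2]).max() > 1e-9 * max(np.abs(F).max(), 1e-300):
            raise ValueError("not an affine fundamental matrix "
                             "(upper-left 2x2 block must vanish)")
        F = F.copy()
        F[:2, :2] = 0.0
        n = np.linalg.norm(F)
        if n == 0:
            raise ValueError("zero matrix")
        self.F = F / n

    def epipolar_line_2(self, u1: float, v1: float) -> np.ndarray:
        """Line coefficients (a, b, c) in image 2 for a point in image 1."""
        return self.F @ np.array([u1, v1, 1.0])

    def residuals(self, pairs: CorrespondenceSet) -> np.ndarray:
        x1 = np.column_stack([pairs.u1, pairs.v1, np.ones(len(pairs))])
        x2 = np.column_stack([pairs.u2, pairs.v2, np.ones(len(pairs))])
        return np.einsum("ni,ij,nj->n", x2, self.F, x1)


@dataclass
class ExtrinsicCandidateSet:
    """The {R_a, R_b} x {+t, -t} ambiguity set of the essential decomposition."""

    R_a: np.ndarray
    R_b: np.ndarray
    t_unit: np.ndarray
    singular_values: np.ndarray | None = None

    def __post_init__(self):
        self.R_a = np.asarray(self.R_a, dtype=float).reshape(3, 3)
        self.R_b = np.asarray(self.R_b, dtype=float).reshape(3, 3)
        t = np.asarray(self.t_unit, dtype=float).reshape(3)
        self.t_unit = t / np.linalg.norm(t)
        # tolerance admits rotation matrices quoted at a few decimals
        for R in (self.R_a, self.R_b):
            if (np.linalg.norm(R.T @ R - np.eye(3)) > 1e-4
                    or np.linalg.det(R) < 0):
                raise ValueError("candidates must be proper rotations")

    def __iter__(self):
        for R in (self.R_a, self.R_b):
            for s in (1.0, -1.0):
                yield R, s * self.t_unit

    def labels(self):
        return ["R_a,+t", "R_a,-t", "R_b,+t", "R_b,-t"]


@dataclass
class ScaleResult:
    """Metric rescaling factor from a feature grid of known spacing."""

    factor: float
    feature_spacing_measured: float
    feature_spacing_true: float


@dataclass
class ExtrinsicSolution:
    """Corrected extrinsics: the telecentric-consistent (R, t)."""

    R: np.ndarray
    t: np.ndarray
    turn_angle_deg: float
    residual_std: float
    fitted_radius: float
    method: str = "reference_fit"
    diagnostics: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# estimation
# ----------------------------------------------------------------------

def estimate_affine_fundamental(pairs: CorrespondenceSet) -> AffineFundamental:
    """Gold-standard affine fundamental matrix from correspondences.

    Centroids are subtracted (and a single isotropic scale applied for
    conditioning — it does not change the minimizer), then the unit
    vector (a, b, c, d) minimizing sum (a u2 + b v2 + c u1 + d v1)^2 is
    the smallest right-singular direction of the centered n x 4 data
    matrix; the constant term is recovered from the centroids.  This is
    the total-least-squares (maximum-likelihood under isotropic noise)
    estimate for the affine model.
    """
    n = len(pairs)
    if n < 4:
        raise ValueError("need at least 4 correspondences")
    A = np.column_stack([pairs.u2, pairs.v2, pairs.u1, pairs.v1])
    cen = A.mean(axis=0)
    Ac = A - cen
    scale = np.sqrt((Ac * Ac).sum() / n)
    if scale == 0:
        raise DegenerateFitError("all correspondences identical")
    U, S, Vt = np.linalg.svd(Ac / scale, full_matrices=False)
    # collinear degeneracy: data must span at least 3 directions in R^4
    if S[2] <= 1e-9 * S[0]:
        raise DegenerateFitError(
            "correspondences are degenerate (collinear points / single "
            "epipolar line)")
    a, b, c, d = Vt[-1]
    e = -cen @ Vt[-1]
    return AffineFundamental(np.array([[0, 0, a], [0, 0, b], [c, d, e]]))


def affine_fundamental_from_cameras(
    cam1: TelecentricCamera, cam2: TelecentricCamera
) -> AffineFundamental:
    """Closed-form affine F of a known telecentric pair (test oracle).

    The epipolar constraint is the vanishing of the 4x4 determinant
    built from the two 2x4 affine projection matrices and the observed
    pixels; expanding that determinant in the four pixel coordinates
    yields the affine F directly.
    """

    def affine_P(cam):
        D = np.diag([cam.fx, cam.fy])
        return D @ cam.R[:2, :], D @ cam.t[:2]

    M1, m1 = affine_P(cam1)
    M2, m2 = affine_P(cam2)

    def det_at(u1, v1, u2, v2):
        A = np.zeros((4, 4))
        A[:2, :3] = M1
        A[2:, :3] = M2
        A[:2, 3] = np.array([u1, v1]) - m1
        A[2:, 3] = np.array([u2, v2]) - m2
        return np.linalg.det(A)

    e = det_at(0, 0, 0, 0)
    c = det_at(1, 0, 0, 0) - e
    d = det_at(0, 1, 0, 0) - e
    a = det_at(0, 0, 1, 0) - e
    b = det_at(0, 0, 0, 1) - e
    return AffineFundamental(np.array([[0, 0, a], [0, 0, b], [c, d, e]]))


def essential_from_pose(R: np.ndarray, t) -> np.ndarray:
    """E = [t]_x R for a known relative pose (test oracle)."""
    t = np.asarray(t, dtype=float)
    tx = np.array([[0, -t[2], t[1]], [t[2], 0, -t[0]], [-t[1], t[0], 0.0]])
    return tx @ np.asarray(R, dtype=float)


# ----------------------------------------------------------------------
# the pinhole-style candidate set (the model mismatch, reproduced)
# ----------------------------------------------------------------------

def candidates_from_essential(E: np.ndarray) -> ExtrinsicCandidateSet:
    """Standard two-rotation decomposition of an essential matrix.

    The input is projected onto the essential manifold (equal nonzero
    singular values, third zero) before decomposition.
    """
    E = np.asarray(E, dtype=float).reshape(3, 3)
    U, S, Vt = np.linalg.svd(E)
    if S[1] <= 1e-12 * max(S[0], 1e-300):
        raise DegenerateGeometryError("essential matrix is (nearly) rank 1")
    if np.linalg.det(U) < 0:
        U = U.copy()
        U[:, -1] *= -1
    if np.linalg.det(Vt) < 0:
        Vt = Vt.copy()
        Vt[-1] *= -1
    W = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    t = U[:, 2]
    if t[np.argmax(np.abs(t))] < 0:  # deterministic sign convention
        t = -t
    return ExtrinsicCandidateSet(
        R_a=U @ W @ Vt, R_b=U @ W.T @ Vt, t_unit=t,
        singular_values=S,
    )


def candidate_extrinsics(
    F: AffineFundamental | np.ndarray, cam1_K: np.ndarray, cam2_K: np.ndarray
) -> ExtrinsicCandidateSet:
    """Pinhole-style extrinsic candidates from a fundamental matrix.

    Forms ``E = K2^T F K1`` and decomposes it as if the cameras were
    pinholes.  For telecentric input this deliberately reproduces the
    model mismatch a standard library commits: the resulting pair
    consists of a near-identity rotation and a strongly rotated one, and
    neither is guaranteed to be the physical relative rotation.  Use
    :func:`correct_extrinsics` for the telecentric-consistent answer.
    """
    Fm = F.F if isinstance(F, AffineFundamental) else np.asarray(F, dtype=float)
    K1 = np.asarray(cam1_K, dtype=float)
    K2 = np.asarray(cam2_K, dtype=float)
    if K1[0, 0] <= 0 or K1[1, 1] <= 0 or K2[0, 0] <= 0 or K2[1, 1] <= 0:
        raise ValueError("K matrices must have positive diagonal")
    return candidates_from_essential(K2.T @ Fm @ K1)


def select_by_identity_rule(cands: ExtrinsicCandidateSet):
    """Pick the candidate rotation farther from the identity.

    The practitioner's rule of thumb for the telecentric mismatch: the
    rotation showing greater deviation from the identity matrix is
    (usually) the meaningful one; the near-identity rotation is the
    reprojection-like spurious solution.  Returns ``(R, t_unit, margin)``
    where margin is the difference of the two Frobenius distances — a
    confidence diagnostic.  The sign of t is immaterial (both give
    geometrically equivalent reconstructions), so +t is returned.
    """
    da = np.linalg.norm(cands.R_a - np.eye(3))
    db = np.linalg.norm(cands.R_b - np.eye(3))
    margin = abs(da - db)
    if margin < 1e-6:
        raise AmbiguousSelectionError(
            "candidate rotations are equidistant from the identity; "
            "use select_by_reference with a known object")
    R = cands.R_a if da > db else cands.R_b
    return R, cands.t_unit.copy(), float(margin)


def _triangulate_candidate(cam1, cam2, R, t, pairs):
    c1 = cam1.with_pose(np.eye(3), np.zeros(3))
    c2 = cam2.with_pose(R, t)
    return triangulate_many(c1, c2, pairs.p1, pairs.p2)


def select_by_reference(
    cands: ExtrinsicCandidateSet,
    pairs: CorrespondenceSet,
    cam1: TelecentricCamera,
    cam2: TelecentricCamera,
    reference: str = "sphere",
    fixed_radius: float | None = None,
):
    """Pick the candidate whose reconstruction best fits a known shape.

    Each of the four (R, ±t) combinations is used to triangulate all
    pairs (camera 1 at the origin); the reference shape is fitted and the
    residual std recorded.  Returns ``(R, t, residual_table)`` where the
    table maps candidate labels to residual stds (the "distorted vs
    corrected" contrast, automated).
    """
    if reference not in ("sphere", "plane"):
        raise ValueError("reference must be 'sphere' or 'plane'")
    if len(pairs) < 10:
        raise ValueError("need at least 10 pairs for reference selection")
    table = {}
    best = None
    for label, (R, t) in zip(cands.labels(), cands):
        try:
            P, gap = _triangulate_candidate(cam1, cam2, R, t, pairs)
            if reference == "sphere":
                fit = fit_sphere(P, fixed_radius=fixed_radius)
            else:
                fit = fit_plane(P)
            std = fit.std
        except (DegenerateGeometryError, DegenerateFitError):
            std = np.inf
        table[label] = float(std)
        if best is None or std < best[0]:
            best = (std, R, t)
    if not np.isfinite(best[0]):
        raise DegenerateGeometryError("all candidates yield degenerate "
                                      "triangulations")
    return best[1], best[2], table


# ----------------------------------------------------------------------
# the telecentric-consistent correction
# ----------------------------------------------------------------------

class TurnAngleFamily:
    """Rotations consistent with an affine fundamental matrix.

    In metric (de-magnified) image coordinates the affine epipolar
    constraint reads ``n2 . m2 + n1 . m1 + e = 0``.  For a relative
    rotation R it forces

      * third column (x, y) of R  ∝  epipolar direction in image 2,
      * third row    (x, y) of R  fixed by n1,
      * |n1| = |n2| (an internal consistency check),

    leaving exactly one free parameter: the turn angle theta about the
    epipolar axis, with ``R(theta) = Rz(alpha2) Ry(theta) Rz(alpha1)``.
    The in-plane baseline component normal to the epipolar lines follows
    from the constant term; the component along them and the axial
    component are unobservable (they only translate the reconstruction)
    and are set to zero.
    """

    def __init__(self, F: AffineFundamental, cam1_K, cam2_K):
        Fm = F.F if isinstance(F, AffineFundamental) else np.asarray(F, float)
        K1 = np.asarray(cam1_K, dtype=float)
        K2 = np.asarray(cam2_K, dtype=float)
        n2 = np.array([Fm[0, 2] * K2[0, 0], Fm[1, 2] * K2[1, 1]])
        n1 = np.array([Fm[2, 0] * K1[0, 0], Fm[2, 1] * K1[1, 1]])
        s2 = np.linalg.norm(n2)
        s1 = np.linalg.norm(n1)
        if s1 == 0 or s2 == 0:
            raise DegenerateGeometryError("degenerate affine fundamental matrix")
        # epipolar direction in image 2 fixes alpha2
        g2 = np.array([-n2[1], n2[0]]) / s2
        self.alpha2 = float(np.arctan2(g2[1], g2[0]))
        # third row of R fixes alpha1 (sign pairing matters: the flipped
        # pairing generates the depth-reversed mirror family)
        self.alpha1 = float(np.arctan2(n1[0], n1[1]))
        self._Rz1 = rotation_matrix([0, 0, 1], self.alpha1)
        self._Rz2 = rotation_matrix([0, 0, 1], self.alpha2)
        self.t_xy = -(Fm[2, 2] / s2) * (n2 / s2)
        self.scale_consistency = float(abs(s1 - s2) / max(s1, s2))

    def rotation(self, theta: float) -> np.ndarray:
        return self._Rz2 @ rotation_matrix([0, 1, 0], theta) @ self._Rz1

    def translation(self, theta: float | None = None) -> np.ndarray:
        return np.array([self.t_xy[0], self.t_xy[1], 0.0])


def correct_extrinsics(
    F: AffineFundamental,
    pairs: CorrespondenceSet,
    cam1: TelecentricCamera,
    cam2: TelecentricCamera,
    reference_radius: float,
    n_grid: int = 256,
    theta_limit_deg: float = 89.0,
) -> ExtrinsicSolution:
    """Recover the telecentric-consistent extrinsics from a reference sphere.

    Scans the turn angle over the admissible family, triangulating the
    correspondence set and fitting a sphere of the known
    ``reference_radius`` at every angle; the angle minimizing the
    deviation from sphere form is refined by parabolic line search.  The
    depth-reversal twin (equal residual, mirrored cloud) is rejected by
    requiring the fitted center to lie beyond the surface points along
    the first camera's viewing direction — a real opaque sphere is seen
    from its convex side.

    The reference must be curved: a plane stays a plane at every turn
    angle and cannot pin the bas-relief parameter down.
    """
    if len(pairs) < 10:
        raise ValueError("need at least 10 pairs")
    fam = TurnAngleFamily(F, cam1.K, cam2.K)

    def recon(theta):
        R = fam.rotation(theta)
        t = fam.translation()
        return _triangulate_candidate(cam1, cam2, R, t, pairs)

    def cost(theta):
        try:
            P, _ = recon(theta)
            return fit_sphere(P, fixed_radius=reference_radius).std
        except (DegenerateGeometryError, DegenerateFitError):
            return np.inf

    lim = np.radians(theta_limit_deg)
    grid = np.concatenate([np.linspace(-lim, -0.02, n_grid // 2),
                           np.linspace(0.02, lim, n_grid // 2)])
    costs = np.array([cost(th) for th in grid])
    if not np.isfinite(costs).any():
        raise DegenerateGeometryError("reference fit failed at every angle")

    def refine(i0):
        lo = grid[max(i0 - 1, 0)]
        hi = grid[min(i0 + 1, len(grid) - 1)]
        res = minimize_scalar(cost, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        return float(res.x), float(res.fun)

    # refine the best minimum on each side of zero; they are the convex /
    # depth-reversed twin pair
    half = n_grid // 2
    cand = []
    for sl, off in ((slice(0, half), 0), (slice(half, None), half)):
        if np.isfinite(costs[sl]).any():
            i0 = int(np.argmin(np.where(np.isfinite(costs[sl]), costs[sl],
                                        np.inf))) + off
            cand.append(refine(i0))
    chosen = None
    table = {}
    for theta, c in cand:
        P, _ = recon(theta)
        fit = fit_sphere(P, fixed_radius=reference_radius)
        convex = fit.params["center"][2] > np.median(P[:, 2])
        table[f"theta={np.degrees(theta):+.3f}deg"] = {
            "residual_std": float(c), "convex_side": bool(convex)}
        # prefer convex-side solutions; among those, smaller residual
        key = (not convex, c)
        if chosen is None or key < chosen[0]:
            chosen = (key, theta, c)
    _, theta, c = chosen
    P, _ = recon(theta)
    fit_free = fit_sphere(P)
    R = fam.rotation(theta)
    return ExtrinsicSolution(
        R=R,
        t=fam.translation(),
        turn_angle_deg=float(np.degrees(theta)),
        residual_std=float(c),
        fitted_radius=float(fit_free.params["radius"]),
        diagnostics={
            "twin_table": table,
            "scale_consistency": fam.scale_consistency,
        },
    )


# ----------------------------------------------------------------------
# metric scale from a feature grid
# ----------------------------------------------------------------------

def _grid_orientation(Q: np.ndarray, n_angles: int = 90) -> float:
    """In-plane angle (rad) along which 1D projections are most peaked."""
    best = (-np.inf, 0.0)
    rng = Q.max(axis=0) - Q.min(axis=0)
    binw = max(rng.max() / 400.0, 1e-9)
    for ang in np.linspace(0.0, np.pi / 2, n_angles, endpoint=False):
        u = Q @ np.array([np.cos(ang), np.sin(ang)])
        edges = np.arange(u.min() - binw, u.max() + 2 * binw, binw)
        h, _ = np.histogram(u, bins=edges)
        p = h / h.sum()
        score = (p * p).sum()  # concentration
        if score > best[0]:
            best = (score, ang)
    return best[1]


def _axis_spacing(u: np.ndarray) -> tuple[float, int]:
    """Median spacing between 1D feature clusters along one grid axis.

    Returns NaN when the projection shows no grid structure: fewer than
    two clusters, or clusters as broad as their separation (a plateau or
    density fluctuations rather than a row of peaks).
    """
    nbins = int(min(400, max(20, len(u) // 15)))
    binw = max((u.max() - u.min()) / nbins, 1e-9)
    edges = np.arange(u.min() - binw, u.max() + 2 * binw, binw)
    h, _ = np.histogram(u, bins=edges)
    thr = max(1.0, 0.25 * h.max())
    above = h >= thr
    min_pop = max(5.0, 0.01 * len(u))  # a feature must hold real support
    centers = []
    widths = []
    i = 0
    mids = 0.5 * (edges[:-1] + edges[1:])
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            w = h[i:j].astype(float)
            if w.sum() >= min_pop:
                centers.append(float((w * mids[i:j]).sum() / w.sum()))
                widths.append((j - i) * binw)
            i = j
        else:
            i += 1
    if len(centers) < 2:
        return np.nan, len(centers)
    order = np.argsort(centers)
    centers = np.asarray(centers)[order]
    widths = np.asarray(widths)[order]
    # a discretely sampled feature can split into sub-clusters a fraction
    # of the pitch apart; merge neighbours closer than half the dominant
    # spacing before measuring it
    if len(centers) > 2:
        rough = float(np.median(np.diff(centers)))
        merged_c, merged_w = [centers[0]], [widths[0]]
        for c, w in zip(centers[1:], widths[1:]):
            if c - merged_c[-1] < 0.5 * rough:
                merged_c[-1] = 0.5 * (merged_c[-1] + c)
                merged_w[-1] = merged_w[-1] + w
            else:
                merged_c.append(c)
                merged_w.append(w)
        centers = np.asarray(merged_c)
        widths = np.asarray(merged_w)
        if len(centers) < 2:
            return np.nan, len(centers)
    spacing = float(np.median(np.diff(centers)))
    # grid features are narrow relative to their pitch; clusters as wide
    # as their separation are density fluctuations, not features
    if spacing < 3.0 * float(np.median(widths)):
        return np.nan, len(centers)
    # refine each center from the raw points it captures (the histogram
    # centroid is quantized at the bin width)
    # tight capture window: background points from the perpendicular
    # line family would otherwise drag the means around
    win = min(0.45 * spacing, max(1.0 * float(np.median(widths)), 2 * binw))
    refined = []
    for c in centers:
        m = np.abs(u - c) <= win
        if m.sum() >= 3:
            refined.append(float(u[m].mean()))
    if len(refined) < 2:
        return np.nan, len(refined)
    return float(np.median(np.diff(np.sort(refined)))), len(refined)


def estimate_scale(cloud: PointCloud, true_spacing: float) -> ScaleResult:
    """Metric scale factor from a reconstructed feature grid.

    The cloud (a reconstruction of a plate carrying features at a known
    pitch) is projected onto its best-fit plane; feature positions are
    clustered along the two grid axes and the measured spacing compared
    with ``true_spacing``.  ``factor = true / measured``: multiplying the
    cloud's coordinates by it makes the grid metric.
    """
    if true_spacing <= 0:
        raise ValueError("true_spacing must be positive")
    if len(cloud) < 10:
        raise ValueError("too few points for grid-scale estimation")
    pl = fit_plane(cloud.points)
    n = pl.params["normal"]
    e1 = np.cross(n, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(n, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    Q = (cloud.points - cloud.points.mean(axis=0)) @ np.column_stack([e1, e2])
    ang = _grid_orientation(Q)
    spacings = []
    counts = []
    for a in (ang, ang + np.pi / 2):
        u = Q @ np.array([np.cos(a), np.sin(a)])
        s, ncl = _axis_spacing(u)
        counts.append(ncl)
        if np.isfinite(s):
            spacings.append(s)
    if not spacings:
        raise DegenerateFitError(
            f"found fewer than 2 feature clusters (got {max(counts)})")
    measured = float(np.median(spacings))
    return ScaleResult(
        factor=true_spacing / measured,
        feature_spacing_measured=measured,
        feature_spacing_true=float(true_spacing),
    )
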