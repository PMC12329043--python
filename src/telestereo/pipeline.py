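"""End-to-end measurement pipeline: simulate → match → calibrate →
reconstruct → validate.

These functions chain the library modules in the order a measurement
session runs them; the command-line interface is a thin wrapper around
them, and the synthetic experiments in the test-suite call them directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera import TelecentricCamera, triangulate_many
from .correspondence import CorrespondenceSet, find_correspondences
from .extrinsics import (
    AmbiguousSelectionError,
    ExtrinsicSolution,
    candidate_extrinsics,
    correct_extrinsics,
    estimate_affine_fundamental,
    select_by_identity_rule,
)
from .fitting import PointCloud
from .synthetic import (
    ImageStack,
    PatternStack,
    ProjectorModel,
    RenderResult,
    SceneSpec,
    make_pattern_stack,
    render_stack,
)

__all__ = [
    "SimulationResult",
    "CalibrationResult",
    "simulate",
    "match",
    "calibrate",
    "reconstruct",
]


@dataclass
class SimulationResult:
    stack1: ImageStack
    stack2: ImageStack
    truth1: RenderResult
    truth2: RenderResult
    patterns: PatternStack
    cam1: TelecentricCamera
    cam2: TelecentricCamera
    projector: ProjectorModel
    seed: int


@dataclass
class CalibrationResult:
    """Everything the calibration stage determines and logs."""

    F: np.ndarray
    candidates: object
    identity_rule: dict
    solution: ExtrinsicSolution
    residual_table: dict = field(default_factory=dict)

    def to_dict(self, cam1: TelecentricCamera, cam2: TelecentricCamera,
                scale_factor: float | None = None) -> dict:
        return {
            "K1": [float(v) for v in np.diag(cam1.K)],
            "K2": [float(v) for v in np.diag(cam2.K)],
            "R": [float(v) for v in self.solution.R.reshape(-1)],
            "t_unit": [float(v) for v in
                       (self.solution.t / max(np.linalg.norm(self.solution.t),
                                              1e-300))],
            "t_mm": [float(v) for v in self.solution.t],
            "turn_angle_deg": float(self.solution.turn_angle_deg),
            "selection_method": self.solution.method,
            "margin_or_residual_table": {
                "identity_rule": self.identity_rule,
                "reference_fit": self.solution.diagnostics.get("twin_table", {}),
                "candidate_table": self.residual_table,
            },
            "scale_factor": scale_factor,
        }


def simulate(
    scene: SceneSpec,
    cam1: TelecentricCamera,
    cam2: TelecentricCamera,
    projector: ProjectorModel,
    n_frames: int = 100,
    pattern_size: tuple[int, int] = (512, 512),
    cutoff: float = 0.12,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> SimulationResult:
    """Render the pattern sequence onto the scene for both cameras.

    The two cameras share the pattern sequence (one projector) but draw
    independent noise; everything is reproducible from ``seed``.
    """
    patterns = make_pattern_stack(n_frames, pattern_size, cutoff, seed=seed,
                                  pattern_pitch=projector.pattern_pitch)
    r1 = render_stack(scene, cam1, projector, patterns, noise_sigma,
                      seed=seed + 1, camera_id="cam1")
    r2 = render_stack(scene, cam2, projector, patterns, noise_sigma,
                      seed=seed + 2, camera_id="cam2")
    return SimulationResult(r1.stack, r2.stack, r1, r2, patterns,
                            cam1, cam2, projector, seed)


def match(
    stack1: ImageStack,
    stack2: ImageStack,
    coarse_stride: int = 8,
    dense_stride: int = 2,
    band_half_width: float = 2.0,
    min_score: float = 0.3,
    coarse_min_score: float = 0.6,
    mutual: bool = True,
) -> tuple[CorrespondenceSet, CorrespondenceSet, np.ndarray]:
    """Two-phase correspondence search.

    Phase 1 scans the full second image at a coarse stride (no geometry
    known yet), estimates the affine fundamental matrix from the
    confident pairs, and phase 2 searches densely inside a narrow band
    around the epipolar lines.  The dense phase applies the left-right
    consistency check by default: it removes half-occluded pixels (seen
    by one camera only) that would otherwise pass a lax correlation
    threshold.  Returns (coarse, dense, F).
    """
    coarse = find_correspondences(
        stack1, stack2, search="full", min_score=coarse_min_score,
        stride=coarse_stride,
    )
    if len(coarse) < 8:
        raise RuntimeError(
            f"coarse matching found only {len(coarse)} confident pairs")
    F = estimate_affine_fundamental(coarse).F
    dense = find_correspondences(
        stack1, stack2, search="epipolar_band", F=F,
        band_half_width=band_half_width, min_score=min_score,
        stride=dense_stride, mutual=mutual,
    )
    return coarse, dense, F


def calibrate(
    pairs: CorrespondenceSet,
    cam1: TelecentricCamera,
    cam2: TelecentricCamera,
    reference_radius: float,
    n_grid: int = 256,
    calib_min_score: float = 0.9,
) -> CalibrationResult:
    """Extrinsic calibration with telecentric model correction.

    Estimates the affine fundamental matrix, records the pinhole-style
    candidate set (what a standard library would offer) together with
    the identity-rule pick, then recovers the telecentric-consistent
    rotation by reference-sphere fitting over the admissible turn-angle
    family.

    Calibration is an outlier-sensitive least-squares problem, so only
    pairs scoring at least ``calib_min_score`` enter it (the outlier
    threshold used for trustworthy points); the dense reconstruction may
    still use a laxer threshold afterwards.
    """
    confident = pairs[pairs.score >= calib_min_score]
    if len(confident) >= 50:
        pairs = confident
    Fobj = estimate_affine_fundamental(pairs)
    cands = candidate_extrinsics(Fobj, cam1.K, cam2.K)
    try:
        R_id, t_id, margin = select_by_identity_rule(cands)
        id_info = {"margin": margin,
                   "R": [float(v) for v in R_id.reshape(-1)]}
    except AmbiguousSelectionError as exc:
        id_info = {"margin": 0.0, "error": str(exc)}
    sol = correct_extrinsics(Fobj, pairs, cam1, cam2,
                             reference_radius=reference_radius, n_grid=n_grid)
    dev = {
        lab: float(np.linalg.norm(R - np.eye(3)))
        for lab, (R, _) in zip(cands.labels(), cands)
    }
    return CalibrationResult(F=Fobj.F, candidates=cands,
                             identity_rule=id_info, solution=sol,
                             residual_table=dev)


def reconstruct(
    pairs: CorrespondenceSet,
    cam1: TelecentricCamera,
    cam2: TelecentricCamera,
    R: np.ndarray,
    t: np.ndarray,
    min_score: float | None = None,
    scale: float = 1.0,
) -> PointCloud:
    """Triangulate matched pairs into a point cloud (camera-1 frame).

    The per-pair correlation becomes the cloud's quality channel and the
    ray–ray gap is kept as a secondary diagnostic.  ``scale`` applies a
    metric rescaling factor (see ``estimate_scale``).
    """
    if min_score is not None:
        pairs = pairs[pairs.score >= min_score]
    c1 = cam1.with_pose(np.eye(3), np.zeros(3))
    c2 = cam2.with_pose(R, t)
    P, gap = triangulate_many(c1, c2, pairs.p1, pairs.p2)
    return PointCloud(P * scale, score=pairs.score, gap=gap * scale)
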