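"""Shared fixtures: synthetic rigs and one full end-to-end experiment.

The expensive pieces (rendering + matching + calibration of the
reference-sphere experiment) run once per session and are shared by the
pipeline tests and the acceptance suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import telestereo as ts

# desk-scale rig: 256 px sensor keeping the full 11 mm field of view
DESK_SIZE = 256
DESK_PITCH = 2.74e-3 * (2848 / DESK_SIZE)


def desk_rig(angle_deg=38.5, flip_camera2=False):
    return ts.default_rig(angle_deg, pixel_pitch=DESK_PITCH,
                          image_size=(DESK_SIZE, DESK_SIZE),
                          flip_camera2=flip_camera2)


def sphere_cap_points(rng, n, radius=2.5, half_angle_deg=55.0, center=(0, 0, 0)):
    """Uniform samples on the camera-facing cap of a sphere."""
    phi = rng.uniform(0, 2 * np.pi, n)
    mu = rng.uniform(np.cos(np.radians(half_angle_deg)), 1.0, n)
    s = np.sqrt(1.0 - mu**2)
    return radius * np.column_stack(
        [s * np.cos(phi), s * np.sin(phi), mu]
    ) + np.asarray(center, dtype=float)


def exact_pairs(cam1, cam2, X, rng=None, noise_px=0.0):
    """Noise-free (or jittered) correspondences of known world points."""
    p1 = ts.project(cam1, X)
    p2 = ts.project(cam2, X)
    if noise_px > 0:
        p1 = p1 + rng.normal(0, noise_px, p1.shape)
        p2 = p2 + rng.normal(0, noise_px, p2.shape)
    return ts.CorrespondenceSet(p1[:, 0], p1[:, 1], p2[:, 0], p2[:, 1],
                                np.ones(len(X)))


def random_rig(rng, angle_deg=None, flip_camera2=False):
    """Desk rig with random cyclotorsion and camera-center jitter.

    Camera centers keep their physical placement on the optical axes
    (see ``default_rig``), perturbed by a couple of millimetres, so the
    pose translations reflect a real mounting rather than an arbitrary
    convention.
    """
    if angle_deg is None:
        angle_deg = rng.uniform(15.0, 60.0)
    cam1, cam2, proj = desk_rig(angle_deg, flip_camera2=flip_camera2)
    out = []
    for cam in (cam1, cam2):
        tw = ts.rotation_matrix([0, 0, 1], np.radians(rng.uniform(-5, 5)))
        R = tw @ cam.R
        # jitter the camera center: C -> C + delta, t = -R C
        C = -cam.R.T @ cam.t
        out.append(cam.with_pose(R, -R @ (C + rng.normal(0, 2.0, 3))))
    return out[0], out[1]


@dataclass
class SphereExperiment:
    sim: object
    dense: object
    F: np.ndarray
    cal: object
    cloud: object
    cam1: object
    cam2: object
    R_true: np.ndarray
    radius: float
    noise_sigma: float


@pytest.fixture(scope="session")
def sphere_experiment() -> SphereExperiment:
    """Full synthetic reference-sphere run: simulate, match (threshold
    0.3), calibrate with sphere-reference disambiguation, reconstruct."""
    radius, noise = 2.5, 0.02
    cam1, cam2, proj = desk_rig(38.5)
    sim = ts.simulate(ts.Sphere(center=[0, 0, 0], radius=radius),
                      cam1, cam2, proj, n_frames=100, noise_sigma=noise,
                      seed=7)
    coarse, dense, F = ts.match(sim.stack1, sim.stack2, coarse_stride=8,
                                dense_stride=2, min_score=0.3)
    cal = ts.calibrate(dense, cam1, cam2, reference_radius=radius)
    cloud = ts.reconstruct(dense, cam1, cam2, cal.solution.R,
                           cal.solution.t, min_score=0.3)
    return SphereExperiment(
        sim=sim, dense=dense, F=F, cal=cal, cloud=cloud,
        cam1=cam1, cam2=cam2, R_true=cam2.R @ cam1.R.T,
        radius=radius, noise_sigma=noise,
    )
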