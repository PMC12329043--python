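"""Affine fundamental estimation, candidate ambiguity, disambiguation
and metric scaling."""

import numpy as np
import pytest

import telestereo as ts
from telestereo.camera import rotation_matrix
from telestereo.correspondence import CorrespondenceSet
from telestereo.extrinsics import (
    AffineFundamental,
    AmbiguousSelectionError,
    ExtrinsicCandidateSet,
    TurnAngleFamily,
    affine_fundamental_from_cameras,
    candidate_extrinsics,
    candidates_from_essential,
    correct_extrinsics,
    essential_from_pose,
    estimate_affine_fundamental,
    estimate_scale,
    select_by_identity_rule,
    select_by_reference,
)
from telestereo.fitting import DegenerateFitError, PointCloud

from conftest import desk_rig, exact_pairs, random_rig, sphere_cap_points

# Candidate rotation pair printed for the physical rig: the spurious
# near-identity solution and the meaningful strongly-rotated one.
R_NEAR_IDENTITY = np.array([
    [0.99868, 0.049236, 0.014582],
    [-0.048842, 0.99846, -0.026233],
    [-0.015851, 0.025486, 0.99955],
])
R_STRONGLY_ROTATED = np.array([
    [-0.64667, -0.055855, -0.76073],
    [0.044468, -0.99838, 0.035504],
    [-0.76148, -0.010869, 0.6481],
])


def min_angle_to(R, cands):
    return min(ts.rotation_angle_deg(R, Rc) for Rc, _ in cands)


class TestAffineFundamental:
    def test_affine_form_enforced(self):
        with pytest.raises(ValueError):
            AffineFundamental(np.eye(3))
        F = AffineFundamental(np.array([[0, 0, 1.0], [0, 0, 2.0],
                                        [3.0, 4, 5]]))
        assert np.linalg.norm(F.F) == pytest.approx(1.0)

    def test_estimate_matches_analytic_and_annihilates_pairs(self):
        rng = np.random.default_rng(0)
        cam1, cam2 = random_rig(rng, 38.5)
        X = sphere_cap_points(rng, 200)
        pairs = exact_pairs(cam1, cam2, X)
        F = estimate_affine_fundamental(pairs)
        assert np.abs(F.residuals(pairs)).max() < 1e-8
        Fa = affine_fundamental_from_cameras(cam1, cam2)
        assert (np.abs(F.F - Fa.F).max() < 1e-8
                or np.abs(F.F + Fa.F).max() < 1e-8)

    def test_metric_epipolar_scales_agree(self):
        # internal consistency of the affine epipolar geometry: the
        # metric coefficient norms of the two images must coincide
        rng = np.random.default_rng(1)
        for _ in range(10):
            cam1, cam2 = random_rig(rng)
            F = affine_fundamental_from_cameras(cam1, cam2)
            fam = TurnAngleFamily(F, cam1.K, cam2.K)
            assert fam.scale_consistency < 1e-9

    def test_single_epipolar_line_degenerate(self):
        # all points on one world line: correspondences collinear
        rng = np.random.default_rng(2)
        cam1, cam2 = random_rig(rng, 40.0)
        lam = rng.uniform(-2, 2, 50)
        X = np.outer(lam, [1.0, 0.4, 0.2])
        with pytest.raises(DegenerateFitError):
            estimate_affine_fundamental(exact_pairs(cam1, cam2, X))

    def test_too_few_pairs(self):
        z = np.zeros(3)
        with pytest.raises(ValueError):
            estimate_affine_fundamental(CorrespondenceSet(z, z, z, z, z))


class TestCandidateExtrinsics:
    def test_exact_essential_contains_true_rotation(self):
        # candidate completeness over random rigs, noise-free
        rng = np.random.default_rng(3)
        for _ in range(100):
            ang = rng.uniform(5, 80)
            R = rotation_matrix(rng.normal(size=3), np.radians(ang))
            t = rng.normal(size=3)
            t /= np.linalg.norm(t)
            cands = candidates_from_essential(essential_from_pose(R, t))
            assert min_angle_to(R, cands) < 1e-6
            assert min(np.linalg.norm(t - s * cands.t_unit)
                       for s in (1, -1)) < 1e-6

    def test_swapping_camera_roles_transposes_rotation(self):
        rng = np.random.default_rng(4)
        R = rotation_matrix([0.2, 1, 0.1], 0.6)
        t = np.array([0.8, 0.1, 0.55])
        E = essential_from_pose(R, t / np.linalg.norm(t))
        fwd = candidates_from_essential(E)
        # swapped cameras see the constraint transposed
        rev = candidates_from_essential(E.T)
        for Rf, _ in fwd:
            assert min_angle_to(Rf.T, rev) < 1e-6

    def test_telecentric_mismatch_produces_identity_and_half_turn(self):
        # feeding the affine F of a telecentric pair through the
        # pinhole-style decomposition yields the characteristic pair:
        # one candidate hugging the identity, one strongly rotated
        cam1, cam2, _ = desk_rig(38.5)
        F = affine_fundamental_from_cameras(cam1, cam2)
        cands = candidate_extrinsics(F, cam1.K, cam2.K)
        devs = sorted(np.linalg.norm(R - np.eye(3)) for R, _ in cands)
        assert devs[0] < 0.5
        assert devs[-1] > 2.0

    def test_positive_diagonal_k_required(self):
        F = AffineFundamental(np.array([[0, 0, 0], [0, 0, 1.0],
                                        [0, -1.0, 0.1]]))
        with pytest.raises(ValueError):
            candidate_extrinsics(F, np.diag([-1.0, 1, 1]), np.eye(3))


class TestIdentityRule:
    def test_printed_candidate_pair_selects_strong_rotation(self):
        cands = ExtrinsicCandidateSet(R_a=R_NEAR_IDENTITY,
                                      R_b=R_STRONGLY_ROTATED,
                                      t_unit=[1.0, 0, 0])
        R, t, margin = select_by_identity_rule(cands)
        assert abs(R[0, 0]) == pytest.approx(0.64667)
        assert margin > 1.0

    def test_identity_versus_small_rotation(self):
        R10 = rotation_matrix([0, 1, 0], np.radians(10))
        cands = ExtrinsicCandidateSet(np.eye(3), R10, [0, 0, 1.0])
        R, _, _ = select_by_identity_rule(cands)
        assert np.allclose(R, R10)

    def test_equidistant_rotations_ambiguous(self):
        Ra = rotation_matrix([0, 0, 1], 0.3)
        Rb = rotation_matrix([1, 0, 0], 0.3)
        with pytest.raises(AmbiguousSelectionError):
            select_by_identity_rule(
                ExtrinsicCandidateSet(Ra, Rb, [0, 1.0, 0]))


class TestSelectByReference:
    def test_sphere_reference_picks_true_rotation(self):
        rng = np.random.default_rng(5)
        cam1, cam2 = random_rig(rng, 40.0)
        R_rel = cam2.R @ cam1.R.T
        t_rel = cam2.t - R_rel @ cam1.t
        cands = candidates_from_essential(
            essential_from_pose(R_rel, t_rel / np.linalg.norm(t_rel)))
        pairs = exact_pairs(cam1, cam2, sphere_cap_points(rng, 300))
        Rsel, tsel, table = select_by_reference(cands, pairs, cam1, cam2,
                                                "sphere")
        assert ts.rotation_angle_deg(Rsel, R_rel) < 1e-3
        best = min(table.values())
        worst_other = min(v for k, v in table.items()
                          if not np.isclose(v, best, rtol=1e-6))
        assert worst_other >= 10 * max(best, 1e-12)

    def test_both_translation_signs_equivalent(self):
        rng = np.random.default_rng(6)
        cam1, cam2 = random_rig(rng, 38.5)
        R_rel = cam2.R @ cam1.R.T
        t_rel = cam2.t - R_rel @ cam1.t
        cands = candidates_from_essential(
            essential_from_pose(R_rel, t_rel / np.linalg.norm(t_rel)))
        pairs = exact_pairs(cam1, cam2,
                            sphere_cap_points(rng, 200, half_angle_deg=50),
                            rng=rng, noise_px=0.05)
        _, _, table = select_by_reference(cands, pairs, cam1, cam2,
                                          "sphere")
        assert table["R_a,+t"] == pytest.approx(table["R_a,-t"], abs=1e-9)
        assert table["R_b,+t"] == pytest.approx(table["R_b,-t"], abs=1e-9)

    def test_plane_reference_rejects_near_degenerate_candidates(self):
        # a plane stays a plane under every candidate, so it cannot see
        # the twisted partner; what it does expose is the catastrophic
        # noise amplification of near-parallel-ray candidates from the
        # telecentric mismatch
        rng = np.random.default_rng(7)
        cam1, cam2 = random_rig(rng, 40.0)
        F = affine_fundamental_from_cameras(cam1, cam2)
        cands = candidate_extrinsics(F, cam1.K, cam2.K)
        n = 400
        X = np.column_stack([rng.uniform(-3, 3, n), rng.uniform(-3, 3, n),
                             np.zeros(n)])
        pairs = exact_pairs(cam1, cam2, X, rng=rng, noise_px=0.05)
        _, _, table = select_by_reference(cands, pairs, cam1, cam2, "plane")
        devs = {lab: np.linalg.norm(R - np.eye(3))
                for lab, (R, _) in zip(cands.labels(), cands)}
        near_label = min(devs, key=devs.get)
        far_label = max(devs, key=devs.get)
        assert table[far_label] < table[near_label]

    def test_needs_enough_pairs(self):
        cands = ExtrinsicCandidateSet(np.eye(3),
                                      rotation_matrix([0, 1, 0], 0.5),
                                      [1.0, 0, 0])
        cam1, cam2, _ = desk_rig()
        z = np.zeros(5)
        with pytest.raises(ValueError):
            select_by_reference(cands, CorrespondenceSet(z, z, z, z, z),
                                cam1, cam2)


class TestCorrectExtrinsics:
    def test_recovers_true_rotation_noise_free(self):
        rng = np.random.default_rng(8)
        for flip in (False, True):
            cam1, cam2 = random_rig(rng, 38.5, flip_camera2=flip)
            R_rel = cam2.R @ cam1.R.T
            pairs = exact_pairs(cam1, cam2, sphere_cap_points(rng, 300))
            F = estimate_affine_fundamental(pairs)
            sol = correct_extrinsics(F, pairs, cam1, cam2,
                                     reference_radius=2.5)
            assert ts.rotation_angle_deg(sol.R, R_rel) < 1e-3
            assert sol.residual_std < 1e-6
            assert sol.fitted_radius == pytest.approx(2.5, rel=1e-4)

    def test_family_contains_true_rotation(self):
        rng = np.random.default_rng(9)
        cam1, cam2 = random_rig(rng, 45.0)
        R_rel = cam2.R @ cam1.R.T
        F = affine_fundamental_from_cameras(cam1, cam2)
        fam = TurnAngleFamily(F, cam1.K, cam2.K)
        best = min(
            ts.rotation_angle_deg(fam.rotation(th), R_rel)
            for th in np.linspace(-np.pi, np.pi, 3601)
        )
        assert best < 0.1

    def test_world_scale_leaves_geometry_unchanged(self):
        # scaling every world length changes neither F nor the selected
        # rotation — the metric scale is fundamentally unobservable and
        # only the grid-based scale estimate responds
        rng = np.random.default_rng(10)
        cam1, cam2 = random_rig(rng, 40.0)
        X = sphere_cap_points(rng, 300)
        F1 = estimate_affine_fundamental(exact_pairs(cam1, cam2, X))
        F2 = estimate_affine_fundamental(exact_pairs(cam1, cam2, 2.0 * X))
        assert (np.abs(F1.F - F2.F).max() < 1e-9
                or np.abs(F1.F + F2.F).max() < 1e-9)
        sol1 = correct_extrinsics(F1, exact_pairs(cam1, cam2, X),
                                  cam1, cam2, reference_radius=2.5)
        sol2 = correct_extrinsics(F2, exact_pairs(cam1, cam2, 2.0 * X),
                                  cam1, cam2, reference_radius=5.0)
        assert ts.rotation_angle_deg(sol1.R, sol2.R) < 1e-3
        c1 = candidate_extrinsics(F1, cam1.K, cam2.K)
        c2 = candidate_extrinsics(F2, cam1.K, cam2.K)
        assert sorted(np.linalg.norm(R - np.eye(3)) for R, _ in c1) == \
            pytest.approx(sorted(np.linalg.norm(R - np.eye(3))
                                 for R, _ in c2), abs=1e-9)


class TestEstimateScale:
    @staticmethod
    def grid_cloud(rng, spacing=1.0, n=6000, width=0.12, scale=1.0,
                   Rw=None):
        ks = np.arange(-4, 5)
        pts = []
        for k in ks:
            m = n // (2 * len(ks))
            x = k * spacing + rng.uniform(-width / 2, width / 2, m)
            y = rng.uniform(-4.5 * spacing, 4.5 * spacing, m)
            pts.append(np.column_stack([x, y, np.zeros(m)]))
            x2 = rng.uniform(-4.5 * spacing, 4.5 * spacing, m)
            y2 = k * spacing + rng.uniform(-width / 2, width / 2, m)
            pts.append(np.column_stack([x2, y2, np.zeros(m)]))
        P = np.vstack(pts) + rng.normal(0, 0.003, (len(np.vstack(pts)), 3))
        P = P * scale
        if Rw is not None:
            P = P @ Rw.T
        return PointCloud(P)

    def test_metric_cloud_gives_unit_factor(self):
        rng = np.random.default_rng(11)
        sr = estimate_scale(self.grid_cloud(rng), 1.0)
        assert sr.factor == pytest.approx(1.0, rel=0.005)

    def test_uniform_scaling_inverted(self):
        rng = np.random.default_rng(12)
        for s in (0.5, 1.0 / 1.9928, 1.3):
            Rw = rotation_matrix([0.3, 1, 0.2], 0.7)
            sr = estimate_scale(self.grid_cloud(rng, scale=s, Rw=Rw), 1.0)
            assert sr.factor == pytest.approx(1.0 / s, rel=0.005)
            assert sr.factor * sr.feature_spacing_measured == \
                pytest.approx(sr.feature_spacing_true, rel=1e-9)

    def test_single_feature_rejected(self):
        rng = np.random.default_rng(13)
        line = PointCloud(np.column_stack([
            rng.uniform(-0.05, 0.05, 200), rng.uniform(-3, 3, 200),
            np.zeros(200)]))
        with pytest.raises(DegenerateFitError):
            estimate_scale(line, 1.0)
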