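"""Robust affine estimation: minimal/least-squares solvers, RANSAC, LM, RR."""

import numpy as np
import pytest

from fetomosaic.correspondence import CorrespondenceSet
from fetomosaic.geometry import AffineTransform
from fetomosaic.registration import (
    DegenerateSampleError,
    RansacConfig,
    RegistrationFailureError,
    ransac_affine,
    refine_lm,
    register_pair,
    reprojection_residuals,
    robust_regression_affine,
    solve_affine_lsq,
    solve_affine_minimal,
)

CORNERS_400 = np.array([[0, 0], [399, 0], [0, 399], [399, 399]], dtype=float)


def make_set(rng, A, n, noise=0.0, frame=400.0):
    src = rng.uniform(0, frame, (n, 2))
    dst = A.apply(src)
    if noise:
        dst = dst + rng.normal(scale=noise, size=dst.shape)
    return CorrespondenceSet(src, dst)


def corner_error(A_est, A_true, corners=CORNERS_400):
    return np.linalg.norm(A_est.apply(corners) - A_true.apply(corners), axis=1).max()


class TestMinimalSolver:
    def test_identity_pairs(self):
        c = CorrespondenceSet([[0, 0], [1, 0], [0, 1]], [[0, 0], [1, 0], [0, 1]])
        assert solve_affine_minimal(c).almost_equal(AffineTransform.identity())

    def test_recovers_random_transform(self, rng):
        for _ in range(20):
            A = AffineTransform(np.column_stack([np.eye(2) + rng.uniform(-0.2, 0.2, (2, 2)), rng.uniform(-20, 20, 2)]))
            c = make_set(rng, A, 3)
            est = solve_affine_minimal(c)
            assert np.abs(est.matrix - A.matrix).max() < 1e-9
            assert reprojection_residuals(est, c).max() < 1e-9  # exact interpolation

    def test_collinear_sources_rejected(self):
        c = CorrespondenceSet([[0, 0], [1, 1], [2, 2]], [[0, 0], [1, 1], [2, 2]])
        with pytest.raises(DegenerateSampleError):
            solve_affine_minimal(c)


class TestLsqSolver:
    def test_exact_recovery_noise_free(self, rng):
        A = AffineTransform.from_params(1.02, 0.05, 8.0, -0.03, 0.98, -3.0)
        est = solve_affine_lsq(make_set(rng, A, 50))
        assert np.abs(est.matrix - A.matrix).max() < 1e-9

    def test_n3_equals_minimal(self, rng):
        A = AffineTransform.from_params(1.1, 0.0, 2.0, 0.0, 0.9, 1.0)
        c = make_set(rng, A, 3)
        assert solve_affine_lsq(c).almost_equal(solve_affine_minimal(c), atol=1e-9)

    def test_optimality_under_noise(self, rng):
        A = AffineTransform.from_params(1.0, 0.02, 4.0, -0.02, 1.0, 2.0)
        c = make_set(rng, A, 200, noise=0.5)
        est = solve_affine_lsq(c)
        e_est = float(np.sum(reprojection_residuals(est, c) ** 2))
        e_true = float(np.sum(reprojection_residuals(A, c) ** 2))
        assert e_est <= e_true

    def test_rank_deficient_rejected(self):
        src = np.column_stack([np.arange(5.0), np.arange(5.0)])  # collinear
        with pytest.raises(DegenerateSampleError):
            solve_affine_lsq(CorrespondenceSet(src, src))


class TestRansac:
    def test_all_consistent_all_inliers(self, rng):
        A = AffineTransform.from_params(1.01, 0.03, 5.0, -0.02, 0.99, -2.0)
        c = make_set(rng, A, 100)
        reg = ransac_affine(c, RansacConfig(seed=0))
        assert reg.n_inliers == 100
        lsq = solve_affine_lsq(c)
        assert np.abs(reg.transform.matrix - lsq.matrix).max() < 1e-6

    def test_gross_outliers_rejected(self, rng):
        A = AffineTransform.from_params(1.0, 0.05, 10.0, -0.05, 1.0, 6.0)
        c = make_set(rng, A, 500)
        n_out = 150
        idx = rng.choice(500, n_out, replace=False)
        offs = rng.uniform(15, 40, (n_out, 2)) * rng.choice([-1, 1], (n_out, 2))
        dst = c.dst.copy()
        dst[idx] += offs
        c = CorrespondenceSet(c.src, dst)
        reg = ransac_affine(c, RansacConfig(seed=1))
        excluded = np.count_nonzero(~reg.inlier_mask[idx])
        assert excluded >= 0.95 * n_out
        assert corner_error(reg.transform, A) < 0.1

    def test_residual_exactly_at_threshold_is_inlier(self):
        """A pair whose re-projection error is exactly 6.0 counts as inlier (<=)."""
        # identity-consistent grid plus one point displaced by exactly (0, 6)
        gx, gy = np.meshgrid(np.arange(0.0, 100.0, 10.0), np.arange(0.0, 100.0, 10.0))
        src = np.column_stack([gx.ravel(), gy.ravel()])
        dst = src.copy()
        src = np.vstack([src, [50.0, 50.0]])
        dst = np.vstack([dst, [50.0, 56.0]])
        c = CorrespondenceSet(src, dst)
        assert reprojection_residuals(AffineTransform.identity(), c)[-1] == 6.0
        reg = ransac_affine(c, RansacConfig(threshold=6.0, seed=0))
        assert reg.inlier_mask[-1]
        # strictly beyond the bound the same point is excluded
        dst[-1] = [50.0, 56.1]
        reg = ransac_affine(CorrespondenceSet(src, dst), RansacConfig(threshold=6.0, seed=0))
        assert not reg.inlier_mask[-1]

    def test_failure_with_too_few_points(self):
        with pytest.raises(RegistrationFailureError):
            ransac_affine(CorrespondenceSet(np.zeros((2, 2)), np.zeros((2, 2))))

    def test_deterministic_and_permutation_invariant_inlier_set(self, rng):
        A = AffineTransform.from_params(1.0, 0.0, 5.0, 0.0, 1.0, -4.0)
        c = make_set(rng, A, 200)
        idx = rng.choice(200, 60, replace=False)
        dst = c.dst.copy()
        dst[idx] += rng.uniform(15, 40, (60, 2))
        c = CorrespondenceSet(c.src, dst)
        reg1 = ransac_affine(c, RansacConfig(seed=5))
        reg2 = ransac_affine(c, RansacConfig(seed=5))
        assert np.array_equal(reg1.inlier_mask, reg2.inlier_mask)
        perm = rng.permutation(200)
        reg3 = ransac_affine(c.subset(perm), RansacConfig(seed=5))
        assert np.array_equal(reg3.inlier_mask, reg1.inlier_mask[perm])


class TestRefineLM:
    def test_fixed_point_at_lsq_solution(self, rng):
        A = AffineTransform.from_params(1.05, -0.02, 3.0, 0.01, 0.97, -1.0)
        c = make_set(rng, A, 80, noise=0.3)
        lsq = solve_affine_lsq(c)
        refined = refine_lm(lsq, c)
        assert np.abs(refined.matrix - lsq.matrix).max() < 1e-8

    def test_converges_to_closed_form_from_perturbation(self, rng):
        A = AffineTransform.from_params(1.0, 0.04, 7.0, -0.04, 1.0, 2.0)
        c = make_set(rng, A, 100, noise=0.5)
        lsq = solve_affine_lsq(c)
        A0 = AffineTransform(lsq.matrix + 0.1)
        refined, history = refine_lm(A0, c, full_output=True)
        assert np.abs(refined.matrix - lsq.matrix).max() < 1e-6
        assert all(b <= a + 1e-12 for a, b in zip(history, history[1:]))  # monotone

    def test_energy_never_increases_vs_start(self, rng):
        A0 = AffineTransform.from_params(1.2, 0.1, -5.0, 0.1, 0.8, 5.0)
        c = make_set(rng, AffineTransform.identity(), 50, noise=1.0)
        refined = refine_lm(A0, c)
        e0 = float(np.sum(reprojection_residuals(A0, c) ** 2))
        e1 = float(np.sum(reprojection_residuals(refined, c) ** 2))
        assert e1 <= e0


class TestRobustRegression:
    def test_clean_data_matches_lsq(self, rng):
        A = AffineTransform.from_params(1.0, 0.03, 6.0, -0.03, 1.0, -2.0)
        c = make_set(rng, A, 200)
        rr = robust_regression_affine(c)
        lsq = solve_affine_lsq(c)
        assert corner_error(rr.transform, lsq) < 1e-4

    def test_outliers_hurt_rr_less_than_lsq(self, rng):
        A = AffineTransform.from_params(1.0, 0.0, 8.0, 0.0, 1.0, -6.0)
        c = make_set(rng, A, 300)
        idx = rng.choice(300, 60, replace=False)
        dst = c.dst.copy()
        dst[idx] += rng.uniform(20, 40, (60, 2))
        c = CorrespondenceSet(c.src, dst)
        rr_err = corner_error(robust_regression_affine(c).transform, A)
        lsq_err = corner_error(solve_affine_lsq(c), A)
        assert rr_err < lsq_err

    def test_large_f_scale_limit_is_lsq(self, rng):
        A = AffineTransform.from_params(1.0, 0.02, 3.0, 0.02, 1.0, 1.0)
        c = make_set(rng, A, 100, noise=1.0)
        rr = robust_regression_affine(c, f_scale=1e6)
        assert corner_error(rr.transform, solve_affine_lsq(c)) < 1e-4


class TestRegisterPair:
    def test_identical_frames_identity(self, short_sequence):
        f = short_sequence.frames[0]
        reg = register_pair(f, f, mask=short_sequence.mask)
        corners = np.array([[0, 0], [319, 0], [0, 319], [319, 319]], dtype=float)
        err = np.linalg.norm(reg.transform.apply(corners) - corners, axis=1).max()
        assert err < 0.05
        assert reg.n_inliers / reg.n >= 0.99

    def test_simulator_pair_known_transform(self, short_sequence):
        seq = short_sequence
        reg = register_pair(seq.frames[0], seq.frames[1], mask=seq.mask, pair_index=0)
        assert corner_error(reg.transform, seq.gt_pairwise[0],
                            np.array([[0, 0], [319, 0], [0, 319], [319, 319]], float)) <= 0.5

    def test_particles_land_in_outlier_list(self, artifact_sequence):
        seq = artifact_sequence
        reg = register_pair(
            seq.frames[0], seq.frames[1], flow=seq.corrupted_flow(0), mask=seq.mask, pair_index=0
        )
        lab = seq.artifact_labels[0]
        out = np.zeros(lab.shape, bool)
        pts = reg.outlier_points.astype(int)
        out[pts[:, 1], pts[:, 0]] = True
        sampled = np.zeros(lab.shape, bool)
        sampled[::2, ::2] = True
        sampled &= seq.mask.raster(lab.shape)
        particle = (lab == 1) & sampled
        recall = np.count_nonzero(out & particle) / np.count_nonzero(particle)
        assert recall >= 0.9
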