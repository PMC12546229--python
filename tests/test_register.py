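"""Coarse-rotation algebra, trunk translation, trimmed ICP, composition."""

import numpy as np
import pytest

from treereg import PointCloud
from treereg.errors import FineFailureError
from treereg.preprocess import GroundPlane, fit_ground_plane
from treereg.primitives import Cylinder
from treereg.register import (IcpConfig, apply_transform, extract_branch_only,
                              rotation_from_branches, transform_plane,
                              translation_from_trunks, trimmed_icp,
                              _rigid_solve)
from treereg.transform import RigidTransform

PLANE = GroundPlane(normal=np.array([0.0, 0.0, 1.0]), offset=0.0, inlier_count=1)
VERT = Cylinder(axis_point=[0, 0, 0], axis_dir=[0, 0, 1], radius=0.03)


def branch_cyl(point, direction, radius=0.01):
    return Cylinder(axis_point=point, axis_dir=direction, radius=radius)


class TestRotationAlgebra:
    def test_rot_z_matches_symbolic_expansion(self, rng):
        """Rotation about the vertical line through O equals
        Trans(O) . Rz(alpha) . Trans(-O) over 1000 random draws."""
        for _ in range(1000):
            alpha = rng.uniform(-np.pi, np.pi)
            O = rng.uniform(-3, 3, 2)
            T1 = RigidTransform.rot_z(alpha, center=O).matrix
            to = np.eye(4); to[:2, 3] = O
            back = np.eye(4); back[:2, 3] = -O
            rz = RigidTransform.rot_z(alpha).matrix
            np.testing.assert_allclose(T1, to @ rz @ back, atol=1e-12)

    def test_rotation_center_is_fixed(self, rng):
        alpha, O = 0.7, np.array([0.4, -0.2])
        T1 = RigidTransform.rot_z(alpha, center=O)
        for z in (-1.0, 0.0, 2.5):
            p = np.array([O[0], O[1], z])
            np.testing.assert_allclose(T1.apply(p), p, atol=1e-9)

    def test_identical_axes_give_identity(self):
        b = branch_cyl([0.1, 0, 1.0], [0.8, 0.6, 0.0])
        O, alpha, T1, fallback = rotation_from_branches(b, b, VERT, VERT)
        assert fallback  # identical projections are parallel
        assert alpha == 0.0
        np.testing.assert_allclose(T1.matrix, np.eye(4), atol=1e-12)

    def test_recovers_constructed_rotation(self):
        """Target branch built by rotating the source scene 30 deg about the
        vertical line through (0.4, -0.2), chosen on the source axis: the
        recovered center and angle must match (a center off the axis is not
        identifiable from one line pair and is compensated by T2)."""
        O_true = np.array([0.4, -0.2])
        alpha_true = np.deg2rad(30)
        T_true = RigidTransform.rot_z(alpha_true, center=O_true)
        d = np.array([0.9, 0.1, 0.2])
        src = branch_cyl([0.4 + 0.09, -0.2 + 0.01, 1.0], d)  # axis through O
        tgt = branch_cyl(T_true.apply(src.axis_point), T_true.rotation @ d)
        tgt_trunk = Cylinder(axis_point=T_true.apply(VERT.axis_point),
                             axis_dir=[0, 0, 1], radius=0.03)
        O, alpha, T1, fallback = rotation_from_branches(src, tgt, VERT, tgt_trunk)
        assert not fallback
        assert alpha == pytest.approx(alpha_true, abs=1e-6)
        np.testing.assert_allclose(O, O_true, atol=1e-6)

    def test_t1_maps_source_axis_line_onto_target_line(self):
        """Even when the true center is off the source axis, T1 built from
        the projected-axis intersection maps the source axis line onto the
        target axis line."""
        T_true = RigidTransform.rot_z(0.6, center=[1.0, 0.7])
        d = np.array([0.8, -0.3, 0.1])
        src = branch_cyl([0.1, 0.05, 1.2], d)
        tgt = branch_cyl(T_true.apply(src.axis_point), T_true.rotation @ d)
        tgt_trunk = Cylinder(axis_point=T_true.apply(VERT.axis_point),
                             axis_dir=[0, 0, 1], radius=0.03)
        _, _, T1, fallback = rotation_from_branches(src, tgt, VERT, tgt_trunk)
        assert not fallback
        # mapped source axis points lie on the target projected line
        for t in (-0.5, 0.0, 1.0):
            p = T1.apply(src.axis_point + t * src.axis_dir)[:2]
            v = p - tgt.axis_point[:2]
            d2 = tgt.axis_dir[:2] / np.linalg.norm(tgt.axis_dir[:2])
            assert abs(v[0] * d2[1] - v[1] * d2[0]) < 1e-9

    def test_composition_order(self):
        """Applying T1 then T2 equals applying Tc = T2 . T1 pointwise."""
        T1 = RigidTransform.rot_z(0.5, center=[1.0, 2.0])
        T2 = RigidTransform.translation_only([0.1, -0.2, 0.05])
        Tc = T2 @ T1
        rng = np.random.default_rng(1)
        pts = rng.uniform(-1, 1, (50, 3))
        np.testing.assert_allclose(T2.apply(T1.apply(pts)), Tc.apply(pts),
                                   atol=1e-12)


def tree_slab_cloud(rng, center=(0, 0), n=4000, r=0.031):
    """Noiseless full cylinder over heights 0..0.5 m around `center`."""
    ang = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(0.0, 0.5, n)
    pts = np.column_stack([center[0] + r * np.cos(ang),
                           center[1] + r * np.sin(ang), z])
    return PointCloud(pts)


class TestTranslation:
    def test_identity_for_identical_clouds(self, rng):
        cloud = tree_slab_cloud(rng)
        G_s, G_t, T2 = translation_from_trunks(cloud, cloud, PLANE, PLANE,
                                               RigidTransform.identity(), seed=0)
        assert np.linalg.norm(T2.translation) < 5e-4

    def test_recovers_constructed_shift(self, rng):
        src = tree_slab_cloud(rng)
        shift = np.array([1.0, 2.0, 0.5])
        tgt = PointCloud(src.points + shift)
        tgt_plane = GroundPlane(normal=np.array([0.0, 0.0, 1.0]), offset=-0.5,
                                inlier_count=1)
        _, _, T2 = translation_from_trunks(src, tgt, PLANE, tgt_plane,
                                           RigidTransform.identity(), seed=0)
        np.testing.assert_allclose(T2.translation, shift, atol=1e-3)

    def test_opposed_half_cylinders_small_bias(self, rng):
        """Each station sees one half of the trunk; the recovered centers
        must still agree within 5 mm."""
        full = tree_slab_cloud(rng, n=8000)
        noise = rng.normal(0, 0.002, full.points.shape)
        pts = full.points + noise
        front = PointCloud(pts[full.points[:, 0] > 0])
        back = PointCloud(pts[full.points[:, 0] <= 0])
        G_s, G_t, T2 = translation_from_trunks(front, back, PLANE, PLANE,
                                               RigidTransform.identity(), seed=1)
        assert np.linalg.norm(G_s - G_t) < 0.005


class TestTrimmedIcp:
    def test_identity_on_identical_clouds(self, rng):
        cloud = PointCloud(rng.uniform(0, 1, (500, 3)))
        Tf, rms, iters, _ = trimmed_icp(cloud, cloud,
                                        IcpConfig(max_corr_dist=None))
        np.testing.assert_allclose(Tf.matrix, np.eye(4), atol=1e-9)
        assert iters <= 2

    def test_recovers_small_rigid_motion(self, rng):
        src = PointCloud(rng.uniform(0, 1, (2000, 3)))
        T_true = RigidTransform.rot_z(0.05) @ RigidTransform.translation_only(
            [0.010, 0.005, 0.002])
        tgt = apply_transform(src, T_true)
        Tf, rms, _, _ = trimmed_icp(src, tgt, IcpConfig(max_corr_dist=None))
        from treereg.metrics import rotation_error
        assert rotation_error(Tf.rotation, T_true.rotation) < 1e-3
        assert np.linalg.norm(Tf.translation - T_true.translation) < 5e-4

    def test_single_solve_equals_svd_oracle(self, rng):
        """One rigid solve on fixed correspondences equals the closed-form
        cross-covariance SVD solution."""
        src = rng.uniform(0, 1, (100, 3))
        R_true = RigidTransform.rot_z(0.3).rotation
        tgt = src @ R_true.T + [0.2, -0.1, 0.4]
        T = _rigid_solve(src, tgt)
        # independent oracle: direct Kabsch recomputation
        cs, ct = src.mean(0), tgt.mean(0)
        H = (src - cs).T @ (tgt - ct)
        U, _, Vt = np.linalg.svd(H)
        D = np.diag([1, 1, np.sign(np.linalg.det(Vt.T @ U.T))])
        R_oracle = Vt.T @ D @ U.T
        np.testing.assert_allclose(T.rotation, R_oracle, atol=1e-12)
        np.testing.assert_allclose(T.rotation, R_true, atol=1e-9)

    def test_trimmed_rms_non_increasing(self, rng):
        src = PointCloud(rng.uniform(0, 0.5, (1500, 3)))
        tgt = apply_transform(src, RigidTransform.rot_z(0.1,
                                                        center=[0.2, 0.2]))
        _, _, _, history = trimmed_icp(src, tgt, IcpConfig(max_corr_dist=None))
        diffs = np.diff(history)
        assert np.all(diffs <= 1e-12)

    def test_empty_cloud_raises(self):
        with pytest.raises(FineFailureError):
            trimmed_icp(PointCloud(np.zeros((0, 3))),
                        PointCloud(np.zeros((5, 3))))


class TestBranchOnly:
    def test_label_oracle_on_synthetic_tree(self):
        from treereg import TreeSpec, generate_tree
        tree = generate_tree(TreeSpec(surface_sampling=0.004,
                                      ground_sampling=0.03, ground_extent=0.6,
                                      n_branches=8, trunk_lean_deg=0.0, seed=4))
        plane = fit_ground_plane(tree, seed=0)
        trunk = Cylinder(axis_point=[0, 0, 0], axis_dir=[0, 0, 1], radius=0.028)
        out = extract_branch_only(tree, trunk, plane, margin=0.015)
        # retained points are branch-labeled up to margin-zone crossers
        assert np.mean(out.labels == 2) > 0.95

    def test_infinite_margin_raises(self, fast_tree):
        plane = fit_ground_plane(fast_tree, seed=0)
        trunk = Cylinder(axis_point=[0, 0, 0], axis_dir=[0, 0, 1], radius=0.03)
        with pytest.raises(FineFailureError):
            extract_branch_only(fast_tree, trunk, plane, margin=np.inf)


class TestApplyTransform:
    def test_identity(self, rng):
        cloud = PointCloud(rng.uniform(0, 1, (100, 3)))
        out = apply_transform(cloud, RigidTransform.identity())
        np.testing.assert_array_equal(out.points, cloud.points)

    def test_inverse_round_trip(self, rng):
        cloud = PointCloud(rng.uniform(0, 1, (100, 3)))
        T = RigidTransform.rot_z(1.1, center=[0.5, -0.3]) \
            @ RigidTransform.translation_only([1, 2, 3])
        back = apply_transform(apply_transform(cloud, T), T.inverse())
        np.testing.assert_allclose(back.points, cloud.points, atol=1e-12)

    def test_pure_translation(self, rng):
        cloud = PointCloud(rng.uniform(0, 1, (50, 3)))
        t = np.array([0.1, -0.2, 0.3])
        out = apply_transform(cloud, RigidTransform.translation_only(t))
        np.testing.assert_allclose(out.points - cloud.points,
                                   np.tile(t, (50, 1)), atol=1e-15)

    def test_plane_transforms_consistently(self, rng):
        cloud = PointCloud(rng.uniform(-1, 1, (200, 3)))
        plane = GroundPlane(normal=np.array([0.0, 0.0, 1.0]), offset=-0.1,
                            inlier_count=1)
        T = RigidTransform.rot_z(0.8, center=[1.0, 0.5]) \
            @ RigidTransform.translation_only([0.3, 0.1, 0.7])
        from treereg.preprocess import height_above_ground
        h_before = height_above_ground(cloud.points, plane)
        moved = apply_transform(cloud, T)
        h_after = height_above_ground(moved.points, transform_plane(plane, T))
        np.testing.assert_allclose(h_after, h_before, atol=1e-12)
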