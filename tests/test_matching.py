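"""Dynamic-weight scoring, threshold gating, one-to-one branch matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treereg import MatchConfig, PointCloud
from treereg.errors import ContractViolationError, EmptyRegionError
from treereg.matching import (BranchSegment, match_branches, pair_score,
                              extract_key_region, segment_branch_ring,
                              threshold_gate)
from treereg.preprocess import GroundPlane
from treereg.primitives import Cluster, Cylinder

CFG = MatchConfig()
PLANE = GroundPlane(normal=np.array([0.0, 0.0, 1.0]), offset=0.0, inlier_count=1)


def make_segment(r, theta, h, inliers=100, gt=None):
    cyl = Cylinder(axis_point=[0, 0, h], axis_dir=[1, 0, 0], radius=r,
                   inlier_idx=np.arange(inliers), inlier_ratio=1.0)
    return BranchSegment(cluster=Cluster(np.arange(inliers)), cylinder=cyl,
                         r=r, theta=theta, h=h, inlier_count=inliers,
                         gt_branch_id=gt)


def residuals_to_score_args(x):
    """Map normalized residuals x to raw (d_r, d_theta, d_h)."""
    return x[0] * CFG.tol_r, x[1] * CFG.tol_theta, x[2] * CFG.tol_h


class TestThresholdGate:
    def test_pass_within_all_tolerances(self):
        assert threshold_gate(0.002, np.deg2rad(5), 0.020, CFG)

    def test_radius_violation_fails(self):
        assert not threshold_gate(0.006, np.deg2rad(1), 0.001, CFG)

    def test_exact_boundary_fails_strict(self):
        assert not threshold_gate(0.005, np.deg2rad(15), 0.050, CFG)

    def test_negative_residual_is_contract_violation(self):
        with pytest.raises(ContractViolationError):
            threshold_gate(-0.001, 0.0, 0.0, CFG)


class TestPairScore:
    def test_equal_residuals_give_third_weights(self):
        score, w_r, w_t, w_h = pair_score(*residuals_to_score_args([0.5] * 3), CFG)
        assert (w_r, w_t, w_h) == (pytest.approx(1 / 3),) * 3
        assert score == pytest.approx(0.5)

    def test_hand_derived_asymmetric_case(self):
        """x = (0.1, 0.5, 0.5): weights and fused score frozen from a hand
        evaluation of the negative-log weighting."""
        score, w_r, w_t, w_h = pair_score(*residuals_to_score_args([0.1, 0.5, 0.5]),
                                          CFG)
        assert w_r == pytest.approx(0.62420, abs=1e-5)
        assert w_t == pytest.approx(0.18790, abs=1e-5)
        assert w_h == pytest.approx(0.18790, abs=1e-5)
        assert score == pytest.approx(0.25032, abs=1e-5)

    def test_perfect_match_limit(self):
        score, *_ = pair_score(0.0, 0.0, 0.0, CFG)
        assert score == pytest.approx(1e-6, abs=1e-9)

    def test_residual_at_tolerance_is_contract_violation(self):
        with pytest.raises(ContractViolationError):
            pair_score(CFG.tol_r, 0.0, 0.0, CFG)

    @pytest.mark.parametrize("x", [0.1, 0.5, 0.9])
    def test_equal_residual_closed_form(self, x):
        score, *_ = pair_score(*residuals_to_score_args([x] * 3), CFG)
        assert score == pytest.approx(x, abs=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(min_value=0.0, max_value=0.999999), min_size=3,
                    max_size=3))
    def test_weights_sum_to_one(self, x):
        _, w_r, w_t, w_h = pair_score(*residuals_to_score_args(x), CFG)
        assert w_r + w_t + w_h == pytest.approx(1.0, abs=1e-9)
        assert min(w_r, w_t, w_h) >= 0

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-3, max_value=0.99), min_size=3,
                    max_size=3),
           st.floats(min_value=0.1, max_value=10.0))
    def test_scale_equivariance(self, x, factor):
        """Rescaling a residual and its tolerance together leaves the score
        unchanged."""
        base, *_ = pair_score(*residuals_to_score_args(x), CFG)
        scaled_cfg = MatchConfig(tol_r=CFG.tol_r * factor)
        scaled, *_ = pair_score(x[0] * CFG.tol_r * factor, x[1] * CFG.tol_theta,
                                x[2] * CFG.tol_h, scaled_cfg)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestMatchBranches:
    def test_self_match(self):
        s = make_segment(0.010, np.deg2rad(60), 1.0)
        result = match_branches([s], [s], CFG)
        assert result.success
        assert result.best.score == pytest.approx(1e-6, abs=1e-9)

    def test_disjoint_features_fail(self):
        s = make_segment(0.010, np.deg2rad(60), 1.0)
        t = make_segment(0.020, np.deg2rad(60), 2.0)
        assert not match_branches([s], [t], CFG).success

    def test_greedy_equals_exhaustive_on_3x3(self):
        """Greedy ascending-score assignment matches the exhaustive optimal
        assignment on a hand-built 3x3 instance with distinct scores."""
        import itertools
        S = [make_segment(0.010 + i * 0.0008, np.deg2rad(60), 1.0 + 0.01 * i,
                          inliers=100 + i) for i in range(3)]
        T = [make_segment(0.010 + j * 0.0008, np.deg2rad(60) + np.deg2rad(2) * j,
                          1.0 + 0.012 * j, inliers=200 + j) for j in range(3)]
        result = match_branches(S, T, CFG)
        assert result.success

        def pscore(s, t):
            d = (abs(s.r - t.r), abs(s.theta - t.theta), abs(s.h - t.h))
            if not threshold_gate(*d, CFG):
                return None
            return pair_score(*d, CFG)[0]

        best_total, best_assign = np.inf, None
        for perm in itertools.permutations(range(3)):
            scores = [pscore(S[i], T[perm[i]]) for i in range(3)]
            if any(v is None for v in scores):
                continue
            if sum(scores) < best_total:
                best_total, best_assign = sum(scores), perm
        got = {(p.src_idx, p.tgt_idx) for p in result.retained}
        assert got == {(i, best_assign[i]) for i in range(3)}
        # best = maximum combined inliers among accepted pairs
        expected_best = max(result.retained,
                            key=lambda p: p.combined_inliers)
        assert result.best.combined_inliers == expected_best.combined_inliers

    def test_symmetry_under_swap(self):
        S = [make_segment(0.010, np.deg2rad(50), 0.8, inliers=80, gt=1),
             make_segment(0.013, np.deg2rad(70), 1.3, inliers=120, gt=2)]
        T = [make_segment(0.0102, np.deg2rad(52), 0.81, inliers=90, gt=1),
             make_segment(0.0131, np.deg2rad(69), 1.29, inliers=110, gt=2)]
        fwd = match_branches(S, T, CFG)
        rev = match_branches(T, S, CFG)
        assert fwd.success and rev.success
        assert {(p.src_idx, p.tgt_idx) for p in fwd.retained} == \
               {(p.tgt_idx, p.src_idx) for p in rev.retained}
        assert (fwd.best.src.gt_branch_id, fwd.best.tgt.gt_branch_id) == \
               (rev.best.tgt.gt_branch_id, rev.best.src.gt_branch_id)

    def test_empty_inputs(self):
        assert not match_branches([], [], CFG).success


class TestRegions:
    def test_key_region_empty_above_tree(self, fast_tree):
        cfg = MatchConfig(key_region=(50.0, 60.0))
        with pytest.raises(EmptyRegionError):
            extract_key_region(fast_tree, PLANE, cfg)

    def test_key_region_full_range_is_identity(self, fast_tree):
        cfg = MatchConfig(key_region=(-10.0, 50.0))
        out = extract_key_region(fast_tree, PLANE, cfg)
        assert len(out) == len(fast_tree)

    def test_key_region_matches_label_oracle(self, fast_tree):
        cfg = MatchConfig(key_region=(0.2, 1.6))
        out = extract_key_region(fast_tree, PLANE, cfg)
        z = fast_tree.points[:, 2]
        assert len(out) == np.sum((z >= 0.2) & (z <= 1.6))

    def test_ring_distances_match_point_to_line_formula(self, rng):
        trunk = Cylinder(axis_point=[0.1, -0.2, 0.0], axis_dir=[0.05, 0.02, 1.0],
                         radius=0.03)
        pts = rng.uniform(-0.5, 0.5, (1000, 3))
        cloud = PointCloud(pts)
        ring = segment_branch_ring(cloud, trunk, CFG)
        # closed-form point-to-line distance oracle
        a, d = trunk.axis_point, trunk.axis_dir
        dist = np.linalg.norm(np.cross(pts - a, d), axis=1)
        expected = (dist >= CFG.ring_min) & (dist <= CFG.ring_max)
        assert len(ring) == expected.sum()
        np.testing.assert_allclose(
            np.sort(ring.points[:, 0]), np.sort(pts[expected][:, 0]), atol=1e-12)

    @pytest.mark.parametrize("radial,kept", [(0.10, True), (0.05, False)])
    def test_ring_band_boundaries(self, radial, kept):
        trunk = Cylinder(axis_point=[0, 0, 0], axis_dir=[0, 0, 1], radius=0.03)
        cloud = PointCloud([[radial, 0.0, 1.0]])
        ring = segment_branch_ring(cloud, trunk, CFG)
        assert (len(ring) == 1) == kept
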