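"""Registration evaluation: rotation/translation/pointwise errors, match
success against ground-truth branch correspondence, model completeness, and
structural tree parameters.

Internally everything is radians and meters; the reporting layer converts to
mrad / mm / cm, the units conventional for TLS registration tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .errors import ContractViolationError, EvaluationError, FitFailureError
from .matching import MatchConfig, MatchResult, filter_candidates, \
    segment_branch_ring
from .preprocess import GroundPlane, height_above_ground
from .primitives import ransac_cylinder
from .transform import RigidTransform


@dataclass
class RegistrationReport:
    """Errors in reporting units: e_R mrad, e_t / e_p / per-axis mm."""

    e_R: float
    e_t: float
    e_p: float
    e_p_xyz: tuple[float, float, float]
    success: bool
    completeness: float | None = None

    def to_json_dict(self) -> dict:
        d = {"e_R_mrad": self.e_R, "e_t_mm": self.e_t,
             "e_p_x_mm": self.e_p_xyz[0], "e_p_y_mm": self.e_p_xyz[1],
             "e_p_z_mm": self.e_p_xyz[2], "e_p_mm": self.e_p,
             "success": self.success}
        if self.completeness is not None:
            d["completeness_pct"] = 100.0 * self.completeness
        return d


@dataclass
class StructuralParams:
    """Tree descriptors reported in cm (diameters) per horticultural convention."""

    tree_height: float
    basal_trunk_diameter: float
    n_primary_branches: int
    max_branch_diameter: float
    avg_branch_diameter: float

    def to_json_dict(self) -> dict:
        return {"tree_height_cm": self.tree_height,
                "basal_trunk_diameter_cm": self.basal_trunk_diameter,
                "n_primary_branches": self.n_primary_branches,
                "max_branch_diameter_cm": self.max_branch_diameter,
                "avg_branch_diameter_cm": self.avg_branch_diameter}


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=np.float64)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-6) \
            or np.linalg.det(R) < 0:
        raise ContractViolationError("input is not a proper rotation matrix")
    return R


def rotation_angle(R: np.ndarray) -> float:
    """Axis-angle magnitude beta = arccos((tr(R) - 1) / 2), in [0, pi]."""
    R = _check_rotation(R)
    return float(np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)))


def rotation_error(R: np.ndarray, R_gt: np.ndarray) -> float:
    """Angular difference arccos((tr(R_gt R^T) - 1)/2), radians; symmetric."""
    return rotation_angle(_check_rotation(R_gt) @ _check_rotation(R).T)


def translation_error(t: np.ndarray, t_gt: np.ndarray) -> float:
    """Euclidean distance between translation vectors, meters."""
    return float(np.linalg.norm(np.asarray(t, dtype=np.float64).reshape(3)
                                - np.asarray(t_gt, dtype=np.float64).reshape(3)))


def pointwise_error(src: PointCloud, T: RigidTransform, T_gt: RigidTransform,
                    ) -> tuple[float, np.ndarray]:
    """Mean distance between estimated and ground-truth mappings of the source.

    Returns (e_p, per-axis means of |coordinate differences|), both in meters.
    """
    if len(src) == 0:
        raise ContractViolationError("pointwise error needs a non-empty cloud")
    diff = T.apply(src.points) - T_gt.apply(src.points)
    e_p = float(np.mean(np.linalg.norm(diff, axis=1)))
    return e_p, np.mean(np.abs(diff), axis=0)


def match_success(match: MatchResult,
                  gt_correspondence: dict[int, int] | None = None) -> bool:
    """True iff the best matched pair agrees with the ground-truth branch map.

    ``gt_correspondence`` maps source branch ids to target branch ids; None
    means the identity map (the synthetic generator keeps ids across scans).
    """
    if not match.success:
        return False
    s_id = match.best.src.gt_branch_id
    t_id = match.best.tgt.gt_branch_id
    if s_id is None or t_id is None:
        raise EvaluationError("best pair lacks ground-truth branch ids")
    expected = gt_correspondence.get(s_id) if gt_correspondence is not None else s_id
    return expected == t_id


def completeness(test: PointCloud, reference: PointCloud,
                 thresh: float = 0.005) -> float:
    """Fraction of reference points with a test-cloud neighbor within ``thresh``.

    Directional coverage: the reference (ground-truth) model is scored
    against the assembled test model.
    """
    if len(reference) == 0:
        raise ContractViolationError("completeness needs a non-empty reference")
    if len(test) == 0:
        return 0.0
    d, _ = cKDTree(test.points).query(reference.points)
    return float(np.mean(d <= thresh))


def make_report(T: RigidTransform, T_gt: RigidTransform, src: PointCloud,
                match: MatchResult | None = None,
                completeness_value: float | None = None) -> RegistrationReport:
    """Assemble all error metrics in reporting units."""
    e_R = rotation_error(T.rotation, T_gt.rotation)
    e_t = translation_error(T.translation, T_gt.translation)
    e_p, e_xyz = pointwise_error(src, T, T_gt)
    success = match.success if match is not None else True
    return RegistrationReport(
        e_R=1e3 * e_R, e_t=1e3 * e_t, e_p=1e3 * e_p,
        e_p_xyz=(1e3 * e_xyz[0], 1e3 * e_xyz[1], 1e3 * e_xyz[2]),
        success=success, completeness=completeness_value)


def structural_params(cloud: PointCloud, plane: GroundPlane, seed: int = 0,
                      cfg: MatchConfig | None = None,
                      min_branch_diameter: float = 0.01) -> StructuralParams:
    """Tree height, basal trunk diameter and primary-branch diameters.

    Trunk diameter is measured at 0.25 m above the ground plane (cylinder fit
    on the 0.20-0.30 m slab); branch diameters reuse the matcher's key-ring
    machinery, counting first-order branches with basal diameter > 1 cm.
    """
    cfg = cfg or MatchConfig()
    h = height_above_ground(cloud.points, plane)
    tree_height = float(h.max())
    slab = cloud.select((h >= 0.20) & (h <= 0.30))
    if len(slab) < 6:
        raise EvaluationError("too few points in the basal trunk slab")
    try:
        trunk = ransac_cylinder(slab, dist_thresh=0.005, n_iter=5000, seed=seed,
                                axis_prior=np.array([0.0, 0.0, 1.0]),
                                max_axis_dev=np.deg2rad(10.0))
    except FitFailureError as exc:
        raise EvaluationError(f"basal trunk fit failed: {exc}") from exc
    # branch ring around the full-height trunk axis
    key = cloud.select((h >= cfg.key_region[0]) & (h <= cfg.key_region[1]))
    full_trunk = ransac_cylinder(key, dist_thresh=0.005, n_iter=5000,
                                 seed=seed + 1,
                                 axis_prior=np.array([0.0, 0.0, 1.0]),
                                 max_axis_dev=np.deg2rad(10.0))
    # widen the height band so every primary branch is counted, not just the
    # matcher's middle-lower window
    wide_cfg = MatchConfig(
        tol_r=cfg.tol_r, tol_theta=cfg.tol_theta, tol_h=cfg.tol_h,
        ring_min=cfg.ring_min, ring_max=cfg.ring_max,
        min_inlier_ratio=cfg.min_inlier_ratio,
        key_region=(0.1, tree_height),
        cluster_tolerance=cfg.cluster_tolerance,
        cluster_min_size=max(10, cfg.cluster_min_size // 3),
        cluster_max_size=cfg.cluster_max_size,
        branch_dist_thresh=cfg.branch_dist_thresh,
        ransac_iters=cfg.ransac_iters)
    band = cloud.select((h >= wide_cfg.key_region[0]) & (h <= tree_height))
    ring = segment_branch_ring(band, full_trunk, wide_cfg)
    segments = filter_candidates(ring, full_trunk, plane, wide_cfg, seed=seed + 2)
    diameters = np.array([2.0 * s.r for s in segments])
    # allometric sanity: a first-order branch is thinner than its parent
    # trunk; anything larger is a degenerate grazing-cylinder fit
    counted = diameters[(diameters > min_branch_diameter)
                        & (diameters <= 2.0 * trunk.radius)]
    return StructuralParams(
        tree_height=100.0 * tree_height,
        basal_trunk_diameter=100.0 * 2.0 * trunk.radius,
        n_primary_branches=int(len(counted)),
        max_branch_diameter=100.0 * float(counted.max()) if len(counted) else 0.0,
        avg_branch_diameter=100.0 * float(counted.mean()) if len(counted) else 0.0)
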