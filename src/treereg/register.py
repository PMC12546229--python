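"""Coarse and fine rigid registration of two opposed tree scans.

Coarse stage (closed form, 4-DoF): the matched branch axes are projected
onto the horizontal plane; their intersection O and signed angle alpha give
a rotation T1 about the vertical line through O. Translation T2 then comes
from the basal trunk: a cylinder is fitted to the 0.20-0.30 m trunk slab of
each scan and the axis points at 0.25 m height are brought into coincidence.
Tc = T2 . T1.

Fine stage: point-to-point ICP restricted to branch points only (ground and
trunk are excluded -- their simple, highly overlapping geometry dominates
the error metric and drags the pose into over-registration), trimming the
farthest 10% of correspondences each iteration. T = Tf . Tc.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .errors import (CoarseFailureError, DegenerateProjectionError,
                     FineFailureError, FitFailureError, ParallelLinesError)
from .matching import MatchResult
from .preprocess import GroundPlane, height_above_ground
from .primitives import Cylinder, Line2D, line_intersection_2d, project_axis_xoy, \
    ransac_cylinder
from .transform import RigidTransform

log = logging.getLogger(__name__)

TRUNK_BAND = (0.20, 0.30)   # basal trunk slab (m above ground) for translation
TRUNK_REF_HEIGHT = 0.25     # height of the trunk-center reference point G


@dataclass
class IcpConfig:
    """Trimmed-ICP settings (overlap ratio 90% per the method)."""

    overlap_ratio: float = 0.90
    max_iter: int = 50
    rel_rms_tol: float = 1e-5
    max_corr_dist: float = 0.040  # 5 x default voxel size

    def __post_init__(self) -> None:
        if not 0.0 < self.overlap_ratio <= 1.0:
            raise ValueError("overlap_ratio must be in (0, 1]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class CoarseAlignment:
    """Closed-form coarse result: Tc = T2 . T1."""

    O: np.ndarray
    alpha: float
    T1: RigidTransform
    G_src: np.ndarray
    G_tgt: np.ndarray
    T2: RigidTransform
    Tc: RigidTransform
    parallel_fallback: bool = False


def apply_transform(cloud: PointCloud, T: RigidTransform) -> PointCloud:
    """Map every point through T; labels/branch ids ride along, normals rotate."""
    out = cloud.with_points(T.apply(cloud.points))
    if out.normals is not None:
        out = PointCloud(out.points, labels=out.labels, branch_id=out.branch_id,
                         normals=out.normals @ T.rotation.T)
    return out


def transform_plane(plane: GroundPlane, T: RigidTransform) -> GroundPlane:
    """Ground plane expressed in the transformed frame."""
    n = T.rotation @ plane.normal
    offset = plane.offset - float(n @ T.translation)
    return GroundPlane(normal=n, offset=offset, inlier_count=plane.inlier_count)


def _canonical_branch_line(branch: Cylinder, trunk: Cylinder) -> Line2D:
    """XOY projection of a branch axis oriented to point away from the trunk.

    The raw fitted direction is sign-ambiguous; orienting it outward (positive
    dot with the radial vector from the trunk axis) makes the rotation angle
    between two scans' projections single-valued.
    """
    v = branch.axis_point - trunk.axis_point
    radial = v - (v @ trunk.axis_dir) * trunk.axis_dir
    d = branch.axis_dir if float(branch.axis_dir @ radial) >= 0 else -branch.axis_dir
    oriented = Cylinder(axis_point=branch.axis_point, axis_dir=d,
                        radius=branch.radius)
    return project_axis_xoy(oriented)


def rotation_from_branches(src_cyl: Cylinder, tgt_cyl: Cylinder,
                           src_trunk: Cylinder, tgt_trunk: Cylinder,
                           ) -> tuple[np.ndarray, float, RigidTransform, bool]:
    """Rotation center O, angle alpha, and T1 = Rz(alpha) about the line through O.

    Falls back to rotating about the source trunk's XOY footprint when the
    projected axes are (near-)parallel (alpha ~ 0 or ~ pi). Returns
    (O, alpha, T1, used_parallel_fallback).
    """
    try:
        src_line = _canonical_branch_line(src_cyl, src_trunk)
        tgt_line = _canonical_branch_line(tgt_cyl, tgt_trunk)
    except DegenerateProjectionError as exc:
        raise CoarseFailureError(f"branch axis projects to a point: {exc}") from exc
    try:
        O, alpha = line_intersection_2d(src_line, tgt_line)
        fallback = False
    except ParallelLinesError:
        O = np.asarray(src_trunk.axis_point[:2], dtype=np.float64)
        cross = src_line.dir[0] * tgt_line.dir[1] - src_line.dir[1] * tgt_line.dir[0]
        dot = float(src_line.dir @ tgt_line.dir)
        alpha = 0.0 if dot > 0 and abs(cross) < 1e-12 else float(np.arctan2(cross, dot))
        fallback = True
        log.info("rotation_from_branches: parallel axes; rotating about trunk "
                 "footprint, alpha=%.4f rad", alpha)
    return O, alpha, RigidTransform.rot_z(alpha, center=O), fallback


def _trunk_center(cloud: PointCloud, plane: GroundPlane, seed: int,
                  dist_thresh: float = 0.005, n_iter: int = 5000,
                  max_axis_dev: float = np.deg2rad(10.0)) -> np.ndarray:
    """Fitted basal-trunk axis point at the reference height above ground."""
    h = height_above_ground(cloud.points, plane)
    slab = cloud.select((h >= TRUNK_BAND[0]) & (h <= TRUNK_BAND[1]))
    if len(slab) < 6:
        raise CoarseFailureError(
            f"basal trunk slab has only {len(slab)} points; cannot localize trunk")
    try:
        cyl = ransac_cylinder(slab, dist_thresh=dist_thresh, n_iter=n_iter,
                              seed=seed, axis_prior=np.array([0.0, 0.0, 1.0]),
                              max_axis_dev=max_axis_dev)
    except FitFailureError as exc:
        raise CoarseFailureError(f"basal trunk fit failed: {exc}") from exc
    denom = float(plane.normal @ cyl.axis_dir)
    if abs(denom) < 1e-6:
        raise CoarseFailureError("trunk axis parallel to the ground plane")
    t = (TRUNK_REF_HEIGHT - float(plane.normal @ cyl.axis_point + plane.offset)) / denom
    return cyl.axis_point + t * cyl.axis_dir


def translation_from_trunks(src_cloud: PointCloud, tgt_cloud: PointCloud,
                            src_plane: GroundPlane, tgt_plane: GroundPlane,
                            after_T1: RigidTransform, seed: int = 0,
                            ) -> tuple[np.ndarray, np.ndarray, RigidTransform]:
    """(G_src, G_tgt, T2): pure translation aligning the basal trunk centers.

    The source cloud (and its ground plane) are first mapped through T1 so
    that T2 composes as Tc = T2 . T1.
    """
    src_rot = apply_transform(src_cloud, after_T1)
    src_plane_rot = transform_plane(src_plane, after_T1)
    G_src = _trunk_center(src_rot, src_plane_rot, seed=seed)
    G_tgt = _trunk_center(tgt_cloud, tgt_plane, seed=seed + 1)
    T2 = RigidTransform.translation_only(G_tgt - G_src)
    return G_src, G_tgt, T2


def coarse_register(src_cloud: PointCloud, tgt_cloud: PointCloud,
                    match: MatchResult, src_trunk: Cylinder, tgt_trunk: Cylinder,
                    src_plane: GroundPlane, tgt_plane: GroundPlane,
                    seed: int = 0) -> CoarseAlignment:
    """Full coarse stage from a successful branch match."""
    if not match.success:
        raise CoarseFailureError("coarse registration requires a branch match")
    O, alpha, T1, fallback = rotation_from_branches(
        match.best.src.cylinder, match.best.tgt.cylinder, src_trunk, tgt_trunk)
    G_src, G_tgt, T2 = translation_from_trunks(
        src_cloud, tgt_cloud, src_plane, tgt_plane, after_T1=T1, seed=seed)
    return CoarseAlignment(O=O, alpha=alpha, T1=T1, G_src=G_src, G_tgt=G_tgt,
                           T2=T2, Tc=T2 @ T1, parallel_fallback=fallback)


# ------------------------------------------------------------------ fine stage

def extract_branch_only(cloud: PointCloud, trunk: Cylinder, plane: GroundPlane,
                        margin: float = 0.015) -> PointCloud:
    """Strip trunk (axis distance < radius + margin) and any residual ground."""
    d = trunk.distance_to_axis(cloud.points)
    h = height_above_ground(cloud.points, plane)
    keep = (d >= trunk.radius + margin) & (h > 0.02)
    out = cloud.select(keep)
    if len(out) == 0:
        raise FineFailureError("no branch points remain after trunk/ground removal")
    return out


def _rigid_solve(src: np.ndarray, tgt: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform (Kabsch / SVD, reflection-corrected)."""
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - cs).T @ (tgt - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform.from_rt(R, ct - R @ cs)


def trimmed_icp(src: PointCloud, tgt: PointCloud, cfg: IcpConfig | None = None,
                ) -> tuple[RigidTransform, float, int, list[float]]:
    """Point-to-point ICP keeping the closest ``overlap_ratio`` correspondences.

    Each iteration: exact nearest neighbors (KD-tree), keep the closest
    ceil(overlap_ratio * N) pairs, drop pairs beyond ``max_corr_dist``, solve
    the SVD rigid transform on the kept set, accumulate. Stops when the
    relative change of the trimmed RMS falls below ``rel_rms_tol``.

    Returns (Tf, final_trimmed_rms, n_iterations, rms_history).
    """
    cfg = cfg or IcpConfig()
    if len(src) == 0 or len(tgt) == 0:
        raise FineFailureError("ICP requires non-empty clouds")
    tree = cKDTree(tgt.points)
    pts = src.points.copy()
    T = RigidTransform.identity()
    n_keep = int(np.ceil(cfg.overlap_ratio * len(pts)))
    rms_history: list[float] = []
    prev_rms = np.inf
    n_used = 0
    for it in range(cfg.max_iter):
        d, idx = tree.query(pts)
        order = np.argsort(d, kind="stable")[:n_keep]
        if cfg.max_corr_dist is not None:
            order = order[d[order] <= cfg.max_corr_dist]
        if len(order) < 3:
            raise FineFailureError(
                f"only {len(order)} correspondences within range; ICP cannot proceed")
        rms = float(np.sqrt(np.mean(d[order] ** 2)))
        rms_history.append(rms)
        step = _rigid_solve(pts[order], tgt.points[idx[order]])
        pts = step.apply(pts)
        T = step @ T
        n_used = it + 1
        if rms < 1e-12:  # exact alignment; nothing left to refine
            break
        if np.isfinite(prev_rms) and abs(prev_rms - rms) < cfg.rel_rms_tol * rms:
            break
        prev_rms = rms
    return T, rms_history[-1], n_used, rms_history


def fine_register(src_cloud: PointCloud, tgt_cloud: PointCloud,
                  coarse: CoarseAlignment, src_trunk: Cylinder,
                  tgt_trunk: Cylinder, src_plane: GroundPlane,
                  tgt_plane: GroundPlane, cfg: IcpConfig | None = None,
                  trunk_margin: float = 0.015,
                  ) -> tuple[RigidTransform, RigidTransform, float, int]:
    """Branch-only trimmed ICP on top of the coarse pose.

    Returns (T, Tf, final_rms, n_iter) with T = Tf . Tc.
    """
    src_branches = extract_branch_only(src_cloud, src_trunk, src_plane,
                                       margin=trunk_margin)
    tgt_branches = extract_branch_only(tgt_cloud, tgt_trunk, tgt_plane,
                                       margin=trunk_margin)
    src_pre = apply_transform(src_branches, coarse.Tc)
    Tf, rms, n_iter, _ = trimmed_icp(src_pre, tgt_branches, cfg)
    return Tf @ coarse.Tc, Tf, rms, n_iter
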