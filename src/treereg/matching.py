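"""Branch-segment extraction and matching across two opposed scans.

The matcher never looks for point-level overlap. Instead it extracts short
branch segments from an annular "key ring" around the trunk (0.07-0.14 m from
the trunk axis, where primary branches are most cylindrical and wind-stable),
characterizes each segment by three features --

* ``r``      radius of the RANSAC-fitted branch cylinder (m),
* ``theta``  angle between branch and trunk axes (rad, folded to [0, pi/2]),
* ``h``      height of the segment centroid above the fitted ground plane (m),

-- gates all source x target pairings by per-feature tolerances, and fuses
the surviving residuals with a dynamic negative-log weighting: with
normalized residuals x_i = d_i / tol_i,

    w_i   = -ln(x_i) / sum_j(-ln(x_j)),
    score = sum_i w_i * x_i,

so the most consistent features dominate the similarity assessment. Lower
scores mean better matches. The final pair is chosen among the one-to-one
assigned candidates by the highest cylinder-inlier support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cloud import PointCloud
from .errors import ContractViolationError, EmptyRegionError, FitFailureError
from .preprocess import GroundPlane, height_above_ground
from .primitives import Cluster, Cylinder, euclidean_cluster, ransac_cylinder

log = logging.getLogger(__name__)

_EPS = 1e-6  # clamp for normalized residuals; -ln is undefined at 0 and 1


@dataclass
class MatchConfig:
    """Tolerances and geometry of the branch matcher (defaults from the method).

    Attributes
    ----------
    tol_r, tol_theta, tol_h
        Feature gates: 5 mm radius, 15 deg axis angle, 50 mm height.
    ring_min, ring_max
        Radial band around the trunk axis holding the key branch segments.
    min_inlier_ratio
        Cylinder-quality gate on candidate clusters (30%).
    key_region
        Height band (m above ground) of the middle-lower crown searched.
    """

    tol_r: float = 0.005
    tol_theta: float = np.deg2rad(15.0)
    tol_h: float = 0.050
    ring_min: float = 0.07
    ring_max: float = 0.14
    min_inlier_ratio: float = 0.30
    key_region: tuple[float, float] = (0.2, 1.6)
    cluster_tolerance: float = 0.012
    cluster_min_size: int = 30
    cluster_max_size: int = 2000
    branch_dist_thresh: float = 0.004
    ransac_iters: int = 5000

    def __post_init__(self) -> None:
        if not (self.tol_r > 0 and self.tol_theta > 0 and self.tol_h > 0):
            raise ValueError("all tolerances must be positive")
        if not self.ring_min < self.ring_max:
            raise ValueError("ring_min must be below ring_max")
        if not self.key_region[0] < self.key_region[1]:
            raise ValueError("key_region must be a non-empty (h_lo, h_hi) band")


@dataclass
class BranchSegment:
    """A candidate branch cluster with its fitted cylinder and features."""

    cluster: Cluster
    cylinder: Cylinder
    r: float
    theta: float
    h: float
    inlier_count: int
    gt_branch_id: int | None = None

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("branch radius must be positive")
        if not 0.0 <= self.theta <= np.pi / 2 + 1e-12:
            raise ValueError("theta must lie in [0, pi/2]")


@dataclass
class CandidatePair:
    """A scored source-target pairing."""

    src: BranchSegment
    tgt: BranchSegment
    d_r: float
    d_theta: float
    d_h: float
    w_r: float = 0.0
    w_theta: float = 0.0
    w_h: float = 0.0
    score: float = np.inf
    src_idx: int = -1
    tgt_idx: int = -1

    @property
    def combined_inliers(self) -> int:
        return self.src.inlier_count + self.tgt.inlier_count


@dataclass
class MatchResult:
    """Outcome of branch matching; ``success`` is False when nothing survives."""

    best: CandidatePair | None
    retained: list[CandidatePair] = field(default_factory=list)

    @property
    def success(self) -> bool:
        return self.best is not None


# ------------------------------------------------------------------ extraction

def extract_key_region(cloud: PointCloud, plane: GroundPlane,
                       cfg: MatchConfig) -> PointCloud:
    """Height-band selection of the tree's middle-lower section."""
    h = height_above_ground(cloud.points, plane)
    lo, hi = cfg.key_region
    keep = (h >= lo) & (h <= hi)
    if not np.any(keep):
        raise EmptyRegionError(
            f"no points in key height band [{lo}, {hi}] m; cannot match")
    return cloud.select(keep)


def segment_branch_ring(key_cloud: PointCloud, trunk: Cylinder,
                        cfg: MatchConfig) -> PointCloud:
    """Keep points whose distance to the trunk axis lies in [ring_min, ring_max]."""
    d = trunk.distance_to_axis(key_cloud.points)
    return key_cloud.select((d >= cfg.ring_min) & (d <= cfg.ring_max))


def branch_features(points: np.ndarray, cylinder: Cylinder, trunk: Cylinder,
                    plane: GroundPlane) -> tuple[float, float, float]:
    """(r, theta, h) of a branch segment.

    theta folds the two axis orientations with ``arccos |b . t|`` so that a
    branch parallel to the trunk scores 0 regardless of direction sign; h is
    the height of the member-point centroid above the ground plane.
    """
    r = float(cylinder.radius)
    cos_t = np.clip(abs(float(cylinder.axis_dir @ trunk.axis_dir)), 0.0, 1.0)
    theta = float(np.arccos(cos_t))
    h = float(height_above_ground(points.mean(axis=0), plane))
    return r, theta, h


def filter_candidates(ring_cloud: PointCloud, trunk: Cylinder,
                      plane: GroundPlane, cfg: MatchConfig,
                      seed: int = 0) -> list[BranchSegment]:
    """Cluster the ring, fit cylinders, keep well-supported candidates.

    Clusters outside the size gate are dropped by the clustering itself;
    clusters whose cylinder inlier ratio falls below ``min_inlier_ratio``
    (or whose fit fails outright) are discarded.
    """
    clusters = euclidean_cluster(ring_cloud, tolerance=cfg.cluster_tolerance,
                                 min_size=cfg.cluster_min_size,
                                 max_size=cfg.cluster_max_size)
    segments: list[BranchSegment] = []
    for ci, cl in enumerate(clusters):
        sub = ring_cloud.select(cl.indices)
        try:
            cyl = ransac_cylinder(sub, dist_thresh=cfg.branch_dist_thresh,
                                  n_iter=cfg.ransac_iters, seed=seed + ci)
        except FitFailureError:
            continue
        if cyl.inlier_ratio < cfg.min_inlier_ratio:
            continue
        r, theta, h = branch_features(sub.points, cyl, trunk, plane)
        gt = None
        if sub.branch_id is not None:
            ids, counts = np.unique(sub.branch_id[sub.branch_id >= 0],
                                    return_counts=True)
            if len(ids):
                gt = int(ids[np.argmax(counts)])
        segments.append(BranchSegment(cluster=cl, cylinder=cyl, r=r,
                                      theta=theta, h=h,
                                      inlier_count=cyl.inlier_count,
                                      gt_branch_id=gt))
    return segments


# ------------------------------------------------------------------ scoring

def threshold_gate(d_r: float, d_theta: float, d_h: float,
                   cfg: MatchConfig) -> bool:
    """All three residuals strictly below their tolerances."""
    if min(d_r, d_theta, d_h) < 0:
        raise ContractViolationError("residuals must be non-negative")
    return d_r < cfg.tol_r and d_theta < cfg.tol_theta and d_h < cfg.tol_h


def pair_score(d_r: float, d_theta: float, d_h: float,
               cfg: MatchConfig) -> tuple[float, float, float, float]:
    """Dynamically weighted fused residual (score, w_r, w_theta, w_h).

    Normalized residuals are clamped to [1e-6, 1 - 1e-6]; when all three are
    equal the weights take their analytic limit of 1/3 each, so the score
    equals the common normalized residual exactly.
    """
    x = np.array([d_r / cfg.tol_r, d_theta / cfg.tol_theta, d_h / cfg.tol_h])
    if np.any(x >= 1.0):
        raise ContractViolationError(
            "pair_score called on a pair that fails the threshold gate")
    x = np.clip(x, _EPS, 1.0 - _EPS)
    if np.all(x == x[0]):
        w = np.full(3, 1.0 / 3.0)
    else:
        neg_log = -np.log(x)
        w = neg_log / neg_log.sum()
    score = float(w @ x)
    return score, float(w[0]), float(w[1]), float(w[2])


def match_branches(S: list[BranchSegment], T: list[BranchSegment],
                   cfg: MatchConfig) -> MatchResult:
    """Score all m x n pairings, assign one-to-one, pick the best-supported pair.

    Pipeline: (1) gate + score every pairing; (2) greedy one-to-one
    assignment in ascending score order, so each source and each target
    branch is used at most once; (3) among accepted pairs the final match is
    the one with the highest combined cylinder-inlier count (ties broken by
    lower score) -- fit support as a global confidence measure.
    """
    scored: list[CandidatePair] = []
    for si, s in enumerate(S):
        for ti, t in enumerate(T):
            d_r = abs(s.r - t.r)
            d_theta = abs(s.theta - t.theta)
            d_h = abs(s.h - t.h)
            if not threshold_gate(d_r, d_theta, d_h, cfg):
                continue
            score, w_r, w_t, w_h = pair_score(d_r, d_theta, d_h, cfg)
            scored.append(CandidatePair(src=s, tgt=t, d_r=d_r, d_theta=d_theta,
                                        d_h=d_h, w_r=w_r, w_theta=w_t, w_h=w_h,
                                        score=score, src_idx=si, tgt_idx=ti))
    scored.sort(key=lambda p: (p.score, p.src_idx, p.tgt_idx))
    used_s: set[int] = set()
    used_t: set[int] = set()
    accepted: list[CandidatePair] = []
    for p in scored:
        if p.src_idx in used_s or p.tgt_idx in used_t:
            continue
        accepted.append(p)
        used_s.add(p.src_idx)
        used_t.add(p.tgt_idx)
    if not accepted:
        log.info("match_branches: no pair survived gating (%d x %d candidates)",
                 len(S), len(T))
        return MatchResult(best=None, retained=[])
    best = min(accepted, key=lambda p: (-p.combined_inliers, p.score))
    return MatchResult(best=best, retained=accepted)


def score_table_rows(result: MatchResult) -> list[dict]:
    """Flatten retained pairs to dict rows for the debug CSV dump."""
    rows = []
    for p in result.retained:
        rows.append({"src_id": p.src_idx, "tgt_id": p.tgt_idx,
                     "d_r": p.d_r, "d_theta": p.d_theta, "d_h": p.d_h,
                     "w_r": p.w_r, "w_theta": p.w_theta, "w_h": p.w_h,
                     "score": p.score,
                     "combined_inliers": p.combined_inliers,
                     "best": p is result.best})
    return rows
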