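"""Geometric kernel: seeded RANSAC cylinder fitting, Euclidean clustering,
axis projection onto the horizontal plane, and 2D line intersection.

Cylinder hypotheses are generated from two points with PCA surface normals
(the axis is the cross product of the normals; the axis point is the
intersection of the normal lines in the plane orthogonal to the axis), then
polished by nonlinear least squares on the inlier set. All angles are
radians; signed 2D angles are counter-clockwise positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import least_squares
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .errors import (DegenerateInputError, DegenerateProjectionError,
                     FitFailureError, ParallelLinesError)


@dataclass
class Cylinder:
    """RANSAC-fitted cylinder: axis (point + unit direction), radius, inliers."""

    axis_point: np.ndarray
    axis_dir: np.ndarray
    radius: float
    inlier_idx: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    inlier_ratio: float = 0.0

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, dtype=np.float64).reshape(3)
        d = np.asarray(self.axis_dir, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(d)
        if not np.isclose(norm, 1.0, atol=1e-9):
            d = d / norm
        self.axis_dir = d
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")

    def distance_to_axis(self, points: np.ndarray) -> np.ndarray:
        """Perpendicular distance from each point to the (infinite) axis line."""
        v = np.atleast_2d(points) - self.axis_point
        along = v @ self.axis_dir
        return np.linalg.norm(v - np.outer(along, self.axis_dir), axis=1)

    @property
    def inlier_count(self) -> int:
        return int(len(self.inlier_idx))


@dataclass(frozen=True)
class Cluster:
    """A connected component of the tolerance graph (indices into the cloud)."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64).reshape(-1)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("cluster indices must be unique")
        object.__setattr__(self, "indices", np.sort(idx))

    @property
    def size(self) -> int:
        return int(len(self.indices))


@dataclass(frozen=True)
class Line2D:
    """2D line through ``point`` with unit direction ``dir``."""

    point: np.ndarray
    dir: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=np.float64).reshape(2)
        d = np.asarray(self.dir, dtype=np.float64).reshape(2)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("line direction must be non-null")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "dir", d / norm)


# ------------------------------------------------------------------ normals

def estimate_normals(points: np.ndarray, k: int = 10) -> np.ndarray:
    """Unit surface normals from k-NN PCA (smallest-eigenvalue direction).

    Normal orientation is arbitrary; cylinder hypothesis generation is
    insensitive to the sign.
    """
    n = len(points)
    k = min(k, n - 1)
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k + 1)
    nbrs = points[idx]                               # (N, k+1, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]                          # smallest eigenvalue
    norms = np.linalg.norm(normals, axis=1)
    norms[norms == 0] = 1.0
    return normals / norms[:, None]


# ------------------------------------------------------------------ cylinder

def _orthobasis(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``w`` (unit) to a right-handed basis."""
    a = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(w, a)
    u /= np.linalg.norm(u)
    return u, np.cross(w, u)


def _canonical_dir(d: np.ndarray, ref: np.ndarray) -> np.ndarray:
    dot = d @ ref
    if abs(dot) < 1e-12:  # perpendicular to the reference: fix sign lexically
        for comp in d:
            if abs(comp) > 1e-12:
                return d if comp > 0 else -d
        return d
    return d if dot > 0 else -d


def _refine_cylinder(points: np.ndarray, axis_point: np.ndarray,
                     axis_dir: np.ndarray, radius: float) -> Cylinder:
    """Nonlinear least squares on |radial distance - r| over the given points."""
    w0 = axis_dir / np.linalg.norm(axis_dir)
    u0, v0 = _orthobasis(w0)
    centroid = points.mean(axis=0)
    c0 = axis_point + ((centroid - axis_point) @ w0) * w0  # axis foot of centroid

    def unpack(p):
        a, b, px, py, r = p
        w = w0 + a * u0 + b * v0
        w = w / np.linalg.norm(w)
        c = c0 + px * u0 + py * v0
        return c, w, r

    def residuals(p):
        c, w, r = unpack(p)
        v = points - c
        d = np.linalg.norm(v - np.outer(v @ w, w), axis=1)
        return d - r

    sol = least_squares(residuals, x0=np.array([0.0, 0.0, 0.0, 0.0, radius]),
                        method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                        max_nfev=200)
    c, w, r = unpack(sol.x)
    if r <= 0:
        r = abs(r) if r != 0 else radius
        if r <= 0:
            raise FitFailureError("cylinder refinement collapsed to zero radius")
    return Cylinder(axis_point=c, axis_dir=w, radius=float(r))


def ransac_cylinder(cloud: PointCloud, dist_thresh: float, n_iter: int = 5000,
                    seed: int = 0, axis_prior: np.ndarray | None = None,
                    max_axis_dev: float | None = None) -> Cylinder:
    """Seeded RANSAC cylinder fit with optional axis-direction constraint.

    Inliers are points with ``| distance-to-axis - radius | <= dist_thresh``.
    When ``axis_prior`` is given, hypotheses whose axis deviates from it by
    more than ``max_axis_dev`` radians are rejected; the returned direction
    has positive dot product with the prior (or +z without one).
    """
    pts = cloud.points
    n = len(pts)
    if n < 6:
        raise DegenerateInputError(f"cylinder fit needs >= 6 points, got {n}")
    rng = np.random.default_rng(seed)
    normals = estimate_normals(pts, k=10)

    i = rng.integers(0, n, size=n_iter)
    j = rng.integers(0, n, size=n_iter)
    ok = i != j
    n1, n2 = normals[i], normals[j]
    w = np.cross(n1, n2)
    wn = np.linalg.norm(w, axis=1)
    ok &= wn > 1e-6
    if axis_prior is not None:
        prior = np.asarray(axis_prior, dtype=np.float64)
        prior = prior / np.linalg.norm(prior)
        cos_dev = np.abs(np.einsum("ij,j->i", w, prior)) / np.where(wn > 0, wn, 1.0)
        ok &= cos_dev >= np.cos(max_axis_dev if max_axis_dev is not None else np.pi)
        if not np.any(ok):
            raise FitFailureError("no cylinder hypothesis satisfied the axis constraint")
    elif not np.any(ok):
        raise FitFailureError("no valid cylinder hypothesis (degenerate normals)")

    i, j, w = i[ok], j[ok], w[ok] / wn[ok, None]
    p1, p2 = pts[i], pts[j]
    n1, n2 = normals[i], normals[j]
    # intersect the two normal lines in the plane orthogonal to the axis
    u = np.cross(w, np.where(np.abs(w[:, [0]]) < 0.9,
                             [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]]))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(w, u)
    def proj2(x):  # coordinates in the (u, v) plane
        return np.stack([np.einsum("ij,ij->i", x, u),
                         np.einsum("ij,ij->i", x, v)], axis=1)
    q1, q2 = proj2(p1), proj2(p2)
    m1, m2 = proj2(n1), proj2(n2)
    det = m1[:, 0] * (-m2[:, 1]) - (-m2[:, 0]) * m1[:, 1]
    solvable = np.abs(det) > 1e-9
    i, j, w, u, v = i[solvable], j[solvable], w[solvable], u[solvable], v[solvable]
    q1, q2, m1, m2, det = q1[solvable], q2[solvable], m1[solvable], m2[solvable], det[solvable]
    if len(w) == 0:
        raise FitFailureError("no solvable cylinder hypothesis")
    rhs = q2 - q1
    t = (rhs[:, 0] * (-m2[:, 1]) - (-m2[:, 0]) * rhs[:, 1]) / det
    c2d = q1 + t[:, None] * m1
    r_cand = 0.5 * (np.linalg.norm(q1 - c2d, axis=1) + np.linalg.norm(q2 - c2d, axis=1))
    center = c2d[:, [0]] * u + c2d[:, [1]] * v  # 3D axis point (plane origin = 0)
    plausible = (r_cand > 1e-4) & (r_cand < 10.0)
    w, u, v, center, r_cand = w[plausible], u[plausible], v[plausible], \
        center[plausible], r_cand[plausible]
    if len(w) == 0:
        raise FitFailureError("no plausible cylinder hypothesis")

    # score hypotheses on a subsample, chunked over candidates
    score_pts = pts
    if n > 4000:
        score_pts = pts[rng.choice(n, 4000, replace=False)]
    best_i, best_count = 0, -1
    for lo in range(0, len(w), 128):
        wc, cc, rc = w[lo:lo + 128], center[lo:lo + 128], r_cand[lo:lo + 128]
        d = score_pts[None, :, :] - cc[:, None, :]          # (C, M, 3)
        along = np.einsum("cmi,ci->cm", d, wc)
        radial = np.linalg.norm(d - along[:, :, None] * wc[:, None, :], axis=2)
        counts = (np.abs(radial - rc[:, None]) <= dist_thresh).sum(axis=1)
        k = int(np.argmax(counts))
        if counts[k] > best_count:
            best_count, best_i = int(counts[k]), lo + k
    cand = Cylinder(axis_point=center[best_i], axis_dir=w[best_i],
                    radius=float(r_cand[best_i]))
    inliers = np.abs(cand.distance_to_axis(pts) - cand.radius) <= dist_thresh
    if inliers.sum() < 6:
        raise FitFailureError("best cylinder hypothesis has fewer than 6 inliers")
    refined = _refine_cylinder(pts[inliers], cand.axis_point, cand.axis_dir, cand.radius)
    ref = (np.asarray(axis_prior, dtype=np.float64) if axis_prior is not None
           else np.array([0.0, 0.0, 1.0]))
    refined.axis_dir = _canonical_dir(refined.axis_dir, ref / np.linalg.norm(ref))
    if axis_prior is not None and max_axis_dev is not None:
        cos_dev = abs(refined.axis_dir @ ref / np.linalg.norm(ref))
        if cos_dev < np.cos(max_axis_dev):
            raise FitFailureError("refined cylinder violates the axis constraint")
    inlier_idx = np.flatnonzero(
        np.abs(refined.distance_to_axis(pts) - refined.radius) <= dist_thresh)
    refined.inlier_idx = inlier_idx
    refined.inlier_ratio = float(len(inlier_idx) / n)
    return refined


# ------------------------------------------------------------------ clustering

def euclidean_cluster(cloud: PointCloud, tolerance: float = 0.012,
                      min_size: int = 30, max_size: int = 2000) -> list[Cluster]:
    """Connected components of the <=tolerance adjacency graph.

    Components outside [min_size, max_size] are discarded (the size gate that
    removes curved/compound segments and thin fragments); survivors are
    returned in descending size order (ties by smallest member index).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    n = len(cloud)
    if n == 0:
        return []
    tree = cKDTree(cloud.points)
    pairs = tree.query_pairs(tolerance, output_type="ndarray")
    if len(pairs):
        adj = sparse.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        n_comp, comp = connected_components(adj, directed=False)
    else:
        n_comp, comp = n, np.arange(n)
    clusters = []
    for c in range(n_comp):
        idx = np.flatnonzero(comp == c)
        if min_size <= len(idx) <= max_size:
            clusters.append(Cluster(idx))
    clusters.sort(key=lambda cl: (-cl.size, int(cl.indices[0])))
    return clusters


# ------------------------------------------------------------------ 2D geometry

def project_axis_xoy(cyl: Cylinder) -> Line2D:
    """Project a cylinder axis onto the horizontal (XOY) plane."""
    dxy = cyl.axis_dir[:2]
    if np.linalg.norm(dxy) < 1e-6:
        raise DegenerateProjectionError("axis is vertical; XOY projection is null")
    return Line2D(point=cyl.axis_point[:2], dir=dxy)


def line_intersection_2d(a: Line2D, b: Line2D) -> tuple[np.ndarray, float]:
    """Intersection point and signed CCW angle rotating ``a.dir`` onto ``b.dir``.

    Raises :class:`ParallelLinesError` when |sin(angle)| < 1e-3; the caller
    is expected to fall back to a rotation about the trunk footprint.
    """
    cross = a.dir[0] * b.dir[1] - a.dir[1] * b.dir[0]
    dot = float(a.dir @ b.dir)
    if abs(cross) < 1e-3:
        raise ParallelLinesError("projected axes are (near-)parallel")
    # a.point + t a.dir = b.point + s b.dir
    rhs = b.point - a.point
    t = (rhs[0] * b.dir[1] - rhs[1] * b.dir[0]) / cross
    O = a.point + t * a.dir
    alpha = float(np.arctan2(cross, dot))
    return O, alpha
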