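"""Scan preprocessing: ground-plane RANSAC, ground removal, statistical
outlier removal and voxel-grid downsampling.

The fitted ground plane is the height datum for every later stage; the cloud
is never re-leveled, because leveled TLS scans share the vertical axis and
the coarse model exploits exactly that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .errors import DegenerateInputError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroundPlane:
    """Plane {x : normal . x + offset = 0}; normal is unit and points up."""

    normal: np.ndarray
    offset: float
    inlier_count: int

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(n)
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError("plane normal must be unit length")
        if n[2] <= 0:
            raise ValueError("plane normal must point up (positive z)")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "offset", float(self.offset))


def _lsq_plane(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares plane through a point set (SVD of centered coords)."""
    centroid = points.mean(axis=0)
    _, s, vt = np.linalg.svd(points - centroid, full_matrices=False)
    if s[0] <= 0 or s[1] / s[0] < 1e-12:
        raise DegenerateInputError("points are collinear; plane is not unique")
    normal = vt[-1]
    if normal[2] < 0:
        normal = -normal
    if normal[2] == 0:  # vertical plane cannot be a ground plane
        raise DegenerateInputError("degenerate (vertical) ground plane")
    return normal, float(-normal @ centroid)


def fit_ground_plane(cloud: PointCloud, dist_thresh: float = 0.010,
                     n_iter: int = 1000, seed: int = 0,
                     max_tilt: float = np.deg2rad(20.0)) -> GroundPlane:
    """Seeded RANSAC plane fit refined by least squares on the inlier set.

    Candidate planes tilted more than ``max_tilt`` from horizontal are
    rejected: the scanner is leveled, so the ground must be near-horizontal,
    and without the constraint the fit can lock onto the nearly planar
    visible shell of a large trunk.

    Parameters
    ----------
    dist_thresh : float
        Inlier distance to the candidate plane, meters (default 10 mm).
    n_iter : int
        Number of 3-point hypotheses.
    seed : int
        RNG seed; the fit is bit-reproducible for a fixed seed.
    max_tilt : float
        Maximum plane tilt from horizontal, radians.
    """
    pts = cloud.points
    n = len(pts)
    if n < 3:
        raise DegenerateInputError(f"plane fit needs >= 3 points, got {n}")
    rng = np.random.default_rng(seed)
    # hypothesis triples are drawn from the lowest 30% of the cloud: under a
    # leveled scanner the ground is the bottom-most structure, and trees with
    # sparse ground coverage would otherwise starve the sampler
    z_cut = np.quantile(pts[:, 2], 0.3)
    pool = np.flatnonzero(pts[:, 2] <= z_cut)
    if len(pool) < 3:
        pool = np.arange(n)
    # vectorized hypothesis generation: all sample triples at once
    idx = pool[rng.integers(0, len(pool), size=(n_iter, 3))]
    p0, p1, p2 = pts[idx[:, 0]], pts[idx[:, 1]], pts[idx[:, 2]]
    normals = np.cross(p1 - p0, p2 - p0)
    norms = np.linalg.norm(normals, axis=1)
    ok = norms > 1e-12
    ok &= np.abs(normals[:, 2]) >= np.cos(max_tilt) * norms
    if not np.any(ok):
        raise DegenerateInputError(
            "no near-horizontal plane hypothesis (all triples collinear or tilted)")
    normals = normals[ok] / norms[ok, None]
    offsets = -np.einsum("ij,ij->i", normals, p0[ok])
    # score in chunks to bound memory at n_candidates x chunk
    score_pts = pts
    if n > 20000:
        score_pts = pts[rng.choice(n, 20000, replace=False)]
    best_i, best_count = 0, -1
    for lo in range(0, len(normals), 256):
        d = np.abs(score_pts @ normals[lo:lo + 256].T + offsets[lo:lo + 256])
        counts = (d <= dist_thresh).sum(axis=0)
        i = int(np.argmax(counts))
        if counts[i] > best_count:
            best_count, best_i = int(counts[i]), lo + i
    normal, offset = normals[best_i], offsets[best_i]
    # refine on the full-cloud inlier set
    inliers = np.abs(pts @ normal + offset) <= dist_thresh
    if inliers.sum() < 3:
        raise DegenerateInputError("RANSAC plane found fewer than 3 inliers")
    normal, offset = _lsq_plane(pts[inliers])
    inliers = np.abs(pts @ normal + offset) <= dist_thresh
    return GroundPlane(normal=normal, offset=offset, inlier_count=int(inliers.sum()))


def height_above_ground(point: np.ndarray, plane: GroundPlane) -> float | np.ndarray:
    """Signed distance normal . x + offset (positive above ground)."""
    pts = np.asarray(point, dtype=np.float64)
    if pts.ndim == 1:
        return float(plane.normal @ pts + plane.offset)
    return pts @ plane.normal + plane.offset


def remove_ground(cloud: PointCloud, plane: GroundPlane,
                  band: float = 0.020) -> PointCloud:
    """Drop points with height above the plane <= ``band`` (default 20 mm)."""
    h = height_above_ground(cloud.points, plane)
    keep = h > band
    log.debug("remove_ground: removed %d of %d points", int((~keep).sum()), len(cloud))
    return cloud.select(keep)


def statistical_outlier_removal(cloud: PointCloud, k: int = 5,
                                std_mult: float = 0.1) -> PointCloud:
    """Classic SOR filter: keep points whose mean k-NN distance <= mu + m*sigma.

    mu and sigma are the mean and standard deviation of the per-point mean
    neighbor distances over the whole cloud (one-sided upper cut).
    """
    n = len(cloud)
    if n <= k:
        raise DegenerateInputError(f"SOR needs more than k={k} points, got {n}")
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    mu, sigma = mean_d.mean(), mean_d.std()
    keep = mean_d <= mu + std_mult * sigma
    log.debug("SOR: removed %d of %d points", int((~keep).sum()), n)
    return cloud.select(keep)


def voxel_downsample(cloud: PointCloud, voxel: float = 0.008) -> PointCloud:
    """One centroid per occupied axis-aligned voxel.

    Voxel index of point x is floor((x - origin)/voxel) per axis, origin
    being the per-axis minimum of the cloud.
    """
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    if len(cloud) == 0:
        return cloud.copy()
    origin = cloud.points.min(axis=0)
    ijk = np.floor((cloud.points - origin) / voxel).astype(np.int64)
    # lexicographic voxel key -> group by first occurrence to keep determinism
    _, first, inverse = np.unique(ijk, axis=0, return_index=True, return_inverse=True)
    n_vox = len(first)
    sums = np.zeros((n_vox, 3))
    np.add.at(sums, inverse, cloud.points)
    counts = np.bincount(inverse, minlength=n_vox).astype(np.float64)
    centroids = sums / counts[:, None]
    # order voxels by first-seen input index so output order is stable
    order = np.argsort(first, kind="stable")
    out = PointCloud(centroids[order])
    if cloud.labels is not None or cloud.branch_id is not None:
        # majority-free shortcut: take the attribute of the first point in each voxel
        rep = first[order]
        if cloud.labels is not None:
            out.labels = cloud.labels[rep]
        if cloud.branch_id is not None:
            out.branch_id = cloud.branch_id[rep]
    return out


def preprocess(cloud: PointCloud, dist_thresh: float = 0.010, band: float = 0.020,
               sor_k: int = 5, sor_std_mult: float = 0.1, voxel: float = 0.008,
               n_iter: int = 1000, seed: int = 0,
               max_tilt: float = np.deg2rad(20.0)) -> tuple[PointCloud, GroundPlane]:
    """Full cleaning chain: plane fit -> ground removal -> SOR -> voxel grid."""
    plane = fit_ground_plane(cloud, dist_thresh=dist_thresh, n_iter=n_iter,
                             seed=seed, max_tilt=max_tilt)
    above = remove_ground(cloud, plane, band=band)
    if len(above) > sor_k:
        above = statistical_outlier_removal(above, k=sor_k, std_mult=sor_std_mult)
    return voxel_downsample(above, voxel=voxel), plane
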