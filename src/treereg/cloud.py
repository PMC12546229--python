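"""In-memory point-cloud container shared by every stage of the pipeline.

Coordinates are always meters in a right-handed frame with +z up (the scanner
is assumed leveled, so z is the shared vertical across scans). Optional
per-point semantic labels and branch identities are carried by synthetic
clouds and used only for evaluation, never by the registration itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class Label(IntEnum):
    """Semantic point categories."""

    GROUND = 0
    TRUNK = 1
    BRANCH = 2
    OTHER = 3


@dataclass
class PointCloud:
    """N points with optional per-point labels, branch ids and normals.

    Parameters
    ----------
    points : (N, 3) float array
        Coordinates in meters.
    labels : (N,) int array, optional
        Per-point :class:`Label` codes.
    branch_id : (N,) int array, optional
        Ground-truth branch identity (synthetic data only); -1 where absent.
    normals : (N, 3) float array, optional
        Analytic outward surface normals (synthetic data only).
    """

    points: np.ndarray
    labels: np.ndarray | None = None
    branch_id: np.ndarray | None = None
    normals: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite coordinates")
        self.points = pts
        n = len(pts)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int32).reshape(-1)
            if len(self.labels) != n:
                raise ValueError("labels length must equal point count")
        if self.branch_id is not None:
            self.branch_id = np.asarray(self.branch_id, dtype=np.int32).reshape(-1)
            if len(self.branch_id) != n:
                raise ValueError("branch_id length must equal point count")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64).reshape(n, 3)

    def __len__(self) -> int:
        return len(self.points)

    def select(self, index: np.ndarray) -> "PointCloud":
        """Subset by boolean mask or integer index, carrying all attributes."""
        return PointCloud(
            points=self.points[index],
            labels=None if self.labels is None else self.labels[index],
            branch_id=None if self.branch_id is None else self.branch_id[index],
            normals=None if self.normals is None else self.normals[index],
        )

    def with_points(self, points: np.ndarray) -> "PointCloud":
        """Same attributes, new coordinates (e.g. after a rigid transform)."""
        return PointCloud(
            points=points,
            labels=self.labels,
            branch_id=self.branch_id,
            normals=self.normals,
        )

    def copy(self) -> "PointCloud":
        return PointCloud(
            points=self.points.copy(),
            labels=None if self.labels is None else self.labels.copy(),
            branch_id=None if self.branch_id is None else self.branch_id.copy(),
            normals=None if self.normals is None else self.normals.copy(),
        )


def concatenate(clouds: list[PointCloud]) -> PointCloud:
    """Stack clouds; optional attributes survive only if present on all parts."""
    if not clouds:
        return PointCloud(np.zeros((0, 3)))
    pts = np.vstack([c.points for c in clouds])
    labels = None
    if all(c.labels is not None for c in clouds):
        labels = np.concatenate([c.labels for c in clouds])
    bid = None
    if all(c.branch_id is not None for c in clouds):
        bid = np.concatenate([c.branch_id for c in clouds])
    normals = None
    if all(c.normals is not None for c in clouds):
        normals = np.vstack([c.normals for c in clouds])
    return PointCloud(pts, labels=labels, branch_id=bid, normals=normals)
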