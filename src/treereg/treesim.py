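"""Procedural tall-spindle tree clouds and two-station TLS scan simulation.

The generator emulates a dormant tall-spindle apple tree: a near-vertical
tapered trunk (defaults: 3.3 m tall, 6.2 cm basal diameter), 8-18 straight
tapered primary branches (basal diameters 1.4-3.3 cm) inserted between 0.3
and 2.8 m at 50-90 deg from the trunk axis, a flat ground disc, ~2 mm
surface sampling and 2 mm Gaussian sensor noise. Every point carries a
semantic label, a branch id and an analytic outward normal.

Two opposed stations are simulated by a visibility operator (default:
front-face culling against the analytic normals; optionally spherical-flip
hidden-point removal), and the source scan is expressed in its own frame via
the inverse of a sampled 4-DoF ground-truth transform, so that T_gt maps
source to target exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import ConvexHull

from .cloud import Label, PointCloud, concatenate
from .errors import SimulationError, TreeSpecError
from .io import write_cloud
from .register import apply_transform
from .transform import RigidTransform


@dataclass(frozen=True)
class TreeSpec:
    """Parameters of one synthetic tree (all lengths in meters)."""

    height: float = 3.3
    basal_trunk_diameter: float = 0.062
    trunk_taper: float = 0.20            # fraction of basal radius lost per m
    trunk_lean_deg: float = 0.8          # trunk axis tilt from vertical
    n_branches: int = 11
    branch_diameter_range: tuple[float, float] = (0.014, 0.033)
    branch_insertion_height_range: tuple[float, float] = (0.3, 2.8)
    branch_insertion_angle_range: tuple[float, float] = (50.0, 90.0)  # deg
    branch_length_range: tuple[float, float] = (0.3, 0.7)
    branch_taper: float = 0.4            # fractional radius loss base -> tip
    azimuth_jitter_deg: float = 20.0     # jitter around the phyllotactic spiral
    surface_sampling: float = 0.002
    noise_sigma: float = 0.002
    ground_extent: float = 1.0           # ground disc radius
    ground_sampling: float = 0.012
    seed: int = 0

    def validate(self) -> None:
        for name in ("height", "basal_trunk_diameter", "surface_sampling",
                     "ground_extent", "ground_sampling"):
            if getattr(self, name) <= 0:
                raise TreeSpecError(f"{name} must be positive")
        if self.n_branches < 0:
            raise TreeSpecError("n_branches must be >= 0")
        if self.noise_sigma < 0:
            raise TreeSpecError("noise_sigma must be >= 0")
        if self.trunk_taper * self.height >= 1.0:
            raise TreeSpecError("trunk tapers to zero radius below the tree top")
        if self.branch_taper >= 1.0:
            raise TreeSpecError("branch_taper must be < 1")
        for rng_name in ("branch_diameter_range", "branch_insertion_height_range",
                         "branch_insertion_angle_range", "branch_length_range"):
            lo, hi = getattr(self, rng_name)
            if not 0 < lo <= hi:
                raise TreeSpecError(f"{rng_name} must be well-ordered and positive")
        lo, hi = self.branch_insertion_height_range
        if hi > self.height:
            raise TreeSpecError("branches cannot be inserted above the tree top")
        if self.branch_insertion_angle_range[1] > 90.0 + 1e-9:
            raise TreeSpecError("insertion angles beyond 90 deg point below "
                                "horizontal and may reach underground")

    def trunk_radius_at(self, h: float | np.ndarray) -> float | np.ndarray:
        """Analytic trunk radius at height h (linear taper)."""
        return 0.5 * self.basal_trunk_diameter * (1.0 - self.trunk_taper * h)


@dataclass
class ScanPair:
    """Two simulated station scans with their ground-truth relation."""

    source: PointCloud
    target: PointCloud
    T_gt: RigidTransform
    correspondence: dict[int, int]
    spec: TreeSpec
    stations: dict = field(default_factory=dict)


def _orthobasis(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(w, a)
    u /= np.linalg.norm(u)
    return u, np.cross(w, u)


def _sample_frustum(base: np.ndarray, direction: np.ndarray, length: float,
                    r_base: float, r_tip: float, spacing: float,
                    rng: np.random.Generator,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Surface-sample a tapered cylinder (frustum); returns (points, normals).

    Rings are placed every ``spacing`` along the axis; each ring carries
    ceil(2 pi r / spacing) points at a random phase, giving ~isotropic
    ~``spacing`` coverage. Normals are the exact outward radial directions.
    """
    w = direction / np.linalg.norm(direction)
    u, v = _orthobasis(w)
    s = np.arange(0.0, length + 0.5 * spacing, spacing)
    s = np.clip(s, 0.0, length)
    radii = r_base + (r_tip - r_base) * (s / length)
    counts = np.maximum(3, np.ceil(2.0 * np.pi * radii / spacing)).astype(int)
    ring_idx = np.repeat(np.arange(len(s)), counts)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    within = np.arange(counts.sum()) - np.repeat(starts, counts)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=len(s))
    ang = 2.0 * np.pi * within / np.repeat(counts, counts) + phase[ring_idx]
    radial = np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v
    pts = (base + np.outer(s[ring_idx], w)
           + radii[ring_idx, None] * radial)
    return pts, radial


def generate_tree(spec: TreeSpec) -> PointCloud:
    """Labeled, branch-id'd, normal-carrying point cloud in the tree frame.

    The tree frame has the trunk base at the origin and +z up; ground is the
    z = 0 plane. Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    parts: list[PointCloud] = []

    # trunk: tapered frustum along a near-vertical axis
    lean = np.deg2rad(spec.trunk_lean_deg)
    lean_az = rng.uniform(0.0, 2.0 * np.pi)
    trunk_dir = np.array([np.sin(lean) * np.cos(lean_az),
                          np.sin(lean) * np.sin(lean_az),
                          np.cos(lean)])
    trunk_len = spec.height / trunk_dir[2]
    r0 = 0.5 * spec.basal_trunk_diameter
    r_top = spec.trunk_radius_at(spec.height)
    t_pts, t_nrm = _sample_frustum(np.zeros(3), trunk_dir, trunk_len,
                                   r0, r_top, spec.surface_sampling, rng)
    parts.append(PointCloud(t_pts,
                            labels=np.full(len(t_pts), Label.TRUNK, dtype=np.int32),
                            branch_id=np.full(len(t_pts), -1, dtype=np.int32),
                            normals=t_nrm))

    # branches: straight tapered frusta off the trunk surface
    golden = np.deg2rad(137.5)
    lo_h, hi_h = spec.branch_insertion_height_range
    lo_d, hi_d = spec.branch_diameter_range
    lo_a, hi_a = spec.branch_insertion_angle_range
    lo_l, hi_l = spec.branch_length_range
    u_t, v_t = _orthobasis(trunk_dir)
    for k in range(spec.n_branches):
        h_ins = rng.uniform(lo_h, min(hi_h, spec.height))
        az = k * golden + np.deg2rad(spec.azimuth_jitter_deg) * rng.normal()
        r_b = 0.5 * rng.uniform(lo_d, hi_d)
        psi = np.deg2rad(rng.uniform(lo_a, hi_a))   # angle from trunk axis
        length = rng.uniform(lo_l, hi_l)
        axis_pt = trunk_dir * (h_ins / trunk_dir[2])
        radial = np.cos(az) * u_t + np.sin(az) * v_t
        b_dir = np.cos(psi) * trunk_dir + np.sin(psi) * radial
        base = axis_pt + spec.trunk_radius_at(h_ins) * radial
        if base[2] + min(0.0, b_dir[2]) * length < 0:
            raise TreeSpecError(f"branch {k} would reach below ground")
        b_pts, b_nrm = _sample_frustum(base, b_dir, length, r_b,
                                       (1.0 - spec.branch_taper) * r_b,
                                       spec.surface_sampling, rng)
        parts.append(PointCloud(
            b_pts,
            labels=np.full(len(b_pts), Label.BRANCH, dtype=np.int32),
            branch_id=np.full(len(b_pts), k, dtype=np.int32),
            normals=b_nrm))

    # ground disc on z = 0
    n_grid = int(np.ceil(2.0 * spec.ground_extent / spec.ground_sampling)) + 1
    g = np.linspace(-spec.ground_extent, spec.ground_extent, n_grid)
    gx, gy = np.meshgrid(g, g)
    mask = gx ** 2 + gy ** 2 <= spec.ground_extent ** 2
    g_pts = np.column_stack([gx[mask], gy[mask], np.zeros(mask.sum())])
    g_nrm = np.tile([0.0, 0.0, 1.0], (len(g_pts), 1))
    parts.append(PointCloud(g_pts,
                            labels=np.full(len(g_pts), Label.GROUND, dtype=np.int32),
                            branch_id=np.full(len(g_pts), -1, dtype=np.int32),
                            normals=g_nrm))

    tree = concatenate(parts)
    if spec.noise_sigma > 0:
        noisy = tree.points + rng.normal(0.0, spec.noise_sigma, tree.points.shape)
        tree = PointCloud(noisy, labels=tree.labels, branch_id=tree.branch_id,
                          normals=tree.normals)
    return tree


# ------------------------------------------------------------------ visibility

def _frontface_visible(cloud: PointCloud, station: np.ndarray) -> np.ndarray:
    if cloud.normals is None:
        raise SimulationError("front-face culling needs analytic normals")
    view = station - cloud.points
    return np.einsum("ij,ij->i", cloud.normals, view) > 0.0


def hidden_point_removal(points: np.ndarray, station: np.ndarray,
                         radius_factor: float = 100.0) -> np.ndarray:
    """Spherical-flip hidden-point removal; returns a boolean visibility mask."""
    rel = points - station
    norms = np.linalg.norm(rel, axis=1)
    R = radius_factor * norms.max()
    flipped = rel + 2.0 * (R - norms)[:, None] * rel / norms[:, None]
    hull = ConvexHull(np.vstack([flipped, np.zeros(3)]))
    mask = np.zeros(len(points), dtype=bool)
    mask[hull.vertices[hull.vertices < len(points)]] = True
    return mask


def simulate_two_stations(tree: PointCloud, distance: float = 2.3,
                          azimuths_deg: tuple[float, float] = (0.0, 180.0),
                          occlusion: str = "frontface",
                          scanner_height: float = 1.4,
                          pose_jitter_deg: float = 0.0,
                          seed: int = 0,
                          spec: TreeSpec | None = None) -> ScanPair:
    """Simulate two opposed stations and a sampled ground-truth transform.

    The target scan keeps the tree frame; the source scan is mapped through
    the inverse of T_gt (4-DoF by default: yaw uniform on (-pi, pi],
    horizontal translation uniform on +-2 m, vertical on +-0.2 m;
    ``pose_jitter_deg`` adds small roll/pitch for robustness studies).
    """
    rng = np.random.default_rng(seed)
    scans = []
    stations = []
    for az_deg in azimuths_deg:
        az = np.deg2rad(az_deg)
        station = np.array([distance * np.cos(az), distance * np.sin(az),
                            scanner_height])
        stations.append(station)
        if occlusion == "frontface":
            mask = _frontface_visible(tree, station)
        elif occlusion == "hpr":
            mask = hidden_point_removal(tree.points, station)
        else:
            raise ValueError(f"unknown occlusion model {occlusion!r}")
        if not np.any(mask):
            raise SimulationError(f"station at {az_deg} deg sees no points")
        scans.append(tree.select(mask))
    src_vis, target = scans[0], scans[1]

    yaw = rng.uniform(-np.pi, np.pi)
    t = np.array([rng.uniform(-2.0, 2.0), rng.uniform(-2.0, 2.0),
                  rng.uniform(-0.2, 0.2)])
    R = RigidTransform.rot_z(yaw).rotation
    if pose_jitter_deg > 0:
        rx, ry = np.deg2rad(rng.uniform(-pose_jitter_deg, pose_jitter_deg, 2))
        Rx = np.array([[1, 0, 0], [0, np.cos(rx), -np.sin(rx)],
                       [0, np.sin(rx), np.cos(rx)]])
        Ry = np.array([[np.cos(ry), 0, np.sin(ry)], [0, 1, 0],
                       [-np.sin(ry), 0, np.cos(ry)]])
        R = R @ Rx @ Ry
    T_gt = RigidTransform.from_rt(R, t)
    source = apply_transform(src_vis, T_gt.inverse())

    ids = set()
    for scan in (src_vis, target):
        if scan.branch_id is not None:
            ids.update(int(i) for i in np.unique(scan.branch_id) if i >= 0)
    return ScanPair(source=source, target=target, T_gt=T_gt,
                    correspondence={i: i for i in sorted(ids)},
                    spec=spec if spec is not None else TreeSpec(seed=seed),
                    stations={"distance": distance, "azimuths_deg": list(azimuths_deg),
                              "scanner_height": scanner_height,
                              "positions": [s.tolist() for s in stations]})


def sample_spec(seed: int, index: int = 0, base: TreeSpec | None = None) -> TreeSpec:
    """Draw one tree spec from the documented study ranges.

    Branch counts are stratified over 8..18 by index (so a suite of >= 11
    pairs spans the whole range); the remaining parameters are sampled
    uniformly from the orchard statistics the generator emulates.
    """
    base = base or TreeSpec()
    rng = np.random.default_rng(seed)
    height = float(rng.uniform(2.5, 3.7))
    lo_h = base.branch_insertion_height_range[0]
    hi_h = min(base.branch_insertion_height_range[1], height - 0.4)
    return replace(
        base,
        height=height,
        basal_trunk_diameter=float(rng.uniform(0.05, 0.08)),
        branch_insertion_height_range=(lo_h, hi_h),
        n_branches=8 + (index % 11),
        seed=seed)


def make_fixture_suite(n: int, base_spec: TreeSpec | None = None, seed: int = 0,
                       out_dir: str | None = None,
                       pair_kwargs: dict | None = None) -> list[ScanPair]:
    """n seeded ScanPairs (seeds = seed .. seed + n - 1), optionally serialized.

    When ``out_dir`` is given, each pair is written as
    ``pair_<i>/source.ply``, ``pair_<i>/target.ply`` and
    ``pair_<i>/gt_transform.json`` with a top-level ``manifest.json``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pairs: list[ScanPair] = []
    manifest = []
    for i in range(n):
        pair_seed = seed + i
        spec = sample_spec(pair_seed, index=i, base=base_spec)
        tree = generate_tree(spec)
        pair = simulate_two_stations(tree, seed=pair_seed + 100003, spec=spec,
                                     **(pair_kwargs or {}))
        pairs.append(pair)
        if out_dir is not None:
            pdir = os.path.join(out_dir, f"pair_{i:03d}")
            os.makedirs(pdir, exist_ok=True)
            write_cloud(pair.source, os.path.join(pdir, "source.ply"))
            write_cloud(pair.target, os.path.join(pdir, "target.ply"))
            pair.T_gt.save_json(os.path.join(pdir, "gt_transform.json"))
            manifest.append({"pair": f"pair_{i:03d}", "seed": pair_seed,
                             "n_branches": spec.n_branches,
                             "T_gt": pair.T_gt.to_json_dict()["matrix"]})
    if out_dir is not None:
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump({"n": n, "seed": seed, "pairs": manifest}, fh, indent=2)
            fh.write("\n")
    return pairs
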