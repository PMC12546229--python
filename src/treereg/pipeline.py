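"""End-to-end registration driver: preprocess -> trunk fits -> branch match
-> coarse alignment -> branch-only trimmed ICP.

All randomness (plane RANSAC, cylinder RANSAC per stage) is fanned out
deterministically from one top-level seed, so the whole pipeline is
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cloud import PointCloud
from .config import PipelineConfig, seed_sequence
from .errors import FitFailureError, MatchFailureError
from .matching import (BranchSegment, MatchResult, extract_key_region,
                       filter_candidates, match_branches, segment_branch_ring)
from .preprocess import GroundPlane, preprocess
from .primitives import Cylinder, ransac_cylinder
from .register import CoarseAlignment, IcpConfig, coarse_register, fine_register
from .transform import RigidTransform

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything a caller may want to inspect after a run."""

    T: RigidTransform
    Tc: RigidTransform
    Tf: RigidTransform
    coarse: CoarseAlignment
    match: MatchResult
    src_segments: list[BranchSegment]
    tgt_segments: list[BranchSegment]
    src_plane: GroundPlane
    tgt_plane: GroundPlane
    src_trunk: Cylinder
    tgt_trunk: Cylinder
    src_pre: PointCloud
    tgt_pre: PointCloud
    icp_rms: float = np.nan
    icp_iters: int = 0
    stage_log: dict = field(default_factory=dict)


def _prepare_side(cloud: PointCloud, cfg: PipelineConfig, seeds: list[int],
                  ) -> tuple[PointCloud, GroundPlane, Cylinder,
                             list[BranchSegment]]:
    """Preprocess one scan, fit its key-region trunk, extract branch segments."""
    pp = cfg.preprocess
    clean, plane = preprocess(cloud, dist_thresh=pp.ground_dist_thresh,
                              band=pp.ground_band, sor_k=pp.sor_k,
                              sor_std_mult=pp.sor_std_mult, voxel=pp.voxel,
                              n_iter=pp.ground_iters, seed=seeds[0],
                              max_tilt=pp.ground_max_tilt)
    key = extract_key_region(clean, plane, cfg.match)
    try:
        trunk = ransac_cylinder(key, dist_thresh=cfg.trunk.dist_thresh,
                                n_iter=cfg.trunk.n_iter, seed=seeds[1],
                                axis_prior=np.array([0.0, 0.0, 1.0]),
                                max_axis_dev=cfg.trunk.max_axis_dev)
    except FitFailureError as exc:
        raise MatchFailureError(f"key-region trunk fit failed: {exc}") from exc
    ring = segment_branch_ring(key, trunk, cfg.match)
    segments = filter_candidates(ring, trunk, plane, cfg.match, seed=seeds[2])
    return clean, plane, trunk, segments


def register_pair(source: PointCloud, target: PointCloud,
                  cfg: PipelineConfig | None = None,
                  seed: int | None = None) -> PipelineResult:
    """Register a source scan onto a target scan.

    Raises :class:`MatchFailureError` when no branch pair survives gating
    (the method's documented failure mode), and Coarse/FineFailureError for
    downstream geometric failures.
    """
    cfg = cfg or PipelineConfig()
    seeds = seed_sequence(cfg.seed if seed is None else seed, n=8)
    src_pre, src_plane, src_trunk, S = _prepare_side(source, cfg, seeds[0:3])
    tgt_pre, tgt_plane, tgt_trunk, T_segs = _prepare_side(target, cfg, seeds[3:6])
    log.info("candidates: %d source, %d target branch segments",
             len(S), len(T_segs))
    match = match_branches(S, T_segs, cfg.match)
    if not match.success:
        raise MatchFailureError(
            f"no branch pair survived gating ({len(S)} x {len(T_segs)} candidates)")
    coarse = coarse_register(src_pre, tgt_pre, match, src_trunk, tgt_trunk,
                             src_plane, tgt_plane, seed=seeds[6])
    icp_cfg = cfg.icp if isinstance(cfg.icp, IcpConfig) else IcpConfig(**cfg.icp)
    T, Tf, rms, iters = fine_register(src_pre, tgt_pre, coarse, src_trunk,
                                      tgt_trunk, src_plane, tgt_plane,
                                      cfg=icp_cfg, trunk_margin=cfg.trunk_margin)
    return PipelineResult(
        T=T, Tc=coarse.Tc, Tf=Tf, coarse=coarse, match=match,
        src_segments=S, tgt_segments=T_segs,
        src_plane=src_plane, tgt_plane=tgt_plane,
        src_trunk=src_trunk, tgt_trunk=tgt_trunk,
        src_pre=src_pre, tgt_pre=tgt_pre,
        icp_rms=rms, icp_iters=iters,
        stage_log={"n_src_segments": len(S), "n_tgt_segments": len(T_segs),
                   "alpha_rad": coarse.alpha,
                   "parallel_fallback": coarse.parallel_fallback,
                   "icp_rms": rms, "icp_iters": iters})
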