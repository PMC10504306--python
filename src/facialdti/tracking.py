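"""Deterministic FACT streamline tractography with FA / angle / length rules.

Fiber assignment by continuous tracking: the propagation direction at any
point is the principal eigenvector of the voxel containing the point
(nearest-voxel lookup, no interpolation), sign-aligned with the previous
step.  A track terminates when it would enter a voxel with FA below the
threshold (default 0.15), when the turn between successive steps exceeds
the angle threshold (default 60 degrees), when it leaves the grid, or at
the step cap.  Both half-tracks launched from a seed along +e1 and -e1 are
concatenated, and whole fibers shorter than the minimum length (default
2 mm) are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dtifit import EigenSystem

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrackingParams:
    fa_threshold: float = 0.15
    angle_threshold: float = 60.0  # degrees, between successive steps
    min_length: float = 2.0        # mm, whole-fiber length filter
    step_size: float = 0.2         # mm
    max_steps: int = 2000          # per half-track

    def __post_init__(self):
        if not (0 < self.fa_threshold < 1):
            raise ValueError("fa_threshold must be in (0, 1)")
        if not (0 < self.angle_threshold < 180):
            raise ValueError("angle_threshold must be in (0, 180) degrees")
        if self.min_length <= 0 or self.step_size <= 0 or self.max_steps < 1:
            raise ValueError("min_length, step_size, max_steps must be positive")


@dataclass
class Streamline:
    points: np.ndarray  # (n, 3) world mm, ordered
    side: str

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class SeedSet:
    """Sphere centers expanded to per-voxel-center seed points."""

    centers: np.ndarray       # (c, 3) world mm
    diameter: float           # mm
    center_sides: list        # side label per center
    points: np.ndarray        # (m, 3) world mm
    point_sides: np.ndarray   # (m,) side label per seed point


def world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    pts = np.atleast_2d(points)
    return pts @ inv[:3, :3].T + inv[:3, 3]


def containing_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Half-open ownership: voxel i owns continuous index in [i-0.5, i+0.5)."""
    return np.floor(world_to_voxel(points, affine) + 0.5).astype(int)


def _in_grid(idx: np.ndarray, grid_shape) -> np.ndarray:
    return np.all((idx >= 0) & (idx < np.asarray(grid_shape)), axis=-1)


def make_seeds(seed_centers, diameter: float, grid_shape, affine: np.ndarray,
               sides=None, density: int = 1, rng=None) -> SeedSet:
    """Seed points at every voxel center within ``diameter/2`` of a center.

    ``density > 1`` adds uniformly jittered copies inside each seed voxel
    (reproducible through ``rng``).
    """
    from .phantom import voxel_centers

    centers = np.atleast_2d(np.asarray(seed_centers, float))
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    sides = ["none"] * len(centers) if sides is None else list(sides)
    grid_shape = tuple(int(n) for n in grid_shape)
    vox = voxel_centers(grid_shape, affine)
    all_pts, all_sides = [], []
    for c, side in zip(centers, sides):
        sel = np.linalg.norm(vox - c, axis=1) <= diameter / 2.0
        if not sel.any():
            # a sphere that misses every voxel center is outside the grid
            raise ValueError(
                f"seed sphere at {np.round(c, 2)} (d={diameter} mm) contains "
                "no voxel center of the grid"
            )
        pts = vox[sel]
        if density > 1:
            if rng is None:
                rng = np.random.default_rng(0)
            scales = np.linalg.norm(affine[:3, :3], axis=0)
            extra = [pts + rng.uniform(-0.5, 0.5, pts.shape) * scales
                     for _ in range(density - 1)]
            pts = np.vstack([pts] + extra)
        all_pts.append(pts)
        all_sides.append(np.full(len(pts), side, dtype=object))
    return SeedSet(centers=centers, diameter=float(diameter), center_sides=sides,
                   points=np.vstack(all_pts), point_sides=np.concatenate(all_sides))


def _half_track(seed: np.ndarray, launch_dir: np.ndarray, eigs: EigenSystem,
                fa: np.ndarray, affine: np.ndarray,
                params: TrackingParams) -> list:
    """Points after the seed along one launch direction (may be empty)."""
    grid_shape = fa.shape
    cos_thr = np.cos(np.deg2rad(params.angle_threshold))
    pos = np.asarray(seed, float)
    prev = np.asarray(launch_dir, float)
    out = []
    for _ in range(params.max_steps):
        idx = containing_voxel(pos, affine)[0]
        d = eigs.eigenvectors[tuple(idx)][:, 0]
        if np.dot(d, prev) < 0:
            d = -d
        # first step from the seed is unconstrained (prev == launch dir == d0)
        if np.dot(d, prev) < cos_thr:
            break
        nxt = pos + params.step_size * d
        nidx = containing_voxel(nxt, affine)[0]
        if not _in_grid(nidx, grid_shape):
            break
        if fa[tuple(nidx)] < params.fa_threshold:
            break
        out.append(nxt)
        pos, prev = nxt, d
    return out


def track_streamline(seed_point, eigs: EigenSystem, fa: np.ndarray,
                     affine: np.ndarray, params: TrackingParams | None = None,
                     side: str = "none") -> Streamline | None:
    """Track one fiber from a seed; None if the seed voxel is below threshold."""
    params = params or TrackingParams()
    seed = np.asarray(seed_point, float)
    idx = containing_voxel(seed, affine)[0]
    if not _in_grid(idx, fa.shape):
        raise ValueError(f"seed {seed} lies outside the grid")
    if fa[tuple(idx)] < params.fa_threshold:
        return None
    e1 = eigs.eigenvectors[tuple(idx)][:, 0]
    fwd = _half_track(seed, e1, eigs, fa, affine, params)
    bwd = _half_track(seed, -e1, eigs, fa, affine, params)
    pts = np.vstack(bwd[::-1] + [seed] + fwd) if (fwd or bwd) else seed[None, :]
    if pts.shape[0] < 2:
        return None
    return Streamline(points=pts, side=side)


def _track_batch(seeds: np.ndarray, launch: np.ndarray, eigs: EigenSystem,
                 fa: np.ndarray, affine: np.ndarray, params: TrackingParams):
    """Vectorized half-track propagation for many seeds at once.

    Returns a list (one entry per seed) of lists of points after the seed.
    Semantics identical to ``_half_track``; equality is asserted in tests.
    """
    grid_shape = fa.shape
    cos_thr = np.cos(np.deg2rad(params.angle_threshold))
    n = len(seeds)
    pos = seeds.astype(float).copy()
    prev = launch.astype(float).copy()
    alive = np.ones(n, bool)
    tracks = [[] for _ in range(n)]
    inv = np.linalg.inv(affine)
    for _ in range(params.max_steps):
        if not alive.any():
            break
        ai = np.flatnonzero(alive)
        p = pos[ai]
        idx = np.floor(p @ inv[:3, :3].T + inv[:3, 3] + 0.5).astype(int)
        d = eigs.eigenvectors[idx[:, 0], idx[:, 1], idx[:, 2], :, 0]
        dots = np.einsum("ij,ij->i", d, prev[ai])
        d = np.where(dots[:, None] < 0, -d, d)
        dots = np.abs(dots)
        ok = dots >= cos_thr
        nxt = p + params.step_size * d
        nidx = np.floor(nxt @ inv[:3, :3].T + inv[:3, 3] + 0.5).astype(int)
        ing = np.all((nidx >= 0) & (nidx < np.asarray(grid_shape)), axis=-1)
        ok &= ing
        sub = np.zeros_like(ok)
        ci = np.clip(nidx, 0, np.asarray(grid_shape) - 1)
        sub[ing] = fa[ci[ing, 0], ci[ing, 1], ci[ing, 2]] >= params.fa_threshold
        ok &= sub
        for row, (k, keep) in enumerate(zip(ai, ok)):
            if keep:
                tracks[k].append(nxt[row])
        live_idx = ai[ok]
        pos[live_idx] = nxt[ok]
        prev[live_idx] = d[ok]
        alive[ai[~ok]] = False
    return tracks


def track_all(seeds: SeedSet, eigs: EigenSystem, fa: np.ndarray,
              affine: np.ndarray, params: TrackingParams | None = None) -> list:
    """Track every seed point; drop fibers shorter than ``min_length``."""
    params = params or TrackingParams()
    pts = seeds.points
    idx = containing_voxel(pts, affine)
    ok = _in_grid(idx, fa.shape)
    idx_c = np.clip(idx, 0, np.asarray(fa.shape) - 1)
    ok &= fa[idx_c[:, 0], idx_c[:, 1], idx_c[:, 2]] >= params.fa_threshold
    live = np.flatnonzero(ok)
    if live.size == 0:
        logger.warning("track_all: no seed points above the FA threshold")
        return []
    e1 = eigs.eigenvectors[idx[live, 0], idx[live, 1], idx[live, 2], :, 0]
    fwd = _track_batch(pts[live], e1, eigs, fa, affine, params)
    bwd = _track_batch(pts[live], -e1, eigs, fa, affine, params)
    streams = []
    counts: dict = {}
    for j, si in enumerate(live):
        pts_j = bwd[j][::-1] + [pts[si]] + fwd[j]
        if len(pts_j) < 2:
            continue
        s = Streamline(points=np.vstack(pts_j), side=str(seeds.point_sides[si]))
        if s.length < params.min_length:
            continue
        streams.append(s)
        counts[s.side] = counts.get(s.side, 0) + 1
    logger.info("track_all: retained %d streamlines (%s)", len(streams),
                ", ".join(f"{k}={v}" for k, v in sorted(counts.items())))
    return streams
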