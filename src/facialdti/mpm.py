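"""Streamline voxelization and majority-rule maximum probability maps.

Each subject's retained streamlines are rasterized into per-side binary
"visited" maps on the common grid; the group-level maximum probability map
(MPM) then assigns each voxel the side label voted for by a strict
majority (> n/2) of subjects, with background as the default when no label
reaches a majority (including exact ties).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .tracking import Streamline, containing_voxel, _in_grid

logger = logging.getLogger(__name__)

BACKGROUND, LEFT, RIGHT = 0, 1, 2
LABEL_NAMES = {BACKGROUND: "background", LEFT: "left", RIGHT: "right"}
LABEL_CODES = {"left": LEFT, "right": RIGHT}


@dataclass
class SubjectLabelMap:
    """Per-side binary visited maps, one subject, common grid."""

    left: np.ndarray   # bool (x, y, z)
    right: np.ndarray  # bool (x, y, z)

    def __post_init__(self):
        if self.left.shape != self.right.shape:
            raise ValueError("left/right maps must share a grid")


@dataclass
class MaxProbabilityMap:
    labels: np.ndarray    # uint8, 0 background / 1 left / 2 right
    support: np.ndarray   # uint16, subjects voting for the winning label
    n_subjects: int


def voxelize_streamlines(streams: list, grid_shape, affine: np.ndarray) -> SubjectLabelMap:
    """Mark every voxel (half-open ownership) containing a streamline point."""
    grid_shape = tuple(int(n) for n in grid_shape)
    maps = {"left": np.zeros(grid_shape, bool), "right": np.zeros(grid_shape, bool)}
    if not streams:
        warnings.warn("empty streamline set: returning an all-zero label map",
                      stacklevel=2)
        return SubjectLabelMap(left=maps["left"], right=maps["right"])
    for s in streams:
        if s.side not in maps:
            raise ValueError(f"streamline side {s.side!r} is not left/right")
        idx = containing_voxel(s.points, affine)
        if not np.all(_in_grid(idx, grid_shape)):
            raise ValueError("streamline point outside the grid")
        maps[s.side][idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return SubjectLabelMap(left=maps["left"], right=maps["right"])


def build_mpm(maps: list) -> MaxProbabilityMap:
    """Fuse subject label maps by strict per-voxel majority.

    A label wins a voxel iff more than half the subjects voted for it; when
    both sides clear that bar (a subject may vote for both at one voxel),
    the larger count wins and an exact tie falls back to background.
    """
    if not maps:
        raise ValueError("need at least one subject label map")
    shape = maps[0].left.shape
    for i, m in enumerate(maps):
        if m.left.shape != shape:
            raise ValueError(
                f"subject {i} grid {m.left.shape} differs from {shape}"
            )
    n = len(maps)
    votes_l = np.sum([m.left for m in maps], axis=0)
    votes_r = np.sum([m.right for m in maps], axis=0)
    half = n / 2.0
    maj_l = votes_l > half
    maj_r = votes_r > half
    labels = np.zeros(shape, np.uint8)
    labels[maj_l & ~maj_r] = LEFT
    labels[maj_r & ~maj_l] = RIGHT
    both = maj_l & maj_r
    labels[both & (votes_l > votes_r)] = LEFT
    labels[both & (votes_r > votes_l)] = RIGHT
    support = np.zeros(shape, np.uint16)
    support[labels == LEFT] = votes_l[labels == LEFT]
    support[labels == RIGHT] = votes_r[labels == RIGHT]
    return MaxProbabilityMap(labels=labels, support=support, n_subjects=n)


def named_mpms(healthy_maps: list, patient_maps: list) -> dict:
    """The three study MPMs: healthy-only, patient-only, and pooled."""
    if not healthy_maps or not patient_maps:
        raise ValueError("both cohorts must be non-empty")
    out = {
        "healthy": build_mpm(healthy_maps),
        "patient": build_mpm(patient_maps),
        "all": build_mpm(healthy_maps + patient_maps),
    }
    for name, m in out.items():
        logger.info("%s MPM: n=%d, %d left / %d right voxels", name,
                    m.n_subjects, int((m.labels == LEFT).sum()),
                    int((m.labels == RIGHT).sum()))
    return out
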