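"""Synthetic bilateral nerve-phantom cohorts with known diffusion ground truth.

Each phantom subject is a diffusion-weighted volume containing two thin,
curved, mirror-symmetric tubes standing in for the left and right
intratemporal facial nerves, embedded in an isotropic background.  Tube
voxels carry a cylindrically symmetric tensor (eigenvalues ``ad, rd, rd``
with the principal axis along the local tube tangent); the tensor field is
turned into diffusion-weighted signals with the monoexponential model
``S = s0 * exp(-b * g' D g)`` and Rician noise.

Patient cohorts receive a unilateral lesion expressed as a multiplicative
increase in radial diffusivity with axial diffusivity unchanged -- the
demyelination signature (myelin damage raises RD; axonal injury would raise
AD).  Healthy cohorts are bilaterally symmetric up to between-subject and
between-side biological variability.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

# Healthy-side diffusivities (mm^2/s) of the intratemporal facial nerve;
# the patient lesion multiplies RD by ~1.128 and leaves AD at 1.0.
DEFAULT_AD = 1.20e-3
DEFAULT_RD = 0.78e-3
DEFAULT_RD_EFFECT = 0.00088 / 0.00078  # ≈ 1.128
DEFAULT_GRID_SHAPE = (64, 64, 64)
DEFAULT_VOXEL_SIZE = 0.4  # mm, the common analysis grid
DEFAULT_TUBE_RADIUS = 1.0  # mm, nerve-caliber scale
#: Fraction of right-affected patients (13 of 19 in the modelled cohort).
RIGHT_AFFECTED_FRACTION = 13 / 19

MARGIN_VOXELS = 2       # clearance between the centerline and any grid face
MIN_TUBE_LENGTH = 10.0  # mm, minimum usable arc length


# ---------------------------------------------------------------------------
# acquisition scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-volume b-values (s/mm^2) and unit gradient directions."""

    bvalues: np.ndarray
    bvectors: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvalues, dtype=float)
        bvecs = np.asarray(self.bvectors, dtype=float)
        object.__setattr__(self, "bvalues", bvals)
        object.__setattr__(self, "bvectors", bvecs)
        if bvals.ndim != 1 or bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"scheme shape mismatch: {bvals.shape} b-values vs "
                f"{bvecs.shape} b-vectors (need (n,) and (n, 3))"
            )
        if np.any(bvals < 0):
            raise ValueError("negative b-value in scheme")
        dw = bvals > 0
        if np.count_nonzero(~dw) < 1 or np.count_nonzero(dw) < 6:
            raise ValueError(
                "scheme needs >= 1 b=0 volume and >= 6 diffusion-weighted "
                f"volumes; got {np.count_nonzero(~dw)} and {np.count_nonzero(dw)}"
            )
        norms = np.linalg.norm(bvecs, axis=1)
        if np.any(np.abs(norms[dw] - 1.0) > 1e-6):
            raise ValueError("b>0 gradient directions must be unit vectors")
        if np.any(norms[~dw] > 1e-12):
            raise ValueError("b=0 entries must have zero gradient vectors")

    @property
    def n_volumes(self) -> int:
        return self.bvalues.size


def electrostatic_directions(n: int, iterations: int = 2000) -> np.ndarray:
    return _electrostatic_directions_cached(int(n), int(iterations)).copy()


@functools.lru_cache(maxsize=8)
def _electrostatic_directions_cached(n: int, iterations: int) -> np.ndarray:
    """``n`` unit vectors spread over the half-sphere by antipodal repulsion.

    Deterministic: initialised from a Fibonacci hemisphere and relaxed by
    projected gradient descent on the sum of inverse pairwise distances
    (counting each point together with its antipode, as appropriate for
    axial diffusion-sensitising directions).
    """
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = (i + 0.5) / n  # upper hemisphere
    r = np.sqrt(1.0 - z**2)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    lr = 0.05
    for _ in range(iterations):
        diff = pts[:, None, :] - pts[None, :, :]
        ssum = pts[:, None, :] + pts[None, :, :]
        d1 = np.linalg.norm(diff, axis=-1)
        d2 = np.linalg.norm(ssum, axis=-1)
        np.fill_diagonal(d1, np.inf)
        np.fill_diagonal(d2, np.inf)
        force = (diff / d1[..., None] ** 3).sum(axis=1) + (
            ssum / d2[..., None] ** 3
        ).sum(axis=1)
        pts = pts + lr * force
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def default_scheme(n_directions: int = 20, bvalue: float = 1000.0) -> AcquisitionScheme:
    """One b=0 volume plus ``n_directions`` directions at ``bvalue`` s/mm^2."""
    dirs = electrostatic_directions(n_directions)
    bvals = np.concatenate([[0.0], np.full(n_directions, bvalue)])
    bvecs = np.vstack([np.zeros(3), dirs])
    return AcquisitionScheme(bvals, bvecs)


# ---------------------------------------------------------------------------
# geometry and tissue
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NerveGeometry:
    """A tube: ordered centerline control points (world mm) and a radius."""

    centerline: np.ndarray  # (n, 3) world mm
    tube_radius: float      # mm
    side: str               # "left" | "right"

    def __post_init__(self):
        pts = np.asarray(self.centerline, dtype=float)
        object.__setattr__(self, "centerline", pts)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
            raise ValueError("centerline must be (n>=2, 3) points")
        if np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) == 0):
            raise ValueError("consecutive centerline points must be distinct")
        if self.tube_radius <= 0:
            raise ValueError("tube_radius must be positive")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1).sum())


@dataclass(frozen=True)
class TissueModel:
    """Diffusivities (mm^2/s), base signal and Rician noise scale."""

    ad_true: float = DEFAULT_AD
    rd_true: float = DEFAULT_RD
    iso_background: float = 1.0e-3
    s0: float = 1000.0
    sigma: float = 1000.0 / 30.0  # SNR 30 on the b=0 signal

    def __post_init__(self):
        if not (self.ad_true >= self.rd_true > 0):
            raise ValueError("need ad_true >= rd_true > 0")
        if self.iso_background <= 0 or self.s0 <= 0 or self.sigma < 0:
            raise ValueError("iso_background, s0 must be > 0 and sigma >= 0")


def default_affine(voxel_size: float = DEFAULT_VOXEL_SIZE) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    return aff


def _grid_extent(grid_shape, affine) -> np.ndarray:
    """World-mm extent spanned by voxel centers along each axis."""
    scales = np.linalg.norm(affine[:3, :3], axis=0)
    return (np.asarray(grid_shape) - 1) * scales


def make_centerline(side: str, grid_shape, affine: np.ndarray,
                    n_points: int = 65) -> NerveGeometry:
    """A smooth arc inside the grid, mirror-symmetric between sides.

    The centerline runs along z with a sinusoidal bow in y at a fixed
    left/right offset in x; the left and right curves are exact mirror
    images across the grid's midsagittal (mid-x) plane.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    affine = np.asarray(affine, float)
    scales = np.linalg.norm(affine[:3, :3], axis=0)
    extent = _grid_extent(grid_shape, affine)
    margin = MARGIN_VOXELS * scales
    usable = extent - 2 * margin
    min_extent = MIN_TUBE_LENGTH + 2 * margin[2]
    if usable[2] < MIN_TUBE_LENGTH or np.any(usable <= 0):
        raise ValueError(
            f"grid too small for a {MIN_TUBE_LENGTH:.0f} mm tube with "
            f"{MARGIN_VOXELS}-voxel margins: extent {np.round(extent, 2)} mm, "
            f"need >= {min_extent:.1f} mm along z and positive usable extent "
            "on every axis"
        )
    origin = affine[:3, 3]
    mid_x = origin[0] + extent[0] / 2.0
    x_off = 0.22 * extent[0]
    x = mid_x - x_off if side == "left" else mid_x + x_off
    t = np.linspace(0.0, 1.0, n_points)
    z = origin[2] + margin[2] + usable[2] * t
    y_mid = origin[1] + extent[1] / 2.0
    amp = min(0.12 * extent[1], usable[1] / 2.0 - 1e-9)
    y = y_mid + amp * np.sin(np.pi * t)
    pts = np.column_stack([np.full(n_points, x), y, z])
    return NerveGeometry(pts, DEFAULT_TUBE_RADIUS, side)


def mirror_world_x(points: np.ndarray, grid_shape, affine: np.ndarray) -> np.ndarray:
    """Reflect world points across the grid's midsagittal plane."""
    extent = _grid_extent(grid_shape, affine)
    mid_x = affine[:3, 3][0] + extent[0] / 2.0
    out = np.array(points, dtype=float)
    out[..., 0] = 2.0 * mid_x - out[..., 0]
    return out


def _resample_polyline(points: np.ndarray, spacing: float):
    """Dense points + unit tangents along a polyline at ~``spacing`` mm."""
    seg = np.diff(points, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    n = max(int(np.ceil(s[-1] / spacing)) + 1, 2)
    si = np.linspace(0.0, s[-1], n)
    dense = np.column_stack([np.interp(si, s, points[:, k]) for k in range(3)])
    tang = np.gradient(dense, si, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return dense, tang


def voxel_centers(grid_shape, affine: np.ndarray) -> np.ndarray:
    idx = np.indices(grid_shape).reshape(3, -1).T.astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def build_tensor_field(geometry: NerveGeometry, tissue: TissueModel,
                       grid_shape, affine: np.ndarray):
    """Per-voxel tensors (mm^2/s) and the binary tube mask for one side.

    Tube voxels (center within ``tube_radius`` of the centerline) get
    ``rd * I + (ad - rd) * t t'`` with ``t`` the local tangent; everything
    else is ``iso_background * I``.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    centers = voxel_centers(grid_shape, affine)
    dense, tang = _resample_polyline(geometry.centerline, spacing=0.2)
    dist, nearest = cKDTree(dense).query(centers, workers=1)
    inside = dist <= geometry.tube_radius
    tensors = np.zeros((centers.shape[0], 3, 3))
    tensors[:] = tissue.iso_background * np.eye(3)
    t = tang[nearest[inside]]
    tensors[inside] = tissue.rd_true * np.eye(3) + (
        tissue.ad_true - tissue.rd_true
    ) * np.einsum("ni,nj->nij", t, t)
    mask = inside.reshape(grid_shape)
    return tensors.reshape(grid_shape + (3, 3)), mask


def simulate_dwi(tensors: np.ndarray, scheme: AcquisitionScheme,
                 tissue: TissueModel, rng_seed: int) -> np.ndarray:
    """Monoexponential DWI signals with Rician noise.

    Noise model: ``sqrt((S + n1)^2 + n2^2)`` with ``n1, n2`` independent
    zero-mean Gaussians of SD ``tissue.sigma`` -- the magnitude of a
    complex Gaussian-perturbed signal, hence the characteristic positive
    bias of background magnitude MR data.
    """
    if np.any(scheme.bvalues < 0):
        raise ValueError("negative b-value")
    spatial = tensors.shape[:-2]
    D = tensors.reshape(-1, 3, 3)
    g = scheme.bvectors
    quad = np.einsum("vij,ni,nj->vn", D, g, g)
    clean = tissue.s0 * np.exp(-scheme.bvalues[None, :] * quad)
    if tissue.sigma > 0:
        rng = np.random.default_rng(rng_seed)
        n1 = rng.normal(0.0, tissue.sigma, clean.shape)
        n2 = rng.normal(0.0, tissue.sigma, clean.shape)
        signal = np.sqrt((clean + n1) ** 2 + n2**2)
    else:
        signal = clean
    return signal.reshape(spatial + (scheme.n_volumes,))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, group, lesion model and biological variability.

    ``affected_side`` may be ``"mixed"`` (patients only), which assigns
    right/left lesions at the modelled 13:6 ratio; ``between_subject_sd``
    is a shared log-scale jitter on each subject's diffusivities and
    ``between_side_sd`` an additional independent per-side jitter.
    """

    n_subjects: int
    group: str                      # "healthy" | "patient"
    affected_side: str = "none"     # "left" | "right" | "none" | "mixed"
    rd_effect: float = 1.0
    ad_effect: float = 1.0
    between_subject_sd: float = 0.08
    between_side_sd: float = 0.03
    rng_seed: int = 0

    def __post_init__(self):
        problems = []
        if self.n_subjects < 2:
            problems.append(f"n_subjects must be >= 2 (got {self.n_subjects})")
        if self.group not in ("healthy", "patient"):
            problems.append(f"group must be healthy|patient (got {self.group!r})")
        if self.affected_side not in ("left", "right", "none", "mixed"):
            problems.append(f"bad affected_side {self.affected_side!r}")
        if self.rd_effect <= 0 or self.ad_effect <= 0:
            problems.append("rd_effect and ad_effect must be positive")
        if self.between_subject_sd < 0 or self.between_side_sd < 0:
            problems.append("jitter SDs must be non-negative")
        if self.group == "healthy" and (
            self.affected_side != "none"
            or self.rd_effect != 1.0
            or self.ad_effect != 1.0
        ):
            problems.append(
                "healthy cohorts require affected_side='none' and unit effects"
            )
        if self.group == "patient" and self.affected_side == "none":
            problems.append("patient cohorts need an affected side (or 'mixed')")
        if problems:
            raise ValueError("invalid CohortSpec: " + "; ".join(problems))


def patient_spec(n_subjects: int = 19, rng_seed: int = 0, **kw) -> CohortSpec:
    kw.setdefault("rd_effect", DEFAULT_RD_EFFECT)
    return CohortSpec(n_subjects=n_subjects, group="patient",
                      affected_side="mixed", rng_seed=rng_seed, **kw)


def healthy_spec(n_subjects: int = 18, rng_seed: int = 0, **kw) -> CohortSpec:
    return CohortSpec(n_subjects=n_subjects, group="healthy", rng_seed=rng_seed, **kw)


@dataclass
class PhantomSubject:
    subject_id: str
    group: str
    affected_side: str          # "left" | "right" | "none"
    dwi: np.ndarray             # (x, y, z, n_volumes)
    affine: np.ndarray
    truth_tensors: np.ndarray   # (x, y, z, 3, 3)
    truth_masks: dict           # side -> bool volume
    truth_params: dict          # side -> {"ad": ..., "rd": ...}
    seed: int

    def __post_init__(self):
        if np.any(self.dwi < 0):
            raise ValueError("DWI signals must be non-negative")
        if np.any(self.truth_masks["left"] & self.truth_masks["right"]):
            raise ValueError("left and right truth masks overlap")


def _assign_affected_sides(spec: CohortSpec) -> list[str]:
    if spec.group == "healthy":
        return ["none"] * spec.n_subjects
    if spec.affected_side in ("left", "right"):
        return [spec.affected_side] * spec.n_subjects
    n_right = int(round(spec.n_subjects * RIGHT_AFFECTED_FRACTION))
    return ["right"] * n_right + ["left"] * (spec.n_subjects - n_right)


def draw_cohort_params(spec: CohortSpec, tissue: TissueModel | None = None):
    """Realized per-subject, per-side (ad, rd) truth values and the manifest.

    Log-normal jitter: a shared per-subject factor (between_subject_sd) times
    an independent per-side factor (between_side_sd), then the lesion's
    rd_effect / ad_effect applied to the affected side only.  Returns a
    pandas DataFrame with one row per subject -- the cohort manifest.
    """
    import pandas as pd

    tissue = tissue or TissueModel()
    rng = np.random.default_rng(spec.rng_seed)
    sides = _assign_affected_sides(spec)
    prefix = "H" if spec.group == "healthy" else "P"
    rows = []
    for i in range(spec.n_subjects):
        subj = rng.normal(0.0, 1.0, 2)  # shared (ad, rd)
        side_j = rng.normal(0.0, 1.0, (2, 2))  # (side, param)
        params = {}
        for s_idx, side in enumerate(("left", "right")):
            ad = tissue.ad_true * np.exp(
                spec.between_subject_sd * subj[0]
                + spec.between_side_sd * side_j[s_idx, 0]
            )
            rd = tissue.rd_true * np.exp(
                spec.between_subject_sd * subj[1]
                + spec.between_side_sd * side_j[s_idx, 1]
            )
            if side == sides[i]:
                ad *= spec.ad_effect
                rd *= spec.rd_effect
            rd = min(rd, ad)  # keep the cylinder prolate
            params[side] = {"ad": ad, "rd": rd}
        rows.append({
            "subject_id": f"{prefix}{i + 1:03d}",
            "group": spec.group,
            "affected_side": sides[i],
            "ad_left": params["left"]["ad"],
            "rd_left": params["left"]["rd"],
            "ad_right": params["right"]["ad"],
            "rd_right": params["right"]["rd"],
            "seed": int(rng.integers(0, 2**31 - 1)),
        })
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec, scheme: AcquisitionScheme | None = None,
                    tissue: TissueModel | None = None,
                    grid_shape=DEFAULT_GRID_SHAPE,
                    affine: np.ndarray | None = None):
    """Simulate a full cohort; returns (subjects, manifest DataFrame)."""
    scheme = scheme or default_scheme()
    tissue = tissue or TissueModel()
    affine = default_affine() if affine is None else np.asarray(affine, float)
    manifest = draw_cohort_params(spec, tissue)
    grid_shape = tuple(int(n) for n in grid_shape)
    geometries = {s: make_centerline(s, grid_shape, affine) for s in ("left", "right")}
    # masks and tube tangents are common-space geometry, shared by the cohort
    centers = voxel_centers(grid_shape, affine)
    base = {}
    for side, geo in geometries.items():
        dense, tang = _resample_polyline(geo.centerline, spacing=0.2)
        dist, nearest = cKDTree(dense).query(centers, workers=1)
        inside = dist <= geo.tube_radius
        outer = np.einsum("ni,nj->nij", tang[nearest[inside]], tang[nearest[inside]])
        base[side] = (inside.reshape(grid_shape), outer)
    subjects = []
    for _, row in manifest.iterrows():
        tensors = np.zeros(grid_shape + (3, 3))
        tensors[:] = tissue.iso_background * np.eye(3)
        masks = {}
        for side in ("left", "right"):
            mask, outer = base[side]
            ad, rd = row[f"ad_{side}"], row[f"rd_{side}"]
            tensors[mask] = rd * np.eye(3) + (ad - rd) * outer
            masks[side] = mask
        dwi = simulate_dwi(tensors, scheme, tissue, rng_seed=int(row["seed"]))
        subjects.append(PhantomSubject(
            subject_id=row["subject_id"], group=row["group"],
            affected_side=row["affected_side"], dwi=dwi, affine=affine,
            truth_tensors=tensors, truth_masks=masks,
            truth_params={s: {"ad": row[f"ad_{s}"], "rd": row[f"rd_{s}"]}
                          for s in ("left", "right")},
            seed=int(row["seed"]),
        ))
    logger.info("generated %s cohort: n=%d", spec.group, spec.n_subjects)
    return subjects, manifest
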