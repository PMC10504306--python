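"""Per-voxel diffusion tensor estimation and scalar index maps.

The tensor is fitted by ordinary log-linear least squares: for each voxel,
``ln S_n = ln s0 - b_n g_n' D g_n`` is a linear system in the seven
unknowns ``(ln s0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)``, solved with one
precomputed pseudoinverse applied to every masked voxel.  Scalar indexes
use the standard eigenvalue definitions:

    MD = (l1 + l2 + l3) / 3        AD = l1        RD = (l2 + l3) / 2
    FA = sqrt(3/2) * sqrt(sum (l_i - MD)^2) / sqrt(sum l_i^2)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phantom import AcquisitionScheme

logger = logging.getLogger(__name__)

SIGNAL_FLOOR_FRACTION = 1e-6  # of the per-voxel s0 estimate, applied before log

# component order of the packed symmetric tensor
TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


def design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """(n_volumes, 7) design for the log-linear model; column 0 is ln s0."""
    b = scheme.bvalues
    g = scheme.bvectors
    X = np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError(
            "rank-deficient tensor design: the gradient scheme does not span "
            "the six tensor components (collinear or too few directions)"
        )
    return X


@dataclass
class TensorVolume:
    """Packed fitted tensors (x, y, z, 6), estimated s0, and QC counts."""

    tensors: np.ndarray   # (..., 6) in TENSOR_COMPONENTS order, mm^2/s
    s0: np.ndarray
    mask: np.ndarray
    n_floored_voxels: int = 0

    def as_matrices(self) -> np.ndarray:
        """(..., 3, 3) symmetric matrices."""
        xx, yy, zz, xy, xz, yz = np.moveaxis(self.tensors, -1, 0)
        out = np.empty(self.tensors.shape[:-1] + (3, 3))
        out[..., 0, 0] = xx
        out[..., 1, 1] = yy
        out[..., 2, 2] = zz
        out[..., 0, 1] = out[..., 1, 0] = xy
        out[..., 0, 2] = out[..., 2, 0] = xz
        out[..., 1, 2] = out[..., 2, 1] = yz
        return out


def fit_tensor(dwi: np.ndarray, scheme: AcquisitionScheme,
               mask: np.ndarray | None = None) -> TensorVolume:
    """Ordinary least-squares tensor fit inside ``mask`` (zero elsewhere).

    Signals are clamped to ``SIGNAL_FLOOR_FRACTION * s0`` before the log;
    voxels whose b=0 estimate is non-positive are flagged and zero-filled.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.shape[-1] != scheme.n_volumes:
        raise ValueError(
            f"DWI has {dwi.shape[-1]} volumes but scheme has {scheme.n_volumes}"
        )
    spatial = dwi.shape[:-1]
    mask = np.ones(spatial, bool) if mask is None else np.asarray(mask, bool)
    X = design_matrix(scheme)
    pinv = np.linalg.pinv(X)

    sig = dwi[mask]  # (v, n)
    s0_est = sig[:, scheme.bvalues == 0].mean(axis=1)
    bad = s0_est <= 0
    floor = SIGNAL_FLOOR_FRACTION * np.where(bad, 1.0, s0_est)
    floored = sig < floor[:, None]
    n_floored = int(np.count_nonzero(floored.any(axis=1) | bad))
    logsig = np.log(np.maximum(sig, floor[:, None]))
    beta = logsig @ pinv.T  # (v, 7)

    tensors = np.zeros(spatial + (6,))
    s0 = np.zeros(spatial)
    tvals = beta[:, 1:]
    tvals[bad] = 0.0
    tensors[mask] = tvals
    s0_fit = np.exp(beta[:, 0])
    s0_fit[bad] = 0.0
    s0[mask] = s0_fit
    if n_floored:
        logger.info("tensor fit: %d voxels hit the signal floor", n_floored)
    return TensorVolume(tensors=tensors, s0=s0, mask=mask,
                        n_floored_voxels=n_floored)


@dataclass
class EigenSystem:
    """Sorted eigenvalues (descending) and orthonormal eigenvectors."""

    eigenvalues: np.ndarray    # (..., 3), l1 >= l2 >= l3, mm^2/s
    eigenvectors: np.ndarray   # (..., 3, 3); [..., :, k] is e_{k+1}
    n_clamped_voxels: int = 0  # voxels whose negative eigenvalues were zeroed

    @property
    def e1(self) -> np.ndarray:
        return self.eigenvectors[..., :, 0]


def eigendecompose(tensors: TensorVolume | np.ndarray) -> EigenSystem:
    """Eigendecomposition with negative eigenvalues clamped to zero.

    The principal direction e1 keeps an arbitrary sign; consumers must
    treat it as axial (antipodally symmetric).
    """
    mats = tensors.as_matrices() if isinstance(tensors, TensorVolume) else np.asarray(tensors, float)
    if not np.all(np.isfinite(mats)):
        idx = np.argwhere(~np.isfinite(mats).all(axis=(-2, -1)))[0]
        raise ValueError(f"non-finite tensor at voxel {tuple(int(i) for i in idx)}")
    vals, vecs = np.linalg.eigh(mats)  # ascending
    vals = vals[..., ::-1]
    vecs = vecs[..., ::-1]
    n_clamped = int(np.count_nonzero((vals < 0).any(axis=-1)))
    if n_clamped:
        logger.info("eigendecompose: clamped negatives in %d voxels", n_clamped)
    vals = np.clip(vals, 0.0, None)
    return EigenSystem(eigenvalues=np.ascontiguousarray(vals),
                       eigenvectors=np.ascontiguousarray(vecs),
                       n_clamped_voxels=n_clamped)


@dataclass
class ScalarMaps:
    fa: np.ndarray   # unitless, in [0, 1]
    md: np.ndarray   # mm^2/s
    ad: np.ndarray   # mm^2/s
    rd: np.ndarray   # mm^2/s


def scalar_maps(eigs: EigenSystem) -> ScalarMaps:
    """FA/MD/AD/RD volumes from sorted non-negative eigenvalues.

    FA is defined as 0 where all three eigenvalues vanish.
    """
    lam = eigs.eigenvalues
    md = lam.mean(axis=-1)
    ad = lam[..., 0]
    rd = lam[..., 1:].mean(axis=-1)
    num = ((lam - md[..., None]) ** 2).sum(axis=-1)
    den = (lam**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0))
    fa = np.where(den > 0, fa, 0.0)
    return ScalarMaps(fa=fa, md=md, ad=ad, rd=rd)


def cylinder_scalars(ad: float, rd: float) -> dict:
    """Closed-form FA/MD/AD/RD of a cylindrically symmetric tensor."""
    lam = np.array([ad, rd, rd], dtype=float)
    md = lam.mean()
    num = ((lam - md) ** 2).sum()
    den = (lam**2).sum()
    fa = 0.0 if den == 0 else float(np.sqrt(1.5 * num / den))
    return {"fa": fa, "md": float(md), "ad": float(ad), "rd": float(rd)}
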