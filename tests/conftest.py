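import numpy as np
import pytest

from facialdti import phantom


GRID32 = (32, 32, 32)


@pytest.fixture(scope="session")
def scheme():
    return phantom.default_scheme()


@pytest.fixture(scope="session")
def affine04():
    return phantom.default_affine(0.4)


@pytest.fixture(scope="session")
def noiseless_tissue():
    return phantom.TissueModel(sigma=0.0)


@pytest.fixture(scope="session")
def curved_noiseless_subject(scheme, affine04, noiseless_tissue):
    """One noiseless phantom subject on a 32^3 grid with the curved tubes."""
    spec = phantom.healthy_spec(2, rng_seed=7, between_subject_sd=0.0,
                                between_side_sd=0.0)
    subjects, manifest = phantom.generate_cohort(
        spec, scheme, noiseless_tissue, GRID32, affine04)
    return subjects[0], manifest


def straight_field(grid=(40, 20, 20), voxel=0.4, fa_lo=0.05, fa_hi=0.9,
                   x_lo=8, x_hi=32):
    """Uniform +x principal-direction field with FA above threshold only in
    the slab ``x_lo <= i < x_hi`` (voxel indices).  Returns (eigs, fa, affine).
    """
    from facialdti.dtifit import EigenSystem

    aff = phantom.default_affine(voxel)
    fa = np.full(grid, fa_lo)
    fa[x_lo:x_hi, :, :] = fa_hi
    vecs = np.zeros(grid + (3, 3))
    vecs[..., 0, 0] = 1.0
    vecs[..., 1, 1] = 1.0
    vecs[..., 2, 2] = 1.0
    vals = np.zeros(grid + (3,))
    eigs = EigenSystem(eigenvalues=vals, eigenvectors=vecs)
    return eigs, fa, aff
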