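import numpy as np
import pytest

from rsnpipe.images import BoldRun, BrainMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_run(data, tr_s=2.4, voxel_size_mm=3.0):
    """Wrap a 4D array in a BoldRun with a plain scaled-identity affine."""
    data = np.asarray(data, dtype=float)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size_mm
    return BoldRun(data=data, affine=affine, tr_s=tr_s,
                   voxel_size_mm=np.repeat(voxel_size_mm, 3))


def full_mask(shape):
    return BrainMask(np.ones(shape, dtype=bool))


def ols_oracle(x, y):
    """Independent normal-equations least-squares solver (with intercept via
    explicit column).  Returns coefficients without the intercept row."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    design = np.column_stack([np.ones(x.shape[0]), x])
    beta = np.linalg.pinv(design.T @ design) @ design.T @ y
    return beta[1:]
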