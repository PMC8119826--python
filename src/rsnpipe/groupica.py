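"""Temporal-concatenation group spatial ICA.

Subjects' in-mask time series are demeaned (and by default variance
normalized) per voxel, temporally concatenated into one (time x voxels)
matrix, reduced to ``d`` principal axes, and decomposed with fixed-point ICA
(symmetric decorrelation, log-cosh contrast) along the *spatial* dimension so
that components are statistically independent over voxels — the standard
MELODIC-style group decomposition.  Each recovered map is sign-fixed to
positive skewness (maps read as activations) and z-scored over in-mask
voxels.

Thresholding of the z-scored maps supports two dialects:

* ``fdr`` (default): two-sided normal p per voxel, Benjamini-Hochberg at
  q = level (default 0.05);
* ``level``: retain voxels with ``|z| >= level * max|z|`` (proportional
  threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.extmath import randomized_svd
from statsmodels.stats.multitest import multipletests

from .images import BoldRun, BrainMask, flatten_run

__all__ = [
    "ReducedData",
    "SpatialMapSet",
    "concat_and_reduce",
    "fit_spatial_ica",
    "compute_mixing",
    "bh_reject",
    "threshold_maps",
]

_EXACT_SVD_LIMIT = 800  # use exact SVD below this size, randomized above


@dataclass
class ReducedData:
    """PCA-reduced concatenated data: rows are projections onto the top-d
    principal axes (``reduced = U_d^T X``, shape (d, n_voxels))."""

    reduced: np.ndarray          # (d, n_voxels)
    basis: np.ndarray            # (total_T, d) temporal principal axes U_d
    explained_variance_ratio: np.ndarray  # length d, non-increasing
    subject_slices: list = field(default_factory=list)


@dataclass
class SpatialMapSet:
    """Group IC maps (z-scored per map over in-mask voxels) plus metadata.

    ``masks`` and ``usable`` are filled by :func:`threshold_maps`; ``mixing``
    by :func:`compute_mixing`.
    """

    maps: np.ndarray             # (k, n_voxels)
    mask_ref: BrainMask
    k: int
    seed: int
    mixing: np.ndarray | None = None
    masks: np.ndarray | None = None      # (k, n_voxels) bool
    usable: np.ndarray | None = None     # (k,) bool — non-empty mask
    threshold_meta: dict | None = None
    converged: bool = True
    n_iter: int = 0

    def retained(self, indices) -> "SpatialMapSet":
        """Subset of components (after template matching)."""
        idx = np.asarray(list(indices), dtype=int)
        return SpatialMapSet(
            maps=self.maps[idx],
            mask_ref=self.mask_ref,
            k=len(idx),
            seed=self.seed,
            mixing=None if self.mixing is None else self.mixing[:, idx],
            masks=None if self.masks is None else self.masks[idx],
            usable=None if self.usable is None else self.usable[idx],
            threshold_meta=self.threshold_meta,
            converged=self.converged,
            n_iter=self.n_iter,
        )


def _svd_topd(x: np.ndarray, d: int):
    if min(x.shape) <= _EXACT_SVD_LIMIT:
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        return u[:, :d], s[:d], vt[:d]
    return randomized_svd(x, n_components=d, n_oversamples=10, n_iter=7,
                          random_state=0)


def _noise_std(y: np.ndarray, n_signal: int) -> np.ndarray:
    """Voxel-wise noise standard deviation: residual spread after removing
    the subject's top ``n_signal`` principal components (the MELODIC-style
    variance-normalization convention, which preserves signal contrast)."""
    n_signal = min(n_signal, y.shape[0] - 1)
    u, s, vt = _svd_topd(y, n_signal)
    resid = y - (u * s) @ vt
    sd = resid.std(axis=0, ddof=0)
    sd[sd < 1e-12] = 1.0
    return sd


def _stack_runs(
    runs, mask: BrainMask, var_normalize: bool, n_signal: int
) -> tuple[np.ndarray, list]:
    mats, slices, start = [], [], 0
    for run in runs:
        if run.spatial_shape != mask.shape:
            raise ValueError(
                f"run grid {run.spatial_shape} does not match mask {mask.shape}"
            )
        y = flatten_run(run, mask)          # (T, V)
        y = y - y.mean(axis=0, keepdims=True)
        if var_normalize:
            y = y / _noise_std(y, n_signal)
        mats.append(y)
        slices.append(slice(start, start + y.shape[0]))
        start += y.shape[0]
    return np.vstack(mats), slices


def concat_and_reduce(
    runs, mask: BrainMask, d: int, var_normalize: bool = True
) -> ReducedData:
    """Concatenate subjects in time and project onto the top-d principal axes.

    Per subject, each voxel time series is demeaned and, by default,
    variance normalized by its noise standard deviation (residual spread
    after removing the subject's top-d principal components) before
    concatenation.  Returns the ``(d, n_voxels)`` projections, the temporal
    principal axes, and the non-increasing explained-variance spectrum of
    the retained axes.
    """
    d = int(d)
    if d < 1:
        raise ValueError("d must be >= 1")
    x, slices = _stack_runs(runs, mask, var_normalize, n_signal=d)
    total_t, n_vox = x.shape
    if d > min(total_t, n_vox):
        raise ValueError(
            f"d={d} must be in [1, min(total timepoints={total_t}, voxels={n_vox})]"
        )
    total_var = float((x**2).sum())
    u, s, _ = _svd_topd(x, d)
    # deterministic sign convention: largest-|.| entry of each axis positive
    for j in range(d):
        col = u[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            u[:, j] = -col
    reduced = u.T @ x
    evr = (s**2) / max(total_var, 1e-300)
    return ReducedData(
        reduced=reduced, basis=u, explained_variance_ratio=evr,
        subject_slices=slices,
    )


def fit_spatial_ica(
    reduced: ReducedData | np.ndarray,
    k: int,
    seed: int = 0,
    mask: BrainMask | None = None,
) -> SpatialMapSet:
    """Fixed-point spatial ICA of the reduced data.

    Runs FastICA (parallel/symmetric decorrelation, log-cosh contrast,
    tol 1e-6, max 1000 iterations) on the voxel dimension.  Non-convergence
    is flagged on the returned map set rather than raised.
    """
    r = reduced.reduced if isinstance(reduced, ReducedData) else np.asarray(reduced)
    d, n_vox = r.shape
    k = int(k)
    if k < 1 or k > d:
        raise ValueError(f"k={k} must be in [1, d={d}]")
    rng = np.random.default_rng(seed)
    w_init = rng.standard_normal((k, k))
    ica = FastICA(
        n_components=k,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        tol=1e-6,
        max_iter=1000,
        w_init=w_init,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        sources = ica.fit_transform(r.T)  # (V, k)
    n_iter = int(ica.n_iter_)
    converged = n_iter < 1000
    maps = sources.T.astype(np.float64)
    # sign convention: positive skewness (maps read as activations)
    sk = stats.skew(maps, axis=1)
    maps[sk < 0] *= -1.0
    # z-score each map over in-mask voxels
    maps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(
        axis=1, ddof=0, keepdims=True
    )
    if mask is None:
        mask_ref = BrainMask(np.ones((n_vox, 1, 1), dtype=bool))  # flat grid
    else:
        if mask.n_voxels != n_vox:
            raise ValueError(
                f"mask has {mask.n_voxels} voxels, reduced data has {n_vox}"
            )
        mask_ref = mask
    return SpatialMapSet(
        maps=maps, mask_ref=mask_ref, k=k, seed=int(seed),
        converged=converged, n_iter=n_iter,
    )


def compute_mixing(concat_data: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """Recover the (total_T x K) mixing matrix by least-squares projection of
    the concatenated data onto the spatial maps."""
    g = np.asarray(maps, dtype=float)  # (K, V)
    gram = g @ g.T
    return np.asarray(concat_data) @ g.T @ np.linalg.inv(gram)


def bh_reject(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg rejection mask at FDR level ``q``."""
    pvals = np.asarray(pvals, dtype=float)
    reject, _, _, _ = multipletests(pvals.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(pvals.shape)


def threshold_maps(
    mapset: SpatialMapSet, method: str = "fdr", level: float = 0.05
) -> SpatialMapSet:
    """Attach per-component threshold masks to a z-scored map set.

    ``fdr``: two-sided normal p per voxel, BH at q = level (default 0.05).
    ``level``: retain voxels with ``|z| >= level * max|z|``.
    Components with empty masks are flagged unusable.
    """
    maps = mapset.maps
    masks = np.zeros(maps.shape, dtype=bool)
    if method == "fdr":
        for i, z in enumerate(maps):
            p = 2.0 * stats.norm.sf(np.abs(z))
            masks[i] = bh_reject(p, q=level)
    elif method == "level":
        if not 0 < level <= 1:
            raise ValueError("proportional level must be in (0, 1]")
        for i, z in enumerate(maps):
            masks[i] = np.abs(z) >= level * np.abs(z).max()
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    usable = masks.any(axis=1)
    out = SpatialMapSet(
        maps=maps,
        mask_ref=mapset.mask_ref,
        k=mapset.k,
        seed=mapset.seed,
        mixing=mapset.mixing,
        masks=masks,
        usable=usable,
        threshold_meta={"method": method, "level": float(level)},
        converged=mapset.converged,
        n_iter=mapset.n_iter,
    )
    return out
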