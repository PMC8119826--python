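"""Dual regression: subject-specific back-projection of group IC maps.

Stage 1 (spatial regression): at every timepoint the subject's voxel vector
is regressed on the K group maps, yielding subject-specific node time
courses.  Stage 2 (temporal regression): every voxel's time series is
regressed on the (optionally variance-normalized) stage-1 time courses,
yielding subject-specific spatial parameter-estimate (PE) maps and z maps.

Intercepts are handled by demeaning both sides at each stage, which is
algebraically identical to including an explicit intercept column and keeps
the normal-equations oracle trivial.  Stage-1 variance normalization (the
``--des_norm`` convention) is ON by default: PE-map and RSN-score magnitudes
depend on it, group-test validity does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import BoldRun, BrainMask, flatten_run
from .groupica import SpatialMapSet

__all__ = ["SubjectMaps", "stage1_timecourses", "stage2_maps", "run_dual_regression"]


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; offending components listed."""

    def __init__(self, message: str, components=None):
        super().__init__(message)
        self.components = list(components or [])


@dataclass
class SubjectMaps:
    """Per-subject dual-regression outputs."""

    subject_id: str
    timecourses: np.ndarray   # (T, K) stage-1 node time courses
    pe_maps: np.ndarray       # (K, n_voxels) stage-2 parameter estimates
    z_maps: np.ndarray        # (K, n_voxels)
    normalization: bool


def _check_rank(x: np.ndarray, what: str) -> None:
    k = x.shape[1]
    rank = np.linalg.matrix_rank(x)
    if rank < k:
        # identify offending columns via the R diagonal of a pivoted-ish QR
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = [int(i) for i in np.where(diag < 1e-10 * max(diag.max(), 1e-300))[0]]
        raise RankDeficiencyError(
            f"{what} design is rank deficient (rank {rank} < {k}); "
            f"suspect components {bad}",
            components=bad,
        )


def stage1_timecourses(
    run: BoldRun, group_maps: SpatialMapSet, mask: BrainMask
) -> np.ndarray:
    """Spatial regression: OLS of each timepoint's voxel vector on the group
    maps (intercept over voxels).  Returns ``(T, K)`` coefficients."""
    y = flatten_run(run, mask)                 # (T, V)
    g = np.asarray(group_maps.maps, dtype=float).T   # (V, K)
    if g.shape[0] != y.shape[1]:
        raise ValueError(
            f"group maps have {g.shape[0]} voxels, run has {y.shape[1]} in-mask"
        )
    if g.shape[1] == 0:
        raise ValueError("retained component set is empty")
    gc = g - g.mean(axis=0, keepdims=True)
    _check_rank(gc, "stage-1 (spatial)")
    yc = y - y.mean(axis=1, keepdims=True)
    gram_inv = np.linalg.inv(gc.T @ gc)
    return yc @ gc @ gram_inv                  # (T, K)


def stage2_maps(
    run: BoldRun,
    timecourses: np.ndarray,
    mask: BrainMask,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Temporal regression: per-voxel OLS of the voxel time series on the
    stage-1 time courses (intercept in time).

    Returns ``(pe_maps, z_maps)``, each ``(K, n_voxels)``; z is PE over its
    residual-based standard error with T - K - 1 degrees of freedom.
    """
    y = flatten_run(run, mask)                 # (T, V)
    x = np.asarray(timecourses, dtype=float)
    t, k = x.shape
    if t != y.shape[0]:
        raise ValueError(f"time courses have {t} rows, run has {y.shape[0]}")
    if t < k + 2:
        raise ValueError(f"need T >= K + 2 (T={t}, K={k})")
    xc = x - x.mean(axis=0, keepdims=True)
    sd = xc.std(axis=0, ddof=1)
    if np.any(sd < 1e-12):
        bad = [int(i) for i in np.where(sd < 1e-12)[0]]
        raise ValueError(f"constant stage-1 time-course column(s): {bad}")
    if normalize:
        xc = xc / sd
    _check_rank(xc, "stage-2 (temporal)")
    yc = y - y.mean(axis=0, keepdims=True)
    gram_inv = np.linalg.inv(xc.T @ xc)
    pe = gram_inv @ xc.T @ yc                  # (K, V)
    resid = yc - xc @ pe
    dof = t - k - 1
    sigma2 = (resid**2).sum(axis=0) / dof      # (V,)
    se = np.sqrt(np.outer(np.diag(gram_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, pe / se, 0.0)
    return pe, z


def run_dual_regression(
    runs,
    group_maps: SpatialMapSet,
    mask: BrainMask,
    normalize: bool = True,
    subject_ids=None,
) -> list:
    """Both stages for every subject; deterministic.

    Returns a list of :class:`SubjectMaps` in input order.
    """
    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(len(runs))]
    out = []
    for sid, run in zip(subject_ids, runs):
        tc = stage1_timecourses(run, group_maps, mask)
        pe, z = stage2_maps(run, tc, mask, normalize=normalize)
        out.append(
            SubjectMaps(
                subject_id=sid, timecourses=tc, pe_maps=pe, z_maps=z,
                normalization=normalize,
            )
        )
    return out
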