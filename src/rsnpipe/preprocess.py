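"""Minimal BOLD preprocessing on data already in a common grid.

Four deterministic, shape-preserving steps (except the discard step, which
shortens the time axis), applied in the fixed order

    discard -> smooth -> normalize -> highpass

Motion/slice-timing correction, brain extraction and spatial normalization
are out of scope: inputs are assumed to live in one shared grid already.

The temporal high-pass is implemented as regression removal of a
discrete-cosine drift basis spanning all frequencies strictly below the
cutoff, with the temporal mean retained.  This is the exact-linear-algebra
analogue of the usual FSL-style filter and is directly testable against a
least-squares oracle.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .images import BoldRun, BrainMask, flatten_run

__all__ = [
    "fwhm_to_sigma",
    "discard_initial",
    "smooth_gaussian",
    "dct_drift_basis",
    "highpass_temporal",
    "normalize_intensity",
    "preprocess_run",
]


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian full-width-at-half-maximum to standard deviation."""
    return float(fwhm) / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def discard_initial(run: BoldRun, n_discard: int) -> BoldRun:
    """Drop the first ``n_discard`` volumes (initial transients)."""
    n_discard = int(n_discard)
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= run.n_timepoints:
        raise ValueError(
            f"cannot discard {n_discard} of {run.n_timepoints} volumes"
        )
    if n_discard == 0:
        return run.with_data(run.data.copy(), note="discard:0")
    return run.with_data(run.data[..., n_discard:], note=f"discard:{n_discard}")


def smooth_gaussian(run: BoldRun, fwhm_mm: float) -> BoldRun:
    """Convolve each volume with an isotropic Gaussian of the given FWHM.

    Sigma is expressed in voxels per axis; volume edges use reflective
    boundary handling so interior mass is preserved on small grids.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return run.with_data(run.data.copy(), note="smooth:0")
    sigma_vox = fwhm_to_sigma(fwhm_mm) / run.voxel_size_mm  # per-axis
    out = ndimage.gaussian_filter(
        run.data, sigma=tuple(sigma_vox) + (0.0,), mode="reflect"
    )
    return run.with_data(out, note=f"smooth:fwhm={fwhm_mm}mm")


def dct_drift_basis(n_timepoints: int, tr_s: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine drift regressors with frequencies below ``cutoff_hz``.

    Column ``k`` (k = 1..k_max) is cos(pi * k * (t + 1/2) / T), whose
    frequency is k / (2 * T * TR); all columns with frequency strictly below
    the cutoff are returned.  Shape ``(T, k_max)`` (possibly zero columns).
    """
    T = int(n_timepoints)
    k_max = int(np.ceil(2.0 * T * tr_s * cutoff_hz)) - 1
    k_max = max(0, min(k_max, T - 1))
    t = np.arange(T)
    ks = np.arange(1, k_max + 1)
    return np.cos(np.pi * np.outer(t + 0.5, ks) / T)


def highpass_temporal(run: BoldRun, cutoff_hz: float) -> BoldRun:
    """Remove slow drifts below ``cutoff_hz`` per voxel; mean retained."""
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    nyquist = 1.0 / (2.0 * run.tr_s)
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist:.4g} Hz for TR {run.tr_s}s"
        )
    T = run.n_timepoints
    basis = dct_drift_basis(T, run.tr_s, cutoff_hz)
    x = run.data.reshape(-1, T)
    mean = x.mean(axis=1, keepdims=True)
    if basis.shape[1] == 0:
        out = x - mean + mean  # no drift terms below cutoff: identity
    else:
        xc = x - mean
        # DCT columns are orthogonal: projection via per-column normal eqs
        scale = (basis**2).sum(axis=0)
        beta = (xc @ basis) / scale
        out = xc - beta @ basis.T + mean
    return run.with_data(
        out.reshape(run.data.shape), note=f"highpass:{cutoff_hz}Hz"
    )


def normalize_intensity(
    run: BoldRun, mask: BrainMask | None = None, target: float = 10000.0
) -> BoldRun:
    """Scale the run so its 4D in-mask grand mean equals ``target``.

    Follows the FSL grand-mean convention (default 10000).
    """
    if target <= 0:
        raise ValueError("target must be positive")
    if mask is None:
        grand = float(run.data.mean())
    else:
        grand = float(flatten_run(run, mask).mean())
    if grand <= 0:
        raise ValueError(f"in-mask grand mean {grand:.4g} is not positive")
    return run.with_data(
        run.data * (target / grand), note=f"normalize:target={target}"
    )


def preprocess_run(
    run: BoldRun,
    mask: BrainMask | None = None,
    n_discard: int = 5,
    fwhm_mm: float = 6.0,
    target_mean: float = 10000.0,
    highpass_hz: float = 0.01,
) -> BoldRun:
    """Apply the full fixed-order pipeline: discard, smooth, normalize,
    highpass.  Any step can be disabled with 0 / None."""
    out = discard_initial(run, n_discard)
    if fwhm_mm:
        out = smooth_gaussian(out, fwhm_mm)
    if target_mean:
        out = normalize_intensity(out, mask, target_mean)
    if highpass_hz:
        out = highpass_temporal(out, highpass_hz)
    return out
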