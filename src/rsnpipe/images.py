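"""Core image containers and NIfTI-1 input/output.

Everything downstream works on two containers: :class:`BoldRun` (one
subject's 4D BOLD volume plus grid geometry and repetition time) and
:class:`BrainMask` (a 3D boolean mask on the same grid).  Spatial maps are
handled as flat ``(K, n_voxels)`` arrays over the in-mask voxels; the helpers
at the bottom convert between volume and flat representations.

Voxel indices are 0-based throughout; all volumes of a cohort must share one
affine and grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GeometryError",
    "BoldRun",
    "BrainMask",
    "read_bold",
    "read_volume",
    "read_mask",
    "read_map_stack",
    "write_bold",
    "write_volume",
    "write_map_stack",
    "check_cohort_geometry",
    "flatten_run",
    "flatten_volume",
    "unflatten_maps",
]


class GeometryError(ValueError):
    """Raised when grids, affines or shapes are inconsistent."""


@dataclass
class BoldRun:
    """One subject's 4D BOLD run.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Voxel time series, finite, t >= 2.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform; must be invertible.
    tr_s : float
        Repetition time in seconds.
    voxel_size_mm : ndarray, shape (3,)
        Voxel edge lengths in millimetres.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float
    voxel_size_mm: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.voxel_size_mm = np.atleast_1d(
            np.asarray(self.voxel_size_mm, dtype=np.float64)
        )
        if self.voxel_size_mm.size == 1:
            self.voxel_size_mm = np.repeat(self.voxel_size_mm, 3)
        if self.data.ndim != 4:
            raise GeometryError(f"BOLD data must be 4D, got ndim={self.data.ndim}")
        if self.data.shape[3] < 2:
            raise GeometryError("BOLD run needs at least 2 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise GeometryError("affine is singular")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel sizes must be positive")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray, note: str | None = None) -> "BoldRun":
        """Copy geometry onto new voxel data, appending a provenance note."""
        prov = list(self.provenance)
        if note is not None:
            prov.append(note)
        return replace(self, data=np.asarray(data, dtype=np.float64), provenance=prov)


@dataclass
class BrainMask:
    """3D boolean brain mask with at least one in-mask voxel."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise GeometryError("mask must be 3D")
        if not self.data.any():
            raise ValueError("mask has no in-mask voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# NIfTI I/O


def _default_affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = np.broadcast_to(voxel_size_mm, (3,))
    return aff


def read_bold(path, tr_s: float | None = None) -> BoldRun:
    """Read a 4D NIfTI-1 file as a :class:`BoldRun`.

    ``tr_s`` overrides the header pixdim[4] when given (headers of synthetic
    or converted data are not always trustworthy).
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 4:
        raise GeometryError(f"{path}: expected a 4D volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    tr = float(tr_s) if tr_s is not None else header_tr
    if tr <= 0:
        raise ValueError(f"{path}: repetition time unavailable; pass tr_s")
    return BoldRun(
        data=data,
        affine=np.asarray(img.affine),
        tr_s=tr,
        voxel_size_mm=np.asarray(zooms[:3], dtype=float),
    )


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D map (a 4D file with t=1 is accepted and squeezed).

    Returns ``(data, affine)``.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D map, got shape {data.shape}")
    return data, np.asarray(img.affine)


def read_mask(path) -> BrainMask:
    data, _ = read_volume(path)
    return BrainMask(data > 0)


def read_map_stack(path, mask: BrainMask) -> np.ndarray:
    """Read a 4D NIfTI (component = 4th axis) as flat ``(K, n_voxels)`` maps."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 3:
        data = data[..., None]
    if data.shape[:3] != mask.shape:
        raise GeometryError(
            f"{path}: map grid {data.shape[:3]} does not match mask grid {mask.shape}"
        )
    return data[mask.data].T.copy()  # (K, n_voxels)


def write_bold(run: BoldRun, path) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    zooms = tuple(run.voxel_size_mm) + (run.tr_s,)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def write_map_stack(maps: np.ndarray, mask: BrainMask, affine: np.ndarray, path) -> None:
    """Write flat ``(K, n_voxels)`` maps as a 4D NIfTI (component axis last)."""
    maps = np.atleast_2d(np.asarray(maps, dtype=np.float64))
    k = maps.shape[0]
    vol = np.zeros(mask.shape + (k,), dtype=np.float32)
    vol[mask.data] = maps.T
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def check_cohort_geometry(paths) -> None:
    """Verify that all NIfTI files share one grid and affine.

    Raises :class:`GeometryError` naming the first offending pair.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        return
    ref = nib.load(str(paths[0]))
    ref_shape, ref_aff = ref.shape[:3], np.asarray(ref.affine)
    for p in paths[1:]:
        img = nib.load(str(p))
        if img.shape[:3] != ref_shape or not np.allclose(
            np.asarray(img.affine), ref_aff, atol=1e-4
        ):
            raise GeometryError(
                f"geometry mismatch between {paths[0].name} "
                f"(shape {ref_shape}) and {p.name} (shape {img.shape[:3]})"
            )


# ---------------------------------------------------------------------------
# Flat <-> volume conversion


def flatten_run(run: BoldRun, mask: BrainMask) -> np.ndarray:
    """Return the in-mask time-by-voxel matrix, shape ``(t, n_voxels)``."""
    if run.spatial_shape != mask.shape:
        raise GeometryError(
            f"run grid {run.spatial_shape} does not match mask grid {mask.shape}"
        )
    return run.data[mask.data].T.copy()


def flatten_volume(vol: np.ndarray, mask: BrainMask) -> np.ndarray:
    vol = np.asarray(vol, dtype=np.float64)
    if vol.shape != mask.shape:
        raise GeometryError(
            f"volume grid {vol.shape} does not match mask grid {mask.shape}"
        )
    return vol[mask.data].copy()


def unflatten_maps(maps: np.ndarray, mask: BrainMask, fill: float = 0.0) -> np.ndarray:
    """Expand flat ``(K, n_voxels)`` maps (or one flat map) into volumes.

    Returns shape ``(x, y, z)`` for a single map, ``(x, y, z, K)`` otherwise.
    """
    maps = np.asarray(maps, dtype=np.float64)
    single = maps.ndim == 1
    maps = np.atleast_2d(maps)
    vol = np.full(mask.shape + (maps.shape[0],), fill, dtype=np.float64)
    vol[mask.data] = maps.T
    return vol[..., 0] if single else vol
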