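"""Template-based selection of resting-state network components.

Group IC maps are spatially cross-correlated (Pearson, over in-mask voxels)
against a set of reference network template maps; components whose best
template correlation reaches the threshold (default 0.3, the usual ``fslcc``
cut) are retained as networks, the rest are treated as artifact components.
A component may match several templates and a template several components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .images import BrainMask
from .groupica import SpatialMapSet

__all__ = ["TemplateSet", "MatchTable", "spatial_corr", "match_components"]


@dataclass
class TemplateSet:
    """Flat ``(M, n_voxels)`` template maps with one label per template."""

    maps: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if len(self.labels) != self.maps.shape[0]:
            raise ValueError("one label per template map required")
        if self.maps.shape[0] < 1:
            raise ValueError("at least one template required")


@dataclass
class MatchTable:
    """All template matches at threshold plus the retained component set."""

    rows: pd.DataFrame  # columns: ic_index, template_index, r
    retained_ics: list
    r_matrix: np.ndarray  # (n_ics, n_templates) full correlation table
    r_thresh: float


def spatial_corr(
    map_a: np.ndarray, map_b: np.ndarray, mask: BrainMask | np.ndarray | None = None
) -> float:
    """Pearson correlation of two maps over in-mask voxels.

    Maps may be flat vectors (mask=None or a flat boolean vector) or volumes
    with a :class:`BrainMask`.  Zero variance in either map is undefined and
    reported as NaN.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if isinstance(mask, BrainMask):
        a, b = a[mask.data], b[mask.data]
    elif mask is not None:
        m = np.asarray(mask, dtype=bool)
        a, b = a[m], b[m]
    a, b = a.ravel(), b.ravel()
    if a.shape != b.shape:
        raise ValueError(f"map shapes differ: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ValueError("need at least 3 in-mask voxels")
    ac = a - a.mean()
    bc = b - b.mean()
    va, vb = float(ac @ ac), float(bc @ bc)
    if va <= 0 or vb <= 0:
        return float("nan")
    return float(ac @ bc / np.sqrt(va * vb))


def match_components(
    mapset: SpatialMapSet,
    templates: TemplateSet,
    r_thresh: float = 0.3,
    use_abs: bool = False,
) -> MatchTable:
    """Cross-correlate every IC against every template; retain ICs whose best
    (signed, or absolute with ``use_abs``) correlation reaches ``r_thresh``.

    Correlations are computed on the unthresholded z maps within the brain
    mask.  Returns all pairs at threshold plus the retained list.
    """
    ics = np.asarray(mapset.maps, dtype=float)
    tmps = np.asarray(templates.maps, dtype=float)
    if ics.shape[1] != tmps.shape[1]:
        raise ValueError(
            f"IC maps have {ics.shape[1]} voxels, templates {tmps.shape[1]}"
        )

    def _std(x):
        xc = x - x.mean(axis=1, keepdims=True)
        sd = np.sqrt((xc**2).mean(axis=1, keepdims=True))
        sd[sd <= 0] = np.nan
        return xc / sd

    r = _std(ics) @ _std(tmps).T / ics.shape[1]  # (n_ics, n_templates)
    score = np.abs(r) if use_abs else r
    with np.errstate(invalid="ignore"):
        hit = score >= r_thresh
    retained = sorted(int(i) for i in np.where(np.nanmax(score, axis=1) >= r_thresh)[0])
    ic_idx, t_idx = np.where(hit)
    rows = pd.DataFrame(
        {
            "ic_index": ic_idx.astype(int),
            "template_index": t_idx.astype(int),
            "template_label": [templates.labels[j] for j in t_idx],
            "r": r[ic_idx, t_idx],
        }
    ).sort_values(["ic_index", "template_index"], ignore_index=True)
    return MatchTable(rows=rows, retained_ics=retained, r_matrix=r, r_thresh=r_thresh)
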