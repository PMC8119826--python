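"""Node-by-node network matrices and hierarchical cluster comparison.

From per-subject node time courses (dual-regression stage-1 outputs) the
module builds K x K full-correlation and partial-correlation matrices with
Fisher-z variants, averages them per group in z space, hierarchically
clusters the nodes by the similarity of their connectivity profiles
(distance 1 - corr(row_i, row_j), the netmat-reordering convention), and
compares the cluster structure between groups at a common cut — typically a
height calibrated on the control group, so cluster counts may differ.

Partial correlations come from the (optionally ridge-regularized) inverse
covariance:  r_ij|rest = -P_ij / sqrt(P_ii P_jj).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "NetMat",
    "ClusterTree",
    "full_corr",
    "partial_corr",
    "subject_netmat",
    "group_netmat",
    "hclust_netmat",
    "height_for_k",
    "compare_group_clusters",
    "plot_netmat",
]

_COND_LIMIT = 1e8
_Z_CLIP = 0.999999  # |r| clip before atanh


def _fisher_z(r: np.ndarray) -> np.ndarray:
    z = np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))
    np.fill_diagonal(z, 0.0)
    return z


@dataclass
class NetMat:
    """Full and partial correlation matrices (diagonal zeroed by convention)
    with Fisher-z variants."""

    full_r: np.ndarray
    partial_r: np.ndarray
    full_z: np.ndarray
    partial_z: np.ndarray
    ridge: float = 0.0
    level: str = "subject"     # 'subject' | 'group'
    group_label: str | None = None

    @property
    def k(self) -> int:
        return self.full_r.shape[0]


@dataclass
class ClusterTree:
    """Agglomerative clustering of netmat nodes."""

    linkage: np.ndarray        # scipy linkage table, (K-1, 4)
    leaf_order: np.ndarray
    cut: dict                  # {'k': int} or {'height': float}
    assignments: np.ndarray    # node -> cluster id (1-based, scipy style)
    source: str
    method: str

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.assignments))


def full_corr(timecourses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of the node time courses; returns ``(r, z)``.

    Diagonal is zeroed by convention in both.  Constant columns are
    rejected.
    """
    tc = np.asarray(timecourses, dtype=float)
    if tc.ndim != 2 or tc.shape[0] < 3:
        raise ValueError("need a (T, K) matrix with T >= 3")
    sd = tc.std(axis=0, ddof=0)
    if np.any(sd < 1e-12):
        bad = [int(i) for i in np.where(sd < 1e-12)[0]]
        raise ValueError(f"constant time-course column(s): {bad}")
    r = np.corrcoef(tc.T)
    np.fill_diagonal(r, 0.0)
    return r, _fisher_z(r)


def partial_corr(
    timecourses: np.ndarray, ridge: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Partial correlations from the inverse (ridge-regularized) covariance.

    With ridge = 0 and an ill-conditioned covariance (condition number above
    1e8) a small ridge is auto-escalated with a warning; a singular
    covariance with ridge = 0 is rejected with guidance.
    """
    tc = np.asarray(timecourses, dtype=float)
    if tc.ndim != 2 or tc.shape[0] < 3:
        raise ValueError("need a (T, K) matrix with T >= 3")
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    k = tc.shape[1]
    if k == 1:
        raise ValueError("need at least 2 nodes")
    cov = np.cov(tc.T)
    if ridge == 0.0:
        cond = np.linalg.cond(cov)
        if not np.isfinite(cond) or cond > 1e15:
            raise np.linalg.LinAlgError(
                "node covariance is singular at ridge=0; pass a positive "
                "ridge (e.g. 0.01 * mean variance) or drop collinear nodes"
            )
        if cond > _COND_LIMIT:
            ridge = 1e-6 * float(np.trace(cov)) / k
            warnings.warn(
                f"covariance condition number {cond:.3g} > {_COND_LIMIT:.0e}; "
                f"auto-escalating ridge to {ridge:.3g}",
                RuntimeWarning,
                stacklevel=2,
            )
    prec = np.linalg.inv(cov + ridge * np.eye(k))
    d = np.sqrt(np.diag(prec))
    r = -prec / np.outer(d, d)
    np.fill_diagonal(r, 0.0)
    r = 0.5 * (r + r.T)  # enforce exact symmetry
    return r, _fisher_z(r)


def subject_netmat(timecourses: np.ndarray, ridge: float = 0.0,
                   group_label: str | None = None) -> NetMat:
    """Full + partial netmat for one subject's ``(T, K)`` time courses."""
    fr, fz = full_corr(timecourses)
    pr, pz = partial_corr(timecourses, ridge=ridge)
    return NetMat(full_r=fr, partial_r=pr, full_z=fz, partial_z=pz,
                  ridge=ridge, level="subject", group_label=group_label)


def group_netmat(subject_netmats, group_labels) -> dict:
    """Element-wise mean of subject z matrices per group.

    Averaging happens on the Fisher-z scale (the contract); back-transformed
    r matrices are reported alongside.  Returns ``{group: NetMat}``.
    """
    labels = list(group_labels)
    if len(labels) != len(subject_netmats):
        raise ValueError("one group label per subject netmat required")
    out = {}
    for g in sorted(set(labels)):
        mats = [nm for nm, lab in zip(subject_netmats, labels) if lab == g]
        fz = np.mean([nm.full_z for nm in mats], axis=0)
        pz = np.mean([nm.partial_z for nm in mats], axis=0)
        fr, pr = np.tanh(fz), np.tanh(pz)
        np.fill_diagonal(fr, 0.0)
        np.fill_diagonal(pr, 0.0)
        out[g] = NetMat(full_r=fr, partial_r=pr, full_z=fz, partial_z=pz,
                        ridge=mats[0].ridge, level="group", group_label=g)
    return out


def _profile_distance(mat: np.ndarray) -> np.ndarray:
    """Condensed distance 1 - corr between netmat rows (diagonal zeroed)."""
    m = np.asarray(mat, dtype=float).copy()
    np.fill_diagonal(m, 0.0)
    c = np.corrcoef(m)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    d = np.clip(0.5 * (d + d.T), 0.0, None)
    return squareform(d, checks=False)


def hclust_netmat(
    netmat: NetMat,
    source: str = "full",
    method: str = "average",
    cut: dict | None = None,
) -> ClusterTree:
    """Agglomerative clustering of nodes by connectivity-profile similarity.

    ``source`` selects the full or partial correlation matrix; ``method`` is
    'average', 'complete' or 'ward'; ``cut`` is ``{'k': int}`` or
    ``{'height': float}`` (default: k=1 tree with no informative cut is not
    allowed — pass a cut).
    """
    if source not in ("full", "partial"):
        raise ValueError("source must be 'full' or 'partial'")
    if method not in ("average", "complete", "ward"):
        raise ValueError("method must be 'average', 'complete' or 'ward'")
    mat = netmat.full_r if source == "full" else netmat.partial_r
    if mat.shape[0] < 2:
        raise ValueError("need K >= 2 nodes")
    cond = _profile_distance(mat)
    z = hierarchy.linkage(cond, method=method)
    if cut is None:
        cut = {"k": 2}
    if "k" in cut:
        k = int(cut["k"])
        if not 1 <= k <= mat.shape[0]:
            raise ValueError(f"cut k={k} out of range")
        assign = hierarchy.fcluster(z, t=k, criterion="maxclust")
    elif "height" in cut:
        h = float(cut["height"])
        if h < 0:
            raise ValueError("cut height must be >= 0")
        assign = hierarchy.fcluster(z, t=h, criterion="distance")
    else:
        raise ValueError("cut must contain 'k' or 'height'")
    order = hierarchy.leaves_list(z)
    return ClusterTree(linkage=z, leaf_order=order, cut=dict(cut),
                       assignments=assign, source=source, method=method)


def height_for_k(tree: ClusterTree, k: int) -> float:
    """Cut height (midpoint of the merge gap) that yields exactly k clusters.

    With K leaves, cutting between merge heights K-1-k and K-k gives k
    clusters; returns the midpoint of that gap.  Used to calibrate a height
    on one group's tree and apply it to the other's.
    """
    z = tree.linkage
    n_leaves = z.shape[0] + 1
    if not 1 <= k <= n_leaves:
        raise ValueError(f"k={k} out of range for {n_leaves} leaves")
    heights = np.sort(z[:, 2])
    if k == n_leaves:
        return float(heights[0] / 2.0)
    lo = heights[n_leaves - 1 - k]
    hi = heights[n_leaves - k] if k > 1 else heights[-1] * 1.1
    return float(0.5 * (lo + hi))


def compare_group_clusters(
    tree_ref: ClusterTree, tree_other: ClusterTree, node_labels=None
) -> dict:
    """Structured diff between two cluster trees over the same node set.

    Reports cluster counts, per-node membership changes (nodes whose
    reference cluster's members they no longer sit with), the mapping of each
    reference cluster onto the other grouping, and which reference clusters
    dissolved (their members absorbed into >= 2 clusters dominated by other
    reference clusters).
    """
    a = np.asarray(tree_ref.assignments)
    b = np.asarray(tree_other.assignments)
    if a.shape != b.shape:
        raise ValueError("trees cover different node sets")
    n = len(a)
    if node_labels is None:
        node_labels = [f"node{i}" for i in range(n)]
    node_labels = list(node_labels)
    ref_ids = np.unique(a)
    other_ids = np.unique(b)
    # majority reference cluster for each 'other' cluster
    other_majority = {}
    for oc in other_ids:
        members = a[b == oc]
        vals, counts = np.unique(members, return_counts=True)
        other_majority[int(oc)] = int(vals[counts.argmax()])
    cluster_map, dissolved, changed = {}, [], []
    best_target = {}
    for rc in ref_ids:
        sel = a == rc
        targets = b[sel]
        vals, counts = np.unique(targets, return_counts=True)
        spread = {int(v): int(c) for v, c in zip(vals, counts)}
        cluster_map[int(rc)] = spread
        best_target[int(rc)] = int(vals[counts.argmax()])
        owned = [oc for oc in vals if other_majority[int(oc)] == int(rc)]
        if len(owned) == 0 and len(vals) >= 2:
            dissolved.append(int(rc))
    # a node changed membership if it did not follow its reference cluster's
    # majority destination
    for i in range(n):
        if int(b[i]) != best_target[int(a[i])]:
            changed.append(node_labels[i])
    return {
        "n_clusters_ref": int(len(ref_ids)),
        "n_clusters_other": int(len(other_ids)),
        "cluster_map": cluster_map,
        "dissolved_ref_clusters": dissolved,
        "changed_nodes": changed,
    }


def plot_netmat(netmat: NetMat, tree: ClusterTree | None = None,
                path=None, node_labels=None):
    """Heat map of the netmat (full below / partial above the diagonal) with
    an optional dendrogram ordering; saves to ``path`` when given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = netmat.k
    order = np.arange(k) if tree is None else tree.leaf_order
    combined = np.tril(netmat.full_r[np.ix_(order, order)], -1) + np.triu(
        netmat.partial_r[np.ix_(order, order)], 1
    )
    fig, axes = plt.subplots(
        1, 2 if tree is not None else 1, figsize=(10, 4.5), squeeze=False
    )
    ax = axes[0, 0]
    im = ax.imshow(combined, cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_title(
        f"{netmat.group_label or netmat.level} netmat (full lower / partial upper)"
    )
    labels = (
        [str(i) for i in order]
        if node_labels is None
        else [str(node_labels[i]) for i in order]
    )
    ax.set_xticks(range(k), labels, rotation=90, fontsize=7)
    ax.set_yticks(range(k), labels, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    if tree is not None:
        hierarchy.dendrogram(tree.linkage, ax=axes[0, 1], labels=labels if
                             node_labels is not None else None)
        axes[0, 1].set_title(f"{tree.method} linkage, {tree.source} netmat")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
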