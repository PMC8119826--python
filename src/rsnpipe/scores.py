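"""Subject-level RSN scores and nonparametric group testing.

The RSN score of a subject on one component is the arithmetic mean of the
subject's stage-2 parameter-estimate map over that component's thresholded
group-map voxels.  Group differences per component are tested with the
Kruskal-Wallis rank test (mid-ranks, tie correction), with an exact
permutation null for small samples and the chi-square reference otherwise.
No multiple-testing correction is applied across components by default
(a Benjamini-Hochberg option is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .groupica import SpatialMapSet, bh_reject

__all__ = [
    "rsn_score",
    "score_table",
    "kruskal_wallis",
    "test_all_components",
    "GroupTestResult",
]

_EXACT_N_MAX = 10          # exact enumeration is mandatory up to this N
_EXACT_ENUM_LIMIT = 200_000  # enumerate when the assignment count fits
_MC_DRAWS = 20_000         # Monte-Carlo fallback for 'exact' beyond the limit


def rsn_score(pe_map: np.ndarray, ic_mask: np.ndarray) -> float:
    """Mean parameter estimate over the component's mask voxels."""
    pe = np.asarray(pe_map, dtype=float).ravel()
    m = np.asarray(ic_mask, dtype=bool).ravel()
    if pe.shape != m.shape:
        raise ValueError(f"PE map ({pe.shape}) and mask ({m.shape}) differ")
    if not m.any():
        raise ValueError("component mask is empty")
    return float(pe[m].mean())


def score_table(subject_maps, mapset: SpatialMapSet, labels: dict) -> pd.DataFrame:
    """One RSN score per subject x retained component.

    ``labels`` maps subject_id -> group.  Requires thresholded group masks on
    ``mapset``.
    """
    if mapset.masks is None:
        raise ValueError("map set has no threshold masks; run threshold_maps first")
    rows = []
    for sm in subject_maps:
        if sm.pe_maps.shape[0] != mapset.k:
            raise ValueError(
                f"{sm.subject_id}: {sm.pe_maps.shape[0]} PE maps vs {mapset.k} components"
            )
        for ic in range(mapset.k):
            rows.append(
                {
                    "subject_id": sm.subject_id,
                    "ic_index": ic,
                    "score": rsn_score(sm.pe_maps[ic], mapset.masks[ic]),
                    "group": labels[sm.subject_id],
                }
            )
    return pd.DataFrame(rows)


def _kw_statistic(ranks: np.ndarray, codes: np.ndarray, n_groups: int,
                  tie_term: float) -> float:
    n = ranks.size
    h = 0.0
    for g in range(n_groups):
        sel = codes == g
        rg = ranks[sel].sum()
        h += rg * rg / sel.sum()
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    if tie_term < 1.0:
        h /= tie_term
    return h


def _tie_term(values: np.ndarray) -> float:
    n = values.size
    _, counts = np.unique(values, return_counts=True)
    return 1.0 - float(((counts**3 - counts).sum()) / (n**3 - n)) if n > 1 else 1.0


def _enumerate_assignments(group_sizes):
    """Yield tuples of index-sets, one per group, covering range(N)."""
    n = sum(group_sizes)

    def rec(remaining, sizes):
        if len(sizes) == 1:
            yield (tuple(remaining),)
            return
        for chosen in combinations(remaining, sizes[0]):
            rest = [i for i in remaining if i not in set(chosen)]
            for tail in rec(rest, sizes[1:]):
                yield (chosen,) + tail

    yield from rec(list(range(n)), list(group_sizes))


def _n_assignments(group_sizes) -> int:
    from math import comb

    n = sum(group_sizes)
    total, rem = 1, n
    for s in group_sizes:
        total *= comb(rem, s)
        rem -= s
    return total


def kruskal_wallis(values, labels, mode: str = "auto", seed: int = 0):
    """Kruskal-Wallis H and p for >= 2 groups.

    ``mode='exact'`` evaluates the permutation null of H over label
    assignments: full enumeration when the assignment count is manageable,
    otherwise a seeded Monte-Carlo estimate.  ``mode='approx'`` uses the
    chi-square reference with G-1 degrees of freedom.  ``mode='auto'``
    selects exact for N <= 10.

    Returns ``(H, p)``.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if values.size != labels.size:
        raise ValueError("values and labels differ in length")
    uniq, codes = np.unique(labels, return_inverse=True)
    n_groups = len(uniq)
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if np.any(sizes == 0):
        raise ValueError("every group must be non-empty")
    n = values.size
    ranks = stats.rankdata(values)  # mid-ranks
    tie = _tie_term(values)
    if tie <= 0:
        # all observations identical: H is 0 by symmetry
        return 0.0, 1.0
    h_obs = _kw_statistic(ranks, codes, n_groups, tie)

    if mode == "auto":
        mode = "exact" if n <= _EXACT_N_MAX else "approx"
    if mode == "approx":
        p = float(stats.chi2.sf(h_obs, n_groups - 1))
        return float(h_obs), max(min(p, 1.0), np.nextafter(0, 1))
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")

    eps = 1e-12
    if _n_assignments(sizes) <= _EXACT_ENUM_LIMIT:
        count = total = 0
        for assignment in _enumerate_assignments(sizes):
            codes_perm = np.empty(n, dtype=int)
            for g, idx in enumerate(assignment):
                codes_perm[list(idx)] = g
            h = _kw_statistic(ranks, codes_perm, n_groups, tie)
            count += h >= h_obs - eps
            total += 1
        return float(h_obs), count / total
    # Monte-Carlo permutation estimate of the exact p
    rng = np.random.default_rng(seed)
    count = 0
    codes_perm = codes.copy()
    for _ in range(_MC_DRAWS):
        rng.shuffle(codes_perm)
        if _kw_statistic(ranks, codes_perm, n_groups, tie) >= h_obs - eps:
            count += 1
    return float(h_obs), (1 + count) / (_MC_DRAWS + 1)


@dataclass
class GroupTestResult:
    """Per-component Kruskal-Wallis results."""

    table: pd.DataFrame  # ic_index, H, p, means per group, direction, significant
    alpha: float
    mode: str
    fdr: bool


def test_all_components(
    scores: pd.DataFrame,
    alpha: float = 0.05,
    mode: str = "auto",
    fdr: bool = False,
    control_group: str = "control",
) -> GroupTestResult:
    """Kruskal-Wallis test of RSN scores per component.

    Flags components with p < alpha (uncorrected by default, mirroring the
    common reporting convention; ``fdr=True`` switches to BH-corrected
    flags).  Also reports per-group means and the sign of the difference
    relative to ``control_group``.
    """
    required = {"subject_id", "ic_index", "score", "group"}
    if not required.issubset(scores.columns):
        raise ValueError(f"score table needs columns {sorted(required)}")
    ics = sorted(scores["ic_index"].unique())
    subjects = scores["subject_id"].unique()
    counts = scores.groupby("ic_index")["subject_id"].nunique()
    if (counts != len(subjects)).any():
        raise ValueError("every subject must be scored on every component")
    rows = []
    for ic in ics:
        sub = scores[scores["ic_index"] == ic]
        h, p = kruskal_wallis(sub["score"].to_numpy(), sub["group"].to_numpy(),
                              mode=mode)
        means = sub.groupby("group")["score"].mean()
        other = [g for g in means.index if g != control_group]
        direction = ""
        if control_group in means.index and len(other) == 1:
            direction = (
                "lower" if means[other[0]] < means[control_group] else "higher"
            )
        row = {"ic_index": ic, "H": h, "p": p, "direction": direction}
        for g, m in means.items():
            row[f"mean_{g}"] = m
        rows.append(row)
    table = pd.DataFrame(rows)
    if fdr:
        table["significant"] = bh_reject(table["p"].to_numpy(), q=alpha)
    else:
        table["significant"] = table["p"] < alpha
    return GroupTestResult(table=table, alpha=alpha, mode=mode, fdr=fdr)
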