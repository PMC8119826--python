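"""Replicated simulation studies exercising the pipeline end to end.

Each study generates synthetic cohorts with planted effects, runs the
relevant slice of the analysis, and measures recovery / detection /
calibration.  They are used by the validation tests, the acceptance script
and the examples; all are deterministic given their base seed.

Problem sizes follow the reference synthetic cohort (24 x 24 x 12 grid of
3 mm voxels, 150 timepoints, 10 controls + 10 patients, 6 networks of which
3 are attenuated in patients by a factor 0.5); calibration studies use
smaller grids so that hundreds of null replicates stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .images import BrainMask
from .simdata import (
    SimConfig,
    simulate_cohort,
    modular_covariance,
    dissolved_modular_covariance,
    sample_mvn_timecourses,
)
from .preprocess import smooth_gaussian
from .groupica import concat_and_reduce, fit_spatial_ica, threshold_maps
from .templates import TemplateSet, match_components
from .dualreg import run_dual_regression
from .scores import score_table, test_all_components
from .perminf import PermConfig, permutation_maxstat
from .netmodel import (
    subject_netmat,
    group_netmat,
    hclust_netmat,
    height_for_k,
    compare_group_clusters,
)

__all__ = [
    "RecoveryReplicate",
    "recovery_replicate",
    "recovery_study",
    "fwe_calibration_study",
    "netmat_recovery_study",
    "dissolution_study",
]


@dataclass
class RecoveryReplicate:
    """Per-replicate outcome of the planted-effect recovery study."""

    seed: int
    match_r: np.ndarray          # best |spatial r| per planted network
    matched_ic: np.ndarray       # which recovered IC matched each network
    p_values: np.ndarray         # KW p per planted network
    patient_lower: np.ndarray    # bool per planted network
    attenuated: np.ndarray       # bool, ground truth
    flagged: np.ndarray          # p < alpha AND patient mean lower


def recovery_replicate(
    seed: int,
    config_kwargs: dict | None = None,
    ica_extra: int = 2,
    alpha: float = 0.05,
    smooth_fwhm_mm: float = 6.0,
) -> RecoveryReplicate:
    """One cohort through simulate -> smooth -> group ICA -> template match
    (templates = true maps) -> dual regression -> RSN scores -> group test.

    Planted networks are matched to recovered ICs greedily by max |spatial
    r|; each network's flag requires p < alpha with the patient mean lower.
    """
    cfg = SimConfig(seed=seed, **(config_kwargs or {}))
    cohort = simulate_cohort(cfg)
    runs = cohort.runs
    if smooth_fwhm_mm:
        runs = [smooth_gaussian(r, smooth_fwhm_mm) for r in runs]
    mask = cohort.mask
    k_ica = cfg.n_networks + ica_extra
    red = concat_and_reduce(runs, mask, d=k_ica)
    mapset = fit_spatial_ica(red, k=k_ica, seed=seed, mask=mask)
    mapset = threshold_maps(mapset, method="fdr", level=0.05)

    truth_maps = cohort.truth.true_maps  # full grid == mask here
    templates = TemplateSet(
        maps=truth_maps, labels=[f"net{j}" for j in range(cfg.n_networks)]
    )
    match = match_components(mapset, templates, r_thresh=0.3, use_abs=True)
    # per planted network: the recovered IC with the highest |r|
    absr = np.abs(match.r_matrix)            # (k_ica, K)
    matched_ic = absr.argmax(axis=0)
    match_r = absr.max(axis=0)

    # analyze only the matched components (the retained network set)
    retained = sorted(set(int(i) for i in matched_ic))
    retained_set = mapset.retained(retained)
    pos = {ic: j for j, ic in enumerate(retained)}
    subject_maps = run_dual_regression(
        runs, retained_set, mask, normalize=True, subject_ids=cohort.subject_ids
    )
    labels = dict(zip(cohort.subject_ids, cfg.group_labels))
    scores = score_table(subject_maps, retained_set, labels)
    result = test_all_components(scores, alpha=alpha, mode="approx")
    tab = result.table.set_index("ic_index")

    k_nets = cfg.n_networks
    p_values = np.array(
        [tab.loc[pos[int(matched_ic[j])], "p"] for j in range(k_nets)]
    )
    patient_lower = np.array(
        [tab.loc[pos[int(matched_ic[j])], "direction"] == "lower"
         for j in range(k_nets)]
    )
    attenuated = (
        cfg.amplitude_factor["patient"] < cfg.amplitude_factor["control"]
    )
    flagged = (p_values < alpha) & patient_lower
    return RecoveryReplicate(
        seed=seed,
        match_r=match_r,
        matched_ic=matched_ic,
        p_values=p_values,
        patient_lower=patient_lower,
        attenuated=attenuated,
        flagged=flagged,
    )


def recovery_study(
    n_replicates: int = 20, base_seed: int = 100, **kwargs
) -> dict:
    """Replicated recovery study; returns summary rates.

    ``attenuated_detection_rate``: fraction of (replicate x attenuated
    network) cells flagged with the patient mean lower.
    ``null_flag_rate``: fraction of null-network cells with p < alpha
    (any direction — the nominal false-positive rate).
    """
    reps = [
        recovery_replicate(seed=base_seed + i, **kwargs)
        for i in range(n_replicates)
    ]
    att = np.concatenate([r.flagged[r.attenuated] for r in reps])
    null_p = np.concatenate([r.p_values[~r.attenuated] for r in reps])
    min_match = float(min(r.match_r.min() for r in reps))
    all_matched = all((r.match_r >= 0.8).all() for r in reps)
    return {
        "replicates": reps,
        "n_replicates": n_replicates,
        "min_match_r": min_match,
        "all_networks_matched": bool(all_matched),
        "attenuated_detection_rate": float(att.mean()),
        "null_flag_rate": float((null_p < 0.05).mean()),
        "n_attenuated_cells": int(att.size),
        "n_null_cells": int(null_p.size),
    }


def fwe_calibration_study(
    n_datasets: int = 200,
    grid=(6, 6, 4),
    n_per_group: int = 8,
    n_perm: int = 1000,
    alpha: float = 0.05,
    base_seed: int = 7,
    use_tfce: bool = False,
) -> dict:
    """Family-wise error calibration of the max-statistic test on null data.

    Each dataset is pure N(0,1) subject maps; a family-wise rejection is
    any voxel with corrected p <= alpha.  Returns the empirical FWE rate.
    """
    mask = BrainMask(np.ones(grid, dtype=bool))
    n_vox = mask.n_voxels
    labels = np.array(["control"] * n_per_group + ["patient"] * n_per_group)
    rejections = 0
    for i in range(n_datasets):
        rng = np.random.default_rng([base_seed, i])
        maps = rng.standard_normal((2 * n_per_group, n_vox))
        cfg = PermConfig(
            n_perm=n_perm, seed=base_seed * 100_003 + i, use_tfce=use_tfce
        )
        res = permutation_maxstat(maps, labels, mask, cfg)
        rejections += bool((res.p_corrected <= alpha).any())
    return {
        "n_datasets": n_datasets,
        "alpha": alpha,
        "fwe_rate": rejections / n_datasets,
    }


def netmat_recovery_study(
    n_seeds: int = 20,
    module_sizes=(3, 3, 3, 3),
    within_r: float = 0.6,
    between_r: float = 0.1,
    n_timepoints: int = 200,
    n_subjects: int = 10,
    base_seed: int = 11,
    source: str = "full",
    method: str = "average",
) -> dict:
    """Planted-module recovery: cluster a group-averaged sampled netmat (the
    analysis's unit of clustering), score with the adjusted Rand index
    against the planted modules."""
    from sklearn.metrics import adjusted_rand_score

    cov, truth = modular_covariance(module_sizes, within_r, between_r)
    k_modules = len(module_sizes)
    aris = []
    for i in range(n_seeds):
        rng = np.random.default_rng([base_seed, i])
        nms = [
            subject_netmat(sample_mvn_timecourses(cov, n_timepoints, rng))
            for _ in range(n_subjects)
        ]
        gnm = group_netmat(nms, ["all"] * n_subjects)["all"]
        tree = hclust_netmat(gnm, source=source, method=method,
                             cut={"k": k_modules})
        aris.append(adjusted_rand_score(truth, tree.assignments))
    aris = np.asarray(aris)
    return {"aris": aris, "min_ari": float(aris.min()),
            "mean_ari": float(aris.mean())}


def dissolution_study(
    n_replicates: int = 20,
    module_sizes=(3, 3, 3, 3),
    dissolved: int = 3,
    within_r: float = 0.6,
    between_r: float = 0.1,
    coupling_r: float = 0.45,
    n_per_group: int = 10,
    n_timepoints: int = 200,
    base_seed: int = 23,
    source: str = "full",
    method: str = "average",
) -> dict:
    """Planted cluster dissolution: control cohorts carry M modules, patient
    cohorts have one module's coherence absorbed into the others.

    Clusters are cut at the height calibrated on the control tree to give
    exactly M clusters; the patient tree is cut at the same height.  Success
    per replicate means patient count = control count - 1.
    """
    cov_c, truth = modular_covariance(module_sizes, within_r, between_r)
    cov_p, _ = dissolved_modular_covariance(
        module_sizes, dissolved, within_r, between_r, coupling_r
    )
    m = len(module_sizes)
    control_counts, patient_counts, diffs = [], [], []
    for i in range(n_replicates):
        rng = np.random.default_rng([base_seed, i])
        nm_c = [
            subject_netmat(sample_mvn_timecourses(cov_c, n_timepoints, rng))
            for _ in range(n_per_group)
        ]
        nm_p = [
            subject_netmat(sample_mvn_timecourses(cov_p, n_timepoints, rng))
            for _ in range(n_per_group)
        ]
        groups = group_netmat(
            nm_c + nm_p, ["control"] * n_per_group + ["patient"] * n_per_group
        )
        tree_c = hclust_netmat(groups["control"], source=source, method=method,
                               cut={"k": m})
        h = height_for_k(tree_c, m)
        tree_c = hclust_netmat(groups["control"], source=source, method=method,
                               cut={"height": h})
        tree_p = hclust_netmat(groups["patient"], source=source, method=method,
                               cut={"height": h})
        diff = compare_group_clusters(tree_c, tree_p)
        control_counts.append(diff["n_clusters_ref"])
        patient_counts.append(diff["n_clusters_other"])
        diffs.append(diff)
    control_counts = np.asarray(control_counts)
    patient_counts = np.asarray(patient_counts)
    success = patient_counts == control_counts - 1
    return {
        "control_counts": control_counts,
        "patient_counts": patient_counts,
        "success_rate": float(success.mean()),
        "diffs": diffs,
        "truth_modules": truth,
    }
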