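"""End-to-end pipeline runner and plain-text configuration.

Stage graph:  simulate (optional) -> preprocess -> group ICA -> template
match -> dual regression -> RSN scores -> permutation inference -> network
matrices -> report.  Every stage writes its parameters (plus the config
hash and input checksums) next to its outputs; rerunning with an identical
configuration reproduces all numerical outputs exactly, so TSV/JSON outputs
are byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .images import (
    BrainMask,
    check_cohort_geometry,
    read_bold,
    read_mask,
    read_map_stack,
    write_map_stack,
)
from .simdata import SimConfig, simulate_cohort, write_dataset
from .preprocess import preprocess_run
from .groupica import concat_and_reduce, fit_spatial_ica, threshold_maps
from .templates import TemplateSet, match_components
from .dualreg import run_dual_regression
from .scores import score_table, test_all_components
from .perminf import PermConfig, permutation_maxstat, extract_clusters
from .netmodel import (
    subject_netmat,
    group_netmat,
    hclust_netmat,
    height_for_k,
    compare_group_clusters,
    plot_netmat,
)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineResult"]

log = logging.getLogger("rsnpipe")


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths.

    ``simulate=True`` generates the cohort from ``sim`` (a
    :class:`~rsnpipe.simdata.SimConfig` keyword dict); otherwise
    ``data_dir`` must hold the standard dataset layout (``*_bold.nii.gz``,
    ``mask.nii.gz``, ``labels.tsv``).  ``templates='truth'`` uses the
    simulated ground-truth maps as the template set; otherwise a 4D NIfTI
    path.
    """

    outdir: str = "rsnpipe_out"
    simulate: bool = True
    sim: dict = field(default_factory=dict)
    data_dir: str | None = None
    tr_s: float | None = None
    templates: str = "truth"

    # preprocess
    discard: int = 5
    fwhm_mm: float = 6.0
    target_mean: float = 10000.0
    highpass_hz: float = 0.01

    # group ICA
    ica_k: int | None = None      # None: planted K + 2 when simulating
    ica_d: int | None = None      # None: same as ica_k
    ica_seed: int = 7
    var_normalize: bool = True
    threshold_method: str = "fdr"
    threshold_level: float = 0.05

    # template matching
    match_thresh: float = 0.3
    match_abs: bool = True

    # dual regression / scores
    des_norm: bool = True
    alpha: float = 0.05
    kw_mode: str = "auto"
    score_fdr: bool = False

    # permutation inference
    n_perm: int = 10000
    perm_seed: int = 7
    tfce: bool = False
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    connectivity: int = 26

    # network matrices
    netmat_source: str = "full"
    netmat_linkage: str = "average"
    netmat_k: int = 4
    netmat_ridge: float = 0.0
    figures: bool = True

    write_subject_maps: bool = False
    version: str = "0.1.0"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        doc = asdict(self)
        doc.pop("outdir", None)  # hash the analysis, not the output location
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Objects and paths produced by :func:`run_pipeline`."""

    config: PipelineConfig
    outdir: Path
    mapset: object
    match: object
    subject_maps: list
    scores: pd.DataFrame
    kw_results: pd.DataFrame
    cluster_report: pd.DataFrame
    group_netmats: dict
    trees: dict
    cluster_diff: dict


def _sha(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _stage(outdir: Path, name: str, params: dict, cfg_hash: str) -> Path:
    d = outdir / name
    d.mkdir(parents=True, exist_ok=True)
    doc = {"stage": name, "config_hash": cfg_hash, "params": params}
    with open(d / "params.json", "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=str)
    return d


def _write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline; deterministic given the config seeds."""
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    config.to_yaml(outdir / "config.yaml")

    # ------------------------------------------------------------------ data
    if config.simulate:
        sim_kwargs = dict(config.sim)
        # a positive baseline intensity keeps grand-mean scaling well-posed
        sim_kwargs.setdefault("baseline", 100.0)
        sim_cfg = SimConfig(**sim_kwargs)
        cohort = simulate_cohort(sim_cfg)
        data_dir = outdir / "data"
        manifest = write_dataset(cohort, data_dir)
        runs = cohort.runs
        mask = cohort.mask
        subject_ids = cohort.subject_ids
        groups = list(sim_cfg.group_labels)
        planted_k = sim_cfg.n_networks
        checksums = {"labels": _sha(manifest["labels"]), "mask": _sha(manifest["mask"])}
        if config.templates == "truth":
            template_set = TemplateSet(
                maps=cohort.truth.true_maps,
                labels=[f"net{j}" for j in range(planted_k)],
            )
        else:
            template_set = None
    else:
        if not config.data_dir:
            raise ValueError("data_dir required when simulate=False")
        data_dir = Path(config.data_dir)
        labels_df = pd.read_csv(data_dir / "labels.tsv", sep="\t")
        check_cohort_geometry(
            [data_dir / "mask.nii.gz"]
            + [data_dir / f"{sid}_bold.nii.gz" for sid in labels_df["subject_id"]]
        )
        mask = read_mask(data_dir / "mask.nii.gz")
        subject_ids = list(labels_df["subject_id"])
        groups = list(labels_df["group"])
        runs = [
            read_bold(data_dir / f"{sid}_bold.nii.gz", tr_s=config.tr_s)
            for sid in subject_ids
        ]
        planted_k = None
        checksums = {"labels": _sha(data_dir / "labels.tsv"),
                     "mask": _sha(data_dir / "mask.nii.gz")}
        template_set = None
    if template_set is None:
        if config.templates in (None, "", "truth"):
            raise ValueError("templates must be a NIfTI path when not simulating")
        tmaps = read_map_stack(config.templates, mask)
        template_set = TemplateSet(
            maps=tmaps, labels=[f"template{j}" for j in range(tmaps.shape[0])]
        )
    counts = pd.Series(groups).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError(
            f"need at least 2 subjects in each of 2 groups, got {counts.to_dict()}"
        )
    log.info("data: %d subjects, groups %s", len(runs), counts.to_dict())

    # ----------------------------------------------------------- preprocess
    d = _stage(outdir, "preprocess", {
        "discard": config.discard, "fwhm_mm": config.fwhm_mm,
        "target_mean": config.target_mean, "highpass_hz": config.highpass_hz,
        "checksums": checksums,
    }, cfg_hash)
    runs = [
        preprocess_run(
            r, mask, n_discard=config.discard, fwhm_mm=config.fwhm_mm,
            target_mean=config.target_mean, highpass_hz=config.highpass_hz,
        )
        for r in runs
    ]
    log.info("preprocess done (%.1fs)", time.perf_counter() - t0)

    # ------------------------------------------------------------ group ICA
    k_ica = config.ica_k or ((planted_k + 2) if planted_k else None)
    if k_ica is None:
        raise ValueError("ica_k must be set when not simulating")
    d_red = config.ica_d or k_ica
    d = _stage(outdir, "ica", {
        "k": k_ica, "d": d_red, "seed": config.ica_seed,
        "var_normalize": config.var_normalize,
        "threshold": [config.threshold_method, config.threshold_level],
    }, cfg_hash)
    reduced = concat_and_reduce(runs, mask, d=d_red,
                                var_normalize=config.var_normalize)
    mapset = fit_spatial_ica(reduced, k=k_ica, seed=config.ica_seed, mask=mask)
    mapset = threshold_maps(mapset, method=config.threshold_method,
                            level=config.threshold_level)
    affine = runs[0].affine
    write_map_stack(mapset.maps, mask, affine, d / "group_ics.nii.gz")
    write_map_stack(mapset.masks.astype(float), mask, affine, d / "ic_masks.nii.gz")
    with open(d / "ica_meta.json", "w") as fh:
        json.dump({"k": k_ica, "seed": config.ica_seed,
                   "converged": bool(mapset.converged),
                   "n_iter": int(mapset.n_iter),
                   "threshold_meta": mapset.threshold_meta,
                   "explained_variance_ratio":
                       reduced.explained_variance_ratio.round(8).tolist()},
                  fh, indent=2, sort_keys=True)
    log.info("ICA done: k=%d converged=%s (%.1fs)", k_ica, mapset.converged,
             time.perf_counter() - t0)

    # ------------------------------------------------------ template match
    d = _stage(outdir, "match", {"thresh": config.match_thresh,
                                 "abs": config.match_abs}, cfg_hash)
    match = match_components(mapset, template_set, r_thresh=config.match_thresh,
                             use_abs=config.match_abs)
    _write_tsv(match.rows, d / "match_table.tsv")
    with open(d / "retained.json", "w") as fh:
        json.dump({"retained_ics": match.retained_ics}, fh, indent=2)
    usable_ics = [ic for ic in match.retained_ics
                  if mapset.usable is None or mapset.usable[ic]]
    if not usable_ics:
        raise RuntimeError("no component matched any template; nothing to analyze")
    match.retained_ics = usable_ics
    retained = mapset.retained(usable_ics)
    log.info("match: retained %d/%d components", retained.k, mapset.k)

    # ------------------------------------------------------ dual regression
    d = _stage(outdir, "dualreg", {"des_norm": config.des_norm,
                                   "k": retained.k}, cfg_hash)
    subject_maps = run_dual_regression(
        runs, retained, mask, normalize=config.des_norm, subject_ids=subject_ids
    )
    for sm in subject_maps:
        _write_tsv(
            pd.DataFrame(
                sm.timecourses,
                columns=[f"ic{j}" for j in match.retained_ics],
            ),
            d / f"{sm.subject_id}_timecourses.tsv",
        )
        if config.write_subject_maps:
            write_map_stack(sm.pe_maps, mask, affine, d / f"{sm.subject_id}_pe.nii.gz")
    log.info("dual regression done (%.1fs)", time.perf_counter() - t0)

    # --------------------------------------------------------------- scores
    d = _stage(outdir, "scores", {"alpha": config.alpha, "mode": config.kw_mode,
                                  "fdr": config.score_fdr}, cfg_hash)
    labels_map = dict(zip(subject_ids, groups))
    scores = score_table(subject_maps, retained, labels_map)
    scores["ic_index"] = scores["ic_index"].map(
        dict(enumerate(match.retained_ics))
    )
    _write_tsv(scores, d / "scores.tsv")
    kw = test_all_components(scores, alpha=config.alpha, mode=config.kw_mode,
                             fdr=config.score_fdr)
    _write_tsv(kw.table, d / "kw_results.tsv")
    log.info("scores: %d/%d components significant at alpha=%.3g",
             int(kw.table["significant"].sum()), len(kw.table), config.alpha)

    # -------------------------------------------------- permutation inference
    d = _stage(outdir, "randomise", {
        "n_perm": config.n_perm, "seed": config.perm_seed, "tfce": config.tfce,
        "alpha": config.alpha, "connectivity": config.connectivity,
    }, cfg_hash)
    cluster_rows = []
    p_stack, t_stack = [], []
    group_arr = np.asarray(groups)
    group_a, group_b = sorted(counts.index)  # alphabetical: control, patient
    for j, ic in enumerate(match.retained_ics):
        stacked = np.stack([sm.pe_maps[j] for sm in subject_maps])
        pcfg = PermConfig(
            n_perm=config.n_perm, seed=config.perm_seed + j,
            use_tfce=config.tfce, tfce_E=config.tfce_E, tfce_H=config.tfce_H,
            connectivity=config.connectivity,
        )
        res = permutation_maxstat(stacked, group_arr, mask, pcfg,
                                  group_a=group_a, group_b=group_b)
        rep = extract_clusters(res.p_corrected, res.stat, mask,
                               alpha=config.alpha,
                               connectivity=config.connectivity)
        rep.insert(0, "ic_index", ic)
        cluster_rows.append(rep)
        p_stack.append(res.p_corrected)
        t_stack.append(res.stat)
    nonempty = [r for r in cluster_rows if len(r)]
    cluster_report = (
        pd.concat(nonempty, ignore_index=True) if nonempty else
        pd.DataFrame(columns=["ic_index", "cluster_id", "voxel_count",
                              "max_stat", "peak_x", "peak_y", "peak_z",
                              "mean", "sd"])
    )
    _write_tsv(cluster_report, d / "cluster_report.tsv")
    write_map_stack(np.stack(p_stack), mask, affine, d / "corrected_p.nii.gz")
    write_map_stack(np.stack(t_stack), mask, affine, d / "tstat.nii.gz")
    log.info("permutation inference done (%.1fs)", time.perf_counter() - t0)

    # -------------------------------------------------------------- netmats
    d = _stage(outdir, "netmat", {
        "source": config.netmat_source, "linkage": config.netmat_linkage,
        "k": config.netmat_k, "ridge": config.netmat_ridge,
    }, cfg_hash)
    subject_nms = [
        subject_netmat(sm.timecourses, ridge=config.netmat_ridge,
                       group_label=labels_map[sm.subject_id])
        for sm in subject_maps
    ]
    gnm = group_netmat(subject_nms, groups)
    node_names = [f"ic{j}" for j in match.retained_ics]
    for g, nm in gnm.items():
        _write_tsv(pd.DataFrame(nm.full_r, columns=node_names),
                   d / f"{g}_netmat_full.tsv")
        _write_tsv(pd.DataFrame(nm.partial_r, columns=node_names),
                   d / f"{g}_netmat_partial.tsv")
    k_cut = min(config.netmat_k, retained.k)
    ref_group = group_a if group_a in gnm else sorted(gnm)[0]
    tree_ref = hclust_netmat(gnm[ref_group], source=config.netmat_source,
                             method=config.netmat_linkage, cut={"k": k_cut})
    h = height_for_k(tree_ref, k_cut)
    trees = {
        g: hclust_netmat(nm, source=config.netmat_source,
                         method=config.netmat_linkage, cut={"height": h})
        for g, nm in gnm.items()
    }
    for g, tree in trees.items():
        _write_tsv(
            pd.DataFrame(tree.linkage,
                         columns=["node_a", "node_b", "height", "size"]),
            d / f"{g}_linkage.tsv",
        )
        if config.figures:
            plot_netmat(gnm[g], tree, d / f"{g}_netmat.png",
                        node_labels=node_names)
    with open(d / "cluster_assignments.json", "w") as fh:
        json.dump(
            {g: {n: int(c) for n, c in zip(node_names, t.assignments)}
             for g, t in trees.items()},
            fh, indent=2, sort_keys=True,
        )
    other_groups = [g for g in trees if g != ref_group]
    diff = {}
    for g in other_groups:
        diff[g] = compare_group_clusters(trees[ref_group], trees[g],
                                         node_labels=node_names)
    with open(d / "cluster_diff.json", "w") as fh:
        json.dump({"reference": ref_group, "cut_height": round(h, 10),
                   "diff": diff}, fh, indent=2, sort_keys=True)
    log.info("netmat done (%.1fs)", time.perf_counter() - t0)

    # --------------------------------------------------------------- report
    d = _stage(outdir, "report", {}, cfg_hash)
    summary = {
        "config_hash": cfg_hash,
        "n_subjects": len(runs),
        "groups": {str(k): int(v) for k, v in counts.items()},
        "ica_k": k_ica,
        "retained_ics": match.retained_ics,
        "n_significant_components": int(kw.table["significant"].sum()),
        "n_significant_clusters": int(len(cluster_report)),
        "cluster_counts": {g: int(t.n_clusters) for g, t in trees.items()},
    }
    with open(d / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("pipeline complete (%.1fs)", time.perf_counter() - t0)
    return PipelineResult(
        config=config, outdir=outdir, mapset=retained, match=match,
        subject_maps=subject_maps, scores=scores, kw_results=kw.table,
        cluster_report=cluster_report, group_netmats=gnm, trees=trees,
        cluster_diff=diff,
    )
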