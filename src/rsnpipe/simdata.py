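"""Synthetic multi-subject 4D BOLD cohorts with known network structure.

The generator emulates the statistical structure that the downstream analysis
assumes: K spatially compact non-negative network maps (isotropic Gaussian
bumps, peak 1), per-network time courses drawn from a zero-mean multivariate
normal with configurable between-network covariance, a group-specific
amplitude factor per network (patients attenuated — the planted effect), white
Gaussian voxel noise, and an optional slow polynomial drift to exercise the
temporal high-pass filter.

Subject v,t data are

    y(v, t) = sum_k  a[group, k] * s_k(t) * m_k(v)  +  drift(v, t)  +  eps(v, t)

with ``eps`` iid N(0, noise_sigma^2) and an optional constant baseline
intensity added (off by default; the pipeline runner simulates with a
positive baseline so that grand-mean intensity normalization is
well-posed).  The whole cohort is a pure function of
:class:`SimConfig` (same seed -> identical data, bitwise).

The module also provides modular node-covariance builders used by the
network-matrix clustering studies (planted modules, and a "dissolved" variant
in which one module trades its internal coherence for coupling to the
remaining modules — the synthetic analogue of a resting-state network cluster
being absorbed into the others).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .images import (
    BoldRun,
    BrainMask,
    _default_affine,
    read_bold,
    read_mask,
    write_bold,
    write_map_stack,
    write_volume,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimCohort",
    "default_blob_centers",
    "make_network_maps",
    "make_timecourses",
    "synthesize_subject",
    "simulate_cohort",
    "write_dataset",
    "load_dataset",
    "modular_covariance",
    "dissolved_modular_covariance",
    "sample_mvn_timecourses",
]

CONTROL = "control"
PATIENT = "patient"


def default_blob_centers(grid_dims, k: int) -> np.ndarray:
    """Deterministically spread ``k`` blob centers over the grid interior.

    Centers are placed on the smallest axis-aligned lattice (restricted to the
    central half of each axis) with at least ``k`` sites, taken in C order.
    """
    grid_dims = tuple(int(g) for g in grid_dims)
    n = [1, 1, 1]
    axis = 0
    while n[0] * n[1] * n[2] < k:
        n[axis] += 1
        axis = (axis + 1) % 3
    coords = []
    for g, m in zip(grid_dims, n):
        if m == 1:
            coords.append(np.array([g // 2]))
        else:
            coords.append(np.rint(np.linspace(0.25 * g, 0.75 * g, m)).astype(int))
    lattice = np.array(np.meshgrid(*coords, indexing="ij")).reshape(3, -1).T
    return lattice[:k].copy()


@dataclass
class SimConfig:
    """Generative settings for one synthetic cohort.

    Defaults describe the reference study cohort: a 24 x 24 x 12 grid of 3 mm
    voxels, 150 timepoints at TR 2.4 s, 6 networks (Gaussian bumps of FWHM
    12 mm), 10 controls and 10 patients, with patients attenuated by a factor
    0.5 on the first 3 networks, and white noise of sigma 0.5 against
    unit-variance node time courses and peak-1 maps.
    """

    grid_dims: tuple = (24, 24, 12)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 150
    tr_s: float = 2.4
    n_networks: int = 6
    blob_centers: np.ndarray | None = None
    blob_fwhm_mm: np.ndarray | float = 12.0
    node_covariance: np.ndarray | None = None
    n_controls: int = 10
    n_patients: int = 10
    group_labels: tuple | None = None
    amplitude_factor: dict | None = None
    attenuated_networks: tuple | None = None  # default: first half of networks
    patient_factor: float = 0.5
    noise_sigma: float = 0.5
    drift_amplitude: float = 0.0
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_dims = tuple(int(g) for g in self.grid_dims)
        if len(self.grid_dims) != 3 or any(g < 1 for g in self.grid_dims):
            raise ValueError("grid_dims must be 3 positive integers")
        for name in ("voxel_size_mm", "tr_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_timepoints < 2 or self.n_networks < 1:
            raise ValueError("n_timepoints >= 2 and n_networks >= 1 required")
        k = self.n_networks
        if self.blob_centers is None:
            self.blob_centers = default_blob_centers(self.grid_dims, k)
        self.blob_centers = np.atleast_2d(np.asarray(self.blob_centers, dtype=int))
        if self.blob_centers.shape != (k, 3):
            raise ValueError(f"blob_centers must be (K, 3) = ({k}, 3)")
        for c in self.blob_centers:
            if np.any(c < 0) or np.any(c >= np.array(self.grid_dims)):
                raise ValueError(f"blob center {tuple(c)} outside grid {self.grid_dims}")
        self.blob_fwhm_mm = np.broadcast_to(
            np.asarray(self.blob_fwhm_mm, dtype=float), (k,)
        ).copy()
        if np.any(self.blob_fwhm_mm <= 0):
            raise ValueError("blob_fwhm_mm must be positive")
        if self.node_covariance is None:
            self.node_covariance = np.eye(k)
        self.node_covariance = np.asarray(self.node_covariance, dtype=float)
        if self.node_covariance.shape != (k, k):
            raise ValueError("node_covariance must be K x K")
        if not np.allclose(self.node_covariance, self.node_covariance.T, atol=1e-10):
            raise ValueError("node_covariance must be symmetric")
        if np.linalg.eigvalsh(self.node_covariance).min() <= 0:
            raise ValueError("node_covariance must be positive definite")
        if self.group_labels is None:
            self.group_labels = (CONTROL,) * self.n_controls + (PATIENT,) * self.n_patients
        self.group_labels = tuple(self.group_labels)
        for g in (CONTROL, PATIENT):
            if sum(lab == g for lab in self.group_labels) < 2:
                raise ValueError(f"need at least 2 subjects in group '{g}'")
        if self.attenuated_networks is None:
            self.attenuated_networks = tuple(range(k // 2))
        self.attenuated_networks = tuple(int(i) for i in self.attenuated_networks)
        if any(i < 0 or i >= k for i in self.attenuated_networks):
            raise ValueError(f"attenuated_networks out of range for K={k}")
        if self.amplitude_factor is None:
            control = np.ones(k)
            patient = np.ones(k)
            patient[list(self.attenuated_networks)] = self.patient_factor
            self.amplitude_factor = {CONTROL: control, PATIENT: patient}
        self.amplitude_factor = {
            g: np.broadcast_to(np.asarray(a, dtype=float), (k,)).copy()
            for g, a in self.amplitude_factor.items()
        }
        for g, a in self.amplitude_factor.items():
            if np.any(a < 0):
                raise ValueError(f"amplitude factors for '{g}' must be non-negative")
        if self.noise_sigma < 0 or self.drift_amplitude < 0:
            raise ValueError("noise_sigma and drift_amplitude must be non-negative")
        self.seed = int(self.seed)

    @property
    def n_subjects(self) -> int:
        return len(self.group_labels)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_dims))

    def subject_ids(self) -> list[str]:
        return [f"sub-{i:03d}" for i in range(self.n_subjects)]


@dataclass
class SimTruth:
    """Ground truth for a simulated cohort (maps have max value 1)."""

    true_maps: np.ndarray  # (K, n_voxels) flattened over the full grid, C order
    true_timecourses: list  # per subject, (T, K)
    amplitude_factor: dict
    labels: tuple
    seed: int


@dataclass
class SimCohort:
    config: SimConfig
    runs: list
    truth: SimTruth
    mask: BrainMask
    subject_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subject_ids:
            self.subject_ids = self.config.subject_ids()


def _rng(config: SimConfig, subject: int, stream: int) -> np.random.Generator:
    # one independent, reproducible stream per (seed, subject, purpose)
    return np.random.default_rng([config.seed & 0x7FFFFFFF, subject, stream])


def make_network_maps(config: SimConfig) -> np.ndarray:
    """Isotropic Gaussian bump per network, peak exactly 1 at the center voxel.

    Returns flat ``(K, n_voxels)`` maps over the full grid (C order).
    """
    nx, ny, nz = config.grid_dims
    ax = np.arange(nx)[:, None, None]
    ay = np.arange(ny)[None, :, None]
    az = np.arange(nz)[None, None, :]
    maps = np.empty((config.n_networks, config.n_voxels))
    for k in range(config.n_networks):
        cx, cy, cz = config.blob_centers[k]
        sigma_mm = config.blob_fwhm_mm[k] / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        d2 = (
            (ax - cx) ** 2 + (ay - cy) ** 2 + (az - cz) ** 2
        ) * config.voxel_size_mm**2
        maps[k] = np.exp(-d2 / (2.0 * sigma_mm**2)).ravel()
    return maps


def make_timecourses(
    config: SimConfig, subject: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw the subject's ``(T, K)`` node time courses.

    Rows are zero-mean multivariate normal with ``config.node_covariance``.
    Deterministic given ``(config.seed, subject)`` unless an explicit ``rng``
    is supplied.
    """
    if rng is None:
        rng = _rng(config, subject, 0)
    try:
        chol = np.linalg.cholesky(config.node_covariance)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded in config
        raise ValueError("node_covariance is not positive definite") from exc
    z = rng.standard_normal((config.n_timepoints, config.n_networks))
    return z @ chol.T


def _drift(config: SimConfig, subject: int) -> np.ndarray:
    """Slow per-voxel polynomial drift, shared amplitude.  (V, T)."""
    if config.drift_amplitude == 0:
        return np.zeros((config.n_voxels, config.n_timepoints))
    rng = _rng(config, subject, 2)
    t = np.linspace(-1.0, 1.0, config.n_timepoints)
    # Legendre P1..P3: slow trends well below the 0.01 Hz band for short runs
    basis = np.stack([t, 0.5 * (3 * t**2 - 1), 0.5 * (5 * t**3 - 3 * t)])
    coef = rng.standard_normal((config.n_voxels, 3)) / np.sqrt(3.0)
    return config.drift_amplitude * (coef @ basis)


def synthesize_subject(
    truth: SimTruth, config: SimConfig, subject: int
) -> BoldRun:
    """Assemble one subject's 4D run from ground truth."""
    if subject < 0 or subject >= config.n_subjects:
        raise IndexError(f"subject index {subject} out of range")
    group = truth.labels[subject]
    amps = truth.amplitude_factor[group]
    tc = truth.true_timecourses[subject]  # (T, K)
    signal = truth.true_maps.T @ (tc * amps).T  # (V, T)
    data = signal + _drift(config, subject) + config.baseline
    if config.noise_sigma > 0:
        rng = _rng(config, subject, 1)
        data = data + config.noise_sigma * rng.standard_normal(data.shape)
    vol = data.reshape(config.grid_dims + (config.n_timepoints,))
    return BoldRun(
        data=vol,
        affine=_default_affine(config.voxel_size_mm),
        tr_s=config.tr_s,
        voxel_size_mm=np.repeat(config.voxel_size_mm, 3),
        provenance=[f"simulated seed={config.seed} subject={subject} group={group}"],
    )


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Generate the full cohort; pure function of ``config``."""
    maps = make_network_maps(config)
    tcs = [make_timecourses(config, s) for s in range(config.n_subjects)]
    truth = SimTruth(
        true_maps=maps,
        true_timecourses=tcs,
        amplitude_factor=config.amplitude_factor,
        labels=config.group_labels,
        seed=config.seed,
    )
    runs = [synthesize_subject(truth, config, s) for s in range(config.n_subjects)]
    mask = BrainMask(np.ones(config.grid_dims, dtype=bool))
    return SimCohort(config=config, runs=runs, truth=truth, mask=mask)


def write_dataset(cohort: SimCohort, outdir) -> dict:
    """Write the cohort as NIfTI + TSV + JSON files; round-trips losslessly
    within float32 storage precision.  Returns the path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    affine = _default_affine(cfg.voxel_size_mm)
    paths = {"bold": []}
    for sid, run in zip(cohort.subject_ids, cohort.runs):
        p = outdir / f"{sid}_bold.nii.gz"
        write_bold(run, p)
        paths["bold"].append(str(p))
    paths["mask"] = str(outdir / "mask.nii.gz")
    write_volume(cohort.mask.data.astype(np.float32), affine, paths["mask"])
    paths["true_maps"] = str(outdir / "true_maps.nii.gz")
    write_map_stack(
        cohort.truth.true_maps, BrainMask(np.ones(cfg.grid_dims, bool)), affine,
        paths["true_maps"],
    )
    paths["labels"] = str(outdir / "labels.tsv")
    pd.DataFrame(
        {"subject_id": cohort.subject_ids, "group": list(cfg.group_labels)}
    ).to_csv(paths["labels"], sep="\t", index=False)
    paths["truth"] = str(outdir / "truth.json")
    truth_doc = {
        "seed": cfg.seed,
        "tr_s": cfg.tr_s,
        "n_networks": cfg.n_networks,
        "amplitude_factor": {g: a.tolist() for g, a in cfg.amplitude_factor.items()},
        "noise_sigma": cfg.noise_sigma,
        "drift_amplitude": cfg.drift_amplitude,
        "blob_centers": cfg.blob_centers.tolist(),
        "blob_fwhm_mm": cfg.blob_fwhm_mm.tolist(),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_doc, fh, indent=2, sort_keys=True)
    return paths


def load_dataset(outdir):
    """Read back a written dataset.

    Returns ``(runs, mask, labels_frame, truth_dict)``.
    """
    outdir = Path(outdir)
    with open(outdir / "truth.json") as fh:
        truth = json.load(fh)
    labels = pd.read_csv(outdir / "labels.tsv", sep="\t")
    mask = read_mask(outdir / "mask.nii.gz")
    runs = [
        read_bold(outdir / f"{sid}_bold.nii.gz", tr_s=truth["tr_s"])
        for sid in labels["subject_id"]
    ]
    return runs, mask, labels, truth


# ---------------------------------------------------------------------------
# Modular node covariances for the network-matrix studies


def _factor_cov(loadings: np.ndarray) -> np.ndarray:
    """Correlation matrix from a factor-loading matrix with unit total
    variance per node (unique variance fills the remainder)."""
    common = loadings @ loadings.T
    unique = 1.0 - np.diag(common)
    if np.any(unique < -1e-10):
        raise ValueError("factor loadings imply variance > 1")
    cov = common + np.diag(np.clip(unique, 0.0, None))
    # tiny jitter keeps Cholesky happy when unique variance hits 0
    return cov + 1e-9 * np.eye(cov.shape[0])


def modular_covariance(
    module_sizes, within_r: float = 0.6, between_r: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Block-modular node correlation matrix from a one-global + one-factor-
    per-module model.

    Within-module correlation equals ``within_r`` and between-module
    correlation equals ``between_r``.  Returns ``(corr, module_labels)``.
    """
    if not 0 <= between_r < within_r < 1:
        raise ValueError("need 0 <= between_r < within_r < 1")
    sizes = [int(s) for s in module_sizes]
    n = sum(sizes)
    m = len(sizes)
    labels = np.repeat(np.arange(m), sizes)
    load = np.zeros((n, 1 + m))
    load[:, 0] = np.sqrt(between_r)  # global factor
    b = np.sqrt(within_r - between_r)
    for i, mod in enumerate(labels):
        load[i, 1 + mod] = b
    return _factor_cov(load), labels


def dissolved_modular_covariance(
    module_sizes,
    dissolved: int,
    within_r: float = 0.6,
    between_r: float = 0.1,
    coupling_r: float = 0.45,
) -> tuple[np.ndarray, np.ndarray]:
    """Patient-group variant: one module's internal coherence is dissolved.

    The dissolved module's nodes lose their private factor (internal
    correlation drops to the background level) and are instead coupled,
    round-robin, to the remaining modules so that their correlation with the
    absorbing module's nodes is ``coupling_r``.  This is the planted analogue
    of a network cluster being absorbed into the others.
    """
    sizes = [int(s) for s in module_sizes]
    m = len(sizes)
    if not 0 <= dissolved < m:
        raise ValueError("dissolved module index out of range")
    if not between_r < coupling_r < 1:
        raise ValueError("need between_r < coupling_r < 1")
    labels = np.repeat(np.arange(m), sizes)
    n = len(labels)
    load = np.zeros((n, 1 + m))
    load[:, 0] = np.sqrt(between_r)
    b = np.sqrt(within_r - between_r)
    others = [j for j in range(m) if j != dissolved]
    bp = (coupling_r - between_r) / b  # cross-loading on the absorbing factor
    rr = 0
    for i, mod in enumerate(labels):
        if mod != dissolved:
            load[i, 1 + mod] = b
        else:
            target = others[rr % len(others)]
            load[i, 1 + target] = bp
            rr += 1
    return _factor_cov(load), labels


def sample_mvn_timecourses(
    cov: np.ndarray, n_timepoints: int, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean multivariate-normal sample, shape ``(T, K)``."""
    chol = np.linalg.cholesky(np.asarray(cov, dtype=float))
    return rng.standard_normal((int(n_timepoints), cov.shape[0])) @ chol.T
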