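# Methods

## The analysis model

The package targets the standard group-ICA account of resting-state BOLD:
each subject's 4D run is a linear mixture of spatially fixed network maps
with fluctuating time courses plus noise.  Group spatial ICA estimates the
shared maps; dual regression projects them back onto each subject; all
group comparisons are then carried out on subject-level derivatives
(scores, spatial maps, node time courses).  Three readouts are computed:

* a **subject-level RSN score** per component — the mean stage-2
  parameter estimate over the component's thresholded voxels — tested
  between groups with the Kruskal–Wallis rank test;
* a **voxel-wise comparison** of the subject spatial maps under
  max-statistic permutation FWE control, optionally TFCE-enhanced, with
  connected-cluster tabulation;
* **network matrices** (full and partial correlations of the stage-1 node
  time courses), averaged per group on the Fisher-z scale and
  hierarchically clustered by connectivity profile, with a structured
  between-group cluster diff.

Assumptions inherited from this model: spatial stationarity of the maps
across subjects, linear mixing, exchangeability of subjects under the null
(for the permutation and rank tests), and approximate Gaussianity of voxel
noise (only where z maps are interpreted; the group tests are
nonparametric).

## Synthetic cohorts

The generator produces exactly the structure the model assumes:

    y(v,t) = Σ_k a[group,k] · s_k(t) · m_k(v) + drift(v,t) + baseline + ε(v,t)

* `m_k`: isotropic Gaussian bumps, peak 1 at the center voxel, placed on a
  deterministic interior lattice (default FWHM 12 mm on 3 mm voxels);
* `s_k`: zero-mean multivariate normal rows with configurable K×K node
  covariance (identity by default);
* `a[group,k]`: the planted effect — patients carry factor 0.5 on the
  first half of the networks by default;
* `ε`: white Gaussian noise, default σ = 0.5 against unit-variance time
  courses and peak-1 maps (peak SNR 2, a plausible figure for smoothed
  in-network BOLD); chosen once as the reference condition;
* `drift`: per-voxel low-order Legendre polynomials with a shared
  amplitude, off by default, used to exercise the 0.01 Hz high-pass;
* `baseline`: constant intensity offset, zero by default; the pipeline
  runner simulates with baseline 100 so grand-mean scaling is well-posed.

The reference cohort is a 24×24×12 grid of 3 mm voxels, T = 150 at
TR 2.4 s, 6 networks, 10 controls + 10 patients, 3 networks attenuated at
factor 0.5.  Everything is a pure function of the seed (one `default_rng`
stream per subject and purpose), so cohorts, and therefore entire pipeline
runs, are bit-reproducible.

What the generator does **not** emulate: hemodynamic convolution, temporal
autocorrelation, motion and physiological artifacts, subject-specific map
geometry, multi-site effects.  Passing tests therefore demonstrate
correctness of the estimators under the model's own assumptions, not
robustness to the full messiness of scanner data.

For the network-clustering studies a separate factor model builds modular
node covariances (one global factor + one factor per module; within-module
correlation 0.6, background 0.1).  The "dissolved" patient variant removes
one module's private factor and couples its nodes round-robin to the
remaining modules (correlation 0.45 with the absorbing module).  Pure
attenuation of a module's internal correlation would *raise* the cluster
count at a fixed cut height (its nodes become singletons); absorption is
what reduces 4 clusters to 3, matching the phenomenon of a network cluster
being taken up by the others, so the generator plants absorption.

## Parameter conventions and numerical choices

* **Preprocessing order** is fixed (discard → smooth → normalize →
  high-pass) and recorded in each run's provenance.  Smoothing uses
  reflective boundaries (mass preservation on small grids).  The high-pass
  regresses out a discrete-cosine basis containing every frequency
  strictly below the cutoff and retains the temporal mean; with T = 200,
  TR = 2.4 s and 0.01 Hz this is 9 regressors.  Grand-mean target 10000
  (the common FSL convention).
* **PCA/variance normalization**: voxel time series are demeaned per
  subject and divided by their *noise* standard deviation — the residual
  spread after removing the subject's top-d principal components.
  Normalizing by the total standard deviation would flatten within-network
  contrast and visibly degrade map recovery; the noise-std convention is
  the MELODIC-style behavior.  Reduction uses exact SVD up to 800×800 and
  a seeded randomized SVD above.
* **ICA**: fixed-point iteration with log-cosh contrast and symmetric
  decorrelation (scikit-learn's FastICA), tol 1e-6, max 1000 iterations,
  seeded `w_init`; non-convergence is flagged, not raised.  Maps are
  sign-fixed to positive skewness (read as activations) and z-scored over
  in-mask voxels.  Component count is a free parameter; the synthetic
  default is planted K + 2 so artifact rejection is exercised.
* **Thresholding** supports two dialects: voxel-wise two-sided normal p
  with Benjamini–Hochberg at q = 0.05 (default), or a proportional cut
  |z| ≥ level·max|z|.  Both are provided because practice varies; neither
  affects the group tests' validity, only the score mask.
* **Template matching** uses signed Pearson r on unthresholded z maps at
  threshold 0.3; an absolute-value option exists because a sign-fixed IC
  can still anticorrelate with a template.  Retention is
  max-over-templates ≥ threshold; many-to-many matches are reported.
* **Dual regression** handles intercepts by demeaning both sides, which is
  algebraically identical to an explicit intercept column; stage-1 time
  courses are variance-normalized before stage 2 by default (the
  `--des_norm` convention).  This changes score magnitudes, not test
  outcomes, and is exposed as a flag.  The RSN score averages the PE map
  over the component's thresholded mask: an unmasked mean would be
  dominated by out-of-network voxels.
* **Kruskal–Wallis** uses mid-ranks with tie correction.  `exact` mode
  enumerates all label assignments when their count is ≤ 2·10⁵ (always
  the case for N ≤ 10, where exactness matters most) and otherwise
  estimates the permutation p with 20,000 seeded shuffles; `approx` uses
  the χ² reference with G−1 df.  No multiple-testing correction across
  components by default (uncorrected p < .05 is the common reporting
  convention here); a BH option exists.
* **Permutation inference** scores |t| (two-sided default) or a one-sided
  t, optionally TFCE-enhanced (E = 0.5, H = 2, dh = max-stat/100 per map;
  negative values enhanced on the negated map).  Relabelings are
  enumerated exhaustively when C(n, n₁) ≤ n_perm, in which case
  p = #{null max ≥ score}/n_total with the observed labeling included;
  otherwise the (1+b)/(m+1) Monte-Carlo estimator avoids zero p-values.
  Cluster extraction uses 26-connectivity by default (6/18 available).
* **Netmats**: partial correlations come from the inverse covariance;
  ridge defaults to 0 and is auto-escalated with a warning when the
  condition number exceeds 1e8 (hard singularity is an error with
  guidance).  Group averaging happens on the Fisher-z scale (the Jensen
  gap versus averaging r is real and documented by a test).  Clustering
  distance is 1 − corr between netmat rows (connectivity-profile
  similarity), average linkage by default; scipy's nearest-neighbor-chain
  linkage is deterministic.  The between-group cut is a *height*
  calibrated on the control tree (midpoint of the merge gap that yields
  the requested cluster count) and applied to both groups, so counts may
  differ — the readout needed to express cluster dissolution.

## Problem sizes used by the validation suite

The replicated studies run at sizes chosen to finish comfortably on a
single CPU: 20 replicates of the full reference cohort for network
recovery and effect detection; 200 null datasets (6×6×4 grid, 8 vs 8
subjects, 1000 permutations each) for FWE calibration; 20 seeds / 20
replicates for netmat recovery and dissolution; a 16×16×8 cohort for the
end-to-end determinism check.  The acceptance script reruns the same
studies from scratch with seeds derived from its `--seed`.

## Known limitations

* Group ICA is plain temporal concatenation + PCA; no MIGP-style
  incremental reduction, so very large cohorts would need memory care.
* No automatic ICA dimensionality estimation and no mixture-model
  inference on IC maps.
* Permutation designs are limited to two groups (no covariates, no
  sign-flipping one-sample tests); no variance smoothing.
* The Kruskal–Wallis exact mode falls back to Monte-Carlo beyond the
  enumeration limit; the reported p is then an estimate with its own
  (small, seeded) sampling error.
* Partial-correlation ridge regularization is a plain L2 on the
  covariance; no shrinkage-target estimation.
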