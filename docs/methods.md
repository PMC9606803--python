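# Methods

## Pipeline

### Temporal preprocessing

Per subject, on volumes already aligned to a common grid (registration and
spatial normalization are out of scope):

1. drop the first 10 volumes (magnetization equilibrium);
2. framewise displacement (FD) from the 6 rigid-body parameters, Power
   convention: FD₁ = 0, FD_t = Σ|Δtranslation| + r·Σ|Δrotation| with
   r = 50 mm (the standard sphere radius for converting rotations to
   displacement);
3. scrub plan: frames with FD ≥ 0.5 mm are flagged together with the 2
   frames before and 1 after (the keep-criterion is stated as "FD < 0.5",
   so the flag test is ≥; both window sizes are parameters);
4. linear detrend per voxel;
5. OLS regression of 27 nuisance columns: the Friston-24 expansion
   [p_t, p_{t−1}, p_t², p_{t−1}²] of the motion parameters (lag backfilled
   with 0 at the first frame) plus frame-wise white-matter, CSF and global
   means.  Nuisance columns are detrended before fitting; numerically
   collinear columns are dropped with a logged warning.  Global-signal
   regression is on by default and can be disabled;
6. zero-phase band-pass 0.01–0.1 Hz (order-2 Butterworth, forward–backward
   via `sosfiltfilt`; an ideal FFT filter is available by config);
7. scrub interpolation: flagged frames are replaced by linear interpolation
   between the nearest clean frames (nearest-value extension at the edges),
   so the frame count never changes.  Scrubbing is applied after filtering
   by default, treating it as a final motion-cleanup step; a config
   flag moves it before the filter for sensitivity analysis.

A subject-level exclusion helper flags peak motion above one voxel
(max |translation| or 50 mm-scaled |rotation| > minimum voxel size).

### Association mapping

The in-mask voxel series are correlated pairwise (Pearson); the graph has an
edge where r > 0.25 on the signed correlation (an `use_absolute` switch
exists but defaults to off).
Self-correlation is excluded; zero-variance series are treated as never
connected and counted in the log.  N is the degree, K the triangle count
through the voxel computed blockwise as ((A·A)∘A)/2 row sums (block size
bounds memory on large masks; results are integer-exact and verified against
an explicit pair-counting oracle), and Asso = C(N,2) − K.  The subject map
is z-scored within the mask and smoothed with a 6 mm FWHM Gaussian
(σ = FWHM/2√(2 ln 2) per axis in voxel units from the affine).  Smoothing is
applied to the Asso map, never to the BOLD series feeding it.

### Group inference

Voxelwise OLS of the map on intercept + group (patient = 1) + mean-centred
age, sex (M = 1) and education; the group coefficient's t with df = n − p.
Clusters form at the two-sided voxel p < 0.001 t-quantile, positive and
negative tails labelled separately, 18-connectivity by default (6 and 26 by
config).  Cluster-level correction is a group-label permutation
max-cluster-extent procedure (covariates stay attached to their subjects;
the max is taken over both tails), with the Monte-Carlo estimator
p = (1 + #{perm max ≥ extent})/(n_perm + 1).  Permutation was chosen as the assumption-light default; its numbers need
not match a GRF- or AlphaSim-style parametric correction.

### Seed FC branch

The FC branch re-preprocesses from the volume-dropped data in the order
conventional for seed connectivity: smooth the volumes (6 mm) first, then
detrend/regress/filter.  The seed is the full patient-deficit cluster by
default (a peak-centred sphere is available by option).  FC is the Pearson correlation of each in-mask voxel with the
seed-mean series, Fisher z-transformed with r clipped to ±(1 − 1e−7).

### Biomarker evaluation

Features are cluster means (Asso-z in the deficit cluster, FC-z in each
coupling cluster).  Leave-one-out linear SVM (C = 1), features standardized
on each training fold only, patient group positive; accuracy, sensitivity
and specificity from pooled held-out predictions and AUC from held-out
decision values via the Mann–Whitney formulation.  Defining clusters on the
full sample and then cross-validating is circular; the default reproduces
that design, and `experiments.nested_loocv_svm` re-estimates the clusters
inside every training fold for an honest figure (analysis/05 reports both).
Correlations are Pearson r of each feature with MMSE and MoCA,
Benjamini–Hochberg corrected over the full family of tested pairs.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, not
fMRI physics.  On a 12³ grid (3 mm voxels), eight 3³ cuboid regions sit at
the corners of a 10³ brain box; small central cubes act as WM/CSF masks.
Each subject's BOLD is built from standardized AR(1) latents (φ = 0.3):

- the **hub region** carries its own latent *h*;
- every other region loads on *h* (weight √m, m = `hub_coupling` = 0.3)
  and on a **coupling factor** *g* (weight √c, c = the subject's
  neighbour-coupling level), both with sign-balanced loadings across
  regions (anticorrelated-network style) so that neither factor dominates
  the global mean — planted structure must survive global-signal
  regression, which removes whatever resembles the global average;
- the two **DMN stand-ins** load *negatively* on *h* (task-negative
  anticorrelation), so they are never part of the hub's neighbour set;
- voxels load on their region latent with √base_r (base_r = 0.8, the
  within-region voxel correlation), plus AR(1) noise and white measurement
  noise (`noise_sd` = 0.2), scaled to BOLD-like units (1000 ± 50).

Patient severity is the subject's realized neighbour coupling above the
control level, scaled by a fixed constant (0.45) so the default patient
level (c = 0.5 vs 0.05, jitter SD 0.06) maps to severity ≈ 1.  Severity
simultaneously (i) raises cross-region coupling — same-sign region pairs
become interconnected, inflating K — and (ii) scales down the non-DMN
regions' hub loading (`hub_coupling_drop_ad` = 0.9), collapsing the hub's N.
Both act in the planted direction (patient hub Asso down), and expected hub
Asso is monotone decreasing in the patient coupling level.  In patients an
extra latent *d* is mixed into the hub and the DMN regions
(`seed_fc_gain_ad` = 0.8 at severity 1), lifting hub→DMN FC from
anticorrelated toward positive — the planted FC increase — without ever
adding the DMN to the hub's supra-threshold neighbours, which keeps the two
planted effects separable.  MMSE/MoCA are decreasing linear functions of
severity anchored at 28.24→21.3 and 26.95→16.92 with rounding, clipping to
0–30 and noise SD 1.3; age/education are drawn from group-matched normals;
sex is Bernoulli(0.5) independent of group.  Motion is a small random-walk
drift plus Bernoulli spikes (rate 0.03, 1 mm) that exceed the scrub
threshold.  The null generator forces both couplings equal and the FC gain
to zero and randomly permutes the group labels.

Planted effect sizes are configuration, not claims: the defaults were
calibrated once for desk-scale power ≈ 0.9 at n = 20+20 — no published
effect-size estimate exists for the Asso group difference — and then
frozen.

**What the generator does not emulate** — hemodynamic response shape,
physiological (cardiac/respiratory) noise, spatial autocorrelation of noise,
anatomical geometry, registration error, scanner drift beyond a linear
trend.  Passing tests therefore demonstrate that the pipeline recovers the
planted graph/coupling structure under realistic temporal preprocessing,
not that it would behave identically on acquired data.

## Numerical choices

- Fisher z clip ε = 1e−7 at |r| = 1 (atanh(1 − 1e−7) = 8.406).
- Correlations are computed on the full-length scrub-interpolated series;
  no frame deletion.
- K via float64 block matmul, rounded to integer; exact for any realistic
  mask size (counts ≪ 2⁵³).
- Permutations are Monte-Carlo with the +1 estimator (p > 0 always); fixed
  seeds make every run bit-reproducible.
- Degenerate inputs fail loudly: empty masks, constant seed series,
  all-flagged scrub plans, rank-deficient designs, K > C(N,2).
- Chi-square is Pearson's without continuity correction by default (Yates
  behind a flag).

## Validation study

`tests/test_acceptance.py` and `scripts/acceptance.py` run the same
experiments through the package: exact equality of the Asso computation
with a brute-force pair counter on 50 random instances (≤ 200 voxels,
t = 100); closed-form graph cases (cliques, stars, single-edge
perturbations); familywise error over 20 null cohorts ≤ 0.05 + 2 binomial
SE (n_perm = 200); recovery of both planted effects in ≥ 90% of 10 planted
cohorts; LOOCV sanity (100% on margin-verified separable features, chance
on label-independent features); the confusion-matrix arithmetic of a 36/42
cohort; and correlation-direction recovery in ≥ 95% of 20 planted cohorts.
Monte-Carlo sizes (20 cohorts, n_perm = 200, 12³ grids) are the study's
chosen desk-scale conditions.

## Known limitations and notes

- The reference demographic table prints p = 0.097 for both gender and
  age; recomputing from its printed summaries gives ≈ 0.099 for age
  (pooled t) and ≈ 0.074 (uncorrected) / ≈ 0.119 (Yates) for the gender
  chi-square from the printed counts.  The discrepancy is documented here
  and those two rows are not used as test expectations.
- The association statistic is threshold-dependent in practice; r = 0.25 is
  exposed as a parameter and no threshold-freeness is claimed.
- With ~40 effective degrees of freedom after band-pass filtering
  (0.09 Hz × 220 s), sample correlations have SD ≈ 0.15; neighbour counts
  flicker at block level near the threshold, which is the dominant noise
  source in the Asso maps.  This is intrinsic to the statistic at this
  series length, not an implementation artifact.
- The permutation correction controls familywise error per analysis; the
  two branches (Asso, FC) are corrected separately.
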