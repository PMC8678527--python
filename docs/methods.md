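# Methods

## The problem

Resting-state fMRI network analysis conventionally thresholds each
independent component's spatial map and studies only the supra-threshold
voxels — the *activation network* (AN). The complementary, sub-threshold
portion of the same component — here called the *relatively inert network*
(RIN) — is usually discarded, although it covers most of the brain and can
carry weak or spatially diffuse signal of its own. This package implements
the full analysis chain needed to study both halves: network estimation,
AN/RIN splitting with separately estimated time courses, connectivity
statistics over the doubled network set, and a classification benchmark
that measures whether RIN connectivity adds diagnostic information.

## Models and procedures

### Generative model (simulator)

Subject data follow the linear spatial-ICA model `X = A S + E`, with `X`
the `n_time x n_voxels` data matrix, `S` the spatial sources, `A` the
mixing (time-course) matrix, and `E` i.i.d. Gaussian noise of standard
deviation `noise_sd`. Each source is a spherical blob: an inner core of
radius `core_radius` at `core_amplitude` (the true AN) surrounded by a halo
shell out to `halo_radius` at `halo_amplitude` (the true RIN). Blob centres
occupy distinct cells of side `ceil(2*halo_radius)` so halos never overlap;
a grid too small for the requested source count is a configuration error.

Time courses are standard normal with a prescribed correlation matrix per
group, imposed by an eigenvalue factorisation (valid for any positive
semidefinite target, which is checked). Two layouts exist:

* **unpaired** (`group_fnc` side `n_sources`): one time course drives the
  whole blob. Used for decomposition benchmarks, where each blob must be
  one identifiable source.
* **paired** (side `2*n_sources`, cores then halos): core and halo carry
  separate time courses coupled at `coupling` (default 0.6). This is the
  layout in which group differences can be planted selectively on
  halo-involving (RIN) edges while leaving core (AN) correlations intact.
  The default coupling is deliberately moderate: strong coupling (0.9)
  makes many planted-edge configurations infeasible, because a correlation
  matrix with a tightly coupled pair cannot also hold an independent 0.6
  edge into one member of the pair. Planted edges on disjoint source pairs
  at 0.6 remain feasible at coupling 0.6.

An optional order-1 autoregressive filter (`ar_coeff`, default off) adds
BOLD-like temporal smoothness; it is applied before the correlation
shaping's factor is multiplied in and each row is restandardised, so
zero-lag cross-correlations — the quantity all downstream statistics use —
are unchanged and the Pearson oracle stays exact.

Defaults (`core_amplitude 4`, `halo_amplitude 1`, `noise_sd 0.2`, 150
volumes at TR 2 s, 8 sources) give a component z-map in which core voxels
sit near z = 6 and halo voxels near z = 1.3, so the default threshold
mu = 3 cleanly assigns cores to the AN and halos to the RIN — matching the
situation the method is designed for, where thresholding a z-scored map
separates a strong focal response from its weak surround.

What the simulator does **not** emulate: hemodynamic response convolution,
physiological (cardiac/respiratory) noise, motion artifacts, spatial
autocorrelation of noise, inter-subject anatomical variability beyond the
controlled map perturbation of the guided cohort. Passing tests therefore
demonstrate algorithmic correctness and statistical calibration under the
linear mixing model, not robustness to real-scanner confounds.

### Group ICA

Temporal-concatenation group ICA: per-subject PCA to `subject_k`
dimensions (default `ceil(1.5 * n_components)`), stacking along the reduced
time axis, group PCA to `n_components`, whitening, then Infomax ICA. Model
order can be estimated by the classical eigenvalue MDL criterion on the
temporal covariance (argmin over k of
`-N (p-k) log(geometric/arithmetic mean of trailing eigenvalues) +
0.5 k (2p-k) log N`); the i.i.d.-sample assumption behind this form is
noted — spatially smoothed data violate it and push the estimate up, but
the package's inputs may be unsmoothed synthetics, so no dependence
correction is applied.

Infomax uses the natural-gradient update with the extended kurtosis-sign
switch (`I - K tanh(u) u' - u u'`), so both super- and sub-Gaussian sources
are recoverable; the learning rate is halved on divergence and gently
annealed on oscillation, a schedule chosen because the update itself does
not prescribe one. Component sign is normalised to positive skewness
(activation blobs point upward). Stability follows the ICASSO recipe:
20 restarts from random orthogonal initialisations, pooling all components,
average-linkage clustering on `1 - |spatial correlation|`, cutting at
`n_components`, reporting each cluster's centrotype and a stability index
(mean intra-cluster minus mean extra-cluster similarity). The full
ICASSO visualisation toolkit is out of scope.

### Reference-guided subject ICA

Each subject component maximises
`F(w) = a * K(w) + (1-a) * C(w)` over unit-norm `w`, where
`Q(w) = (E[G(Y)] - E[G(z)])^2` is the negentropy proxy of `Y = w' X~`
(`X~` the subject data whitened to the reference count),
`K = (2/pi) * arctan(Q)` its squashed form, and `C = E[Y R]` the
correlation with the group reference. Numerical choices:

* contrast `G`: log-cosh by default (kurtosis available), with the
  Gaussian constant `E[G(z)]` computed once by adaptive quadrature
  (0.374567 for log-cosh);
* `K` maps `[0, inf)` to `[0, 1)` so both objectives share a scale; the
  `2/pi` factor is this package's normalisation choice;
* `a = 0.5` by default — the weighting is an empirical knob, and equal
  weighting is the neutral default;
* projected gradient ascent (analytic gradient, verified against finite
  differences in the tests) with backtracking line search, so the accepted
  objective trace is non-decreasing by construction; initialisation from
  the reference's projection onto the whitened data; convergence when the
  objective gain falls below `tol = 1e-9` or after `max_iter = 500`;
* components are estimated one at a time with no deflation, faithful to
  the per-component objective; if two components converge onto the same
  source (pairwise |r| > 0.95) this is reported, not repaired;
* each run is re-whitened to the number of references before optimisation;
* the final map is oriented to correlate positively with its reference and
  z-scored.

Constrained ICA for independent test subjects — references supplied
externally, no group decomposition — is the same function by construction
(`cica_subject is gig_ica_subject`).

The component time course is `T = (1/V) sum_v y_v f_v`: the voxel-mean
BOLD series weighted by the z-scored map, over **all** in-mask voxels.

### Component screening

Three steps, each configurable: (1) tissue screen — exclude components
whose white-matter or CSF correlation exceeds their gray-matter
correlation, or whose gray-matter correlation falls below 0.05 (the
cutoffs are this package's defaults; no canonical values exist);
(2) spectral screen — low/high power ratio of the periodogram around
0.10 Hz must exceed 10, reflecting the low-frequency character of BOLD
networks; a near-zero high band is reported as a capped ratio of 1e12;
(3) template matching — optimal linear assignment maximising total
absolute spatial correlation with the reference network set on raw
(unthresholded) z-maps, replacing visual inspection with a printed
correlation report; negatively matched candidates are sign-flipped. Peak
coordinates report the maximum positive value (activation peak), ties
broken at the lowest linear index.

### AN/RIN splitting

`d_v = 1` iff the statistic strictly exceeds `mu` (values equal to `mu`
fall in the RIN); `mu = 3` by default, swept over {1, 2, 3, 4}. The
statistic is either each subject's component z-map (`subject_z`, default
for feature extraction — usable on unlabelled new subjects) or the group
one-sample t-map over subject z-values (`group_t`, default for group
difference analyses, one mask per group). Split time courses are

    T_act = (1/Va) sum_v y_v d_v f_v
    T_ine = (1/Ve) sum_v y_v (1 - d_v) f_v

so `Va*T_act + Ve*T_ine = V*T_full` exactly — the decomposition identity
the suite asserts at 1e-10 relative error for every subject, component and
mu. An empty side yields a zero time course plus an explicit emptiness
flag; downstream connectivity treats flagged sides as missing, never as
zeros (large mu can empty an AN in real data). Zero-variance voxels in
t-maps are capped at |t| = 1e6 with a warning.

Group difference maps label a voxel +1 (hot) where group A is activated
and group B inert, -1 (cold) for the converse, and require the voxelwise
two-sample Welch t-test on the raw subject z-values (not the binarised
activation states — the raw values carry more information) to reach
`p < alpha` (default 0.05, voxelwise; cluster-extent correction is out of
scope).

### FNC statistics

Per subject, Pearson correlations between network time courses:
`all` mode interleaves RIN/AN per network (16 x 16 for 8 networks),
`act`/`inert`/`original` are 8 x 8. Group comparison: per unique
off-diagonal element, Fisher z-transform (default on — standard practice
for correlations, with a flag to disable for literal replication), Welch
two-sample t-test (pooled-variance optional), Benjamini–Hochberg FDR over
the tested family (120 unique elements for 16 x 16, 28 for 8 x 8; missing
rows excluded from the family, the diagonal never tested). Alteration
counts tally significant edges per network row, split by direction.

### Classification

Strategies `OriginalFNC` / `ActFNC` / `InertFNC` / `AllFNC` vectorise the
unique off-diagonal elements (28 / 28 / 28 / 120 features; edges touching
any subject's missing network dropped cohort-wide). Per stratified 70/30
split: gradient-boosted-tree (XGBoost) total-gain importance ranks
features on the training rows, the top k = 20 (the retained count is a
package default; ties broken by stable feature order) feed a linear SVM
(RBF available) whose C is chosen from {0.01, 0.1, 1, 10, 100} by 10-fold
CV on the training rows; standardisation statistics also come from
training rows only — a leakage test asserts test rows never influence the
model. Feature selection runs once per training split, not per CV fold
(a replication caveat: per-fold refitting is stricter but the protocol
does not require it). Performance distributions use 100 repeated splits
with seeds 0..99; significance uses label permutation, reported
separately — repeated splitting and permutation answer different
questions and are kept distinct. McNemar's test on two strategies'
predictions uses the continuity-corrected statistic
`(|b-c|-1)^2/(b+c)` with an exact binomial p-value when `b + c < 25`.
The single-feature screen evaluates each edge alone over 20 splits and
flags mean F1 above 0.65.

## Validation studies and problem sizes

`rinan.validation` (driven by `scripts/acceptance.py` and
`tests/test_acceptance.py`) runs each study at sizes chosen to finish in
minutes on one CPU:

* decomposition identity: 20 subjects x 8 components x mu in {1..4},
  noisy cohort, worst-case relative error (also the monotonicity count);
* group ICA recovery: noiseless 8-source cohort, 10 subjects, 150 time
  points, 10x10x10 grid, 20 ICASSO restarts;
* guided recovery: 10 subjects, maps perturbed to r = 0.8, noise 0.2;
* FDR calibration: 100 replicate null cohorts, 20 subjects/group, with
  splitting performed on the known (z-scored true) source maps so the
  replicate loop exercises the statistical machinery rather than repeating
  the ICA estimation 100 times;
* planted-edge power: 50 replicates, 30 subjects/group, one core-to-halo
  edge at 0.6 vs 0.0, same splitting shortcut;
* RIN feature advantage: one full pipeline run (group ICA, guided subject
  ICA, subject-z splitting) on a 30-per-group cohort with differences
  planted only on halo-halo edges, then 100 repeated-split evaluations of
  all four strategies.

## Known limitations

* The simulator's sources are compact spheres on a full-grid "brain";
  real network maps are distributed and overlapping, and real masks are
  irregular (irregular masks are supported, just not emulated).
* In the paired layout, a component's RIN time course picks up small
  contributions from other sources' cores (they lie in its RIN with
  slightly negative z-weights); effects planted at 0.6 dominate this
  cross-talk, but much weaker planted effects would not.
* MDL assumes i.i.d. voxel samples; on spatially smoothed data the order
  estimate inflates.
* One-at-a-time guided estimation with no deflation can return duplicate
  components when references are highly similar; this is detected and
  reported only.
* The classification protocol fits feature selection once per training
  split (see above), and hyperparameter search covers only the SVM's C.
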