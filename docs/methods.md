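# Methods

## Problem setting

A 64-contact extraneural cuff stimulates a peripheral nerve in one
*electrode configuration* at a time (TIS: two sinusoid pairs; biphasic:
bipolar pair or tripolar trio), typically 5 s ON followed by 5 s OFF, while
a 60 fps camera records the limb and a pose-estimation network tracks ten
hindlimb keypoints (hip, knee, ankle, heel, instep, toes 1–5) with a
per-frame confidence.  The analysis asks two questions: do distinct
configurations evoke distinct movements (selectivity), and how varied is
the evoked movement repertoire (diversity)?

## Preprocessing

* Cells with likelihood strictly below 0.5 are masked.  "Interpolating
  across time using the median" is implemented as whole-trial per-keypoint
  median replacement of masked x and y — the simplest reading; a centered
  rolling-median variant is available behind the `window` parameter.
* Flattening maps (x, y) to the Euclidean magnitude per keypoint.  The
  default origin is the image origin (the literal norm of the coordinates);
  a hip-anchored option measures limb-intrinsic geometry instead.  The
  output is the T×10 position matrix.
* Columns are z-scored with the population (ddof = 0) SD; stored
  means/SDs allow exact inversion.  Zero-variance columns are an error.
* Movement gate: per-frame speed is the Euclidean frame-to-frame
  displacement of the *unstandardized* magnitudes × fps, smoothed with a
  centered 0.25 s rolling mean.  The rest baseline is the smoothed-speed
  distribution over the settled tail (last half) of each OFF epoch, so the
  post-stimulation relaxation transient does not inflate it; a
  configuration is retained iff the peak smoothed speed of at least one of
  its ON epochs exceeds baseline mean + k·SD with k = 3 by default (a
  standard detection threshold; the threshold actually used on the in-vivo
  recordings is not published).  Peak rather than mean speed is compared
  because evoked movements can be transient — a limb that jerks and then
  holds a contracted pose has moved, even though its epoch-average speed is
  near rest.  Whether speed was computed on raw or standardized values is
  likewise unpublished; raw preserves px/s units.
* Epochs are half-open [start, stop) with 0-based frame indexing.

## Clustering arm

UMAP (3 components) followed by HDBSCAN, per animal.  Published presets:
biphasic n_neighbors = 50, min_dist = 0, min_cluster_size = 30,
min_samples = 5, cluster_selection_epsilon = 1; TIS n_neighbors = 177,
min_cluster_size = 128, min_samples = 300 (min_samples > min_cluster_size
is unusual but reproduced as printed).  A "custom" profile
(n_neighbors = 30, min_cluster_size = 30, min_samples = 5) is sized for
synthetic trials of a few thousand frames, since the printed presets are
tuned to in-vivo trial sizes.  The embedding seed defaults to 42 and makes
runs reproducible on a fixed platform.

Agreement between cluster labels and configuration labels uses adjusted
mutual information with the arithmetic-mean normalizer and natural
logarithms (AMI is base-invariant).  Frames labeled noise (−1) by HDBSCAN
are excluded before scoring; when both labelings are single-class AMI is
defined as 1.  When multiple subjects are analyzed, AMI is computed per
subject and then averaged.

Null controls:

* **row_shuffle** permutes frame rows while epoch tags stay attached to
  frame indices, destroying the configuration↔dynamics correspondence
  exactly; on the synthetic selective regime AMI collapses from ≈0.96 to
  ≈0.
* **gaussian_noise** adds N(0, (σ·column SD)²) per column (default
  multiplier 1.0).  At desk scale a caveat applies: a synthetic regime
  clean enough to cluster has a between-configuration separation of
  several per-column SDs spread over 10 correlated columns, and σ = 1
  per-column noise degrades but cannot abolish that structure (measured:
  0.96 → 0.67).  The abolition property is therefore demonstrated in the
  noise-dominated regime, σ = 6 (noise variance 36× the data variance),
  where AMI falls below 0.05.  On in-vivo data, where separability is far
  weaker, moderate noise suffices — the σ needed to abolish is a function
  of how separable the data are, which is exactly what the control probes.

Hyperparameter search is a plain grid evaluation over caller-supplied
settings scored by silhouette, AMI, or their combination
(mean of AMI and silhouette rescaled to [0, 1]).

## Syllable arm: sticky AR-HMM

A weak-limit finite sticky HMM with VAR(ar_order) emissions in a
3-dimensional latent obtained by projecting the flattened keypoint
coordinates onto principal components (unit-variance scaled).  Defaults:
K_max = 20 states, ar_order = 3; both are unpublished in the source
protocol ("varied depending on the number and quality of syllables") and
are declared, not inferred.  Parameter estimation follows the two-phase
protocol: an AR-only phase (50 iterations, κ = 1e9) and a full phase
(500 iterations, κ = 1e8).  Each iteration is a blocked update:
forward-filter backward-sample of the state sequence, closed-form
ridge-regularized least squares for per-state AR coefficients and
innovation covariances (states with fewer frames than parameters keep
their previous values), and a MAP transition update with κ added to the
diagonal pseudocounts.  The reported sequence is a deterministic Viterbi
decode, so a fixed seed reproduces output exactly.  States are relabeled
by descending usage; empty states vanish and syllables occupying < 0.5% of
frames are excluded from reports (threshold exposed).  Fitting is
per trial.

Syllable trajectory vectors average the flattened keypoint coordinates
over a 30-frame (0.5 s) window from each bout onset, truncated at bout
end; syllable similarity is the pairwise cosine distance with
average-linkage dendrograms (taller merges = more distinct syllables).

Numerical notes: the forward pass uses per-step normalization (no log-sum
in the inner loop); innovation covariances carry a 1e-6 jitter;
transition probabilities are floored at 1e-300 before logs in the Viterbi
pass; κ values up to 1e300 are handled (the infinite-stickiness limit
decodes a single syllable).

## Selectivity score and group statistics

For configuration *i*, syllable proportions p_ij are computed over its
retained ON frames (frame-based by default; bout-onset counting behind
`by_bout`).  N is the total number of distinct syllables across all
configurations of the trial.  H_i = −Σ p_ij ln p_ij with 0·ln 0 = 0 and
Selectivity_i = 1 − H_i/ln N; the score is invariant to syllable
relabeling and logarithm base, anti-monotone in entropy, and N = 1 is
guarded (score 1 with a warning).

* **Bootstrap**: B = 1000 resamples of size m = 100 with replacement per
  group; mean of resample means, 2.5/97.5 percentile CI, pairwise overlap
  flag.
* **Beta regression**: y ~ Beta(μφ, (1−μ)φ) with logit(μ) = Xβ and scalar
  log-parameterized φ, maximized with BFGS (Nelder–Mead fallback) via
  statsmodels' generic-likelihood scaffolding; Wald SEs and p-values from
  the numerical Hessian.  Scores are compressed off the boundary with
  y′ = (y(n−1) + 0.5)/n before fitting (the source protocol does not say
  how boundary scores were handled).  Categorical predictors are
  dummy-coded against a reference level; numeric columns with many levels
  pass through, so hundreds of configuration labels can be coarsened by
  the caller.  log φ is capped at 30 (near-degenerate samples otherwise
  send the precision toward infinity and stall the optimizer), and a fully
  degenerate sample (all scores identical) short-circuits to the exact
  solution — the mean model fit by least squares on the logit scale,
  unbounded precision, no standard errors — with a warning.
  The implementation agrees with an independent reference fit on fixtures
  to ~1e-4 (see the test suite).
* **Nonparametric**: two-sided tie-corrected Mann–Whitney U; Cohen's d
  with the pooled SD (no small-sample correction); Cliff's delta
  via sorted-array rank counting, identical to brute-force pair
  enumeration.

## Synthetic data generator

Each movement motif is a stable order-1 VAR in the 3-D latent
(z_{t+1} = A z_t + d + ε, spectral radius < 1, damped-oscillation
eigenstructure), emitted through a shared linear map as keypoint offsets
around a hindlimb-arc rest pose.  Motif stationary poses sit at unit-norm,
well-spread latent directions (golden-angle spiral under a seeded random
rotation) so distinct motifs are distinct movements by construction; the
emission is scaled so a unit latent displaces keypoints by ~45 px RMS —
the scale of visible stimulation-evoked limb movement against ~2 px
tracking noise.  The within-motif wobble (latent noise SD 0.1, i.e. ~10%
of the displacement) represents trial-to-trial movement variability.  ON
epochs run the motif recursion from rest; OFF epochs decay the emitted
offset exponentially with a 0.25 s time constant, giving the velocity gap
the movement gate needs.  Dropout cells (2% by default) receive a
likelihood drawn in [0, 0.5) and a uniform coordinate jump up to 20× the
tracking-noise SD, exercising the erroneous-jump filter.

Regimes: *selective* assigns one motif per configuration (injective), with
stationary poses well spread over the latent sphere; *non-selective* maps
all configurations round-robin onto 2 shared motifs whose directions lie
in a narrow cone (unit base direction + SD-0.35 jitter, renormalized) —
non-selective stimulation evokes variations of the same gross movement,
which is what makes its movement repertoire less diverse, not merely
fewer in number.
The generator emulates keypoint kinematics, confidence dropouts and
tracking noise; it does **not** emulate camera geometry, limb-segment
rigid-body constraints, spontaneous (non-evoked) behavior, inter-subject
anatomical variability, or electrode-impedance drift.  Passing tests
therefore demonstrate that the pipeline recovers known structure under
realistic noise, not that in-vivo effect sizes are reproduced; the
published in-vivo values (AMI 0.63 vs 0.36, bootstrap means 0.7854 vs
0.6294, β = 2.75, d = 0.512, δ = 0.270, 0.34 mm tracking error) depend on
recordings that are not redistributable and serve only as directional
references.  Note the synthetic contrast is direction-consistent but
compressed (e.g. mean selectivity ≈ 0.99 vs ≈ 0.94 across regimes): with
only two shared motifs the non-selective regime still maps each
configuration to *one* motif, so its per-configuration entropy stays low.

## Problem sizes used in the shipped studies

The test suite and demo pipeline run reduced problem sizes chosen to keep
a full run on a single CPU short while leaving every statistical
conclusion unchanged: the end-to-end contrast uses 10 subjects × 10
configurations per regime (~100 configuration scores per regime, the same
order as the published group sizes after bootstrap), AR-HMM fits use
10 + 50–60 iterations (convergence on the synthetic trials is reached
within ~20 sweeps; the 50 + 500 protocol defaults remain the function
defaults), and the calibration study uses 500 replicates of n = 120.

## Configuration space and waveforms

The 64 channels are abstracted as a logical 8×8 grid (consistent with the
stride-8 labeling 8(A−1)+B); the physical two-column cuff pitches
(0.4 mm / 1.2 mm, 0.6 mm mid-column gap) are metadata.  Sweeps are
deterministic and duplicate-free: TIS pairs one contact apart with a
configurable pair-B row skip (default every other row — the exact skip
pattern behind the published count of 128 automated configurations is not
printed, so that count is not asserted); bipolar skip-one; tripolar trios
two contacts apart, transverse (row-wise) or longitudinal (column-wise).
Faulty channels remove exactly the configurations containing them.

The TIS envelope is estimated as the dominant non-DC spectral peak of the
analytic-signal magnitude (Hilbert transform), resolution one FFT bin.
Charge accounting: biphasic Q = I·pw per phase; sinusoid Q = I_peak/(πf)
per half-carrier cycle; density Q/area; Shannon k = log₁₀D + log₁₀Q.  The
electrode area that reconciles the published densities with the published
currents (≈1.6×10⁻³ cm²) is back-derived, not a datasheet value, and ships
as a clearly marked constant.

## Known limitations

* The sticky AR-HMM is a weak-limit finite approximation; it does not
  implement the hierarchical-Dirichlet machinery, keypoint-noise model or
  centroid/heading variables of full keypoint motion-sequencing.
* UMAP reproducibility is platform-fixed (seeded single-threaded runs),
  not platform-independent.
* Beta regression treats precision φ as a scalar; variable-dispersion
  models are out of scope.
* The movement gate assumes OFF epochs exist and are rest-like; recordings
  with continuous spontaneous movement would need a different baseline.
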