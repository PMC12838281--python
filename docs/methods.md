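# Methods

This note records the models implemented in `blendeeg`, the parameter
choices that matter, and what the synthetic benchmarks do and do not
establish.

## Synthetic cohort model

`generate_synthetic_cohort` emulates a small resting-state EEG cohort:
36 subjects, 3 severity classes, multi-channel recordings at 250 Hz with
eyes-open/eyes-closed tags.  Each channel signal is

* a sum of band-limited oscillations — three sinusoids with random
  in-band frequencies and phases per band, over the conventional delta
  (1–4 Hz), theta (4–8), alpha (8–13) and beta (13–30 Hz) bands plus any
  custom bands named in the class effects;
* scaled per band by √(class factor), so band *power* scales by the
  factor; the default effect is a graded alpha-band factor of
  1.0 / 1.6 / 2.4 across the three classes, the kind of resting-state
  band-power biomarker the pipeline is designed to detect;
* a multiplicative subject-level amplitude jitter (log-normal, σ = 0.1)
  so subjects within a class are not identical;
* plus 1/f-shaped broadband noise (σ = 1.0) from spectral shaping of
  white noise.

All randomness flows through one `numpy` generator seeded from the spec;
identical specs give bit-identical cohorts.

What the generator does **not** emulate: eye-blink/EMG artifacts, volume
conduction and channel covariance, non-stationarity, or any
phase/connectivity structure.  Passing tests therefore demonstrate that
the pipeline detects planted band-power differences under its stated
protocol — not that it would reach comparable accuracy on clinical
recordings.

Epoching uses 2-s windows without overlap by default; epochs inherit the
subject's label.  Eyes-open and eyes-closed segments are tagged but
pooled by default, since nothing in the protocol requires separating
them.

### Cross-validation granularity

The evaluation protocol is stratified 10-fold CV at **epoch level**, with
feature selection refitted inside every training fold.  Because epochs
inherit subject labels, epoch-level folds can place epochs of the same
subject on both sides of the split; the subject-level amplitude jitter
then acts as a leakage channel that inflates absolute accuracy.  This is
a faithful rendering of the common (and criticized) epoch-level protocol;
`cross_validate(..., grouped=True)` provides the stricter subject-grouped
alternative.  The label-permuted control is run at epoch level too and
sits at chance, confirming that the *pipeline machinery* does not leak —
the leakage is a property of the protocol, not of the implementation.

## Feature families

* **Statistical** (5 per channel): average power `E[v²]`, population
  standard deviation, kurtosis (plain standardized fourth moment, 3 for
  a Gaussian), skewness, mean absolute value.  Zero-variance input
  returns kurtosis = skewness = 0 with a degenerate flag.  The population
  (not sample) divisor is recorded in the matrix metadata.
* **Wavelet** (5 × 5 per channel): the same descriptors on the D1–D4
  detail subbands and A4 approximation of a db4 DWT with symmetric
  padding.  Level 4 at 250 Hz is chosen so the subbands bracket the
  clinical bands (D4 ≈ 7.8–15.6 Hz covers alpha); the decomposition depth
  and boundary mode are package choices, as is per-channel (rather than
  pooled) layout.
* **FCM** (2C per epoch): fuzzy C-means with fuzziness g = 2, tol 1e-6,
  max 300 iterations, centers initialized from random distinct rows
  (jittered if coincident), fitted on the z-scored wavelet-feature
  matrix; the feature vector is the C memberships plus the C Euclidean
  distances to the centers, with C = 3 (one cluster per severity class).
  "FCM as a feature extractor" is under-specified in the literature this
  follows; membership + distance is one defensible construction and is
  isolated behind `build_feature_matrix(family="fcm")`.

The FCM center update uses the standard fuzziness-weighted form
`C_z = Σ q^g a / Σ q^g`; this is the update that makes the objective
provably non-increasing (asserted for every fit).

## Feature selection

All selectors return a binary mask over features; ranks break ties by
ascending feature index, so every selector is deterministic given its
seed.

**Filters.**  One-way ANOVA F, |Pearson r| against the numeric class
code, and plug-in mutual information on 10-bin equal-frequency
discretized features (constant features score 0).  FCCT computes the
feature–feature Spearman matrix, clusters on distance 1 − |ρ| with
average linkage, cuts at a threshold (default 0.5) and keeps the
highest-F member per cluster.  Note a structural property: if a planted
set of informative features is mutually correlated *through the label*
(|ρ| ≈ 0.73 at class separation 2), a 0.5 cut merges them and exactly one
survives — collinearity removal working as designed.  Recovering such a
set requires a cut below 1 − |ρ_within|; the recovery benchmark therefore
runs FCCT at 0.2.

**HFS-MVS.**  Five base rankers behind one contract — CFS merit
(class correlation penalized by mean redundancy), L1 logistic
coefficients at a regularization bisected to ≈k nonzeros, Relief-F
(5 neighbours, prior-weighted misses), LLCFS (iterative local-learning
weights on a kNN graph, Laplacian-smoothness criterion) and UDFS
(L2,1-regularized discriminative scores via iteratively reweighted
eigen-decomposition of the graph quadratic form).  LLCFS and UDFS are
small-scale formulations of their canonical algorithms, treated as
interchangeable rankers.  Each nominates its top-k; a feature is kept
when nominated by ≥ 3 of 5 (majority), with a max-vote fallback so the
mask is never empty.

**Wrappers.**  The shared fitness is `γ·Err(P) + β·|P|/J` with γ = 0.99,
β = 0.01 (the γ + β = 1 convention; the error term dominates and the size
term breaks ties toward smaller subsets).  Err is 3-fold stratified
5-NN error with per-fold z-scoring — cheap enough to evaluate hundreds of
masks, and cached by mask so revisited subsets are free.

* *GWO*: agents move to the mean of three attraction points around the
  α/β/δ leaders; the control scalar decays linearly 2 → 0.
* *SSO-PSO*: the current best individual moves by the salp-leader rule
  around the food source with `r₁ = 2·exp(−(4c/M)²)`; all others follow a
  PSO velocity rule (inertia 0.5, both acceleration constants 2) whose
  attractors are the personal best and the food source.  This "one
  population, one leader" orchestration is one reading of an
  under-specified hybrid; the alternative (two populations exchanging
  bests) was not taken because the single-population form needs no
  migration policy.
* *Binarization*: bit k is 1 iff `σ(x_k) > u_k`, `u_k ~ U(0,1)`; an
  all-zero draw is repaired by forcing the largest-transfer bit.
  Positions live in [0,1]^J, and the wrapper maps `u → 8(u − ½)` before
  the sigmoid so bit probabilities span ≈ [0.02, 0.98]; without the gain
  the transfer is confined to [0.5, 0.73] and the size penalty cannot
  act.
* *BOA*: Bayesian optimization over the **mask vertices**.  A first
  attempt fitted the GP on the continuous positions, but the stochastic
  transfer makes that objective noisy in a way the surrogate cannot
  steer bit-wise (it plateaued well short of the exhaustive optimum on
  8-feature problems).  The shipped form fits an RBF GP on evaluated
  binary corners (deterministic cached fitness), proposes candidates by
  the same sigmoid transfer plus single bit-flips of the incumbent, and
  picks by expected improvement.  `boa_optimize` retains the generic
  continuous GP-EI loop for box-constrained objectives.

Reference population settings for the full-scale protocol are GWO
200 × 500, SSO 600 × 1000, SMO 250 × 500 (perturbation rate 0.5, local
leader limit 75, global 50).  Tests and the acceptance script run
scaled-down profiles (pop 10–15, 10–20 iterations; BOA budget 100–150),
which the benchmarks show are already sufficient on these problem sizes.

## Classifiers

* **SMO-GBM**: spider monkey optimization (local-leader phase with
  component-wise perturbation probability 0.5, inverse-fitness
  global-leader selection — the fitness-proportional rule adapted to
  minimization — greedy acceptance, re-dispersal on local stagnation,
  group split on global stagnation up to population/10 groups, then
  merge) minimizes the 3-fold CV error of a multinomial-deviance gradient
  boosting classifier over (learning rate, stages, depth, min leaf);
  integer axes are relaxed and rounded at evaluation.  One individual is
  seeded at the default hyperparameters (stages 100, rate 0.2, full
  subsample, unrestricted depth, min leaf 1), making
  "tuned ≤ default CV error" a structural guarantee rather than a race.
  The boosting core is scikit-learn's `GradientBoostingClassifier`
  behind the `gbm_fit`/`gbm_predict` surface; multinomial deviance is
  used because the task is 3-class (a generic squared-error reading is
  not applicable to classification here).
* **PLS heads**: NIPALS with unit-norm weights, orthogonal scores and
  `β̂ = W(K'W)⁻¹v`; 1-D responses use the direct recursion, one-hot
  multi-class responses the two-block inner iteration.  Rank exhaustion
  truncates with a warning.  Ten latent components by default.  Features
  are z-scored (training statistics) before PLS in both heads; scores
  are z-scored before the kernels (min-max to [0,1] for the spline
  kernel, its usual domain) — without this the approximation-band power
  features dominate every inner product and the SVM solver stalls on
  ill-conditioned Grams.  LDA uses the pooled covariance with a 1e-8
  ridge.  SVM heads are one-vs-rest soft-margin machines on precomputed
  Grams, regularization C = 1; non-PSD Grams (possible for Bessel and
  spline) are eigenvalue-clipped at zero with a warning.
* **Kernels**: polynomial `(s·s'+1)^d`, Laplacian `exp(−‖s−s'‖/σ)`,
  linear, coordinate-wise product spline, and the first-kind Bessel
  kernel `J_{ν}(σr)/(σr)^ν` with ν = order+1, normalized so k(0) = 1 via
  the analytic limit (the printed form of this kernel in the source
  literature is not well-formed; the canonical kernel is used).
* **Multiple-kernel SVM**: `K = Σ lₙ Kₙ` on the simplex; alternates
  solving the one-vs-rest dual with reweighting
  `lₙ ∝ lₙ·√(αᵀKₙα)` (each kernel's contribution to the discriminant
  norm), stopping at weight change < 1e-4.
* **Soft-voting ensemble**: decision tree, Gaussian NB, multinomial
  logistic GLM and an SVM whose "probabilities" are the softmax of
  one-vs-rest decision values (no Platt calibration).  The vote is the
  argmax of weighted per-class probability sums — the multi-class
  generalization of the binary positive/negative probability-sum rule —
  with ties to the lowest class index.  A member that fails to fit is
  excluded with a warning while ≥ 2 remain.

## Statistics

Cohen's kappa is computed from the confusion matrix as
`(p_o − p_e)/(1 − p_e)`; the Wilcoxon signed-rank test is two-sided, with
the exact null for n ≤ 25 (no ties) and the tie-corrected normal
approximation otherwise; all-identical pairs leave it undefined (NaN).

## Problem sizes and numerical choices

Benchmarks run at sizes where independent oracles are feasible: 255-mask
exhaustive enumeration on 8 features; 300 × 50 planted benchmarks with
5 informative features at class separation 2; 5-D sphere for optimizer
convergence (20 seeds); the end-to-end detection runs 36 subjects ×
4 channels × 40 s (720 2-s epochs, 100 wavelet features) under 10-fold
CV — the channel count and duration are package choices (the emulated
recording protocol fixes neither), selected so a full grid of runs stays
cheap while the planted alpha effect remains clearly detectable (~89%
versus a 33.3% chance floor, permuted control at chance).

Tolerances asserted throughout: FCM membership rows sum to 1 within
1e-9 and the objective never increases; PLS score orthogonality at 1e-8
and full-rank equivalence to least squares at 1e-6; DWT reconstruction
at 1e-8 relative; Gram symmetry at 1e-12; kappa against its closed form
at 1e-12.  Degenerate inputs are contracts, not accidents: empty masks
are repaired before evaluation, coincident FCM centers get indicator
memberships, constant features rank last, and unavailable boosting
backends raise a capability error rather than substituting silently.

## Known limitations

* Absolute accuracies on synthetic cohorts transfer to clinical EEG only
  qualitatively; the generator has no artifacts, no channel covariance
  and a single planted effect.
* Epoch-level CV with subject-inherited labels is optimistic (see
  above); subject-grouped CV is the honest protocol for subject-level
  claims.
* LLCFS and UDFS are small-scale renderings of their canonical
  formulations, adequate as rankers on hundreds of samples, not tuned
  for large-scale use.
* The CatBoost backend adapter is exercised only for its capability
  error unless the library is installed.
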