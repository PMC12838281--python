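# blendeeg

Blended machine-learning pipelines for **multi-class classification of
neuropathic-pain severity from resting-state EEG**.

Chronic neuropathic pain is usually graded from questionnaires; an
EEG-based classifier offers an objective complement.  The working
hypothesis is that pain severity (low / moderate / high) shifts
resting-state band power, so the pipeline is built around band-resolved
features and aggressive feature selection on small cohorts
(tens of subjects, multi-channel recordings at 250 Hz).

The package implements two "blended" model families end to end:

* **Features** — per-epoch statistical descriptors (average power
  `E[v²]`, population σ, kurtosis, skewness, mean absolute value) computed
  on (i) raw channel epochs, (ii) the subbands of a level-4 Daubechies-4
  discrete wavelet transform (D1–D4, A4 ≈ the clinical EEG bands at
  250 Hz), and (iii) fuzzy C-means memberships: FCM minimizes
  `Z = Σᵢ Σ_z q_{iz}^g ‖aᵢ − C_z‖²` by alternating the membership update
  `q_{iz} = 1 / Σ_k (d_{iz}/d_{ik})^{2/(g−1)}` with the weighted center
  update, and each epoch is described by its C memberships plus C
  center distances.
* **Feature selection** — filter methods (one-way ANOVA F, |Pearson r|,
  binned mutual information, Spearman correlation clustering, and a
  5-ranker majority vote over CFS / LASSO / LLCFS / Relief-F / UDFS) and
  wrapper methods that minimize the fitness
  `γ·Err(P) + β·|P|/J` (γ = 0.99, β = 0.01, Err = stratified k-fold
  nearest-neighbour error) with grey wolf optimization, a hybrid
  salp-swarm/particle-swarm optimizer, or Bayesian optimization, all
  binarized through a stochastic sigmoid transfer.
* **Classifiers** — gradient boosting with hyperparameters tuned by
  spider monkey optimization; NIPALS partial least squares
  (`w_h ∝ X'y`, orthogonal scores, `β̂ = W(K'W)⁻¹v`) with an LDA head or
  kernel-SVM heads (polynomial, Bessel, Laplacian, linear, spline); a
  multiple-kernel SVM with simplex kernel weights `K = Σ lₙ Kₙ`; and a
  soft-voting ensemble of decision tree, Gaussian naive Bayes,
  multinomial logistic regression and SVM.
* **Evaluation** — stratified 10-fold cross-validation with selection
  fitted inside each training fold, Cohen's kappa, the two-sided Wilcoxon
  signed-rank test, and a benchmark grid over
  {feature family × selector × classifier}.

Because the clinical dataset has no public accession, the package ships a
first-class synthetic cohort generator (`blendeeg.fixtures`): band-limited
oscillators with class-dependent band-power factors over 1/f noise, with
known ground truth for every downstream stage.

## Worked example

```python
import blendeeg as b
from blendeeg import evaluation as ev

spec = b.SynthSpec(n_subjects=36, n_channels=4, duration_s=40.0, seed=0)
eeg = b.generate_synthetic_cohort(spec)          # graded alpha-band effect
epochs = b.epoch_signals(eeg, window_s=2.0)
F = b.build_feature_matrix(epochs, family="dwt", seed=0)

mask, trace = b.wrapper_select(F.X, F.y, algorithm="sso_pso",
                               pop=10, iters=10, seed=0)
result = ev.cross_validate(
    ev.make_selector("ssopso", pop=10, iters=10),
    "plssvm_polynomial", F, folds=10, seed=0,
    classifier_params={"n_components": 10},
)
```

Output:

```
cohort: 36 subjects, 4 channels at 250 Hz
epochs: 720 x 2 s -> feature matrix 720 x 100
SSO-PSO selected 50/100 features (wrapper fitness 0.0628)
10-fold accuracy: 89.44%  (Cohen's kappa 0.842)
```

The 36-subject cohort carries a graded alpha-band (8–13 Hz) power effect
across the three severity classes.  The wavelet features expose it, the
wrapper keeps a subset whose nearest-neighbour CV error (plus a small
size penalty) is minimal, and the polynomial-kernel PLS-SVM reads 89.4%
10-fold accuracy — far above the 33.3% chance level for balanced
3-class data (a label-permuted control sits at chance; kappa 0.84 means
strong chance-corrected agreement).

A thin CLI mirrors the library:

```bash
blendeeg synth --subjects 36 --seed 0 --out cohort/
blendeeg select features.csv --method ftest --k 10 --out mask.json
blendeeg wrap features.csv --algo ssopso --seed 0 --out mask.json
blendeeg train features.csv --clf plslda
blendeeg grid --config run.yaml --out results/
```

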