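# Methods

This note documents the models, the synthetic-cohort assumptions, and the
numerical conventions that the implementation commits to, including the
choices made where the framework's definition left the design open.

## Evaluation protocol

The unit of every experiment is a **fixed, stratified 5-fold plan**: each
(site, label) cell is shuffled by the seed and dealt cyclically over the
folds ordered by current size, which guarantees per-cell counts within ±1 of
cell/5 and overall fold sizes within ±1 of n/5.  One plan is shared by all
architectures and feature sets so that paired comparisons across models are
valid; the paired t-test pairs per-fold test accuracies.

*5-fold CV* rotates the test fold; the next fold in cyclic order is the
validation fold and the remaining three train the model.  Hyper-parameters
(the SVM's C; the iteration count of the neural models) are chosen by
validation accuracy.  *5×5 nested CV* re-stratifies the four non-test groups
into five inner folds; hyper-parameters are selected by the best **average**
inner-validation accuracy over a shared checkpoint grid, and the five inner
models then vote on the outer test set (25 trained models per architecture).
For the neural models each inner model records, at every checkpoint, its
inner-validation accuracy and its scores on the outer test set, so joint
epoch selection needs no retraining.  The model object retained from a
training run holds the weights of its own best-validation checkpoint; the
nested-CV votes are taken from the recorded scores at the jointly selected
epoch.

Feature standardization (population-variance convention, scale floored at
1e-12 so degenerate columns map to exactly 0) and ridge-RFE feature selection
are fitted on training rows only and re-fitted in every (inner) split.  RFE
removes 10% of the *surviving* features per iteration (configurable down
to 1); within a removed batch, features are ordered by |coefficient| so the
elimination ranking is a strict permutation.  The ridge penalty is fixed at
1.0 — selection is rank-based, so the scale of the penalty matters little.
Default selection sizes are 4000 fMRI edges and 800 structural features at
full scale (the published operating point of this framework); the desk-scale
study uses 300 and 80 (see below).

Transductive models (GCN, EV-GCN) see all node features and the full
population graph; their loss is masked to training nodes and model selection
reads validation-node labels only.  The leakage tests assert bit-identical
fitted state under test-label perturbation.

## Models

All neural models are trained full-batch with Adam (lr 1e-3; 5e-3 for the
graph models; weight decay 5e-4) on a package-authored reverse-mode autodiff
engine over numpy float64 arrays, chosen so the whole framework runs
deterministically on one CPU; every operation's gradient is tested against
central finite differences.  Hidden activations are rectifiers; outputs are
linear before softmax.  Class scores always sum to 1; the gradient contract
returns d(logit of the requested class)/d(input), i.e. the pre-softmax score,
because softmax saturation suppresses gradients.

* **SVM** — scikit-learn SVC, RBF kernel, `gamma='scale'`, C tuned on the
  validation fold (default grid 0.1/1/10).  AUC scores come from a logistic
  (Platt-style) squashing of decision values fitted on the training fold.
* **FCN** — N-500-30-2, dropout 0.5 after both hidden layers.
* **AE-FCN** — encoder N-300-150, decoder 150-300-N, and a classifier head
  that consumes the **reconstruction** (N-300-16-2); loss = MSE + CE with
  unit weights, both heads trained end-to-end.  The architecture description
  this follows lists hidden widths (300, 150, 300, 300, 16) while also
  stating that hidden layers 2 and 5 match; the explicit widths are followed.
  A configuration switch (`head_on_bottleneck`) classifies the 150-d code
  instead.
* **GCN** — three Chebyshev graph-convolution layers (N-128-128-2, order
  K = 3, the published setting of the population-graph literature) over the
  binary same-site graph.  The rescaled Laplacian is
  `L~ = 2L/lambda_max − I` with L the symmetric normalized Laplacian;
  lambda_max is computed by dense eigendecomposition (cohorts here are
  ≤ ~1000 nodes).  Isolated nodes contribute zero Laplacian rows, and a graph
  with no edges falls back to the generic bound lambda_max = 2, so the empty
  graph yields `L~ = −I` and the Chebyshev filter collapses to a per-node map.
* **EV-GCN** — a pairwise association encoder (PAE) maps each participant's
  [sex one-hot ∥ site one-hot] through a shared linear embedding
  `h = tanh(EP + b)` (8 units) and scores each pair by
  `sigmoid(affine([|h_i − h_j| ∥ h_i ⊙ h_j]))`, which is symmetric by
  construction and emits the full dense graph.  During training the graph
  passes through symmetric edge dropout (rate 0.3, surviving edges rescaled
  by 1/(1−rate); identity at evaluation).  Four 16-channel Chebyshev layers
  follow; their outputs are concatenated (64 = 16 × 4) and classified by an
  MLP 64-256-2.  PAE parameters are updated by backpropagation of the same
  cross-entropy loss.  For this trainable graph the Laplacian uses the
  lambda_max = 2 bound (`L~ = −D^(−1/2) W D^(−1/2)`) so it stays
  differentiable with respect to the PAE parameters; the exact dense
  lambda_max is reserved for fixed graphs.

Iteration counts are tuned on a checkpoint grid (every 10 epochs, default cap
300).  The desk-scale study runs cap training at 60 epochs — on the planted
cohorts validation accuracy plateaus within the first few checkpoints, and
this keeps the full five-architecture experiment at a few minutes on one CPU.

## Synthetic cohorts

The generator emulates the statistical structure of a multi-site
autism/control cohort, not its biology:

* The default site table reproduces the 20-site reference composition
  (870 participants, 403 autism / 467 TD; per-site mean ages and sex ratios);
  `abide_like_site_table(scale)` shrinks every cell (floor, minimum 1).
* Connectivity is drawn in Fisher-z edge space:
  `z = template + site_offset + class_shift + noise`, mapped back through
  tanh so matrices are symmetric with unit diagonal and entries in (−1, 1).
  The class shift on planted edges is `d · sqrt(noise_sd² + site_shift_sd²)`
  so the pooled within-class standardized mean difference is ≈ d.  Structural
  features follow the same additive model.  Site effects are a per-feature
  offset drawn once per site (SD `site_shift_sd`, default 0.2; residual noise
  SD 0.3) — the simplest mechanism producing multi-site heterogeneity.
* Phenotypes are drawn per site (age around the site mean, site sex ratio,
  FIQ ~ N(108, 14), Poisson motion-outlier counts) and are independent of the
  label by default; a `pheno_label_leak` knob exists for ablations.
* Optional time-series are Gaussian draws factored from a target correlation
  matrix (non-PSD targets are projected to the nearest PSD matrix with a
  warning), so the empirical correlation converges to the target as T grows.

What the generator does **not** emulate: hemodynamics, temporal
autocorrelation, scanner-specific artifacts, realistic covariance between
edges, or heavy-tailed morphometry.  Passing recovery tests therefore show
that the pipeline is correct and leak-free and that the models can find
planted multivariate signal under site heterogeneity — not that any
particular accuracy is attainable on real cohorts.

Two properties of the multi-site design are worth knowing when reading null
results.  First, because classes are balanced within sites, shared site
offsets inflate within-class variance without separating classes, making
pooled per-edge t-tests slightly conservative.  Second, a label permutation
combined with site-stratified folds leaves a small exploitable association
between site identity and the permuted labels (per-site imbalances are
consistent between training and test folds), so the permutation null sits
slightly above 0.5 rather than exactly at chance; the null band used in the
recovery tests accounts for this.

## Interpretation

SmoothGrad draws `n_noisy = 10` Gaussian perturbations per participant with
SD = 10% of the per-feature training range (the convention of the SmoothGrad
literature), averages the signed input gradients and takes the absolute value
(abs-of-mean; mean-of-abs is available behind a flag).  The kernel SVM
exposes no input gradient and is excluded.  For graph models, noise is added
to the participant's own feature row with the population graph held fixed.

The stability statistic follows the nested-CV structure: for each outer-test
participant, the five inner models yield five saliency maps (lifted into the
shared feature space; features a model never selected contribute zeros);
per feature, SNR = mean / sample std (n−1), with stds below 1e-12 floored
there and flagged; the participant's score is the feature-mean SNR.
Repeating the nested pipeline (default 3 times, fresh model seeds, same fold
plan) and averaging per participant gives the per-architecture SNR
histograms.  Features never selected by any inner model have zero mean and
zero std and contribute SNR 0.

Nodal saliency strength sums each connection's saliency onto both incident
regions (so total strength = 2 × total edge saliency), followed by z-score
normalization (constant vectors map to zeros).  TP/TN/FP/FN groups partition
the cohort by the pooled CV prediction (autism = positive); the TP-vs-TN
contrast uses Welch's t-test and is skipped (flagged) when either group has
fewer than two members.

## Desk-scale study conditions

The acceptance experiment uses a 70%-scaled site table (~590 participants,
all 20 sites), 64 ROIs (2016 edges), 202 structural features (10 cortical ×
9 + 16 noncortical × 7), 50 planted edges and 20 planted structural features
at d = 1.5, feature selection to 300 edges + 80 structural features, and the
60-epoch training cap.  These sizes preserve the full-scale pipeline shape
(same stratification, selection, tuning and voting machinery) while keeping
the complete five-architecture experiment, the permutation null, five seeds
of nested-CV max voting and the SmoothGrad recovery run at a few minutes on
a single CPU.

## Known limitations

* The PAE internal form and layer sizes are committed choices; the framework
  this follows defers them to its citation, and "inputting the entire
  population graph" is read as emitting the full dense weight matrix.
* Model checkpoint serialization covers the neural architectures (spec +
  seed + weights as arrays); the SVM is cheap to refit and is not serialized.
* Nested-CV saliency uses each inner model at its own best-validation
  checkpoint, while its votes use the jointly selected epoch (see above);
  with plateaued validation curves these coincide in practice.
* Leave-one-site-out evaluation and external-cohort transfer are out of
  scope, as are alternative population-graph similarities (age/FIQ) and
  tangent-space connectivity embeddings.
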