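# Methods

This note documents the models and procedures implemented in `heartsel`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic experiments do and do not
show.

## Preprocessing

Clinical tables arrive in the UCI Cleveland CSV dialect: 13 numeric
predictor columns, an integer disease-stage column collapsed to a binary
label (stage > 0 = disease present), `?` marking missing cells.  Three
stages are applied in order.

**Imputation.** Missing cells are replaced by the per-feature median of
the observed cells (mean available by configuration).  The median is the
default because the noise-repair stage is also median-based and the
Cleveland-style columns are skewed and partly ordinal.  A feature with no
observed cells is an error: no statistic is defined for it.

**Noise repair by studentized residuals.** For each feature *j*, the
feature is regressed by ordinary least squares on all other features and
the *externally* studentized residual of every cell is computed (via
`statsmodels`' influence machinery).  Cells with |t| above the threshold
(default 3.0, the conventional outlier cut) are replaced by the feature's
median.  Cells are repaired rather than rows deleted so the sample size —
and hence every downstream confusion-matrix total — is preserved.  If the
regression design for a feature is rank deficient, studentization falls
back to the robust per-feature score (value − median)/(1.4826·MAD) with a
logged notice.

**Normalisation.** Min-max to [0, 1] per feature (z-score optional);
constant features map to 0.  Min-max is the default because the
feature-selection search space and the position-to-mask threshold both
live in [0, 1].  The fitted per-feature parameters are retained and
reused on held-out data — inside the evaluation harness the normaliser is
refit on each training fold only, so test folds never leak into the
scaling.  Held-out min-max output is clipped to [0, 1].

Preprocessing is label-blind by construction: the labels never enter any
of the three stages.

## Squirrel search algorithm (SSA)

Continuous bounded minimisation with a population of N candidate
positions.  After fitness ranking, the best individual is the *hickory*
squirrel, the next `n_acorn` (default 3) are *acorn* squirrels, the rest
*normal*.  Per iteration:

- acorn squirrels glide toward the hickory position,
  `x ← x + dg·G_c·(x_hickory − x)`;
- normal squirrels glide toward a uniformly chosen acorn squirrel;
- with probability `P_dp = 0.1` a glide is interrupted (a predator
  appears) and the squirrel relocates uniformly inside the bounds.

The gliding distance is `dg = hg/(tan φ · sf)` with `hg = 8`, `sf = 18`
and `tan φ = C_D/C_L` the drag/lift ratio; the aerodynamic prefactor
`½ρV²S` (ρ = 1.204 kg·m⁻³, V = 5.25 m·s⁻¹, S = 154 cm²) cancels between
drag and lift, so only `C_D = 0.6` and the per-glide draw
`C_L ~ U(0.675, 1.5)` matter.  Hence `dg ∈ [0.5, 8/(0.4·18)] ≈
[0.5, 1.1111]`, and with the gliding constant `G_c = 1.9` a step covers
between 95% and 211% of the distance to the target.  Out-of-bounds
positions are clamped to the box.

**Seasonal monitoring.** Each iteration starts in winter.  The seasonal
constant of each acorn squirrel is its *squared* Euclidean distance to
the hickory squirrel (implemented exactly in that form; a square-root
variant is available by flag).  When every seasonal constant falls below
the decaying threshold `S_min = 10⁻⁵ / 365^(t/(T/2.5))`, winter ends and
each normal squirrel that did not meet a predator this iteration
relocates by a Lévy flight, `x ← FS_L + Lévy·(FS_U − FS_L)`, restoring
exploration around the lower corner and beyond.  The Lévy step uses the
standard heavy-tailed generator `0.01·ra·σ/|rb|^(1/β)` with β = 1.5 and
σ(β) ≈ 0.6966; its sample kurtosis is far above the Gaussian value, which
is the property the relocation relies on.  The summer state lasts for the
relocation phase only; the next iteration begins in winter again.

**Elitism.** The best-so-far solution is tracked across iterations and
re-injected over the current worst individual whenever an iteration loses
it, so the best-fitness trace is monotonically non-increasing.

**Update-rule scope.** Only the two gliding rules above are active by
default (acorn→hickory, normal→acorn); a third rule sending normal
squirrels directly to the hickory tree exists in some SSA variants and
can be enabled by the `normal_to_hickory` flag.

All stochastic draws flow through one seeded `numpy` generator in a fixed
order: identical seed and configuration reproduce the entire trace.

## Elite opposition-based learning (EOBL)

Once per iteration, after the gliding updates and before role re-ranking,
an opposition population is generated from the elite (current best)
position `x_e`:

`x̃_{i,j} = η·(da_j + db_j) − x_{e,j}`,

where `[da_j, db_j]` is the min/max of coordinate j over the current
population and η is a generalised coefficient.  One η is drawn per
individual per dimension (η ~ U(0,1); η ≡ 1 gives the classical
reflection): the right-hand side otherwise depends only on the elite and
the bounds, and a single shared η would collapse all N opposition
individuals onto one point, defeating the diversity purpose of the
operator.  Opposition coordinates that leave `[da_j, db_j]` are reset
uniformly inside it.  The best N of the union (current ∪ opposition) are
kept, so the operator can never worsen the population's best fitness —
the property the paired-run comparison in the tests and the acceptance
script measures.

## Wrapper feature selection

The optimizer searches `[0,1]^d`.  A position becomes a subset by
selecting feature j iff its coordinate exceeds 0.5; if none does, the
single largest coordinate is selected (lowest index on ties), so subsets
are never empty.  The subset cost is

`fitness = α·ΔR + (1 − α)·|Y|/|T|`, α = 0.99,

with ΔR the mean misclassification rate of the wrapper classifier over
stratified k-fold cross-validation (default 10 folds, seeded) on the
selected columns.  Both terms lie in [0, 1], so the cost does too.  The
wrapper default is 5-nearest-neighbours: fast enough that the search can
afford hundreds of subset evaluations, and a reasonable error proxy on
min-max-scaled features; any estimator factory (including the full
ACNN-LSTM) can be substituted.  α = 0.99 keeps classification error
dominant with subset size as a tie-breaker — the convention for this
weighted cost.  Distinct continuous positions that binarise to the same
mask share one cached evaluation; the cache changes no returned value.

Reported feature indices are 1-based, the field's reporting convention
for this table.

## Attention CNN-LSTM classifier

Tabular records have no inherent sequence, so the m selected features are
given a fixed order (their column order) and each scalar value is
linearly embedded to `embed_dim` (default 16) with per-position weights —
the minimal sequence reading of a multi-channel text-style architecture
for tabular input.  Four parallel channels (kernel sizes 2, 3, 4, 5; 32
filters; LSTM hidden 32) each concatenate a same-padded ReLU 1-D
convolution map with the LSTM hidden sequence over the same embedding,
then max-pool over the m steps.  The pooled vectors of the two
small-kernel channels form the conv-dominant group `C_out` and those of
the two large-kernel channels the LSTM-dominant group `W_out`; the merged
hidden vector is `h = C_out ⊕ W_out` (length 256 at the defaults).

A temporal attention runs over the first channel's per-step states
`h_i = [h'_t ; c_t]` (hidden and cell state concatenated): scores
`e_i = v_aᵀ tanh(W_r h_i + b)`, weights by standard softmax, context
`c = Σ w_i h_i`.  The context is concatenated with `h` before the dense
softmax head rather than replacing it, so the attention augments the
pooled summary instead of discarding it.

**Training.** Cross-entropy, Adam (lr 10⁻³ default), batch 32, up to 200
epochs with early stopping (patience 20) on a stratified 10% validation
split, dropout 0.2 on the merged representation, and decoupled weight
decay 10⁻³.  The regularisation matters: the ~60k-parameter model on
few-hundred-row tables will otherwise memorise noise features.  The
forget-gate biases are initialised to 1, the usual stabilisation of early
LSTM training.  A non-finite loss aborts with a diagnostic.  All
randomness (init, batching, dropout, split) derives from the configured
seeds; a fixed seed reproduces the final loss exactly.

**Autodiff.** The network is trained on a small in-package reverse-mode
engine over numpy arrays (broadcast add/mul, matmul, gate nonlinearities,
concatenation/stacking/slicing, padding, max-pool, softmax, fused
softmax cross-entropy).  Every adjoint is checked against central finite
differences in the test suite (tolerance 10⁻⁴ on a small model), and the
single-example numpy reference implementations of each block
(`nn_ops.py`) provide an independent statement of the arithmetic.

## Evaluation harness

The positive class is "disease present".  Six metrics are computed from
each confusion matrix — sensitivity, specificity, precision, accuracy,
F-score, MCC — rendered as percentages rounded half-up to two decimals
(full precision retained internally); a metric with a zero denominator is
reported as 0 and flagged undefined.  AUC is the rank-based Mann-Whitney
statistic with midrank ties.

The repeated harness runs `n_iterations` (default 10) rounds; each round
seeds its own stratified 10-fold cross-validation and pools the fold
predictions into one confusion matrix covering all n records, so each
round's matrix totals the full sample.  This pooled-CV protocol was
chosen because per-round matrices over the complete sample are the only
reading consistent with reporting ~n-record confusion matrices per round;
a plain random-split protocol is available through the same API by
supplying a different splitter seed policy.  The summary row is the
arithmetic mean of each metric column of the rounded rows, rounded again.

## Synthetic data

The generator emulates the shape of the Cleveland heart-disease table:
n = 303 rows, d = 13 features, positive prevalence 139/303 ≈ 0.459
(Bernoulli per row), k = 4 informative features shifted by
`effect_size = 1.5` standard deviations between classes (noise SD 1.0),
remaining features pure noise, 2% of cells masked at random.  A
categorical mode discretises three noise features to small integer codes,
mimicking the cp/restecg/thal columns.  The planted informative index set
is returned so recovery can be scored.

What it does not emulate: the real table's covariance structure,
non-Gaussian marginals, ordinal codings of the informative features and
informative missingness.  Passing the recovery and classification tests
therefore shows that the search and the classifier behave correctly on a
controlled signal of realistic size and dimension — not that they
reproduce any particular published number on the real download, which is
out of scope here.

## Problem sizes used in the bundled experiments

The test suite and acceptance script run the optimizer at N = 20-30
squirrels and T = 30-500 iterations depending on the check, the subset
oracle on a 3-feature table (7 subsets, exhaustively enumerable), the
recovery experiment at the full 303 × 13 study conditions over 10 seeds,
and one classifier training at n = 600 / effect 2.0 with a 25% holdout.
These sizes give stable pass/fail behaviour at desk scale; all are
configuration parameters, not limits of the implementation.

## Known limitations

- The optimizer is a single-population serial implementation; no island
  models or adaptive parameter control.
- The tabular-to-sequence embedding imposes an arbitrary feature order;
  the attention can compensate but channel kernels still see that order.
- The studentized-residual repair assumes approximately linear
  inter-feature structure; grossly nonlinear clinical features would be
  over-flagged at tight thresholds.
- Training the full classifier inside the selection loop is supported but
  computationally disproportionate; the k-NN wrapper is the intended
  search-time error proxy.
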