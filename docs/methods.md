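# Methods

## Model

A subject-visit is a *set* of feature tokens. Every feature declared in the
schema is mapped to a `d_model`-dimensional token by a per-feature strategy:
numerical values (z-scored by training-split mean/sd stored with the model)
through a linear map `w_f x + b_f`; categorical codes through a per-feature
lookup table (equivalent to one-hot × matrix); imaging embeddings (length
256) through a linear projection. Parameters are per *feature*, not per
modality: the backbone uses no positional encoding — a tabular record has
no meaningful order — so feature identity must be carried by the embedding
itself. Token-order invariance of the forward pass is asserted by test.

A learned classification token is prepended and `L` pre-norm transformer
layers (multi-head self-attention + ReLU feed-forward) aggregate the
attendable tokens; a linear layer maps the CLS state to 13 logits and
sigmoids yield per-label probabilities. Mean-pooling over attendable tokens
is available as a config alternative (`readout="mean"`). The CLS readout is
the default because it is well defined for any number of present tokens.

Missing features are removed by *attention masking*: masked keys receive an
additive −1e9 before the softmax, which underflows to an exactly-zero
attention weight in double precision, so the output is exactly invariant to
the content of masked tokens. The same mechanism emulates missingness
during training: per record per batch, the present set `S` is permuted and
a uniform cut `i ∈ [1, |S|]` keeps only the prefix — every retained-set
size is equally likely and a fixed feature survives with probability
`(|S|+1)/(2|S|)`. Records with *no* present features are excluded from
training batches with a logged warning; at inference they fall back to the
CLS-only path (chance-level output) rather than erroring.

## Objective

Thirteen binary heads are trained jointly with

* focal loss, `γ = 2`, `α_i = (1 − f_i)²` where `f_i` is the label's
  positive fraction among *observed* entries of the *training* split only
  (no leakage into α);
* pairwise ranking hinge with margin `ε = 0.25`, weight `λ = 0.005`,
  summed over label pairs `i < j` where both labels are observed and
  `y_i ≠ y_j`. Equal-label pairs contribute the constant `ε` under the
  literal formula — zero gradient, pure offset — and are excluded by
  default; `strict_equal_pairs=True` restores the literal behavior;
* an explicit L2 term, `β = 0.0005`, over weight matrices only (lookup
  rows, biases and layer-norm gains excluded). AdamW's decoupled weight
  decay is set to 0 so the penalty is not applied twice; passing a nonzero
  `weight_decay` to the optimizer restores the decoupled variant.

Label masking multiplies each per-(record, label) term by the 0/1
observation mask, making the gradient at unascertained entries exactly zero
(checked by finite differences and on the autograd tape). Probabilities are
clamped to `[1e-7, 1 − 1e-7]` before logs.

## Optimization

AdamW (β₁ = 0.9, β₂ = 0.999), base learning rate 0.001, batch size 128,
cosine schedule with warm restarts: first restart after 64 epochs, period
doubling thereafter (restarts at 64, 192, … within a 256-epoch run), floor
`min_lr = 0`. The schedule is stepped per epoch. The last incomplete batch
is kept. Gradient clipping is off by default but exposed. Per epoch the
selection metric — weighted-average AUROC over validation labels with both
classes present — is logged and the best epoch's parameters are returned;
`stop_threshold` allows early stopping once the metric clears a bar.
Training is bitwise reproducible given the config seed.

## Synthetic cohorts

The generator emulates a pooled multi-center dementia cohort:

* cognitive status one-hot with default probabilities (0.4, 0.3, 0.3) for
  NC/MCI/DE — a research-cohort mix, not population prevalence;
* given DE, ten etiologies drawn as correlated Bernoullis through a
  Gaussian copula (equicorrelation 0.2 by default) with marginals
  (0.55, 0.20, 0.20, 0.08, 0.10, 0.05, 0.05, 0.12, 0.05, 0.08) for
  AD, LBD, VD, PRD, FTD, NPH, SEF, PSY, TBI, ODE — AD-dominant with
  meaningful mixed-dementia mass; under NC/MCI all etiologies are 0, so
  etiology ⇒ DE holds by construction;
* numerical features `~ Normal(E·y, σ)` with `σ = 1`; categorical features
  from label-shifted logits; imaging embeddings as a base vector plus
  per-label directions scaled by the effect entry plus isotropic noise;
* per-feature MCAR missingness (default rate 0.1) and pseudo-cohorts each
  forcing a configured label subset to be unascertained.

`planted_effect_matrix` plants mean shifts of two noise standard deviations
on six features per label — strong but not trivial signal, chosen so that
a small backbone must genuinely combine features to separate the thirteen
labels. What passing tests show: the pipeline recovers planted conditional
mean structure under missingness and partial labels. What they do not
show: performance on real clinical distributions — the generator has
Gaussian marginals, MCAR missingness and no longitudinal structure,
visit-level correlation, instrument floor/ceiling effects, or site biases.

## Evaluation choices

* AUROC via the Mann-Whitney pair convention; AUPR via average precision.
* Weighted averages weigh labels by positive count among observed entries.
* Labels lacking both classes in a test cohort are dropped from macro /
  weighted averages with an explicit warning.
* Co-occurrence analysis scores a label combination by the geometric mean
  of member probabilities (arithmetic mean and min are available); the
  inclusion rule inverts the distribution-free AUROC variance bound
  `max_A A(1−A)/min(m, n) = 1/(4m)` at threshold 0.01, giving a minimum of
  25 positives. Combinations up to size 3 are enumerated by default.
* Threshold metrics default to 0.5; MCC returns 0 when its denominator is 0.
* The missingness-ablation harness forces named feature groups missing at
  inference and reports per-cognitive-label AUROC per scenario.

## Statistics

Two-sample tests wrap scipy (Mann-Whitney U, two-sample KS, Brunner-Munzel
with t-approximation, t-test); `alternative="greater"` always means the
first sample is stochastically larger (the KS orientation is flipped
accordingly). Dunn's post-hoc (rank z-tests with tie correction) is
implemented in-package and Bonferroni-corrects over all pairs. Bootstrap
Pearson uses case resampling with a percentile CI. Clinician/model fusion
rescales 0–100 confidence to [0, 1] before averaging with the model
probability; a `strict` mode reproduces raw-scale averaging with a warning
that the confidence term dominates. Rater comparison uses the one-sided
Wilcoxon signed-rank with `p = 1` for the all-zero-difference degenerate
case.

## Imaging pathway

`prepare_subvolume` resamples to isotropic 1.5 mm voxels (the standardized
spacing is exposed as a parameter), clips negatives, scales by the maximum
(preserving the background-zero convention of skull-stripped scans), crops
to the intensity > 0 bounding box, and resizes to 128³; an all-zero volume
falls back to a center crop with a warning. The four-convolutional-block
adapter (3×3×3 kernels, channels 768→512→384→320→256, ReLU, global average
pool) turns a 768×4×4×4 encoder output into a flat 256-vector. The encoder
itself is a pluggable external provider; the repository ships a small
synthetic stand-in (`StandInEncoder`) producing deterministic 768×4×4×4
arrays from 128³ volumes so the adapter path is exercisable on CPU. The
adapter is forward-only here: end-to-end training through the imaging
branch is out of scope, as embeddings normally arrive precomputed.

## Desk-scale choices

The default backbone (L=4, H=4, d_model=64, d_ff=256) and the experiment
sizes used in the tests (n=2000 cohorts, L=2/d=32 models for recovery;
n=1200, 25 epochs, 5 seeds for the dropout-robustness comparison) were
chosen as the smallest configurations at which the studied effects are
unambiguous; all are configurable. The numerics are float64 throughout,
and gradient correctness of every autograd operator is enforced by
finite-difference tests.

## Known limitations

* No calibration, uncertainty quantification, or attention-based
  explanation.
* The hierarchy etiology ⇒ DE is a property of the generator, not a
  constraint of the model; predicted probabilities may violate it.
* Dunn's correction counts all pairs; selected-contrast corrections are
  not implemented.
* The Brunner-Munzel small-sample behavior below n≈10 per group is
  approximate (t-approximation with Satterthwaite degrees of freedom).
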