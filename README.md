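# demiform

A missingness-robust multimodal transformer for multi-label differential
diagnosis of dementia.

## The problem

Differential diagnosis of dementia is hard: etiologies overlap in their
clinical presentation, frequently co-occur (mixed dementia), and real
clinical datasets pooled across centers are riddled with missing features
*and* missing labels — one cohort never ascertains Lewy body disease,
another collects no neuropsychological battery. `demiform` implements a
modeling framework built for exactly this setting, aimed at methodologists
and clinical-ML practitioners who need a transparent, testable reference
implementation.

Each subject-visit is a set of features from three modalities:

* **numerical** (age, test scores) — embedded by a per-feature linear map
  `w_f x + b_f`;
* **categorical** (sex, history flags) — embedded by a per-feature lookup
  table;
* **imaging** — MRI volumes are standardized into 128×128×128 sub-volumes,
  encoded externally, downsampled by a four-block convolutional adapter into
  256-vectors, and then treated as numerical inputs.

A transformer aggregates the resulting tokens without positional encoding
(feature identity lives in the embeddings); thirteen sigmoid heads predict
cognitive status — NC / MCI / DE — and ten etiologies (AD, LBD, VD, PRD,
FTD, NPH, SEF, PSY, TBI, ODE) that may co-occur.

Two masking mechanisms provide the robustness:

* **attention masking** removes missing-feature tokens from information
  flow exactly (a masked token's content cannot influence the output), and
  the same mechanism emulates arbitrary missingness during training via
  Shapley-style dropout: the present feature set `S` is permuted as `σ`, a
  cut `i ~ U{1..|S|}` is drawn, and only the prefix `σ_1..σ_i` is kept;
* **label masking** multiplies every per-(record, label) loss term by an
  observation indicator, so partially labeled cohorts train all heads they
  can and never corrupt the rest.

The training objective is

```
L = L_FL + λ·L_RL + β·‖w‖²
L_FL = (1/N) Σ_k Σ_i −y_ki α_i (1−p_ki)^γ log p_ki − (1−y_ki)(1−α_i) p_ki^γ log(1−p_ki)
L_RL = (1/N) Σ_k Σ_{i<j} max(0, (p_ki − p_kj)(y_kj − y_ki) + ε)
```

with `γ=2`, `α_i = (1 − f_i)²` from the training prevalence `f_i`,
`ε=0.25`, `λ=0.005`, `β=0.0005`, optimized by AdamW (lr 0.001) under a
cosine warm-restart schedule (first restart at epoch 64, period doubling).

Because the real source cohorts are access-restricted, the package ships a
first-class synthetic generator: correlated etiologies via a Gaussian
copula, planted feature effects of known size, MCAR feature missingness,
and pseudo-cohorts with structurally missing labels.

## Worked example

```python
from demiform import (
    SyntheticConfig, default_schema, generate_cohort,
    planted_effect_matrix, split_cohort,
    DementiaTransformer, ModelConfig, TrainConfig,
)

schema = default_schema(n_numerical=16, n_categorical=4)
effects = planted_effect_matrix(schema, shift=2.0, features_per_label=6, seed=11)
cohort = generate_cohort(SyntheticConfig(n=2000, effect_matrix=effects, seed=11), schema)
train, val, test = split_cohort(cohort, (0.7, 0.15, 0.15), seed=11)

model = DementiaTransformer(train, config=ModelConfig(d_model=32, n_layers=2,
                                                      n_heads=4, d_ff=128))
result = model.fit(val_cohort=val,
                   train_config=TrainConfig(epochs=10, batch_size=128, seed=0))
print(result.summary())
report = result.evaluate(test)
print({k: round(v, 3) for k, v in report.averages.items()})
```

Output:

```
Differential dementia diagnosis transformer — fit summary
============================================================
records (train):        1400
features:               20
labels:                 13
layers x heads x d:     2 x 4 x 32
epochs run:             10
best epoch:             9
final train loss:       0.4580
best val weighted AUROC: 0.9891
============================================================
{'micro_auroc': 0.983, 'micro_aupr': 0.932, 'macro_auroc': 0.959,
 'macro_aupr': 0.568, 'weighted_auroc': 0.988, 'weighted_aupr': 0.91}
```

The planted effects (mean shifts of two noise standard deviations on six
features per label) are recovered within ten epochs: weighted AUROC ≈ 0.99
on held-out subjects, with macro AUPR lower because rare etiologies have
few positives. Zeroing the effect matrix drives every AUROC to chance
(0.5), which is the package's core self-check.

A CLI wraps the same steps:

```bash
demiform simulate --out cohort.csv --schema schema.json --seed 7 --n 2000
demiform train --data train.csv --schema schema.json --val val.csv --out model.ckpt
demiform evaluate --model model.ckpt --data test.csv --schema schema.json --out report.json
demiform stats --scores scores.csv --groups groups.csv --test brunner_munzel --alternative greater
```

## Layout

| module | contents |
| --- | --- |
| `demiform.schema` | feature schema, records, cohorts, CSV/JSON I/O, prevalence |
| `demiform.simulate` | synthetic cohort generator and person-level splits |
| `demiform.embedding` | per-feature tokenization, sub-volume pipeline, imaging adapter |
| `demiform.masking` | permutation-prefix feature dropout, attention masks |
| `demiform.losses` | focal + ranking + L2 objective with label masking |
| `demiform.model` | autograd transformer backbone, `DementiaTransformer` / `FitResult` |
| `demiform.training` | AdamW loop, warm-restart schedule, checkpoint selection |
| `demiform.evaluation` | AUROC/AUPR, averaging, co-occurrence, ablation harness |
| `demiform.stats` | group tests, Dunn post-hoc, bootstrap Pearson, score fusion |

See `docs/methods.md` for the modeling assumptions, parameter defaults, and
known limitations.
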