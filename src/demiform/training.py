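"""Mini-batch training: AdamW, cosine warm restarts, checkpoint selection.

Defaults follow the reference schedule: base learning rate 0.001 for 256
epochs, batch size 128, first warm restart after 64 epochs with the restart
period doubling each time.  Per batch, a fresh feature-dropout draw is
sampled for every record; per epoch, the validation selection metric
(weighted-average AUROC over observed labels by default) is logged and the
best epoch's parameters are returned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .autograd import AdamW, Tensor
from .embedding import batch_inputs, embed_batch
from .losses import LossConfig, total_loss
from .masking import build_attention_mask, sample_retained_set
from .model import DementiaTransformer, FitResult, forward_tokens
from .schema import Cohort

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    base_lr: float = 0.001
    epochs: int = 256
    batch_size: int = 128
    first_restart_epochs: int = 64  # T0
    period_multiplier: float = 2.0
    min_lr: float = 0.0
    seed: int = 0
    selection_metric: str = "weighted_auroc"
    feature_dropout: bool = True
    grad_clip: float | None = None
    #: stop early once the selection metric reaches this value (None = never)
    stop_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.first_restart_epochs < 1:
            raise ValueError("epochs and first_restart_epochs must be >= 1")
        if self.period_multiplier < 1 or self.batch_size < 1:
            raise ValueError("period_multiplier and batch_size must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_metric: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)


def lr_at(epoch: float, cfg: TrainConfig) -> float:
    """Cosine learning rate with warm restarts at epoch granularity.

    Within a period of length T = T0 * mult^r the rate is
    min_lr + (base_lr - min_lr) * (1 + cos(pi * t / T)) / 2 with t the time
    since the last restart; restarts occur at T0, T0 + T0*mult, ...
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    t = float(epoch)
    T = float(cfg.first_restart_epochs)
    while t >= T:
        t -= T
        T *= cfg.period_multiplier
    return cfg.min_lr + (cfg.base_lr - cfg.min_lr) * (1 + np.cos(np.pi * t / T)) / 2


def _validation_metric(model: DementiaTransformer, cohort: Cohort) -> float:
    """Weighted-average AUROC over labels observed with both classes."""
    from .evaluation import auroc

    P = model.predict_proba(cohort)
    Y, M = cohort.Y, cohort.M
    scores, weights = [], []
    for i, lab in enumerate(model.taxonomy.labels):
        obs = M[:, i] == 1
        y = Y[obs, i]
        if obs.sum() == 0 or y.min() == y.max():
            warnings.warn(f"label {lab} lacks both classes in validation; excluded")
            continue
        scores.append(auroc(P[obs, i], y))
        weights.append(y.sum())
    if not scores:
        return float("nan")
    w = np.asarray(weights, dtype=float)
    return float(np.average(scores, weights=w / w.sum()))


def train(
    model: DementiaTransformer,
    train_cohort: Cohort,
    val_cohort: Cohort | None,
    loss_cfg: LossConfig,
    train_cfg: TrainConfig,
) -> FitResult:
    """Optimize the model in place and return the best-epoch FitResult."""
    rng = np.random.default_rng(train_cfg.seed)
    params = model.params
    opt = AdamW(params.parameters(), lr=train_cfg.base_lr)
    history = TrainHistory()

    usable = [r for r in train_cohort.records if any(r.observed.values())]
    n_skipped = len(train_cohort.records) - len(usable)
    if n_skipped:
        logger.warning("%d all-missing record(s) excluded from training", n_skipped)

    feature_names = model.schema.names
    best_metric, best_epoch, best_state = -np.inf, 0, params.state_arrays()
    best_state = {k: v.copy() for k, v in best_state.items()}

    for epoch in range(train_cfg.epochs):
        lr = lr_at(epoch, train_cfg)
        opt.lr = lr
        order = rng.permutation(len(usable))
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, len(usable), train_cfg.batch_size):
            batch = [usable[i] for i in order[lo : lo + train_cfg.batch_size]]
            num_x, cat_idx, img_mats, presence = batch_inputs(
                batch, model.schema, params.embedding
            )
            attend = presence.copy()
            if train_cfg.feature_dropout:
                for k, r in enumerate(batch):
                    present = [n for n, p in zip(feature_names, presence[k]) if p]
                    retained = sample_retained_set(present, rng)
                    attend[k] = build_attention_mask(
                        presence[k], feature_names, retained, training=True
                    )
            tokens = embed_batch(num_x, cat_idx, img_mats, model.schema, params.embedding)
            logits = forward_tokens(tokens, attend, params)
            P = logits.sigmoid()
            Y = np.array([r.y for r in batch], dtype=float)
            M = np.array([r.label_mask for r in batch], dtype=float)
            loss = total_loss(P, Y, M, loss_cfg, params.l2_parameters())
            opt.zero_grad()
            loss.backward()
            if train_cfg.grad_clip is not None:
                norm = np.sqrt(
                    sum(float(np.sum(p.grad**2)) for p in params.parameters() if p.grad is not None)
                )
                if norm > train_cfg.grad_clip:
                    for p in params.parameters():
                        if p.grad is not None:
                            p.grad *= train_cfg.grad_clip / norm
            if lr > 0:
                opt.step()
            epoch_loss += loss.item()
            n_batches += 1

        history.train_loss.append(epoch_loss / max(n_batches, 1))
        history.lr.append(lr)

        if val_cohort is not None and len(val_cohort) > 0:
            metric = _validation_metric(model, val_cohort)
        else:
            metric = float("nan")
        history.val_metric.append(metric)
        logger.info(
            "epoch %d: lr=%.5f loss=%.4f val=%.4f", epoch, lr, history.train_loss[-1], metric
        )

        if not np.isnan(metric):
            if metric > best_metric:
                best_metric, best_epoch = metric, epoch
                best_state = {k: v.copy() for k, v in params.state_arrays().items()}
            if train_cfg.stop_threshold is not None and metric >= train_cfg.stop_threshold:
                break
        else:
            best_epoch = epoch
            best_state = {k: v.copy() for k, v in params.state_arrays().items()}

    params.load_state(best_state)
    return FitResult(model=model, history=history, best_epoch=best_epoch)
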