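"""Training objective: masked focal loss + pairwise ranking loss + L2.

Thirteen independent sigmoid heads, one per diagnostic label.  The focal
term down-weights well-classified entries via a (1-p)^gamma modulation and
balances classes with alpha_i = (1 - f_i)^2, the squared complement of the
training prevalence f_i.  The ranking term is a per-record hinge asking each
positive label's probability to exceed each negative label's by a margin
epsilon.  Label masking multiplies every per-(record, label) term by the
0/1 observation mask before summation, so unascertained labels contribute
neither loss nor gradient.

Defaults: gamma=2, epsilon=0.25, lambda_rl=0.005, beta_l2=0.0005.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor

P_CLAMP = 1e-7  # probability clamp before logs


@dataclass
class LossConfig:
    gamma: float = 2.0
    alpha: np.ndarray = field(default_factory=lambda: np.full(13, 0.25))
    epsilon: float = 0.25
    lambda_rl: float = 0.005
    beta_l2: float = 0.0005
    #: include constant-epsilon terms for equal-label pairs (as printed);
    #: they carry no gradient and only shift the ranking term by a constant.
    strict_equal_pairs: bool = False

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if np.any((self.alpha < 0) | (self.alpha > 1)):
            raise ValueError("alpha entries must lie in [0, 1]")
        if not (0 < self.epsilon < 1):
            raise ValueError("epsilon must lie in (0, 1)")
        if self.lambda_rl < 0 or self.beta_l2 < 0:
            raise ValueError("loss weights must be >= 0")


def compute_alpha(prevalence: np.ndarray) -> np.ndarray:
    """alpha_i = (1 - f_i)^2, the squared complement of the positive rate."""
    f = np.asarray(prevalence, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("prevalence entries must lie in [0, 1]")
    return (1.0 - f) ** 2


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def focal_loss(P, Y, M, cfg: LossConfig):
    """Masked focal loss, mean over the batch.

    P, Y, M are (N, 13); accepts numpy arrays (returns float) or autograd
    tensors (returns a Tensor on the tape).
    """
    return_scalar = not isinstance(P, Tensor)
    p = _as_tensor(P).clip(P_CLAMP, 1.0 - P_CLAMP)
    Y = np.asarray(Y, dtype=float)
    M = np.asarray(M, dtype=float)
    if p.shape != Y.shape or Y.shape != M.shape:
        raise ValueError(f"shape mismatch: P{p.shape} Y{Y.shape} M{M.shape}")
    N = Y.shape[0]
    a = cfg.alpha[None, :]
    g = cfg.gamma
    pos = Tensor(Y * a * M) * (1.0 - p) ** g * p.log()
    neg = Tensor((1.0 - Y) * (1.0 - a) * M) * p**g * (1.0 - p).log()
    loss = -(pos + neg).sum() / N
    return loss.item() if return_scalar else loss


def ranking_loss(P, Y, M, cfg: LossConfig):
    """Masked pairwise ranking hinge, mean over the batch.

    Pairs i<j enter only when both labels are observed; pairs with equal
    labels are excluded by default (their printed term is the constant
    epsilon with zero gradient; ``strict_equal_pairs`` restores it).
    """
    return_scalar = not isinstance(P, Tensor)
    p = _as_tensor(P)
    Y = np.asarray(Y, dtype=float)
    M = np.asarray(M, dtype=float)
    if p.shape != Y.shape or Y.shape != M.shape:
        raise ValueError(f"shape mismatch: P{p.shape} Y{Y.shape} M{M.shape}")
    N, L = Y.shape

    # validity of each unordered pair (k, i<j)
    upper = np.triu(np.ones((L, L)), k=1)[None, :, :]
    both_obs = M[:, :, None] * M[:, None, :]
    ydiff = Y[:, None, :] - Y[:, :, None]  # (k, i, j) -> y_j - y_i
    if cfg.strict_equal_pairs:
        valid = upper * both_obs
    else:
        valid = upper * both_obs * (ydiff != 0)

    diff = p.reshape(N, L, 1) - p.reshape(N, 1, L)  # p_i - p_j at (k, i, j)
    hinge = (diff * Tensor(ydiff) + cfg.epsilon).relu()
    loss = (hinge * Tensor(valid)).sum() / N
    return loss.item() if return_scalar else loss


def l2_penalty(weights: list) -> Tensor:
    """Sum of squared entries over the given weight tensors."""
    total: Tensor | None = None
    for w in weights:
        t = _as_tensor(w)
        term = (t * t).sum()
        total = term if total is None else total + term
    return total if total is not None else Tensor(0.0)


def total_loss(P, Y, M, cfg: LossConfig, l2_weights: list | None = None):
    """focal + lambda * ranking + beta * ||w||^2."""
    return_scalar = not isinstance(P, Tensor)
    fl = focal_loss(P, Y, M, cfg)
    rl = ranking_loss(P, Y, M, cfg)
    if return_scalar:
        l2 = 0.0
        for w in l2_weights or []:
            arr = w.data if isinstance(w, Tensor) else np.asarray(w)
            l2 += float(np.sum(arr**2))
        return fl + cfg.lambda_rl * rl + cfg.beta_l2 * l2
    out = fl + cfg.lambda_rl * rl
    if l2_weights:
        out = out + cfg.beta_l2 * l2_penalty(l2_weights)
    return out
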