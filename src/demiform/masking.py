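"""Shapley-style random feature dropout and attention-mask construction.

During training, each record's present feature set S is randomly permuted
(sigma) and a cut point i is drawn uniformly from [1, |S|]; only the prefix
sigma_1..sigma_i is retained and the rest is masked from the transformer.
Every prefix subset is thereby equally likely in size, which exposes the
model to a diverse spectrum of missing-feature patterns (the retained-set
size is uniform on {1..|S|}, and any fixed feature survives with marginal
probability (|S|+1)/(2|S|)).

The draw is refreshed per record per batch.  At inference nothing is
dropped: only genuine missingness masks tokens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MaskDraw:
    """One dropout draw: a permutation of the present set and a cut point."""

    permutation: tuple[str, ...]
    cut: int

    def __post_init__(self) -> None:
        if not (1 <= self.cut <= len(self.permutation)):
            raise ValueError("cut must lie in [1, |S|]")

    @property
    def retained(self) -> tuple[str, ...]:
        return self.permutation[: self.cut]


def sample_retained_set(present: list[str], rng: np.random.Generator) -> set[str]:
    """Draw the retained feature subset {sigma_1..sigma_i}.

    Never empty: i >= 1.  Callers must skip records with no present features.
    """
    m = len(present)
    if m == 0:
        raise ValueError("cannot sample a retained set from an empty present set")
    perm = rng.permutation(m)
    cut = int(rng.integers(1, m + 1))
    return {present[j] for j in perm[:cut]}


def sample_mask_draw(present: list[str], rng: np.random.Generator) -> MaskDraw:
    """Like :func:`sample_retained_set` but returning the full draw."""
    m = len(present)
    if m == 0:
        raise ValueError("cannot sample a retained set from an empty present set")
    perm = rng.permutation(m)
    cut = int(rng.integers(1, m + 1))
    return MaskDraw(permutation=tuple(present[j] for j in perm), cut=cut)


def build_attention_mask(
    presence: np.ndarray,
    feature_names: list[str],
    retained: set[str] | None,
    training: bool,
) -> np.ndarray:
    """Boolean attendability per token.

    A token is attendable iff its feature is observed AND (at inference, or
    it survived the training dropout draw).  ``retained`` must be None at
    inference and a subset of the present features during training.
    """
    presence = np.asarray(presence, dtype=bool)
    if not training:
        if retained is not None:
            raise ValueError("retained must be None at inference")
        return presence.copy()
    if retained is None:
        return presence.copy()
    present_names = {n for n, p in zip(feature_names, presence) if p}
    extra = retained - present_names
    if extra:
        raise ValueError(f"retained set contains unobserved features: {sorted(extra)}")
    return np.array(
        [p and (n in retained) for n, p in zip(feature_names, presence)], dtype=bool
    )
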