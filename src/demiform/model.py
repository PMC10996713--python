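"""Transformer backbone with thirteen sigmoid heads over masked token sets.

Each record's features are embedded into tokens (see :mod:`.embedding`); a
learned classification token is prepended and a stack of pre-norm
transformer layers aggregates the attendable tokens.  No positional
encoding is used — tabular features form a set, and feature identity lives
in the per-feature embedding parameters — so the forward pass is invariant
to token order.  Attention key-masking (additive -1e9 before softmax) makes
the output exactly invariant to the *content* of masked tokens: a blocked
column underflows to a hard zero attention weight.

The public modelling surface follows the Model/Results convention:
:class:`DementiaTransformer` is built from a cohort, its :meth:`fit` returns
a :class:`FitResult` with the selected parameters, training history,
evaluation helpers and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import AdamW, Tensor, concat, layer_norm
from .embedding import EmbeddingParams, TokenSequence, batch_inputs, embed_batch
from .losses import LossConfig, compute_alpha, focal_loss, ranking_loss, total_loss
from .schema import Cohort, FeatureSchema, LabelTaxonomy, Record, compute_prevalence

NEG_INF = -1e9


@dataclass
class ModelConfig:
    """Backbone hyperparameters (the defaults are desk-scale)."""

    d_model: int = 64
    n_layers: int = 4
    n_heads: int = 4
    d_ff: int = 256
    readout: str = "cls"  # or "mean" over attendable tokens
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.readout not in ("cls", "mean"):
            raise ValueError("readout must be 'cls' or 'mean'")


class ModelParams:
    """All trainable weights: embeddings, transformer stack, readout."""

    def __init__(self, schema: FeatureSchema, cfg: ModelConfig, n_labels: int = 13):
        rng = np.random.default_rng(cfg.seed)
        d, dff = cfg.d_model, cfg.d_ff
        self.cfg = cfg
        self.embedding = EmbeddingParams(schema, d, rng)
        self.cls = Tensor(rng.normal(0, 1.0 / np.sqrt(d), d), requires_grad=True)
        self.layers: list[dict[str, Tensor]] = []
        s = 1.0 / np.sqrt(d)
        for _ in range(cfg.n_layers):
            self.layers.append(
                {
                    "wq": Tensor(rng.normal(0, s, (d, d)), requires_grad=True),
                    "wk": Tensor(rng.normal(0, s, (d, d)), requires_grad=True),
                    "wv": Tensor(rng.normal(0, s, (d, d)), requires_grad=True),
                    "wo": Tensor(rng.normal(0, s, (d, d)), requires_grad=True),
                    "ln1_g": Tensor(np.ones(d), requires_grad=True),
                    "ln1_b": Tensor(np.zeros(d), requires_grad=True),
                    "w1": Tensor(rng.normal(0, s, (d, dff)), requires_grad=True),
                    "b1": Tensor(np.zeros(dff), requires_grad=True),
                    "w2": Tensor(rng.normal(0, 1.0 / np.sqrt(dff), (dff, d)), requires_grad=True),
                    "b2": Tensor(np.zeros(d), requires_grad=True),
                    "ln2_g": Tensor(np.ones(d), requires_grad=True),
                    "ln2_b": Tensor(np.zeros(d), requires_grad=True),
                }
            )
        self.lnf_g = Tensor(np.ones(d), requires_grad=True)
        self.lnf_b = Tensor(np.zeros(d), requires_grad=True)
        self.w_out = Tensor(rng.normal(0, s, (d, n_labels)), requires_grad=True)
        self.b_out = Tensor(np.zeros(n_labels), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        out = self.embedding.parameters() + [self.cls]
        for lay in self.layers:
            out += list(lay.values())
        out += [self.lnf_g, self.lnf_b, self.w_out, self.b_out]
        return out

    def l2_parameters(self) -> list[Tensor]:
        """Weight matrices subject to the explicit L2 term (no lookup rows,
        no biases, no layer-norm gains)."""
        out = self.embedding.l2_parameters()
        for lay in self.layers:
            out += [lay["wq"], lay["wk"], lay["wv"], lay["wo"], lay["w1"], lay["w2"]]
        out += [self.w_out]
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {"cls": self.cls.data}
        for name, p in self.embedding.numerical.items():
            state[f"num/{name}/w"] = p["w"].data
            state[f"num/{name}/b"] = p["b"].data
        for name, t in self.embedding.categorical.items():
            state[f"cat/{name}"] = t.data
        for name, p in self.embedding.imaging.items():
            state[f"img/{name}/w"] = p["w"].data
            state[f"img/{name}/b"] = p["b"].data
        for li, lay in enumerate(self.layers):
            for k, t in lay.items():
                state[f"layer{li}/{k}"] = t.data
        state["lnf_g"] = self.lnf_g.data
        state["lnf_b"] = self.lnf_b.data
        state["w_out"] = self.w_out.data
        state["b_out"] = self.b_out.data
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        mapping = self.state_arrays()
        own = {
            **{f"num/{n}/w": p["w"] for n, p in self.embedding.numerical.items()},
            **{f"num/{n}/b": p["b"] for n, p in self.embedding.numerical.items()},
            **{f"cat/{n}": t for n, t in self.embedding.categorical.items()},
            **{f"img/{n}/w": p["w"] for n, p in self.embedding.imaging.items()},
            **{f"img/{n}/b": p["b"] for n, p in self.embedding.imaging.items()},
            "cls": self.cls,
            "lnf_g": self.lnf_g,
            "lnf_b": self.lnf_b,
            "w_out": self.w_out,
            "b_out": self.b_out,
        }
        for li, lay in enumerate(self.layers):
            for k, t in lay.items():
                own[f"layer{li}/{k}"] = t
        for key in mapping:
            own[key].data = np.array(state[key], dtype=float)


def forward_tokens(
    tokens: Tensor | np.ndarray,
    attend: np.ndarray,
    params: ModelParams,
) -> Tensor:
    """Run the backbone on a (B, T, d) token tensor with a (B, T) boolean
    attendability mask; returns (B, 13) logits.

    A CLS token (always attendable) is prepended; masked columns receive an
    additive -1e9 in every attention score so they carry exactly zero weight.
    """
    cfg = params.cfg
    x = tokens if isinstance(tokens, Tensor) else Tensor(tokens)
    B, T, d = x.shape
    H = cfg.n_heads
    dk = d // H

    cls = params.cls.reshape(1, 1, d) * Tensor(np.ones((B, 1, 1)))
    x = concat([cls, x], axis=1)
    attend_full = np.concatenate([np.ones((B, 1), dtype=bool), attend.astype(bool)], axis=1)
    Tf = T + 1
    key_bias = np.where(attend_full, 0.0, NEG_INF)[:, None, None, :]  # (B,1,1,T)

    def split_heads(t: Tensor) -> Tensor:
        return t.reshape(B, Tf, H, dk).transpose(0, 2, 1, 3)

    for lay in params.layers:
        h = layer_norm(x, lay["ln1_g"], lay["ln1_b"])
        q = split_heads(h @ lay["wq"])
        k = split_heads(h @ lay["wk"])
        v = split_heads(h @ lay["wv"])
        scores = (q @ k.transpose(0, 1, 3, 2)) / np.sqrt(dk) + Tensor(key_bias)
        att = scores.softmax(axis=-1)
        ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, Tf, d)
        x = x + ctx @ lay["wo"]
        h2 = layer_norm(x, lay["ln2_g"], lay["ln2_b"])
        x = x + (h2 @ lay["w1"] + lay["b1"]).relu() @ lay["w2"] + lay["b2"]

    x = layer_norm(x, params.lnf_g, params.lnf_b)
    if cfg.readout == "cls":
        pooled = x[:, 0, :]
    else:
        w = attend_full.astype(float)
        w = w / w.sum(axis=1, keepdims=True)
        pooled = (x * Tensor(w[:, :, None])).sum(axis=1)
    return pooled @ params.w_out + params.b_out


@dataclass
class Prediction:
    """Thirteen per-label probabilities, strictly inside (0, 1)."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.clip(np.asarray(self.p, dtype=float), 1e-7, 1 - 1e-7)


def forward(seq: TokenSequence, mask: np.ndarray, params: ModelParams) -> Prediction:
    """Single-record forward pass over an assembled token sequence."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("no attendable tokens: cannot run forward on an empty record")
    logits = forward_tokens(seq.tokens[None, :, :], mask[None, :], params)
    return Prediction(p=1.0 / (1.0 + np.exp(-logits.data[0])))


# ---------------------------------------------------------------------------
# Model / Results objects


class DementiaTransformer:
    """Multi-label differential-diagnosis model over a multimodal cohort.

    Parameters
    ----------
    train_cohort : Cohort
        Training data; numerical standardization statistics and the focal
        alpha vector are computed from it alone.
    config : ModelConfig
        Backbone dimensions.
    loss_config : LossConfig, optional
        If omitted, alpha is set to (1 - f)^2 from the training prevalence.
    """

    def __init__(
        self,
        train_cohort: Cohort,
        config: ModelConfig | None = None,
        loss_config: LossConfig | None = None,
    ):
        self.cohort = train_cohort
        self.schema = train_cohort.schema
        self.taxonomy = train_cohort.taxonomy
        self.config = config or ModelConfig()
        self.params = ModelParams(self.schema, self.config, n_labels=len(self.taxonomy))
        self._fit_standardization()
        if loss_config is None:
            f = compute_prevalence(train_cohort)
            loss_config = LossConfig(alpha=compute_alpha(f))
        self.loss_config = loss_config

    def _fit_standardization(self) -> None:
        stats = {}
        for spec in self.schema.features_of_kind("numerical"):
            vals = [
                float(r.values[spec.name])
                for r in self.cohort.records
                if r.observed.get(spec.name, False)
            ]
            if vals:
                mu = float(np.mean(vals))
                sd = float(np.std(vals))
                stats[spec.name] = (mu, sd if sd > 1e-12 else 1.0)
        self.params.embedding.norm_stats = stats

    # -- inference ----------------------------------------------------------

    def predict_proba(
        self,
        cohort: Cohort | list[Record],
        batch_size: int = 256,
        force_missing: set[str] | None = None,
    ) -> np.ndarray:
        """(n, 13) probabilities; only genuine missingness masks tokens.

        ``force_missing`` ablates the named features at inference time (used
        by the missingness-ablation harness).  Records with no observed
        features get chance output via the CLS-only path.
        """
        records = cohort.records if isinstance(cohort, Cohort) else cohort
        out = np.zeros((len(records), len(self.taxonomy)))
        drop_idx = None
        if force_missing:
            drop_idx = np.array([n in force_missing for n in self.schema.names])
        for lo in range(0, len(records), batch_size):
            chunk = records[lo : lo + batch_size]
            num_x, cat_idx, img_mats, presence = batch_inputs(
                chunk, self.schema, self.params.embedding
            )
            if drop_idx is not None:
                presence = presence & ~drop_idx[None, :]
            tokens = embed_batch(num_x, cat_idx, img_mats, self.schema, self.params.embedding)
            logits = forward_tokens(Tensor(tokens.data), presence, self.params)
            out[lo : lo + len(chunk)] = 1.0 / (1.0 + np.exp(-logits.data))
        return np.clip(out, 1e-7, 1 - 1e-7)

    def loss_on(self, cohort: Cohort) -> float:
        """Total loss (no dropout) on a cohort; diagnostic helper."""
        P = self.predict_proba(cohort)
        return total_loss(
            P, cohort.Y, cohort.M, self.loss_config, self.params.l2_parameters()
        )

    # -- fitting -------------------------------------------------------------

    def fit(self, val_cohort: Cohort | None = None, train_config=None) -> "FitResult":
        """Train with masked mini-batches; returns the Results object."""
        from .training import TrainConfig, train

        train_config = train_config or TrainConfig()
        return train(self, self.cohort, val_cohort, self.loss_config, train_config)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: weights + schema hash + scaling + config."""
        path = Path(path)
        meta = {
            "schema_hash": self.schema.content_hash(),
            "schema": [
                {
                    "name": s.name,
                    "kind": s.kind,
                    "categories": list(s.categories),
                    "embed_dim": s.embed_dim,
                }
                for s in self.schema
            ],
            "taxonomy": list(self.taxonomy.labels),
            "norm_stats": {k: list(v) for k, v in self.params.embedding.norm_stats.items()},
            "model_config": {
                "d_model": self.config.d_model,
                "n_layers": self.config.n_layers,
                "n_heads": self.config.n_heads,
                "d_ff": self.config.d_ff,
                "readout": self.config.readout,
                "seed": self.config.seed,
            },
            "format_version": 1,
        }
        state = self.params.state_arrays()
        with open(path, "wb") as fh:  # keep the exact filename (np.savez appends .npz)
            np.savez(fh, __meta__=json.dumps(meta), **state)

    @classmethod
    def load(cls, path: str | Path) -> "DementiaTransformer":
        from .schema import FeatureSpec

        with np.load(Path(path), allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
            state = {k: archive[k] for k in archive.files if k != "__meta__"}
        schema = FeatureSchema(
            FeatureSpec(
                name=s["name"],
                kind=s["kind"],
                categories=tuple(s["categories"]),
                embed_dim=int(s["embed_dim"]),
            )
            for s in meta["schema"]
        )
        taxonomy = LabelTaxonomy(labels=tuple(meta["taxonomy"]))
        cfg = ModelConfig(**meta["model_config"])
        empty = Cohort(schema=schema, records=[], taxonomy=taxonomy)
        obj = cls.__new__(cls)
        obj.cohort = empty
        obj.schema = schema
        obj.taxonomy = taxonomy
        obj.config = cfg
        obj.params = ModelParams(schema, cfg, n_labels=len(taxonomy))
        obj.params.load_state(state)
        obj.params.embedding.norm_stats = {
            k: tuple(v) for k, v in meta["norm_stats"].items()
        }
        obj.loss_config = LossConfig()
        return obj


@dataclass
class FitResult:
    """Results of a training run: selected weights, history, diagnostics."""

    model: DementiaTransformer
    history: "TrainHistory"
    best_epoch: int

    def predict_proba(self, cohort) -> np.ndarray:
        return self.model.predict_proba(cohort)

    def evaluate(self, cohort: Cohort, threshold: float = 0.5):
        from .evaluation import evaluate_cohort

        return evaluate_cohort(self.model, cohort, threshold=threshold)

    def summary(self) -> str:
        h = self.history
        lines = [
            "Differential dementia diagnosis transformer — fit summary",
            "=" * 60,
            f"records (train):        {len(self.model.cohort)}",
            f"features:               {len(self.model.schema)}",
            f"labels:                 {len(self.model.taxonomy)}",
            f"layers x heads x d:     {self.model.config.n_layers} x "
            f"{self.model.config.n_heads} x {self.model.config.d_model}",
            f"epochs run:             {len(h.train_loss)}",
            f"best epoch:             {self.best_epoch}",
            f"final train loss:       {h.train_loss[-1]:.4f}",
        ]
        if h.val_metric and not np.isnan(h.val_metric[self.best_epoch]):
            lines.append(f"best val weighted AUROC: {h.val_metric[self.best_epoch]:.4f}")
        lines.append("=" * 60)
        return "\n".join(lines)
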