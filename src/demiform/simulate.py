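"""Synthetic NACC-like cohort generation.

Emulates the structure of a pooled multi-cohort dementia dataset: a one-hot
cognitive status (NC/MCI/DE), ten etiology labels that co-occur only under
dementia (sampled as correlated Bernoullis through a Gaussian copula),
mixed numerical/categorical/imaging features whose means shift with the
label vector through a planted effect matrix, per-feature missingness, and
pseudo-cohorts that each omit a configured subset of labels (missing labels).

The generator is the test bed for every downstream stage: planted effects of
known size let parameter-recovery experiments assert that the full pipeline
finds them, and zeroed effects assert that it finds nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .schema import (
    COGNITIVE_LABELS,
    ETIOLOGY_LABELS,
    LABELS,
    Cohort,
    FeatureSchema,
    FeatureSpec,
    LabelTaxonomy,
    Record,
)


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic cohort.

    ``effect_matrix`` has one row per feature (schema order) and one column
    per label (taxonomy order); entry (f, l) is the mean shift of feature f
    when label l is positive.  For categorical features the row shifts the
    logit of the *last* category; for imaging features it scales a fixed
    per-label direction in embedding space.
    """

    n: int = 1000
    cog_probs: tuple[float, float, float] = (0.4, 0.3, 0.3)  # NC, MCI, DE
    etiology_base_probs: tuple[float, ...] = (
        0.55, 0.20, 0.20, 0.08, 0.10, 0.05, 0.05, 0.12, 0.05, 0.08,
    )  # conditional on DE, order = ETIOLOGY_LABELS
    etiology_corr: float = 0.2
    effect_matrix: np.ndarray | None = None  # (n_features, 13)
    noise_sd: float = 1.0
    feature_missing_rate: float = 0.1
    label_missing_profile: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"A": (), "B": ("LBD", "PRD"), "C": ("FTD", "NPH", "SEF")}
    )
    imaging_dim: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        cp = np.asarray(self.cog_probs, dtype=float)
        if cp.min() < 0 or abs(cp.sum() - 1.0) > 1e-12:
            raise ValueError("cog_probs must be nonnegative and sum to 1")
        bp = np.asarray(self.etiology_base_probs, dtype=float)
        if len(bp) != 10 or bp.min() < 0 or bp.max() > 1:
            raise ValueError("etiology_base_probs must be 10 probabilities")
        if not (0 <= self.etiology_corr < 1):
            raise ValueError("etiology_corr must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 <= self.feature_missing_rate < 1):
            raise ValueError("feature_missing_rate must be in [0, 1)")


def default_schema(
    n_numerical: int = 16,
    n_categorical: int = 4,
    n_imaging: int = 0,
    imaging_dim: int = 256,
) -> FeatureSchema:
    """A mixed tabular schema reminiscent of clinical instrument scores."""
    specs: list[FeatureSpec] = []
    for i in range(n_numerical):
        specs.append(FeatureSpec(name=f"num{i:02d}", kind="numerical"))
    for i in range(n_categorical):
        specs.append(
            FeatureSpec(name=f"cat{i:02d}", kind="categorical", categories=("c0", "c1", "c2"))
        )
    for i in range(n_imaging):
        specs.append(
            FeatureSpec(name=f"mri{i:02d}", kind="imaging_embedding", embed_dim=imaging_dim)
        )
    return FeatureSchema(specs)


def planted_effect_matrix(
    schema: FeatureSchema,
    shift: float = 2.0,
    features_per_label: int = 6,
    seed: int = 0,
) -> np.ndarray:
    """Plant ``shift``-sized mean effects of each label on a feature subset.

    Each label gets ``features_per_label`` features drawn (with replacement
    across labels, without within a label) from the schema, with alternating
    sign so labels remain separable rather than collinear.
    """
    rng = np.random.default_rng(seed)
    E = np.zeros((len(schema), 13))
    n_feat = len(schema)
    for li in range(13):
        idx = rng.choice(n_feat, size=min(features_per_label, n_feat), replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(idx))
        E[idx, li] = shift * signs
    return E


def generate_cohort(config: SyntheticConfig, schema: FeatureSchema | None = None) -> Cohort:
    """Sample a fully reproducible synthetic cohort.

    Labels first: cognitive status one-hot from ``cog_probs``; given DE, the
    ten etiologies come from a Gaussian copula with equicorrelation
    ``etiology_corr`` and marginals ``etiology_base_probs``; under NC/MCI all
    etiologies are 0 (hierarchical consistency).  Features second: numerical
    ~ Normal(effect_matrix @ y, noise_sd); categorical from label-shifted
    logits; imaging = base + per-label direction * y + isotropic noise.
    MCAR feature missingness and per-pseudo-cohort label missingness last.
    """
    rng = np.random.default_rng(config.seed)
    schema = schema or default_schema()
    taxonomy = LabelTaxonomy()
    n = config.n

    E = config.effect_matrix
    if E is None:
        E = np.zeros((len(schema), 13))
    E = np.asarray(E, dtype=float)
    if E.shape != (len(schema), 13):
        raise ValueError(
            f"effect_matrix shape {E.shape} does not match (n_features={len(schema)}, 13)"
        )

    # --- labels -----------------------------------------------------------
    cog = rng.choice(3, size=n, p=np.asarray(config.cog_probs))
    Y = np.zeros((n, 13))
    Y[np.arange(n), cog] = 1.0

    de_idx = np.where(cog == 2)[0]
    if len(de_idx) > 0:
        p_base = np.asarray(config.etiology_base_probs)
        rho = config.etiology_corr
        cov = np.full((10, 10), rho)
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(10), cov, size=len(de_idx), method="cholesky")
        thresh = norm.ppf(p_base)  # P(z < thresh) = p_base
        et = (z < thresh).astype(float)
        Y[de_idx, 3:] = et

    # --- features ---------------------------------------------------------
    shifts = Y @ E.T  # (n, n_features)
    values_by_feature: dict[str, np.ndarray | list] = {}
    n_cat_dirs = 0
    for fi, spec in enumerate(schema.specs):
        if spec.kind == "numerical":
            values_by_feature[spec.name] = shifts[:, fi] + rng.normal(0, config.noise_sd, n)
        elif spec.kind == "categorical":
            k = len(spec.categories)
            logits = np.zeros((n, k))
            logits[:, -1] = shifts[:, fi]  # label shift moves mass to last category
            logits += rng.normal(0, 0.1, (n, k))  # mild baseline heterogeneity
            p = np.exp(logits - logits.max(axis=1, keepdims=True))
            p /= p.sum(axis=1, keepdims=True)
            draws = (rng.random(n)[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
            values_by_feature[spec.name] = [spec.categories[d] for d in draws]
            n_cat_dirs += 1
        else:  # imaging_embedding
            d = spec.embed_dim
            base = rng.normal(0, 1, d)
            directions = rng.normal(0, 1, (13, d))
            directions /= np.linalg.norm(directions, axis=1, keepdims=True)
            mat = base[None, :] + (Y * E[fi][None, :]) @ directions
            mat = mat + rng.normal(0, config.noise_sd, (n, d))
            values_by_feature[spec.name] = mat

    # --- missingness ------------------------------------------------------
    observed = rng.random((n, len(schema))) >= config.feature_missing_rate

    cohort_names = list(config.label_missing_profile.keys()) or [""]
    assignment = rng.choice(len(cohort_names), size=n)

    records: list[Record] = []
    for k in range(n):
        cname = cohort_names[assignment[k]]
        missing_labels = set(config.label_missing_profile.get(cname, ()))
        mask = np.array([0.0 if lab in missing_labels else 1.0 for lab in taxonomy.labels])
        values: dict = {}
        obs: dict = {}
        for fi, spec in enumerate(schema.specs):
            obs[spec.name] = bool(observed[k, fi])
            if obs[spec.name]:
                v = values_by_feature[spec.name][k]
                values[spec.name] = v if not isinstance(v, np.ndarray) else v.copy()
        records.append(
            Record(
                subject_id=f"S{k:06d}",
                visit_id="V1",
                values=values,
                observed=obs,
                y=Y[k].copy(),
                label_mask=mask,
                cohort=cname,
            )
        )
    return Cohort(schema=schema, records=records, taxonomy=taxonomy)


def split_cohort(
    cohort: Cohort,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[Cohort, Cohort, Cohort]:
    """Person-level stratified split into (train, val, test).

    All visits of one subject land in one split.  Stratification is by the
    subject's cognitive status at first visit; a stratum with fewer subjects
    than splits falls back to random assignment with a warning.
    """
    import warnings

    fr = np.asarray(fractions, dtype=float)
    if fr.min() <= 0 or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")

    rng = np.random.default_rng(seed)
    by_subject: dict[str, list[Record]] = {}
    for r in cohort.records:
        by_subject.setdefault(r.subject_id, []).append(r)

    def stratum(recs: list[Record]) -> str:
        r = recs[0]
        for i, lab in enumerate(COGNITIVE_LABELS):
            if r.label_mask[i] == 1 and r.y[i] == 1:
                return lab
        return "UNK"

    strata: dict[str, list[str]] = {}
    for sid, recs in by_subject.items():
        strata.setdefault(stratum(recs), []).append(sid)

    buckets: list[list[str]] = [[], [], []]
    for name, sids in sorted(strata.items()):
        sids = sorted(sids)
        rng.shuffle(sids)
        if len(sids) < 3:
            warnings.warn(
                f"stratum {name!r} has {len(sids)} subject(s); random fallback", stacklevel=2
            )
            for sid in sids:
                buckets[rng.choice(3, p=fr)].append(sid)
            continue
        n1 = int(round(fr[0] * len(sids)))
        n2 = int(round(fr[1] * len(sids)))
        buckets[0] += sids[:n1]
        buckets[1] += sids[n1 : n1 + n2]
        buckets[2] += sids[n1 + n2 :]

    out = []
    for bucket in buckets:
        chosen = set(bucket)
        recs = [r for r in cohort.records if r.subject_id in chosen]
        out.append(Cohort(schema=cohort.schema, records=recs, taxonomy=cohort.taxonomy))
    return tuple(out)


def save_ground_truth(config: SyntheticConfig, schema: FeatureSchema, path: str | Path) -> None:
    """Persist the planted effect matrix and config for test assertions."""
    E = config.effect_matrix
    payload = {
        "labels": list(LABELS),
        "features": schema.names,
        "effect_matrix": (np.asarray(E).tolist() if E is not None else None),
        "noise_sd": config.noise_sd,
        "cog_probs": list(config.cog_probs),
        "etiology_base_probs": list(config.etiology_base_probs),
        "etiology_corr": config.etiology_corr,
        "seed": config.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
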