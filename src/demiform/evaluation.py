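"""Evaluation harness: ROC/PR metrics, averaging modes, threshold metrics,
co-occurring-dementia analysis, and the missingness-ablation table.

AUROC follows the Mann-Whitney convention (ties count one half); AUPR uses
the average-precision step-curve convention.  Micro averaging pools every
observed (score, label) pair into one multiset; macro is the unweighted mean
of per-label values; weighted weighs each label by its positive count among
observed entries.

Co-occurring etiologies are evaluated for every subset of two or more
etiology labels with at least ``min_positive_count(0.01) = 25`` positive
records — the smallest positive count for which the distribution-free bound
on the variance of the empirical AUROC, A(1-A)/min(m, n) maximized over the
true AUROC A, stays below the variance threshold.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .schema import COGNITIVE_LABELS, ETIOLOGY_LABELS, Cohort


class UndefinedMetricError(ValueError):
    """Metric undefined for a single-class input."""


def auroc(scores, labels) -> float:
    """Area under the ROC curve == fraction of (pos, neg) pairs ranked
    correctly, ties half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if labels.min() == labels.max():
        raise UndefinedMetricError("AUROC needs at least one positive and one negative")
    return float(roc_auc_score(labels, scores))


def aupr(scores, labels) -> float:
    """Area under the precision-recall step curve (average precision)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if labels.sum() == 0:
        raise UndefinedMetricError("AUPR needs at least one positive")
    return float(average_precision_score(labels, scores))


def binary_report(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and MCC at a fixed threshold.

    MCC uses the zero-denominator convention MCC = 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n if n else 0.0
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom > 0 else 0.0
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec, "mcc": float(mcc)}


def average_metrics(per_label: list[tuple[np.ndarray, np.ndarray]], mode: str, metric: str = "auroc") -> float:
    """Micro / macro / weighted average of a per-label ranking metric.

    ``per_label`` holds (scores, labels) per label, already restricted to
    observed entries.  Labels whose metric is undefined are skipped from
    macro/weighted with a warning; micro pools everything.
    """
    fn = auroc if metric == "auroc" else aupr
    if mode == "micro":
        s = np.concatenate([p[0] for p in per_label])
        y = np.concatenate([p[1] for p in per_label])
        return fn(s, y)
    vals, weights = [], []
    for scores, labels in per_label:
        try:
            vals.append(fn(scores, labels))
        except UndefinedMetricError as e:
            warnings.warn(f"label skipped in {mode} average: {e}")
            continue
        weights.append(float(np.sum(labels)))
    if not vals:
        raise UndefinedMetricError("no label had a defined metric")
    if mode == "macro":
        return float(np.mean(vals))
    if mode == "weighted":
        w = np.asarray(weights)
        if w.sum() == 0:
            raise UndefinedMetricError("weighted average undefined with zero positives")
        return float(np.average(vals, weights=w / w.sum()))
    raise ValueError(f"unknown averaging mode {mode!r}")


def min_positive_count(variance_threshold: float) -> int:
    """Smallest positive count m with the distribution-free AUROC variance
    bound max_A A(1-A)/min(m, n) <= threshold (assuming n >= m).

    The bound peaks at A = 1/2, giving 1/(4m); threshold 0.01 yields 25.
    """
    if variance_threshold <= 0:
        raise ValueError("variance threshold must be positive")
    if variance_threshold > 0.25:
        return 1
    return int(np.ceil(1.0 / (4.0 * variance_threshold)))


@dataclass
class EvalReport:
    per_label: dict[str, dict[str, float]]
    averages: dict[str, float]
    threshold: float

    def to_dict(self) -> dict:
        return {
            "per_label": self.per_label,
            "averages": self.averages,
            "threshold": self.threshold,
        }


def evaluate_scores(
    P: np.ndarray,
    Y: np.ndarray,
    M: np.ndarray,
    labels: tuple[str, ...],
    threshold: float = 0.5,
) -> EvalReport:
    """Full report from probabilities + labels + label masks."""
    per_label: dict[str, dict[str, float]] = {}
    pairs = []
    for i, lab in enumerate(labels):
        obs = M[:, i] == 1
        y = Y[obs, i]
        entry: dict[str, float] = {
            "n_observed": int(obs.sum()),
            "n_positive": int(y.sum()),
        }
        if obs.sum() > 0 and 0 < y.sum() < obs.sum():
            s = P[obs, i]
            entry["auroc"] = auroc(s, y)
            entry["aupr"] = aupr(s, y)
            entry.update(binary_report(s, y, threshold))
            pairs.append((s, y))
        else:
            warnings.warn(f"label {lab} lacks both classes; ranking metrics skipped")
        per_label[lab] = entry
    averages = {}
    if pairs:
        for mode in ("micro", "macro", "weighted"):
            for metric in ("auroc", "aupr"):
                averages[f"{mode}_{metric}"] = average_metrics(pairs, mode, metric)
    return EvalReport(per_label=per_label, averages=averages, threshold=threshold)


def evaluate_cohort(model, cohort: Cohort, threshold: float = 0.5) -> EvalReport:
    P = model.predict_proba(cohort)
    return evaluate_scores(P, cohort.Y, cohort.M, cohort.taxonomy.labels, threshold)


# ---------------------------------------------------------------------------
# Co-occurring dementias


@dataclass
class CombinationResult:
    label_set: tuple[str, ...]
    n_positive: int
    included: bool
    auroc: float = float("nan")
    aupr: float = float("nan")


def cooccurrence_eval(
    P: np.ndarray,
    cohort: Cohort,
    min_threshold: float = 0.01,
    score_rule: str = "geometric",
    max_size: int = 3,
) -> list[CombinationResult]:
    """Evaluate every etiology combination of size >= 2 with enough positives.

    A record is a combination positive iff *all* member labels are 1 (and
    observed); all other fully-observed records are negatives.  The
    combination score aggregates member-label probabilities — geometric mean
    by default; arithmetic mean and min are available.
    """
    min_pos = min_positive_count(min_threshold)
    labels = list(cohort.taxonomy.labels)
    et_idx = {lab: labels.index(lab) for lab in ETIOLOGY_LABELS}
    Y, M = cohort.Y, cohort.M

    results: list[CombinationResult] = []
    for size in range(2, max_size + 1):
        for combo in itertools.combinations(ETIOLOGY_LABELS, size):
            idx = np.array([et_idx[lab] for lab in combo])
            observed_all = (M[:, idx] == 1).all(axis=1)
            pos = observed_all & (Y[:, idx] == 1).all(axis=1)
            n_pos = int(pos.sum())
            if n_pos == 0:
                continue
            included = n_pos >= min_pos
            res = CombinationResult(label_set=combo, n_positive=n_pos, included=included)
            if included:
                sub = P[observed_all][:, idx]
                if score_rule == "geometric":
                    s = np.exp(np.log(np.clip(sub, 1e-12, None)).mean(axis=1))
                elif score_rule == "arithmetic":
                    s = sub.mean(axis=1)
                elif score_rule == "min":
                    s = sub.min(axis=1)
                else:
                    raise ValueError(f"unknown score rule {score_rule!r}")
                y = pos[observed_all].astype(float)
                if 0 < y.sum() < len(y):
                    res.auroc = auroc(s, y)
                    res.aupr = aupr(s, y)
            results.append(res)
    if not any(r.included for r in results):
        warnings.warn("no etiology combination met the minimum positive count")
    return results


# ---------------------------------------------------------------------------
# Missingness ablation


def missingness_ablation(
    model,
    cohort: Cohort,
    feature_groups: dict[str, list[str]],
    scenarios: list[list[str]],
) -> dict[str, dict[str, float]]:
    """AUROC per cognitive label under forced feature-group missingness.

    Each scenario names groups whose features are masked at inference; an
    empty scenario reproduces the unablated metrics.  A scenario that masks
    everything is skipped with a warning.
    """
    all_features = set(model.schema.names)
    out: dict[str, dict[str, float]] = {}
    for scenario in scenarios:
        masked: set[str] = set()
        for gname in scenario:
            masked |= set(feature_groups[gname])
        key = "+".join(scenario) if scenario else "(none)"
        if masked >= all_features:
            warnings.warn(f"scenario {key!r} masks every feature; skipped")
            continue
        P = model.predict_proba(cohort, force_missing=masked or None)
        Y, M = cohort.Y, cohort.M
        row: dict[str, float] = {}
        for lab in COGNITIVE_LABELS:
            i = cohort.taxonomy.index(lab)
            obs = M[:, i] == 1
            y = Y[obs, i]
            if obs.sum() and 0 < y.sum() < len(y):
                row[lab] = auroc(P[obs, i], y)
            else:
                row[lab] = float("nan")
        out[key] = row
    return out
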