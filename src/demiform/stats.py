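"""Downstream statistical procedures for model validation.

Group-difference tests between model-probability strata (Mann-Whitney U,
two-sample Kolmogorov-Smirnov, Brunner-Munzel, t-test, with a Shapiro-Wilk
helper that picks the parametric branch), Kruskal-Wallis with Dunn's
Bonferroni-corrected post-hoc pairs, bootstrap Pearson correlation with a
percentile confidence interval, clinician/model score fusion, and the
one-sided Wilcoxon signed-rank comparison of raw versus AI-augmented rater
performance.  All tests run at the conventional 0.05 level; the functions
return the evidence, not a verdict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    alternative: str
    group_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value must lie in [0, 1]")


class SampleSizeError(ValueError):
    """A sample is too small for the requested test."""


_ALTERNATIVES = ("two-sided", "greater", "less")


def group_test(x, y, test: str = "mann_whitney", alternative: str = "two-sided") -> TestResult:
    """Two-sample test; ``greater`` means x stochastically larger than y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    min_n = 5 if test == "brunner_munzel" else 2
    if len(x) < min_n or len(y) < min_n:
        raise SampleSizeError(f"{test} needs each sample size >= {min_n}")
    if test == "mann_whitney":
        res = sps.mannwhitneyu(x, y, alternative=alternative)
    elif test == "ks_2samp":
        # scipy phrases 'greater' as CDF dominance (x stochastically
        # smaller); flip so 'greater' means x stochastically larger
        flipped = {"two-sided": "two-sided", "greater": "less", "less": "greater"}
        res = sps.ks_2samp(x, y, alternative=flipped[alternative])
    elif test == "brunner_munzel":
        # t-approximation with Satterthwaite degrees of freedom
        res = sps.brunnermunzel(x, y, alternative=alternative, distribution="t")
    elif test == "t_test":
        res = sps.ttest_ind(x, y, alternative=alternative)
    else:
        raise ValueError(f"unknown test {test!r}")
    return TestResult(
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        group_sizes=(len(x), len(y)),
    )


def auto_group_test(x, y, alternative: str = "two-sided", alpha: float = 0.05) -> TestResult:
    """Shapiro-Wilk screening: t-test when both samples look normal,
    Mann-Whitney otherwise (mirrors the usual clinical branching)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    normal = (
        len(x) >= 3
        and len(y) >= 3
        and sps.shapiro(x).pvalue > alpha
        and sps.shapiro(y).pvalue > alpha
    )
    return group_test(x, y, "t_test" if normal else "mann_whitney", alternative)


def kruskal_dunn(groups: list[np.ndarray]) -> tuple[TestResult, np.ndarray]:
    """Kruskal-Wallis omnibus plus Dunn's pairwise z-tests, Bonferroni over
    all pairs.  Returns (omnibus, symmetric corrected-p matrix, diag 1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise SampleSizeError("each group needs n >= 2")
    H, p = sps.kruskal(*groups)
    omnibus = TestResult(
        test="kruskal_wallis",
        statistic=float(H),
        p_value=float(p),
        alternative="two-sided",
        group_sizes=tuple(len(g) for g in groups),
    )

    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction term for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (N - 1))

    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)

    k = len(groups)
    n_pairs = k * (k - 1) // 2
    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(
                (N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            z = (mean_ranks[i] - mean_ranks[j]) / se
            raw = 2 * sps.norm.sf(abs(z))
            corrected = min(1.0, raw * n_pairs)
            pmat[i, j] = pmat[j, i] = corrected
    return omnibus, pmat


def bootstrap_pearson(
    x, y, B: int = 1000, seed: int = 0, ci: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Case-resampled Pearson r: mean over B resamples and percentile CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if B < 200:
        raise ValueError("need B >= 200 resamples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    rng = np.random.default_rng(seed)
    n = len(x)
    rs = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, n)
        xv, yv = x[idx], y[idx]
        if np.std(xv) == 0 or np.std(yv) == 0:
            rs[b] = np.nan
            continue
        rs[b] = np.corrcoef(xv, yv)[0, 1]
    rs = rs[~np.isnan(rs)]
    lo = (1 - ci) / 2
    return float(rs.mean()), (float(np.quantile(rs, lo)), float(np.quantile(rs, 1 - lo)))


def fuse_scores(confidence: float, probability: float, strict: bool = False) -> float:
    """AI-augmented score: mean of the clinician confidence and the model
    probability.

    Default rescales confidence from [0, 100] to [0, 1] first; ``strict``
    averages the raw mismatched scales (replication mode — the 0-100 term
    dominates) and returns a value in [0, 50.5].
    """
    confidence = float(confidence)
    probability = float(probability)
    if not (0 <= confidence <= 100):
        raise ValueError("confidence must lie in [0, 100]")
    if not (0 <= probability <= 1):
        raise ValueError("probability must lie in [0, 1]")
    if strict:
        import warnings

        warnings.warn("strict fusion averages mismatched scales; dominated by confidence")
        return (confidence + probability) / 2
    return (confidence / 100.0 + probability) / 2


def compare_raters(raw_metrics, augmented_metrics) -> TestResult:
    """One-sided Wilcoxon signed-rank: is augmented > raw, pairwise?

    All-zero differences yield the degenerate convention p = 1.
    """
    raw = np.asarray(raw_metrics, dtype=float)
    aug = np.asarray(augmented_metrics, dtype=float)
    if len(raw) != len(aug) or len(raw) < 5:
        raise SampleSizeError("need paired lists of equal length >= 5")
    diff = aug - raw
    if np.all(diff == 0):
        import warnings

        warnings.warn("all paired differences are zero; degenerate test, p = 1")
        return TestResult(
            test="wilcoxon_signed_rank",
            statistic=0.0,
            p_value=1.0,
            alternative="greater",
            group_sizes=(len(raw),),
        )
    res = sps.wilcoxon(aug, raw, alternative="greater")
    return TestResult(
        test="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative="greater",
        group_sizes=(len(raw),),
    )
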