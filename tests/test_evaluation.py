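"""Metric oracles: pair-count AUROC, step-curve AUPR, averaging identities,
threshold metrics, minimum-positive rule, co-occurrence harness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from demiform.evaluation import (
    UndefinedMetricError,
    aupr,
    auroc,
    average_metrics,
    binary_report,
    cooccurrence_eval,
    evaluate_scores,
    min_positive_count,
)
from demiform.schema import Cohort, LabelTaxonomy, Record
from demiform.simulate import SyntheticConfig, default_schema, generate_cohort


def pair_count_auroc(scores, labels):
    """Mann-Whitney pair statistic: correct pairs + half ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_label_inversion_symmetry(self, rng):
        s = rng.random(50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        assert auroc(s, 1 - y) == pytest.approx(1 - auroc(s, y))

    def test_tie_hand_case(self):
        """scores (0.9, 0.8, 0.8, 0.1), labels (1,1,0,0) -> 3.5/4."""
        assert auroc([0.9, 0.8, 0.8, 0.1], [1, 1, 0, 0]) == pytest.approx(0.875)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.1, 0.9], [1, 1])

    def test_fuzz_equals_pair_count_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(4, 40)
            s = np.round(rng.random(n), 2)  # rounding induces ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            assert auroc(s, y) == pytest.approx(pair_count_auroc(s, y), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.sampled_from(["exp", "affine", "cube"]), st.integers(0, 10**6))
    def test_invariance_under_strictly_increasing_transform(self, kind, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=20)
        y = rng.integers(0, 2, 20)
        if y.min() == y.max():
            return
        t = {"exp": np.exp, "affine": lambda x: 3 * x + 7, "cube": lambda x: x**3}[kind]
        assert auroc(t(s), y) == pytest.approx(auroc(s, y), abs=1e-12)


class TestAupr:
    def test_perfect_ranking(self):
        assert aupr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_random_scores_converge_to_prevalence(self, rng):
        n, pi = 10000, 0.3
        y = (rng.random(n) < pi).astype(int)
        s = rng.random(n)
        assert abs(aupr(s, y) - pi) < 0.02

    def test_step_curve_riemann_hand_case(self):
        """4-point case cross-checked against direct summation of the
        precision-recall step curve (average-precision convention:
        sum over positives of precision-at-their-rank * delta-recall)."""
        scores = [0.9, 0.7, 0.6, 0.2]
        labels = [1, 0, 1, 0]
        # descending: ranks 1..4 -> precision at positives: 1/1 (0.9), 2/3 (0.6)
        expected = 0.5 * (1 / 1) + 0.5 * (2 / 3)
        assert aupr(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_no_positive_raises(self):
        with pytest.raises(UndefinedMetricError):
            aupr([0.5, 0.6], [0, 0])


class TestAveraging:
    def test_identical_per_label_values_macro_equals_value(self, rng):
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        v = auroc(s, y)
        per = [(s, y), (s.copy(), y.copy()), (s.copy(), y.copy())]
        assert average_metrics(per, "macro") == pytest.approx(v)

    def test_single_label_all_modes_agree(self, rng):
        s = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        per = [(s, y)]
        vals = {m: average_metrics(per, m) for m in ("micro", "macro", "weighted")}
        assert vals["micro"] == vals["macro"] == vals["weighted"]

    def test_micro_is_pooled_pair_count(self, rng):
        a = (rng.random(20), rng.integers(0, 2, 20))
        b = (rng.random(15), rng.integers(0, 2, 15))
        a[1][:2] = [0, 1]
        b[1][:2] = [0, 1]
        pooled_s = np.concatenate([a[0], b[0]])
        pooled_y = np.concatenate([a[1], b[1]])
        assert average_metrics([a, b], "micro") == pytest.approx(
            pair_count_auroc(pooled_s, pooled_y)
        )

    def test_weighted_uses_positive_counts(self):
        sa = np.array([0.9, 0.8, 0.2, 0.1]); ya = np.array([1, 1, 0, 0])   # AUROC 1, 2 pos
        sb = np.array([0.1, 0.9]); yb = np.array([1, 0])                   # AUROC 0, 1 pos
        got = average_metrics([(sa, ya), (sb, yb)], "weighted")
        assert got == pytest.approx((1.0 * 2 + 0.0 * 1) / 3)


class TestBinaryReport:
    def test_perfect_predictions(self):
        rep = binary_report([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert rep["accuracy"] == rep["sensitivity"] == rep["specificity"] == rep["mcc"] == 1.0

    def test_mcc_hand_case_one_third(self):
        """TP=2, FP=1, FN=1, TN=2 -> MCC = 3/9 = 1/3."""
        scores = [0.9, 0.8, 0.7, 0.2, 0.1, 0.3]
        labels = [1, 1, 0, 1, 0, 0]
        rep = binary_report(scores, labels, threshold=0.5)
        assert rep["mcc"] == pytest.approx(1 / 3)

    def test_all_positive_predictor(self):
        rep = binary_report([0.9, 0.9, 0.9, 0.9], [1, 0, 1, 0], threshold=0.5)
        assert rep["sensitivity"] == 1.0
        assert rep["specificity"] == 0.0
        assert rep["mcc"] == 0.0  # zero-denominator convention


class TestMinPositiveCount:
    @pytest.mark.parametrize("thr,expected", [(0.01, 25), (0.25, 1), (0.005, 50)])
    def test_bound_inversion(self, thr, expected):
        assert min_positive_count(thr) == expected

    def test_above_quarter_returns_one(self):
        assert min_positive_count(0.3) == 1

    def test_nonpositive_threshold_raises(self):
        with pytest.raises(ValueError):
            min_positive_count(0.0)


def _cooccur_cohort(n_pos, seed=0, signal=True):
    """Cohort with an AD+LBD planted subgroup of exactly n_pos records."""
    rng = np.random.default_rng(seed)
    tax = LabelTaxonomy()
    records = []
    n = 600
    P = np.zeros((n, 13))
    for k in range(n):
        y = np.zeros(13)
        y[2] = 1.0
        if k < n_pos:
            y[tax.index("AD")] = 1.0
            y[tax.index("LBD")] = 1.0
        elif k < n_pos + 150:
            y[tax.index("AD")] = 1.0
        else:
            y[tax.index("VD")] = 1.0
        records.append(
            Record(
                subject_id=f"s{k}", visit_id="v", values={}, observed={},
                y=y, label_mask=np.ones(13),
            )
        )
        p = rng.uniform(0.05, 0.3, 13)
        if signal:
            p[y == 1] += 0.6  # informative probabilities
        P[k] = np.clip(p + rng.normal(0, 0.05, 13), 1e-6, 1 - 1e-6)
    schema = default_schema(1, 0)
    return P, Cohort(schema=schema, records=records)


class TestCooccurrence:
    def test_planted_combination_recovered(self):
        P, cohort = _cooccur_cohort(n_pos=100, signal=True)
        results = cooccurrence_eval(P, cohort)
        hit = [r for r in results if set(r.label_set) == {"AD", "LBD"}]
        assert hit and hit[0].included
        assert hit[0].auroc > 0.8

    def test_minimum_positive_boundary_24_vs_25(self):
        for n_pos, included in ((24, False), (25, True)):
            P, cohort = _cooccur_cohort(n_pos=n_pos)
            results = cooccurrence_eval(P, cohort)
            hit = [r for r in results if set(r.label_set) == {"AD", "LBD"}]
            assert hit and hit[0].included is included

    def test_no_cooccurrence_yields_no_qualifying_combination(self):
        cohort = generate_cohort(
            SyntheticConfig(n=200, etiology_corr=0.0, seed=1,
                            etiology_base_probs=(0.3,) + (0.001,) * 9),
            default_schema(2, 0),
        )
        P = np.random.default_rng(0).random((200, 13))
        with pytest.warns(UserWarning, match="no etiology combination"):
            results = cooccurrence_eval(P, cohort)
        assert not any(r.included for r in results)


def test_evaluate_scores_report_structure(rng):
    n = 200
    Y = rng.integers(0, 2, (n, 13)).astype(float)
    M = np.ones((n, 13))
    P = np.clip(0.6 * Y + 0.2 + rng.normal(0, 0.1, (n, 13)), 1e-6, 1 - 1e-6)
    rep = evaluate_scores(P, Y, M, LabelTaxonomy().labels)
    assert set(rep.averages) == {
        "micro_auroc", "micro_aupr", "macro_auroc", "macro_aupr",
        "weighted_auroc", "weighted_aupr",
    }
    for lab, entry in rep.per_label.items():
        assert 0 <= entry["auroc"] <= 1
        assert -1 <= entry["mcc"] <= 1


class TestMissingnessAblation:
    @pytest.fixture(scope="class")
    def ablation_setup(self):
        """Model trained on a cohort where only the first six features carry
        signal; the rest are pure noise."""
        from demiform.model import DementiaTransformer, ModelConfig
        from demiform.training import TrainConfig
        from demiform.simulate import split_cohort

        schema = default_schema(n_numerical=12, n_categorical=0)
        rng = np.random.default_rng(13)
        E = np.zeros((12, 13))
        for li in range(13):
            idx = rng.choice(6, size=3, replace=False)  # signal in f0..f5 only
            E[idx, li] = 2.0 * rng.choice([-1, 1], size=3)
        cohort = generate_cohort(SyntheticConfig(n=1000, effect_matrix=E, seed=13), schema)
        train, _, _ = split_cohort(cohort, (0.8, 0.1, 0.1), seed=13)
        # larger independent probe keeps the chance-level check tight
        test = generate_cohort(SyntheticConfig(n=1500, effect_matrix=E, seed=14), schema)
        model = DementiaTransformer(
            train, config=ModelConfig(d_model=32, n_layers=2, n_heads=4, d_ff=128, seed=0)
        )
        model.fit(val_cohort=None, train_config=TrainConfig(epochs=15, batch_size=128, seed=0))
        groups = {
            "signal": [f"num{i:02d}" for i in range(6)],
            "noise": [f"num{i:02d}" for i in range(6, 12)],
        }
        return model, test, groups

    def test_empty_scenario_reproduces_unablated_metrics(self, ablation_setup):
        from demiform.evaluation import missingness_ablation

        model, test, groups = ablation_setup
        table = missingness_ablation(model, test, groups, [[]])
        P = model.predict_proba(test)
        Y, M = test.Y, test.M
        for lab in ("NC", "MCI", "DE"):
            i = test.taxonomy.index(lab)
            obs = M[:, i] == 1
            assert table["(none)"][lab] == pytest.approx(auroc(P[obs, i], Y[obs, i]))

    def test_masking_noise_group_is_inert_masking_signal_collapses(self, ablation_setup):
        from demiform.evaluation import missingness_ablation

        model, test, groups = ablation_setup
        table = missingness_ablation(model, test, groups, [[], ["noise"], ["signal"]])
        for lab in ("NC", "MCI", "DE"):
            assert abs(table["noise"][lab] - table["(none)"][lab]) < 0.1
            assert abs(table["signal"][lab] - 0.5) < 0.12  # no information -> chance

    def test_masking_everything_is_skipped_with_warning(self, ablation_setup):
        from demiform.evaluation import missingness_ablation

        model, test, groups = ablation_setup
        with pytest.warns(UserWarning, match="every feature"):
            table = missingness_ablation(model, test, groups, [["signal", "noise"]])
        assert table == {}
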