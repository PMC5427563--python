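import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from dockppi.classify import (
    DecisionRule,
    aggregate_topn,
    cross_validate,
    predict_pairs,
    roc_curve,
    select_threshold_max_mcc,
    train_classifier,
)
from dockppi.features import FEATURE_COLUMNS


def feature_frame(values, informative="vdw_attractive"):
    """A feature table with one informative column, the rest zero."""
    n = len(values)
    df = pd.DataFrame(0.0, index=range(n), columns=list(FEATURE_COLUMNS))
    df[informative] = values
    df.insert(0, "model_rank", 1)
    df.insert(0, "pair_id", [f"p{i}" for i in range(n)])
    return df


def pair_comparison_auc(scores, labels):
    """Oracle: AUC as P(score+ > score-) with ties counted half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None]).sum() + 0.5 * (pos[:, None] == neg[None]).sum()
    return wins / (len(pos) * len(neg))


class TestTrainClassifier:
    def test_separable_classes(self, rng):
        pos = feature_frame(rng.normal(10.0, 0.5, 100))
        neg = feature_frame(rng.normal(-10.0, 0.5, 100))
        clf = train_classifier(pos, neg, n_trees=50, seed=0)
        held_pos = feature_frame(rng.normal(10.0, 0.5, 50))
        held_neg = feature_frame(rng.normal(-10.0, 0.5, 50))
        scores = np.concatenate([clf.predict_proba(held_pos), clf.predict_proba(held_neg)])
        labels = np.array([1] * 50 + [0] * 50)
        assert roc_curve(scores, labels).auc > 0.99

    def test_permuted_labels_chance_auc(self, rng):
        x = rng.normal(size=400)
        perm = rng.permutation(400)
        labels = np.array([1] * 200 + [0] * 200)[perm]
        pos = feature_frame(x[labels == 1])
        neg = feature_frame(x[labels == 0])
        _, roc = cross_validate(pos, neg, k=5, n_trees=100, seed=1)
        assert roc.auc == pytest.approx(0.5, abs=0.12)

    def test_seed_determinism(self, rng):
        pos = feature_frame(rng.normal(1.0, 1.0, 60))
        neg = feature_frame(rng.normal(-1.0, 1.0, 60))
        held = feature_frame(rng.normal(0.0, 1.0, 30))
        a = train_classifier(pos, neg, n_trees=50, seed=3).predict_proba(held)
        b = train_classifier(pos, neg, n_trees=50, seed=3).predict_proba(held)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self, rng):
        pos = feature_frame(rng.normal(size=10))
        with pytest.raises(ValueError):
            train_classifier(pos, pos.iloc[:0], seed=0)


class TestCrossValidate:
    def test_stratified_fold_contract(self, rng):
        pos = feature_frame(rng.normal(1, 1, 53))
        neg = feature_frame(rng.normal(-1, 1, 47))
        oof, _ = cross_validate(pos, neg, k=5, n_trees=20, seed=0)
        # every example scored exactly once
        assert len(oof) == 100 and oof["prob"].notna().all()
        assert oof["label"].sum() == 53

    def test_gaussian_separation_matches_analytic_auc(self, rng):
        # equal-variance Gaussians at separation delta have
        # AUC = Phi(delta / sqrt(2)); delta=2 -> 0.921
        delta = 2.0
        pos = feature_frame(rng.normal(delta, 1.0, 1000))
        neg = feature_frame(rng.normal(0.0, 1.0, 1000))
        _, roc = cross_validate(pos, neg, k=10, n_trees=300, seed=0)
        assert roc.auc == pytest.approx(norm.cdf(delta / np.sqrt(2)), abs=0.03)

    def test_k_validation(self, rng):
        pos = feature_frame(rng.normal(size=20))
        neg = feature_frame(rng.normal(size=20))
        with pytest.raises(ValueError):
            cross_validate(pos, neg, k=1)
        with pytest.raises(ValueError):
            cross_validate(pos, neg, k=25)


class TestRocCurve:
    def test_perfect_scores(self):
        assert roc_curve([1, 1, 0, 0], [1, 1, 0, 0]).auc == 1.0

    def test_constant_scores(self):
        assert roc_curve([0.5] * 6, [1, 0, 1, 0, 1, 0]).auc == pytest.approx(0.5)

    def test_hand_case(self):
        # scores .9,.8,.4,.3 / labels 1,0,1,0: 3 of 4 pos-neg pairs won
        roc = roc_curve([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        assert roc.auc == pytest.approx(0.75)

    def test_matches_pair_comparison_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 200))
            scores = rng.choice(np.linspace(0, 1, 17), size=n)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert roc_curve(scores, labels).auc == pytest.approx(
                pair_comparison_auc(scores, labels), abs=1e-12
            )

    def test_endpoints_and_monotonicity(self, rng):
        roc = roc_curve(rng.random(50), rng.integers(0, 2, 50))
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.2, 0.8], [1, 1])


class TestSelectThresholdMaxMcc:
    def test_separable_returns_lowest_gap_value(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        t, m = select_threshold_max_mcc(scores, labels)
        assert m.MCC == 1.0
        assert t == 0.2  # lowest threshold achieving MCC 1 under strict >

    def test_overlapping_gaussians_midpoint(self, rng):
        scores = np.concatenate(
            [rng.normal(0.35, 0.1, 2000), rng.normal(0.65, 0.1, 2000)]
        )
        labels = np.array([0] * 2000 + [1] * 2000)
        t, _ = select_threshold_max_mcc(scores, labels)
        assert t == pytest.approx(0.5, abs=0.05)

    def test_all_scores_equal(self):
        t, m = select_threshold_max_mcc([0.4] * 6, [1, 0, 1, 0, 1, 0])
        assert t == 0.4 and m.MCC == 0.0

    def test_matches_dense_grid_scan(self, rng):
        from dockppi.interface_metrics import ConfusionCounts, classify_metrics

        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        t, m = select_threshold_max_mcc(scores, labels)
        best = -2.0
        for g in np.linspace(0, 1, 4001):
            pred = scores > g
            tp = int((pred & (labels == 1)).sum())
            fp = int((pred & (labels == 0)).sum())
            cm = classify_metrics(
                ConfusionCounts(tp, fp, int((labels == 0).sum()) - fp,
                                int((labels == 1).sum()) - tp)
            )
            best = max(best, cm.MCC)
        assert m.MCC == pytest.approx(best, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_threshold_max_mcc([0.1, 0.9], [1, 1])


class TestAggregateTopn:
    RULE = DecisionRule(probability_threshold=0.13, top_n=3)

    @pytest.mark.parametrize(
        "probs, rule, expected",
        [
            ([0.05, 0.20, 0.10], RULE, True),
            ([0.05, 0.12], DecisionRule(0.13, 2), False),
            ([0.12, 0.90], DecisionRule(0.13, 1), False),  # rank 2 not considered
            ([0.13], DecisionRule(0.13, 1), False),  # strictly greater
            ([0.131], DecisionRule(0.13, 1), True),
        ],
    )
    def test_rule_application(self, probs, rule, expected):
        assert aggregate_topn(probs, rule) is expected

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_topn([], self.RULE)

    def test_positive_set_nested_in_topn(self, rng):
        """Monotonicity: predictions under top-(n-1) are a subset of top-n,
        so TPR and FPR are non-decreasing in n."""
        pair_probs = [rng.random(5).tolist() for _ in range(200)]
        labels = rng.integers(0, 2, 200)
        prev_pos: set[int] = set()
        prev_tpr = prev_fpr = 0.0
        for n in range(1, 6):
            rule = DecisionRule(probability_threshold=0.5, top_n=n)
            pos = {i for i, p in enumerate(pair_probs) if aggregate_topn(p, rule)}
            assert prev_pos <= pos
            tp = sum(labels[i] for i in pos)
            fp = len(pos) - tp
            tpr = tp / labels.sum()
            fpr = fp / (len(labels) - labels.sum())
            assert tpr >= prev_tpr - 1e-12 and fpr >= prev_fpr - 1e-12
            prev_pos, prev_tpr, prev_fpr = pos, tpr, fpr

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            DecisionRule(probability_threshold=1.5)
        with pytest.raises(ValueError):
            DecisionRule(top_n=0)


class TestPredictPairs:
    def test_decisions_follow_rule(self, rng):
        pos = feature_frame(rng.normal(3, 1, 60))
        neg = feature_frame(rng.normal(-3, 1, 60))
        clf = train_classifier(pos, neg, n_trees=50, seed=0)
        table = pd.concat(
            [feature_frame(rng.normal(3, 1, 3)), feature_frame(rng.normal(-3, 1, 3))],
            ignore_index=True,
        )
        table["pair_id"] = ["good"] * 3 + ["bad"] * 3
        table["model_rank"] = [1, 2, 3, 1, 2, 3]
        preds = predict_pairs(clf, table, DecisionRule(0.5, 3))
        by_id = {p.pair_id: p for p in preds}
        assert by_id["good"].decision and not by_id["bad"].decision
        assert by_id["good"].max_considered_prob > 0.5
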