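"""Dataset assembly, the three classifier families, ROC/PR evaluation, Venn."""

import math

import numpy as np
import pandas as pd
import pytest

from dsbpred import (
    GenomicInterval,
    IntervalSet,
    LabeledDataset,
    SeparationError,
    assemble_dataset,
    evaluate_scores,
    percentage,
    train_forest,
    train_lasso,
    train_logistic_unpenalized,
    venn_summary,
)


def concordance_oracle(y, s):
    """AUROC as pairwise concordance probability (ties count 1/2)."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def bernoulli_frame(rng, n, probs):
    return pd.DataFrame(
        {name: (rng.random(n) < p).astype(float) for name, p in probs.items()}
    )


def full_train_dataset(pos, neg, seed=0):
    """All rows in training; token test rows satisfying the split contract."""
    features = pd.concat([pos, neg], ignore_index=True)
    labels = np.r_[np.ones(len(pos), int), np.zeros(len(neg), int)]
    return LabeledDataset(
        features, labels, np.arange(len(labels)), np.array([0, len(labels) - 1]), seed
    )


class TestAssembleDataset:
    def test_stratified_split_sizes_and_balance(self, rng):
        pos = bernoulli_frame(rng, 100, {"x": 0.7})
        neg = bernoulli_frame(rng, 100, {"x": 0.2})
        data = assemble_dataset(pos, neg, test_fraction=0.3, seed=1)
        assert len(data.train_idx) == 140 and len(data.test_idx) == 60
        assert abs(data.y_test.sum() - 30) <= 1
        assert abs(data.y_train.sum() - 70) <= 1

    def test_same_seed_reproduces_split(self, rng):
        pos = bernoulli_frame(rng, 50, {"x": 0.7})
        neg = bernoulli_frame(rng, 50, {"x": 0.2})
        a = assemble_dataset(pos, neg, 0.3, seed=3)
        b = assemble_dataset(pos, neg, 0.3, seed=3)
        assert np.array_equal(a.train_idx, b.train_idx)

    def test_feature_mismatch_lists_difference(self, rng):
        pos = bernoulli_frame(rng, 30, {"x": 0.5, "extra": 0.5})
        neg = bernoulli_frame(rng, 30, {"x": 0.5})
        with pytest.raises(ValueError, match="extra"):
            assemble_dataset(pos, neg, 0.3, seed=0)


class TestRandomForest:
    def test_planted_single_mark_recovered(self, rng):
        pos = bernoulli_frame(rng, 2000, {"mark": 0.91, "noise": 0.5})
        neg = bernoulli_frame(rng, 2000, {"mark": 0.11, "noise": 0.5})
        data = assemble_dataset(pos, neg, 0.3, seed=2)
        res = train_forest(data, seed=2, n_trees=200)
        ev = res.evaluate(data, n_boot=0)
        assert ev.auroc > 0.85
        assert res.importance.idxmax() == "mark"

    def test_label_shuffle_gives_chance_auroc(self, rng):
        pos = bernoulli_frame(rng, 1000, {"mark": 0.91, "noise": 0.5})
        neg = bernoulli_frame(rng, 1000, {"mark": 0.11, "noise": 0.5})
        data = assemble_dataset(pos, neg, 0.3, seed=4)
        shuffled = data.labels.copy()
        rng.shuffle(shuffled)
        data2 = LabeledDataset(
            data.features, shuffled, data.train_idx, data.test_idx, 4
        )
        res = train_forest(data2, seed=4, n_trees=200)
        assert res.evaluate(data2, n_boot=0).auroc == pytest.approx(0.5, abs=0.05)

    def test_single_class_training_rejected(self, rng):
        pos = bernoulli_frame(rng, 50, {"x": 0.5})
        with pytest.raises(ValueError):
            full_train_dataset(pos, pos.iloc[:0], seed=0)

    def test_scores_are_vote_fractions_in_unit_interval(self, rng):
        pos = bernoulli_frame(rng, 100, {"x": 0.9})
        neg = bernoulli_frame(rng, 100, {"x": 0.1})
        data = assemble_dataset(pos, neg, 0.3, seed=5)
        res = train_forest(data, seed=5, n_trees=50)
        s = res.predict_proba(data.features)
        assert np.all((0 <= s) & (s <= 1))
        # vote fractions are multiples of 1/n_trees
        assert np.allclose(np.round(s * 50), s * 50)


class TestLasso:
    def test_sparsity_recovery_with_decoys(self, rng):
        probs_pos = {"signal": 0.9} | {f"decoy{i}": 0.5 for i in range(5)}
        probs_neg = {"signal": 0.1} | {f"decoy{i}": 0.5 for i in range(5)}
        pos = bernoulli_frame(rng, 400, probs_pos)
        neg = bernoulli_frame(rng, 400, probs_neg)
        data = assemble_dataset(pos, neg, 0.3, seed=6)
        res = train_lasso(data, n_folds=5, seed=6)
        assert res.coef["signal"] > 1.0
        decoys = res.coef.drop("signal").abs()
        assert (decoys < 0.3).all()
        assert (decoys == 0).sum() >= 3

    def test_pure_noise_shrinks_everything_to_zero(self, rng):
        probs = {f"f{i}": 0.5 for i in range(4)}
        pos = bernoulli_frame(rng, 300, probs)
        neg = bernoulli_frame(rng, 300, probs)
        data = assemble_dataset(pos, neg, 0.3, seed=7)
        res = train_lasso(data, n_folds=5, seed=7)
        assert np.allclose(res.coef.to_numpy(), 0.0)

    def test_constant_feature_dropped_with_warning(self, rng):
        pos = bernoulli_frame(rng, 200, {"x": 0.8})
        neg = bernoulli_frame(rng, 200, {"x": 0.2})
        pos["flat"] = 1.0
        neg["flat"] = 1.0
        data = assemble_dataset(pos, neg, 0.3, seed=8)
        with pytest.warns(UserWarning, match="flat"):
            res = train_lasso(data, n_folds=5, seed=8)
        assert res.coef["flat"] == 0.0 and "flat" in res.dropped_features


class TestLogistic:
    def test_closed_form_log_odds_single_binary_feature(self):
        # table (a,b,c,d) = (30,10,10,30): beta = ln(9)
        pos = pd.DataFrame({"x": [1.0] * 30 + [0.0] * 10})
        neg = pd.DataFrame({"x": [1.0] * 10 + [0.0] * 30})
        data = full_train_dataset(pos, neg)
        res = train_logistic_unpenalized(data)
        assert res.coef["x"] == pytest.approx(math.log(9), abs=1e-4)
        assert res.pvalues["x"] < 0.01

    def test_null_feature_pvalues_roughly_uniform(self, rng):
        pvals = []
        for _ in range(120):
            pos = pd.DataFrame({"x": (rng.random(60) < 0.5).astype(float)})
            neg = pd.DataFrame({"x": (rng.random(60) < 0.5).astype(float)})
            try:
                res = train_logistic_unpenalized(full_train_dataset(pos, neg))
            except SeparationError:
                continue
            pvals.append(res.pvalues["x"])
        pvals = np.array(pvals)
        assert 0.35 < pvals.mean() < 0.65
        assert (pvals < 0.05).mean() < 0.15

    def test_separable_data_raises(self):
        pos = pd.DataFrame({"x": [1.0] * 30})
        neg = pd.DataFrame({"x": [0.0] * 30})
        with pytest.raises(SeparationError):
            train_logistic_unpenalized(full_train_dataset(pos, neg))


class TestEvaluate:
    def test_perfect_separation_gives_unit_areas(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        ev = evaluate_scores(y, s, n_boot=0)
        assert ev.auroc == 1.0 and ev.aupr == 1.0

    def test_small_example_concordance(self):
        y = np.array([1, 1, 1, 0])
        s = np.array([0.9, 0.8, 0.2, 0.4])
        assert evaluate_scores(y, s, n_boot=0).auroc == pytest.approx(2 / 3)

    def test_matches_concordance_oracle_on_random_draws(self, rng):
        y = (rng.random(200) < 0.4).astype(int)
        s = np.round(rng.random(200), 2)  # ties included
        ev = evaluate_scores(y, s, n_boot=0)
        assert ev.auroc == pytest.approx(concordance_oracle(y, s), abs=1e-10)

    def test_invariance_under_monotone_transform(self, rng):
        y = (rng.random(300) < 0.5).astype(int)
        s = rng.random(300)
        a = evaluate_scores(y, s, n_boot=0).auroc
        b = evaluate_scores(y, np.exp(3 * s), n_boot=0).auroc
        assert a == pytest.approx(b)

    def test_roc_endpoints(self, rng):
        y = (rng.random(100) < 0.5).astype(int)
        s = rng.random(100)
        ev = evaluate_scores(y, s, n_boot=0)
        assert (ev.roc_points.fpr.iloc[0], ev.roc_points.tpr.iloc[0]) == (0.0, 0.0)
        assert (ev.roc_points.fpr.iloc[-1], ev.roc_points.tpr.iloc[-1]) == (1.0, 1.0)

    def test_bootstrap_ci_brackets_point_estimate(self, rng):
        y = np.r_[np.ones(80, int), np.zeros(80, int)]
        s = np.r_[rng.normal(1, 1, 80), rng.normal(0, 1, 80)]
        ev = evaluate_scores(y, s, n_boot=300, seed=1)
        lo, hi = ev.auroc_ci
        assert lo - 0.02 <= ev.auroc <= hi + 0.02

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_scores(np.ones(5, int), np.random.rand(5), n_boot=0)


class TestVenn:
    def test_printed_percentage_rule(self):
        assert percentage(18_084, 18_510) == 97.70
        assert percentage(63_587, 66_591) == 95.49
        assert percentage(1_552, 83_225) == 1.86
        assert percentage(55_048, 84_821) == 64.90
        assert percentage(605, 73_363) == 0.82

    def test_rounding_is_half_up(self):
        assert percentage(1, 8) == 12.50
        assert percentage(1005, 100_000) == 1.01  # 1.005 rounds up

    def test_identical_sets_have_no_exclusive_cells(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 700)])
        v = venn_summary(s, s, s)
        for key in ("pred", "refA", "refB"):
            assert v.counts[key]["neither"] == 0
            assert v.counts[key]["both"] == v.counts[key]["total"]

    def test_overlap_counts_by_single_base(self):
        pred = IntervalSet([GenomicInterval("chr1", 0, 100)])
        refA = IntervalSet([GenomicInterval("chr1", 99, 200)])
        refB = IntervalSet([GenomicInterval("chr1", 100, 200)])
        v = venn_summary(pred, refA, refB)
        assert v.counts["pred"]["refA"] == 1
        assert v.counts["pred"]["refB"] == 0
        assert v.pct("pred", "refA") == 100.0
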