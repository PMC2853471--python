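"""Performance measures, ROC, fold construction and cross-validation.

The threshold-dependent measures are checked against an independent
brute-force tally, the AUC against a Mann-Whitney pair-counting oracle.
"""

import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from nadbinder.encoding import WindowConfig, build_feature_matrix
from nadbinder.evaluation import (
    ConfusionCounts,
    confusion,
    cross_validate,
    make_folds,
    performance,
    roc_auc,
    sweep_windows,
)
from nadbinder.structures import ProteinChain, ResidueLabelSet


def brute_force_tally(pred, truth):
    """Element-by-element oracle for the 2x2 table."""
    tp = fp = tn = fn = 0
    for p, t in zip(pred, truth, strict=True):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and not t:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def mann_whitney_auc(scores, truth):
    """Pair-counting oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusion:
    @pytest.mark.parametrize(
        "pred,truth,expect",
        [
            ([1, 0, 1], [1, 0, 1], (2, 0, 1, 0)),
            ([0, 1, 0], [1, 0, 1], (0, 1, 0, 2)),
            ([], [], (0, 0, 0, 0)),
        ],
    )
    def test_examples(self, pred, truth, expect):
        c = confusion(pred, truth)
        assert (c.TP, c.FP, c.TN, c.FN) == expect

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])

    def test_matches_brute_force_tally(self, rng):
        # the spec'd 1000-trial equivalence check
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            pred = rng.integers(0, 2, n)
            truth = rng.integers(0, 2, n)
            c = confusion(pred, truth)
            assert (c.TP, c.FP, c.TN, c.FN) == brute_force_tally(pred, truth)


class TestPerformance:
    def test_perfect_balanced(self):
        r = performance(ConfusionCounts(TP=50, FP=0, TN=50, FN=0))
        assert (r.Sn, r.Sp, r.Acc, r.MCC) == (100.0, 100.0, 100.0, 1.0)

    def test_hand_computed_example(self):
        r = performance(ConfusionCounts(TP=70, FN=30, TN=77, FP=23))
        assert r.Sn == pytest.approx(70.0)
        assert r.Sp == pytest.approx(77.0)
        assert r.Acc == pytest.approx(73.5)
        expected_mcc = (70 * 77 - 23 * 30) / math.sqrt(93 * 100 * 100 * 107)
        assert r.MCC == pytest.approx(expected_mcc)

    def test_all_positive_predictor_mcc_zero(self):
        r = performance(ConfusionCounts(TP=50, FP=50, TN=0, FN=0))
        assert (r.Sn, r.Sp, r.MCC) == (100.0, 0.0, 0.0)
        assert r.mcc_undefined

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            performance(ConfusionCounts(0, 0, 0, 0))

    def test_mcc_matches_sklearn(self, rng):
        for _ in range(200):
            pred = rng.integers(0, 2, 40)
            truth = rng.integers(0, 2, 40)
            r = performance(confusion(pred, truth))
            assert -1.0 <= r.MCC <= 1.0
            if not r.mcc_undefined:
                assert r.MCC == pytest.approx(matthews_corrcoef(truth, pred))


class TestROC:
    def test_perfect_separation(self):
        curve = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert curve.auc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        curve = roc_auc([0.5] * 10, [1, 0] * 5)
        assert curve.auc == pytest.approx(0.5)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(size=10_000)
        truth = rng.integers(0, 2, 10_000)
        assert roc_auc(scores, truth).auc == pytest.approx(0.5, abs=0.03)

    def test_endpoints_and_monotone(self, rng):
        scores = rng.normal(size=100)
        truth = rng.integers(0, 2, 100)
        c = roc_auc(scores, truth)
        assert c.fpr[0] == c.tpr[0] == 0.0
        assert c.fpr[-1] == c.tpr[-1] == 1.0
        assert np.all(np.diff(c.fpr) >= 0) and np.all(np.diff(c.tpr) >= 0)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_mann_whitney_oracle(self, rng):
        for n in (20, 75, 200):
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            truth = rng.integers(0, 2, n)
            if truth.min() == truth.max():
                truth[0] = 1 - truth[0]
            assert roc_auc(scores, truth).auc == pytest.approx(
                mann_whitney_auc(scores, truth)
            )


class TestFolds:
    def test_ten_chains_five_folds_of_two(self):
        plan = make_folds([f"c{i}" for i in range(10)], k=5, seed=1)
        sizes = [len(plan.fold_chains(f)) for f in range(5)]
        assert sizes == [2] * 5

    def test_partition_and_determinism(self):
        ids = [f"c{i}" for i in range(13)]
        p1 = make_folds(ids, seed=4)
        p2 = make_folds(ids, seed=4)
        assert p1.assignment == p2.assignment
        assert sorted(p1.assignment) == sorted(ids)
        sizes = [len(p1.fold_chains(f)) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1

    def test_too_few_chains(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], k=5)


def _center_rule_dataset(rng, n_chains=15, L=40):
    """Labels are a deterministic function of the centre residue: perfectly
    learnable from any window."""
    aa = list("ARNDCQEGHILKMFPSTWYV")
    chains, labels = [], []
    for i in range(n_chains):
        seq = "".join(rng.choice(aa, L))
        chains.append(ProteinChain(f"c{i}", seq))
        labels.append(
            ResidueLabelSet(f"c{i}", tuple(1 if c in "GYT" else 0 for c in seq))
        )
    return chains, labels


class TestCrossValidate:
    def test_learnable_center_rule_is_perfect(self, rng):
        chains, labels = _center_rule_dataset(rng)
        res = cross_validate(chains, labels, "t 2 g 0.1 j 1 c 10",
                             WindowConfig(3), "binary", seed=0)
        assert res.mean.Acc == pytest.approx(100.0)
        assert res.mean.MCC == pytest.approx(1.0)

    def test_five_per_fold_reports(self, rng):
        chains, labels = _center_rule_dataset(rng, n_chains=10, L=25)
        res = cross_validate(chains, labels, cfg=WindowConfig(3), seed=0)
        assert len(res.per_fold) == 5

    def test_chain_level_fold_integrity(self, small_world):
        _, chains, labels, _, _ = small_world
        _, _, index = build_feature_matrix(chains, labels, "binary", WindowConfig(5))
        plan = make_folds([c.id for c in chains], seed=3)
        folds = index["chain_id"].map(plan.assignment)
        assert (index.groupby("chain_id")[folds.name].count() > 0).all()
        assert folds.groupby(index["chain_id"]).nunique().max() == 1

    def test_shuffled_labels_give_null_mcc(self, rng):
        chains, labels = _center_rule_dataset(rng, n_chains=20, L=50)
        flat = np.concatenate([l.as_array() for l in labels])
        rng2 = np.random.default_rng(11)
        rng2.shuffle(flat)
        shuffled, k = [], 0
        for l in labels:
            n = len(l)
            shuffled.append(ResidueLabelSet(l.chain_id, tuple(int(v) for v in flat[k:k + n])))
            k += n
        res = cross_validate(chains, shuffled, cfg=WindowConfig(3), seed=11)
        assert abs(res.mean.MCC) < 0.15  # small-n null; the 150-chain check is tighter


class TestSweep:
    def test_single_window_row_and_schema(self, rng):
        chains, labels = _center_rule_dataset(rng, n_chains=10, L=25)
        table = sweep_windows(chains, labels, "t 2 g 0.1 j 1 c 1", W_list=(3,), seed=0)
        assert list(table.columns) == ["window", "kernel", "thr", "Sn", "Sp", "Acc", "MCC"]
        assert len(table) == 1 and table.loc[0, "window"] == 3
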