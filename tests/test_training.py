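"""Labelling, oversampling, splitters, metrics and the fit loop."""

import numpy as np
import pytest

from crisprattn.errors import SamplingError, ValidationError
from crisprattn.models import ModelConfig, build_model
from crisprattn.training import (
    TrainConfig,
    balanced_batches,
    evaluate_classifier,
    evaluate_regressor,
    kfold_split,
    label_top_fraction,
    leave_groups_out,
    train_model,
)


class TestLabelTopFraction:
    def test_top_20_percent_of_100(self, rng):
        labels = label_top_fraction(rng.permutation(100).astype(float), 0.2)
        assert labels.sum() == 20

    def test_small_n_rounds(self):
        labels = label_top_fraction([5.0, 1.0, 3.0, 2.0, 4.0], 0.2)
        assert labels.sum() == 1
        assert labels[0] == 1  # the maximum

    def test_ties_broken_by_stable_input_order(self):
        labels = label_top_fraction([1.0] * 10, 0.2)
        assert labels.tolist() == [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]

    def test_positives_are_the_highest_scores(self, rng):
        scores = rng.normal(size=50)
        labels = label_top_fraction(scores, 0.2)
        assert scores[labels == 1].min() >= scores[labels == 0].max()

    def test_empty_and_bad_fraction(self):
        with pytest.raises(ValidationError):
            label_top_fraction([], 0.2)
        with pytest.raises(ValidationError):
            label_top_fraction([1.0], 1.5)


class TestBalancedBatches:
    def test_heavy_imbalance_batches_are_balanced(self):
        labels = np.array([0] * 1000 + [1] * 10)
        seen_neg = []
        for batch in balanced_batches(labels, 32, seed=0):
            frac = labels[batch].mean()
            assert 0.4 <= frac <= 0.6
            seen_neg.extend(b for b in batch if labels[b] == 0)
        # every negative visited exactly once per epoch
        assert sorted(seen_neg) == list(range(1000))

    def test_balanced_input_stays_balanced(self):
        labels = np.array([0, 1] * 50)
        for batch in balanced_batches(labels, 20, seed=1):
            assert 0.4 <= labels[batch].mean() <= 0.6

    def test_single_class_raises(self):
        with pytest.raises(SamplingError):
            next(balanced_batches(np.zeros(10, dtype=int), 4, seed=0))


class TestSplitters:
    def test_kfold_partitions_evenly(self):
        split = kfold_split(list(range(10)), k=5, seed=0)
        sizes = [list(split.fold_assignments.values()).count(f) for f in range(5)]
        assert sizes == [2] * 5
        assert set(split.fold_assignments) == set(range(10))

    def test_kfold_sizes_differ_by_at_most_one(self):
        split = kfold_split(list(range(23)), k=5, seed=1)
        sizes = [list(split.fold_assignments.values()).count(f) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValidationError):
            kfold_split([1, 2], k=5)

    def test_leave_three_sgrnas_out(self, rng):
        groups = [f"sg{i % 10}" for i in range(100)]
        held = {"sg1", "sg4", "sg7"}
        ho = leave_groups_out(list(range(100)), groups, held)
        test_groups = {groups[i] for i in ho.test_idx}
        train_groups = {groups[i] for i in ho.train_idx}
        assert test_groups == held
        assert not (train_groups & test_groups)
        assert len(ho.train_idx) + len(ho.test_idx) == 100

    def test_repeated_draws_give_distinct_triples(self, rng):
        sgrnas = [f"sg{i}" for i in range(10)]
        triples = {tuple(sorted(rng.choice(sgrnas, size=3, replace=False))) for _ in range(10)}
        assert len(triples) > 1  # combinatorially 120 choices, collisions rare


class TestMetrics:
    def test_perfect_separation(self):
        rep = evaluate_classifier([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert rep.auc_roc == pytest.approx(1.0)
        assert rep.pr_auc == pytest.approx(1.0)

    def test_hand_counted_auc(self):
        # pairwise wins: (0.9 beats 0.8 and 0.1; 0.7 beats 0.1 only) -> 3/4
        rep = evaluate_classifier([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
        assert rep.auc_roc == pytest.approx(0.75)

    def test_auc_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 200)
        y[:5], y[5:10] = 1, 0
        s = rng.normal(size=200)
        r1 = evaluate_classifier(y, s).auc_roc
        r2 = evaluate_classifier(y, np.exp(3 * s) + 7).auc_roc
        assert r1 == pytest.approx(r2)

    def test_random_scorer_pr_auc_near_prevalence(self, rng):
        y = np.array([1] * 20 + [0] * 180)
        prevalence = y.mean()
        aucs = [
            evaluate_classifier(y, rng.permutation(len(y)).astype(float)).pr_auc
            for _ in range(200)
        ]
        mean, sd = np.mean(aucs), np.std(aucs)
        assert abs(mean - prevalence) < 3 * sd

    def test_regression_identity(self):
        y = [0.3, -1.0, 2.0, 0.0]
        rep = evaluate_regressor(y, y)
        assert rep.spearman == pytest.approx(1.0)
        assert rep.pearson == pytest.approx(1.0)
        assert rep.mse == 0.0

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_classifier([1, 1, 1], [0.1, 0.5, 0.9])


class TestTrainLoop:
    def test_seeded_run_reproducible_and_loss_decreases(self, rng):
        toks = rng.integers(0, 16, size=(120, 19))
        y = rng.normal(size=120) + toks[:, 3]  # learnable signal
        cfg = ModelConfig.compact(max_len=19, task="regress", seed=5)
        tcfg = TrainConfig(epochs=4, batch_size=32, val_fraction=0.1, seed=5)
        _, _, h1 = train_model(build_model("attn_crispr", cfg), toks, y, cfg=tcfg)
        _, _, h2 = train_model(build_model("attn_crispr", cfg), toks, y, cfg=tcfg)
        assert h1 == h2  # machine-precision reproducibility
        assert h1[-1] < h1[0]

    def test_evaluation_uses_unresampled_holdout(self, rng):
        # positives oversampled in training batches must not inflate the
        # validation set: its class balance equals the raw data's
        toks = rng.integers(0, 16, size=(200, 20))
        y = np.array([1] * 20 + [0] * 180)
        cfg = ModelConfig.compact(max_len=20, task="classify", seed=2)
        tcfg = TrainConfig(epochs=1, batch_size=32, val_fraction=0.2, seed=2)
        _, report, _ = train_model(build_model("attn_mismatch", cfg), toks, y, cfg=tcfg)
        assert report.n_samples == 40
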