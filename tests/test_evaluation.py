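"""Metrics, negative controls, cross-validation and ROC/AUC cross-checks."""

import numpy as np
import pytest
from scipy.stats import rankdata

from pirnadetect.evaluation import (ConfusionCounts, auc_trapezoid,
                                    crossvalidate, make_negatives, metrics,
                                    parameter_sweep)
from pirnadetect.sequence_io import SequenceSet
from pirnadetect.simulate import FixtureSpec


def mann_whitney_auc(y_true, scores):
    """Rank-statistic AUC: tie-aware Mann-Whitney U / (n_pos * n_neg)."""
    y_true = np.asarray(y_true)
    ranks = rankdata(scores)
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    u = ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


class TestMetrics:
    @pytest.mark.parametrize("tpr,fpr,acc_pct", [
        (0.848, 0.160, 84.40),   # balanced design, human piRNA row
        (0.806, 0.213, 79.65),   # balanced design, mouse piRNA row
        (0.837, 0.195, 82.10),   # rat row (printed 82.11 rounds from folds)
    ])
    def test_balanced_acc_consistent_with_rates(self, tpr, fpr, acc_pct):
        n = 1000
        counts = ConfusionCounts(tp=int(round(tpr * n)), fn=n - int(round(tpr * n)),
                                 fp=int(round(fpr * n)), tn=n - int(round(fpr * n)))
        acc, got_tpr, got_fpr = metrics(counts)
        assert got_tpr == pytest.approx(tpr, abs=1e-12)
        assert got_fpr == pytest.approx(fpr, abs=1e-12)
        assert 100 * acc == pytest.approx(acc_pct, abs=0.051)

    def test_symmetric_confusion(self):
        acc, tpr, fpr = metrics(ConfusionCounts(tp=10, fn=10, tn=10, fp=10))
        assert (acc, tpr, fpr) == (0.5, 0.5, 0.5)

    def test_zero_denominators_identified(self):
        with pytest.raises(ZeroDivisionError, match="TPR"):
            metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        with pytest.raises(ZeroDivisionError, match="FPR"):
            metrics(ConfusionCounts(tp=5, fn=5, tn=0, fp=0))

    def test_identities_against_raw_recomputation(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(1, 100, 4)
            acc, tpr, fpr = metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            assert abs(acc - (tp + tn) / (tp + tn + fp + fn)) < 1e-12
            assert abs(tpr - tp / (tp + fn)) < 1e-12
            assert abs(fpr - fp / (tn + fp)) < 1e-12


class TestMakeNegatives:
    def test_construction_contract(self, two_family_data):
        pos, background, _ = two_family_data
        neg = make_negatives(pos, background, rng_seed=0)
        assert len(neg) == len(pos)
        assert [r.length for r in neg] == [r.length for r in pos]

    def test_seed_changes_sequences_not_lengths(self, two_family_data):
        pos, background, _ = two_family_data
        a = make_negatives(pos, background, rng_seed=0)
        b = make_negatives(pos, background, rng_seed=1)
        assert [r.length for r in a] == [r.length for r in b]
        assert any(x.bases != y.bases for x, y in zip(a, b))

    def test_background_too_short_rejected(self, two_family_data, rng):
        pos, _, _ = two_family_data
        from conftest import random_sequences
        short_bg = random_sequences(rng, 5, length_range=(10, 12), prefix="bg")
        with pytest.raises(ValueError, match="length"):
            make_negatives(pos, short_bg, rng_seed=0)


class TestAUC:
    def test_trapezoid_matches_rank_statistic(self, rng):
        """Two equivalent AUC definitions agree on 100 random score sets."""
        for i in range(100):
            n = int(rng.integers(20, 200))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0], y[-1] = 0, 1
            if i % 3 == 0:  # exercise tie handling
                scores = rng.integers(0, 5, n).astype(float)
            else:
                scores = rng.normal(size=n)
            assert auc_trapezoid(y, scores) == pytest.approx(
                mann_whitney_auc(y, scores), abs=1e-9)


class TestCrossValidate:
    @staticmethod
    def oracle_trainer(truth_positive_ids):
        def train(train_pos, train_neg, seed):
            return lambda seqs: np.array(
                [1.0 if r.id in truth_positive_ids else 0.0 for r in seqs])
        return train

    def test_oracle_classifier_is_perfect(self, two_family_data):
        pos, background, _ = two_family_data
        neg = make_negatives(pos, background, rng_seed=0)
        trainer = self.oracle_trainer({r.id for r in pos})
        report = crossvalidate(pos, neg, k=5, trainer=trainer, rng_seed=0)
        assert report.acc == 1.0 and report.auc == 1.0
        # partition laws: per-class fold sizes differ by at most one
        sizes = [c.tp + c.fn for c in report.fold_counts]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == len(pos)

    def test_random_scorer_near_half(self, rng):
        from conftest import random_sequences
        pos = random_sequences(rng, 1000, prefix="p")
        neg = random_sequences(rng, 1000, prefix="n")

        def trainer(train_pos, train_neg, seed):
            local = np.random.default_rng(seed)
            return lambda seqs: local.random(len(seqs))

        report = crossvalidate(pos, neg, k=5, trainer=trainer, rng_seed=1)
        assert 0.45 <= report.auc <= 0.55
        assert 0.47 <= report.acc <= 0.53

    def test_constant_scorer_balanced_accuracy(self, rng):
        from conftest import random_sequences
        pos = random_sequences(rng, 100, prefix="p")
        neg = random_sequences(rng, 100, prefix="n")
        trainer = lambda tp, tn, s: (lambda seqs: np.full(len(seqs), 0.5))
        report = crossvalidate(pos, neg, k=5, trainer=trainer, rng_seed=0)
        assert report.acc == pytest.approx(0.5)

    def test_too_few_folds_rejected(self, two_family_data):
        pos, background, _ = two_family_data
        neg = make_negatives(pos, background, rng_seed=0)
        with pytest.raises(ValueError):
            crossvalidate(pos, neg, k=1, trainer=None)


class TestParameterSweep:
    def test_grid_shape_and_unreachable_threshold(self):
        spec = FixtureSpec(num_families=2, motif_length=12, rng_seed=0)
        table = parameter_sweep(
            sizes=[60], n_th_values=[10, 1000], z_th_values=[1.5],
            fixture_spec=spec, rng_seed=0, k=3,
            clustering_ensemble_size=200, detection_ensemble_size=200)
        assert len(table) == 2
        blocked = table[table.n_th == 1000]
        assert (blocked.mean_families == 0).all()
        assert blocked.acc.isna().all()
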