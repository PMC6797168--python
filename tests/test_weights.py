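import numpy as np
import pytest

from popsignal import (
    auc_weights,
    balanced_accuracy,
    learn_weights,
    monte_carlo_splits,
    select_regularization,
)
from popsignal.weights import predict


def auc_pair_oracle(counts, labels):
    """O(J^2) pair counting: P(count_match > count_nonmatch), ties 1/2."""
    pos = counts[labels == 1]
    neg = counts[labels == -1]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestMonteCarloSplits:
    @pytest.mark.parametrize("j, train_size", [(10, 5), (11, 5), (25, 12)])
    def test_half_split_sizes_disjoint(self, j, train_size):
        labels = np.array([-1, 1] * (j // 2) + [1] * (j % 2))
        for s in monte_carlo_splits(labels, n_runs=5, seed=0):
            assert s.train_idx.size == train_size
            assert s.valid_idx.size == j - train_size
            assert np.intersect1d(s.train_idx, s.valid_idx).size == 0
            for idx in (s.train_idx, s.valid_idx):
                assert {-1, 1} <= set(labels[idx])

    def test_reproducible_from_seed(self):
        labels = np.array([-1, 1] * 10)
        a = monte_carlo_splits(labels, n_runs=3, seed=42)
        b = monte_carlo_splits(labels, n_runs=3, seed=42)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.train_idx, sb.train_idx)
            assert np.array_equal(sa.valid_idx, sb.valid_idx)
        c = monte_carlo_splits(labels, n_runs=3, seed=43)
        assert any(not np.array_equal(sa.train_idx, sc.train_idx) for sa, sc in zip(a, c))

    def test_tiny_class_rejected(self):
        labels = np.array([1] * 10 + [-1] * 3)
        with pytest.raises(ValueError):
            monte_carlo_splits(labels, n_runs=2, seed=0)


class TestBalancedAccuracy:
    @pytest.mark.parametrize(
        "pred, lab, expected",
        [
            ([1, 1, -1, -1], [1, 1, -1, -1], 1.0),
            ([1, 1, 1, 1], [1, 1, -1, -1], 0.5),
            ([1, 1, -1, 1], [1, 1, -1, -1], 0.75),  # TP=2 FN=0 TN=1 FP=1
        ],
    )
    def test_arithmetic(self, pred, lab, expected):
        assert balanced_accuracy(np.array(pred), np.array(lab)) == expected

    def test_single_class_labels_error(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.array([1, -1]), np.array([1, 1]))


class TestSelectRegularization:
    def test_single_element_grid(self, rng):
        x = rng.standard_normal((4, 20))
        y = np.array([-1, 1] * 10)
        assert select_regularization(x, y, grid=[0.3], seed=0) == 0.3

    def test_separable_data_good_bac(self):
        rng = np.random.default_rng(5)
        y = np.array([-1, 1] * 30)
        x = rng.standard_normal((6, 60)) * 0.2
        x[0] += 3.0 * y  # strongly separable along neuron 0
        c = select_regularization(x, y, seed=0)
        # brute evaluation: the chosen C must reach near-perfect fold BAC
        wv = learn_weights(x, y, C=c)
        assert balanced_accuracy(predict(wv, x), y) > 0.95

    def test_tie_breaks_to_smallest(self, rng):
        # perfectly separable by a wide margin: all C tie at BAC=1
        y = np.array([-1, 1] * 12)
        x = np.zeros((2, 24))
        x[0] = 10.0 * y
        c = select_regularization(x, y, grid=(0.5, 0.01, 0.1), seed=0)
        assert c == 0.01


class TestLearnWeights:
    def test_separation_along_one_neuron(self):
        rng = np.random.default_rng(2)
        y = np.array([-1, 1] * 20)
        x = rng.standard_normal((2, 40)) * 0.05
        x[0] += 2.0 * y
        wv = learn_weights(x, y, C=1.0)
        assert abs(wv.weights[0]) > 0.99  # direction found by margin maximization
        assert wv.weights[0] > 0  # positive weight for the "match"-preferring neuron
        assert abs(wv.weights[1]) < 0.15

    def test_unit_norm_and_duplicate_symmetry(self, rng):
        y = np.array([-1, 1] * 15)
        x = rng.standard_normal((3, 30))
        x[0] += 0.8 * y
        xd = np.vstack([x, x[0]])  # duplicate neuron 0's feature column
        wv = learn_weights(xd, y, C=0.5)
        assert abs(np.linalg.norm(wv.weights) - 1.0) < 1e-10
        assert abs(wv.weights[0] - wv.weights[3]) < 1e-6

    def test_sign_recovery_on_separable_session(self, small_session):
        sess = small_session
        sts = sess.test
        split = monte_carlo_splits(sts.labels, n_runs=1, seed=0)[0]
        from popsignal import spike_counts_zscored

        cm = spike_counts_zscored(sts, stats_trials=split.train_idx)
        wv = learn_weights(cm.zscores[:, split.train_idx], sts.labels[split.train_idx], C=0.01)
        recovered = (np.sign(wv.weights) == sess.truth["signs"]).mean()
        assert recovered >= 0.9

    def test_label_permutation_bac_near_chance(self, rng):
        """Training on permuted labels gives chance-level validation BAC."""
        x = rng.standard_normal((6, 40))
        y = np.array([-1, 1] * 20)
        bacs = []
        for _ in range(100):
            perm = rng.permutation(40)
            yp = y[perm]
            wv = learn_weights(x[:, :20], yp[:20], C=0.01)
            bacs.append(balanced_accuracy(predict(wv, x[:, 20:]), yp[20:]))
        assert 0.45 < np.mean(bacs) < 0.55


class TestAUCWeights:
    def test_perfect_separation(self):
        counts = np.array([[0, 1, 2, 10, 11, 12]])
        labels = np.array([-1, -1, -1, 1, 1, 1])
        wv = auc_weights(counts, labels)
        # AUC = 1 -> centered +0.5; single neuron -> unit scaling
        assert wv.weights[0] == pytest.approx(1.0)

    def test_identical_distributions_zero(self):
        counts = np.array([[3, 3, 3, 3]])
        labels = np.array([-1, 1, -1, 1])
        assert auc_weights(counts, labels).weights[0] == 0.0

    def test_matches_pair_count_oracle(self, rng):
        counts = rng.integers(0, 8, size=(5, 30))
        labels = np.where(rng.random(30) < 0.4, 1, -1)
        labels[:2] = [1, -1]
        wv = auc_weights(counts, labels)
        aucs = np.array([auc_pair_oracle(counts[n], labels) for n in range(5)])
        centered = aucs - 0.5
        expect = centered / np.linalg.norm(centered)
        assert np.allclose(wv.weights, expect, atol=1e-12)

    def test_positive_scaling_keeps_weight_sign(self, rng):
        y = np.array([-1, 1] * 15)
        x = rng.standard_normal((3, 30)) * 0.1
        x[1] += 1.5 * y
        w1 = learn_weights(x, y, C=0.1).weights
        x2 = x.copy()
        x2[1] *= 7.0
        w2 = learn_weights(x2, y, C=0.1).weights
        assert np.sign(w1[1]) == np.sign(w2[1]) == 1
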