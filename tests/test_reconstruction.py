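import numpy as np
import pytest

from popsignal import (
    WeightVector,
    center_and_average,
    layer_split,
    make_kernel,
    masked_weights,
    reconstruct_trial,
    reconstruct_trials,
    sign_split,
    subpop_signal,
    univariate_signals,
)


def reconstruction_oracle(spikes_trial, w, kernel_values):
    """Naive double sum: x(t_k) = sum_tau (w . o(t_k - tau)) u(tau)."""
    n, k = spikes_trial.shape
    x = np.zeros(k)
    for t in range(k):
        for tau in range(len(kernel_values)):
            if t - tau >= 0:
                proj = sum(w[nn] * spikes_trial[nn, t - tau] for nn in range(n))
                x[t] += proj * kernel_values[tau]
    return x


class TestKernel:
    def test_closed_form(self):
        ker = make_kernel(rate=1 / 20, support_length=40)
        assert ker.values[0] == 1.0
        assert ker.values[20] == pytest.approx(np.exp(-1.0))
        assert np.all(np.diff(ker.values) < 0)

    def test_normalized_sums_to_one(self):
        ker = make_kernel(rate=1 / 10, normalized=True)
        assert abs(ker.values.sum() - 1.0) < 1e-12

    def test_default_support_and_delta_limit(self):
        assert len(make_kernel(rate=1 / 20)) == 100
        delta = make_kernel(rate=50.0, support_length=1)
        spikes = np.zeros((2, 30), dtype=np.uint8)
        spikes[1, 4] = 1
        w = np.array([0.3, -0.7])
        x = reconstruct_trial(spikes, w, delta)
        assert np.allclose(x, w @ spikes)  # support-1 kernel: raw weighted train


class TestReconstructTrial:
    def test_zero_spikes_zero_signal(self):
        ker = make_kernel()
        assert np.all(reconstruct_trial(np.zeros((3, 50)), np.ones(3), ker) == 0)

    def test_single_spike_impulse_response(self):
        ker = make_kernel(rate=1 / 20, support_length=30)
        spikes = np.zeros((2, 80), dtype=np.uint8)
        spikes[1, 10] = 1
        w = np.array([0.5, -0.8])
        x = reconstruct_trial(spikes, w, ker)
        assert np.all(x[:10] == 0)
        assert np.allclose(x[10:40], -0.8 * ker.values)
        assert np.all(x[40:] == 0)

    def test_matches_double_sum_oracle(self, rng):
        ker = make_kernel(rate=1 / 15)
        spikes = (rng.random((4, 60)) < 0.1).astype(np.uint8)
        w = rng.standard_normal(4)
        got = reconstruct_trial(spikes, w, ker)
        assert np.allclose(got, reconstruction_oracle(spikes, w, ker.values), atol=1e-12)

    def test_vectorized_matches_per_trial(self, random_set, rng):
        ker = make_kernel()
        w = rng.standard_normal(random_set.n_neurons)
        mat = reconstruct_trials(random_set, w, ker)
        for j in range(random_set.n_trials):
            assert np.allclose(mat[j], reconstruct_trial(random_set.spikes[:, j], w, ker), atol=1e-9)

    def test_linearity_in_weights(self, random_set, rng):
        ker = make_kernel()
        w1 = rng.standard_normal(random_set.n_neurons)
        w2 = rng.standard_normal(random_set.n_neurons)
        a, b = 0.7, -1.3
        lhs = reconstruct_trials(random_set, a * w1 + b * w2, ker)
        rhs = a * reconstruct_trials(random_set, w1, ker) + b * reconstruct_trials(random_set, w2, ker)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            reconstruct_trial(np.zeros((3, 10)), np.ones(2), make_kernel())

    def test_filter_area_rescaling(self, rng):
        """Signals with different time constants agree in time-averaged
        value after dividing by the kernel area."""
        from popsignal import SpikeTrainSet

        spikes = (rng.random((6, 10, 500)) < 0.05).astype(np.uint8)
        sts = SpikeTrainSet(spikes=spikes, labels=np.array([-1, 1] * 5))
        w = np.abs(rng.standard_normal(6)) + 0.1
        means = []
        for rate in (1 / 10, 1 / 20, 1 / 50):
            ker = make_kernel(rate)
            x = reconstruct_trials(sts, w, ker) / ker.area
            means.append(x[:, 300:].mean())  # past the onset transient
        means = np.array(means)
        assert np.all(np.abs(means - means.mean()) / means.mean() < 0.05)


class TestCenterAndAverage:
    def test_two_trials_algebra(self):
        a = np.linspace(0, 1, 20)
        b = np.cos(np.linspace(0, 3, 20))
        sig = center_and_average(np.vstack([a, b]), np.array([1, -1]))
        assert np.allclose(sig.difference, a - b, atol=1e-12)
        assert np.allclose(sig.centered[0], (a - b) / 2, atol=1e-12)
        assert np.allclose(sig.centered[1], -(a - b) / 2, atol=1e-12)

    def test_equal_condition_means_zero_difference(self, rng):
        x = rng.standard_normal(30)
        sig = center_and_average(np.vstack([x, x]), np.array([1, -1]))
        assert np.allclose(sig.difference, 0.0, atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        per_trial = rng.standard_normal((12, 25))
        labels = np.array([-1, 1] * 6)
        sig = center_and_average(per_trial, labels)
        z = np.array([per_trial[:, t].sum() / 12 for t in range(25)])
        cen = per_trial - z
        m = cen[labels == 1].mean(axis=0)
        nm = cen[labels == -1].mean(axis=0)
        assert np.allclose(sig.mean_all, z, atol=1e-12)
        assert np.allclose(sig.difference, m - nm, atol=1e-12)
        assert np.allclose(sig.centered.mean(axis=0), 0.0, atol=1e-10)

    def test_single_class_error(self, rng):
        with pytest.raises(ValueError):
            center_and_average(rng.standard_normal((4, 10)), np.array([1, 1, 1, 1]))


class TestSubpopulations:
    def test_sign_split_corrections(self):
        plus, minus = sign_split(np.array([0.6, -0.8]))
        assert plus.correction == minus.correction == 1.0
        plus, minus = sign_split(np.array([0.1, 0.2, -0.3]))
        assert plus.correction == pytest.approx(3 / 4)
        assert minus.correction == pytest.approx(3 / 2)

    def test_zero_weights_in_neither_pool(self):
        plus, minus = sign_split(np.array([0.5, 0.0, -0.5]))
        assert plus.n_sub == minus.n_sub == 1
        assert not plus.mask[1] and not minus.mask[1]

    def test_empty_side_flagged_and_zero_signal(self, random_set):
        plus, minus = sign_split(np.array([0.2, 0.3, 0.1, 0.4, 0.5]))
        assert not minus.valid
        sig = subpop_signal(random_set, np.array([0.2, 0.3, 0.1, 0.4, 0.5]), minus, make_kernel())
        assert not sig.valid
        assert np.all(sig.per_trial == 0)

    def test_sign_decomposition_identity(self, random_set, rng):
        w = rng.standard_normal(random_set.n_neurons)
        w[w == 0] = 0.1
        ker = make_kernel()
        full = reconstruct_trials(random_set, w, ker)
        plus, minus = sign_split(w)
        xp = reconstruct_trials(random_set, masked_weights(w, plus), ker)
        xm = reconstruct_trials(random_set, masked_weights(w, minus), ker)
        assert np.allclose(full, xp / plus.correction + xm / minus.correction, atol=1e-10)

    def test_layer_split_corrections_and_identity(self, random_set, rng):
        w = rng.standard_normal(random_set.n_neurons)
        layers = np.array(["SG", "SG", "G", "G", "IG"])
        specs = layer_split(w, layers)
        assert specs["SG"].correction == pytest.approx(5 / 6)
        ker = make_kernel()
        full = reconstruct_trials(random_set, w, ker)
        total = sum(
            reconstruct_trials(random_set, masked_weights(w, s), ker) / s.correction
            for s in specs.values()
        )
        assert np.allclose(full, total, atol=1e-10)

    def test_all_one_layer(self, rng):
        specs = layer_split(rng.standard_normal(4), np.array(["SG"] * 4))
        assert specs["SG"].correction == pytest.approx(1 / 3)
        assert not specs["G"].valid and not specs["IG"].valid

    def test_subpop_equals_premasked_pipeline(self, random_set, rng):
        w = rng.standard_normal(random_set.n_neurons)
        plus, _ = sign_split(w)
        ker = make_kernel()
        sig = subpop_signal(random_set, w, plus, ker)
        manual = center_and_average(
            reconstruct_trials(random_set, masked_weights(w, plus), ker), random_set.labels
        )
        assert np.allclose(sig.difference, manual.difference, atol=1e-12)


class TestUnivariateSignals:
    def test_zero_weight_zero_signal_and_locality(self, random_set):
        w = np.array([0.5, 0.0, -0.5, 0.3, -0.1])
        aucw = WeightVector(weights=w, method="auc")
        ker = make_kernel()
        sigs = univariate_signals(random_set, aucw, ker)
        assert np.all(sigs[1].per_trial == 0)
        # locality: perturbing other neurons' spikes leaves neuron 0's signal unchanged
        perturbed = random_set.subset_trials(np.arange(random_set.n_trials))
        perturbed.spikes[1:] = 0
        sigs2 = univariate_signals(perturbed, aucw, ker)
        assert np.allclose(sigs[0].per_trial, sigs2[0].per_trial, atol=1e-12)

    def test_single_spike_is_scaled_kernel(self):
        from popsignal import SpikeTrainSet

        spikes = np.zeros((1, 2, 60), dtype=np.uint8)
        spikes[0, 0, 5] = 1
        sts = SpikeTrainSet(spikes=spikes, labels=np.array([1, -1]))
        aucw = WeightVector(weights=np.array([0.4]), method="auc")
        ker = make_kernel(rate=1 / 20, support_length=30)
        sigs = univariate_signals(sts, aucw, ker)
        assert np.allclose(sigs[0].per_trial[0, 5:35], 0.4 * ker.values, atol=1e-12)

    def test_requires_auc_method(self, random_set):
        with pytest.raises(ValueError):
            univariate_signals(random_set, WeightVector(weights=np.ones(5), method="svm"), make_kernel())
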