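"""Single-trial reconstruction of the low-dimensional population signal.

The population signal models the synaptic current a hypothetical read-out
neuron receives from the recorded population: each spike is weighted by
its neuron's decoding weight, weighted trains are summed across neurons
and convolved with a causal exponential kernel (each spike causes a jump
followed by exponential decay).  Signals are centered on the across-trial
mean, averaged by condition, and the match minus non-match difference is
the discrimination statistic.  Sign-specific (plus/minus neurons),
layer-specific (SG/G/IG) and single-neuron (univariate) variants mask the
weight vector and rescale it with a pool-size correction factor so that
signals are comparable across subpopulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .core import SpikeTrainSet
from .weights import WeightVector

#: Default exponential decay rate (1/ms): time constant 20 ms.
DEFAULT_RATE = 1.0 / 20.0


@dataclass
class ExponentialKernel:
    """Causal exponential kernel u(tau) = exp(-rate * tau), tau = 0..L-1 bins.

    ``area`` is the sum of the unnormalized kernel values; dividing a
    signal by it removes the amplitude scaling introduced by the filter
    time constant, leaving only the smoothing.
    """

    rate: float
    support_length: int
    normalized: bool
    values: np.ndarray
    area: float

    def __len__(self) -> int:
        return self.support_length


def make_kernel(
    rate: float = DEFAULT_RATE,
    support_length: int | None = None,
    normalized: bool = False,
) -> ExponentialKernel:
    """Build the exponential kernel; support defaults to ceil(5/rate) bins
    (>= 99.3% of the kernel mass)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if support_length is None:
        support_length = int(np.ceil(5.0 / rate))
    if support_length < 1:
        raise ValueError("support_length must be >= 1")
    tau = np.arange(support_length)
    values = np.exp(-rate * tau)
    area = float(values.sum())
    if normalized:
        values = values / area
    return ExponentialKernel(
        rate=rate, support_length=support_length, normalized=normalized, values=values, area=area
    )


@dataclass
class SubpopulationSpec:
    """Mask + correction factor defining a subpopulation read-out.

    ``correction`` is f = N / (g * N_sub) with g the number of pools the
    population is split into (2 for sign pools, 3 for layers); it scales
    the masked weights so subpopulation signals are comparable across
    pools of different sizes.
    """

    mask: np.ndarray
    kind: str
    correction: float
    n_sub: int
    valid: bool = True


@dataclass
class PopulationSignal:
    """Per-trial population signal and its condition summaries.

    ``per_trial`` holds x_j(t_k) for the (validation) trials used;
    ``centered`` is x_j - z with z the across-trial mean; condition means
    are means of the centered signal, and ``difference`` is
    match minus non-match.
    """

    per_trial: np.ndarray
    centered: np.ndarray
    mean_all: np.ndarray
    cond_mean_match: np.ndarray
    cond_mean_nonmatch: np.ndarray
    difference: np.ndarray
    group: str = "all"
    kernel: ExponentialKernel | None = None
    labels: np.ndarray | None = None
    valid: bool = True


def _weight_array(weights) -> np.ndarray:
    if isinstance(weights, WeightVector):
        return weights.weights
    return np.asarray(weights, dtype=float)


def reconstruct_trial(spikes_trial: np.ndarray, weights, kernel: ExponentialKernel) -> np.ndarray:
    """Population signal of one trial: x(t) = (w^T o(t)) * u, causal.

    ``spikes_trial`` is (neuron x bin).  History before the window is
    zero, so the signal starts at 0 and the convolution is truncated to
    the window length.
    """
    w = _weight_array(weights)
    spikes_trial = np.asarray(spikes_trial)
    if spikes_trial.ndim != 2 or spikes_trial.shape[0] != w.size:
        raise ValueError("weight length must equal the neuron dimension")
    proj = w @ spikes_trial
    return np.convolve(proj, kernel.values)[: spikes_trial.shape[1]]


def reconstruct_trials(
    spikes: SpikeTrainSet, weights, kernel: ExponentialKernel, trials: np.ndarray | None = None
) -> np.ndarray:
    """Vectorized reconstruction over trials; returns (trial x bin)."""
    w = _weight_array(weights)
    if w.size != spikes.n_neurons:
        raise ValueError("weight length must equal the neuron dimension")
    tensor = spikes.spikes if trials is None else spikes.spikes[:, np.asarray(trials), :]
    proj = np.tensordot(w, tensor, axes=(0, 0))  # (trial, bin)
    return fftconvolve(proj, kernel.values[None, :], axes=1)[:, : spikes.n_bins]


def center_and_average(
    per_trial: np.ndarray,
    labels,
    group: str = "all",
    kernel: ExponentialKernel | None = None,
) -> PopulationSignal:
    """Center per-trial signals on their grand mean and average by condition."""
    per_trial = np.asarray(per_trial, dtype=float)
    labels = np.asarray(labels)
    if per_trial.shape[0] != labels.size:
        raise ValueError("labels must match the trial dimension")
    match = labels == 1
    nonmatch = labels == -1
    if not (match.any() and nonmatch.any()):
        raise ValueError("both conditions must be present")
    z = per_trial.mean(axis=0)
    centered = per_trial - z
    m = centered[match].mean(axis=0)
    nm = centered[nonmatch].mean(axis=0)
    return PopulationSignal(
        per_trial=per_trial,
        centered=centered,
        mean_all=z,
        cond_mean_match=m,
        cond_mean_nonmatch=nm,
        difference=m - nm,
        group=group,
        kernel=kernel,
        labels=labels,
    )


def _invalid_signal(shape, group, kernel, labels) -> PopulationSignal:
    zeros = np.zeros(shape)
    return PopulationSignal(
        per_trial=zeros,
        centered=zeros,
        mean_all=np.zeros(shape[1]),
        cond_mean_match=np.zeros(shape[1]),
        cond_mean_nonmatch=np.zeros(shape[1]),
        difference=np.zeros(shape[1]),
        group=group,
        kernel=kernel,
        labels=np.asarray(labels),
        valid=False,
    )


def sign_split(weights) -> tuple[SubpopulationSpec, SubpopulationSpec]:
    """Split the population into plus (w > 0) and minus (w < 0) pools.

    Correction factors are f± = N / (2 N±).  Zero weights belong to
    neither pool; an empty pool yields a spec flagged invalid.
    """
    w = _weight_array(weights)
    n = w.size
    specs = []
    for kind, mask in (("sign:+", w > 0), ("sign:-", w < 0)):
        n_sub = int(mask.sum())
        valid = n_sub > 0
        f = n / (2.0 * n_sub) if valid else np.nan
        specs.append(SubpopulationSpec(mask=mask, kind=kind, correction=f, n_sub=n_sub, valid=valid))
    return specs[0], specs[1]


def layer_split(weights, neuron_layers) -> dict[str, SubpopulationSpec]:
    """Per-layer masked weights with correction f^r = N / (3 N^r).

    ``neuron_layers`` assigns each neuron one of "SG", "G", "IG".
    Empty layers yield invalid specs.
    """
    w = _weight_array(weights)
    neuron_layers = np.asarray(neuron_layers)
    if neuron_layers.size != w.size:
        raise ValueError("every neuron needs a layer assignment")
    unknown = set(neuron_layers) - {"SG", "G", "IG"}
    if unknown:
        raise ValueError(f"unknown layer tags: {unknown}")
    n = w.size
    specs = {}
    for layer in ("SG", "G", "IG"):
        mask = neuron_layers == layer
        n_sub = int(mask.sum())
        valid = n_sub > 0
        f = n / (3.0 * n_sub) if valid else np.nan
        specs[layer] = SubpopulationSpec(
            mask=mask, kind=f"layer:{layer}", correction=f, n_sub=n_sub, valid=valid
        )
    return specs


def masked_weights(weights, spec: SubpopulationSpec) -> np.ndarray:
    """Weights with off-pool entries zeroed and the correction factor applied."""
    w = _weight_array(weights).copy()
    w[~spec.mask] = 0.0
    return spec.correction * w


def subpop_signal(
    spikes: SpikeTrainSet,
    weights,
    spec: SubpopulationSpec,
    kernel: ExponentialKernel,
    labels=None,
    trials: np.ndarray | None = None,
) -> PopulationSignal:
    """Population signal of one subpopulation (plus/minus pool or layer).

    Reconstruction uses the masked, correction-scaled weights; centering
    and condition averaging use the subpopulation's own across-trial
    mean.
    """
    if labels is None:
        labels = spikes.labels if trials is None else spikes.labels[np.asarray(trials)]
    n_trials = spikes.n_trials if trials is None else np.asarray(trials).size
    if not spec.valid:
        return _invalid_signal((n_trials, spikes.n_bins), spec.kind, kernel, labels)
    per_trial = reconstruct_trials(spikes, masked_weights(weights, spec), kernel, trials)
    return center_and_average(per_trial, labels, group=spec.kind, kernel=kernel)


def univariate_signals(
    spikes: SpikeTrainSet,
    aucw: WeightVector,
    kernel: ExponentialKernel,
    labels=None,
    trials: np.ndarray | None = None,
) -> list[PopulationSignal]:
    """Per-neuron signals: each neuron's spikes weighted by its AUC weight.

    Each output depends only on its own neuron's spike train.
    """
    if aucw.method != "auc":
        raise ValueError("univariate signals require AUC weights")
    if labels is None:
        labels = spikes.labels if trials is None else spikes.labels[np.asarray(trials)]
    tensor = spikes.spikes if trials is None else spikes.spikes[:, np.asarray(trials), :]
    out = []
    for n in range(spikes.n_neurons):
        proj = aucw.weights[n] * tensor[n].astype(float)
        per_trial = fftconvolve(proj, kernel.values[None, :], axes=1)[:, : spikes.n_bins]
        if aucw.weights[n] == 0.0:
            per_trial = np.zeros_like(per_trial)
        sig = center_and_average(per_trial, labels, group=f"neuron:{spikes.neuron_ids[n]}", kernel=kernel)
        out.append(sig)
    return out
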