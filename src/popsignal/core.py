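"""Core spike-train data model, population PSTH and spike-count features.

The raw data unit is a set of parallel spike trains: a binary tensor
``spikes[n, j, k]`` over neurons ``n``, trials ``j`` and 1-ms time bins
``k``, together with a per-trial binary condition label (+1 "match",
-1 "non-match").  Two elementary summaries are provided:

* the population PSTH — the neuron- and trial-averaged spike probability
  per bin, smoothed with a normalized Gaussian kernel, and
* per-neuron spike counts in a window, z-scored across trials, which are
  the features from which decoding weights are learned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Default width (std dev, ms) of the PSTH smoothing kernel; the kernel
#: variance is 10 ms^2.
DEFAULT_PSTH_SIGMA = float(np.sqrt(10.0))
#: Default half-width (ms) of the kernel support, i.e. support {-10..10} ms.
DEFAULT_PSTH_SUPPORT = 10.0


@dataclass
class SpikeTrainSet:
    """Binary parallel spike trains with trial condition labels.

    Parameters
    ----------
    spikes
        ``(n_neurons, n_trials, n_bins)`` array of 0/1 spike indicators.
    labels
        ``(n_trials,)`` array with values in {-1, +1}; +1 is "match",
        -1 is "non-match".  Classes may be imbalanced but both must be
        present.
    bin_width
        Bin duration in ms (1 ms for the native resolution).
    window_start
        Time of the first bin relative to stimulus onset, in ms.
    epoch
        Which stimulus presentation the window covers: "target" or "test".
    """

    spikes: np.ndarray
    labels: np.ndarray
    bin_width: float = 1.0
    window_start: float = 0.0
    epoch: str = "test"
    neuron_ids: list | None = None
    session_id: str = ""

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes)
        self.labels = np.asarray(self.labels)
        if self.spikes.ndim != 3:
            raise ValueError("spikes must be a (neuron, trial, time) tensor")
        if not np.isin(self.spikes, (0, 1)).all():
            raise ValueError("spikes must be binary (0/1)")
        if self.labels.shape != (self.spikes.shape[1],):
            raise ValueError("labels length must equal the trial dimension")
        if not np.isin(self.labels, (-1, 1)).all():
            raise ValueError("labels must be -1 (non-match) or +1 (match)")
        if not ((self.labels == 1).any() and (self.labels == -1).any()):
            raise ValueError("both classes must be non-empty")
        if self.epoch not in ("target", "test"):
            raise ValueError("epoch must be 'target' or 'test'")
        if self.neuron_ids is None:
            self.neuron_ids = list(range(self.spikes.shape[0]))

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_trials(self) -> int:
        return self.spikes.shape[1]

    @property
    def n_bins(self) -> int:
        return self.spikes.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Bin start times (ms) relative to stimulus onset."""
        return self.window_start + self.bin_width * np.arange(self.n_bins)

    def subset_trials(self, idx: np.ndarray) -> "SpikeTrainSet":
        """Return a view-like copy restricted to trials ``idx``."""
        idx = np.asarray(idx)
        return SpikeTrainSet(
            spikes=self.spikes[:, idx, :],
            labels=self.labels[idx],
            bin_width=self.bin_width,
            window_start=self.window_start,
            epoch=self.epoch,
            neuron_ids=list(self.neuron_ids),
            session_id=self.session_id,
        )


@dataclass
class CountMatrix:
    """Per-neuron, per-trial spike counts and their z-scores.

    ``zscore_stats`` records the per-neuron mean and variance actually
    used, so that statistics estimated on training trials can be applied
    unchanged to held-out trials.
    """

    counts: np.ndarray
    zscores: np.ndarray
    window: tuple
    zscore_stats: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]


@dataclass
class SmoothedPSTH:
    """Gaussian-smoothed population PSTH over the analysis window."""

    values: np.ndarray
    sigma_w: float
    support: np.ndarray
    kernel: np.ndarray


def gaussian_kernel(sigma_w: float, support_halfwidth: float, bin_width: float = 1.0):
    """Normalized Gaussian kernel w(tau) on support {-h, ..., h} ms.

    The weights ``exp(-tau^2 / (2 sigma_w^2))`` are normalized to sum to
    one over the (finite) support.
    """
    if sigma_w <= 0:
        raise ValueError("sigma_w must be positive")
    if support_halfwidth < sigma_w:
        raise ValueError("support_halfwidth must be >= sigma_w")
    n = int(round(support_halfwidth / bin_width))
    tau = bin_width * np.arange(-n, n + 1)
    w = np.exp(-(tau**2) / (2.0 * sigma_w**2))
    return tau, w / w.sum()


def population_psth(
    spikes: SpikeTrainSet,
    sigma_w: float = DEFAULT_PSTH_SIGMA,
    support_halfwidth: float = DEFAULT_PSTH_SUPPORT,
) -> SmoothedPSTH:
    """Neuron- and trial-averaged spike probability, Gaussian smoothed.

    The raw PSTH is the mean of the binary tensor over neurons and
    trials; it is convolved with the normalized Gaussian kernel (default
    variance 10 ms^2, support +/-10 ms).  The series is zero-padded at
    the edges, so the first/last few bins are slightly attenuated.
    """
    if spikes.spikes.size == 0:
        raise ValueError("no data")
    tau, w = gaussian_kernel(sigma_w, support_halfwidth, spikes.bin_width)
    raw = spikes.spikes.mean(axis=(0, 1))
    # 'same' with an odd-length kernel aligns tau=0 with each bin
    smoothed = np.convolve(raw, w, mode="same")
    return SmoothedPSTH(values=smoothed, sigma_w=sigma_w, support=tau, kernel=w)


def spike_counts_zscored(
    spikes: SpikeTrainSet,
    window: tuple | None = None,
    stats_trials: np.ndarray | None = None,
    ddof: int = 1,
) -> CountMatrix:
    """Window spike counts per neuron/trial, z-scored across trials.

    Parameters
    ----------
    window
        ``(start, stop)`` in ms relative to stimulus onset, half-open;
        defaults to the full recorded window.
    stats_trials
        Trial indices over which the z-scoring mean and variance are
        estimated (e.g. the training half); the statistics are then
        applied to *all* trials.  Defaults to all trials.
    ddof
        Delta degrees of freedom of the variance estimate (sample
        variance, ddof=1, by default).

    Neurons with zero count variance over ``stats_trials`` get z-scores
    of exactly 0 (with a logged warning) so the neuron dimension stays
    stable.
    """
    if window is None:
        k0, k1 = 0, spikes.n_bins
        window = (spikes.window_start, spikes.window_start + spikes.n_bins * spikes.bin_width)
    else:
        k0 = int(round((window[0] - spikes.window_start) / spikes.bin_width))
        k1 = int(round((window[1] - spikes.window_start) / spikes.bin_width))
        if k0 < 0 or k1 > spikes.n_bins or k0 >= k1:
            raise ValueError("window outside recorded bins")
    if stats_trials is None:
        stats_trials = np.arange(spikes.n_trials)
    stats_trials = np.asarray(stats_trials)
    if stats_trials.size == 0:
        raise ValueError("stats_trials must be non-empty")

    counts = spikes.spikes[:, :, k0:k1].sum(axis=2).astype(np.int64)
    mean = counts[:, stats_trials].mean(axis=1)
    var = counts[:, stats_trials].var(axis=1, ddof=ddof)
    zero = var == 0
    if zero.any():
        logger.warning(
            "%d neuron(s) with zero count variance over stats trials; z-scores set to 0",
            int(zero.sum()),
        )
    sd = np.sqrt(np.where(zero, 1.0, var))
    z = (counts - mean[:, None]) / sd[:, None]
    z[zero, :] = 0.0
    return CountMatrix(
        counts=counts,
        zscores=z,
        window=tuple(window),
        zscore_stats={"mean": mean, "var": var, "ddof": ddof, "stats_trials": stats_trials},
    )
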