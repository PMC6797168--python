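"""Synthetic sessions with planted, recoverable structure.

The generator emulates the statistical setting of laminar V1/V4
recordings during a delayed match-to-sample task: 10-30 simultaneously
recorded neurons, on the order of 100 trials per condition, 400-ms
windows at 1-ms resolution, and a condition effect confined to a late
part of the test window with a neuron-specific sign (plus/minus
structure).  Spiking is Bernoulli per 1-ms bin (discrete-time Poisson,
no refractoriness).  An optional shared latent input — Gaussian noise
smoothed at a 20-ms timescale, loaded with opposite sign onto the plus
and minus pools — produces anti-correlated pool signals.  A companion
laminar LFP generator plants a granular-layer current sink flanked by
sources, so the CSD layer-assignment method can be validated against
known borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import SpikeTrainSet

MS_PER_S = 1000.0


@dataclass
class SessionConfig:
    """Ground-truth parameters of one synthetic session.

    Rates are in Hz; times in ms.  ``modulation_depth`` is the
    between-condition firing-rate contrast of each neuron during
    ``effect_window`` of the test epoch: a neuron's rate is shifted by
    +/- depth/2 with the sign set by the condition and the neuron's
    planted sign (plus neurons up in "match", minus neurons up in
    "non-match").  The symmetric split keeps the *population-summed*
    rate identical across conditions — the population PSTH is condition
    blind while the signed pattern is fully decodable, mirroring the
    statistical setting the read-out model is designed for.  The target
    epoch carries no condition effect.  ``shared_latent_sd`` (Hz) sets
    the strength of the common input, loaded +1 on plus and -1 on minus
    neurons.
    """

    n_neurons: int = 20
    n_trials_per_condition: int = 100
    n_bins: int = 400
    baseline_rate: float | np.ndarray = 5.0
    modulation_depth: float = 10.0
    effect_window: tuple = (200.0, 400.0)
    plus_fraction: float = 0.5
    shared_latent_sd: float = 0.0
    latent_timescale: float = 20.0
    layer_sizes: tuple | None = None
    n_channels: int = 16
    channel_spacing: float = 100.0
    snr: float = 5.0
    bin_width: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.plus_fraction <= 1.0:
            raise ValueError("plus_fraction must be in [0, 1]")
        if np.any(np.asarray(self.baseline_rate) < 0):
            raise ValueError("rates must be non-negative")
        if self.layer_sizes is not None and sum(self.layer_sizes) != self.n_neurons:
            raise ValueError("layer sizes must sum to n_neurons")

    @property
    def baseline_rates(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.baseline_rate, dtype=float), (self.n_neurons,)).copy()

    def default_layer_sizes(self) -> tuple:
        base, rem = divmod(self.n_neurons, 3)
        return tuple(base + (1 if i < rem else 0) for i in range(3))


@dataclass
class SyntheticSession:
    """Generated session: spike trains for both epochs, laminar LFP and truth.

    ``truth`` records the planted signs, per-neuron modulation depths,
    latent loadings, layer tags and depths, and the planted G-layer
    borders of the LFP.
    """

    target: SpikeTrainSet
    test: SpikeTrainSet
    lfp: np.ndarray
    lfp_time_axis: np.ndarray
    truth: dict = field(default_factory=dict)
    config: SessionConfig | None = None


def _smoothed_latent(rng, n_trials, n_bins, timescale, bin_width) -> np.ndarray:
    """Unit-variance smoothed Gaussian latent, one series per trial."""
    noise = rng.standard_normal((n_trials, n_bins))
    lat = gaussian_filter1d(noise, sigma=timescale / bin_width, axis=1, mode="reflect")
    sd = lat.std()
    return lat / sd if sd > 0 else lat


def _spike_tensor(rng, rates_hz: np.ndarray, bin_width: float) -> np.ndarray:
    """Bernoulli spikes from per-(neuron, trial, bin) rates in Hz.

    Negative rates (a strong negative modulation on a low baseline) are
    clipped to zero; a Bernoulli probability above 1 is an error.
    """
    p = np.clip(rates_hz, 0.0, None) * bin_width / MS_PER_S
    if (p > 1.0).any():
        raise ValueError("rate * bin width exceeds 1: invalid Bernoulli probability")
    return (rng.random(p.shape) < p).astype(np.uint8)


def generate_session(config: SessionConfig) -> SyntheticSession:
    """Generate one session (both epochs + laminar LFP), reproducibly.

    Rates: baseline + sign_n * y_j * (depth/2) * 1[t in effect window]
    (test epoch only, y_j the trial's +/-1 label) + loading_n *
    latent_j(t), clipped at zero before Bernoulli sampling.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_neurons, config.n_bins
    ntc = config.n_trials_per_condition
    j = 2 * ntc
    labels = np.concatenate([-np.ones(ntc, dtype=int), np.ones(ntc, dtype=int)])

    n_plus = int(round(config.plus_fraction * n))
    signs = np.full(n, -1.0)
    signs[rng.permutation(n)[:n_plus]] = 1.0
    loadings = signs.copy()  # opposite loadings for the two pools

    layer_sizes = config.layer_sizes or config.default_layer_sizes()
    neuron_layers = np.repeat(np.array(["SG", "G", "IG"]), layer_sizes)

    baseline = config.baseline_rates
    times = config.bin_width * np.arange(k)
    in_window = (times >= config.effect_window[0]) & (times < config.effect_window[1])

    lfp, lfp_time, lfp_truth = generate_laminar_lfp(config, rng=rng, n_trials=j)
    upper, lower = lfp_truth["borders"]
    span = lfp_truth["probe_span"]
    # neuron depths drawn uniformly inside the band of the neuron's layer
    bands = {"SG": (span[0] + 1.0, upper), "G": (upper, lower), "IG": (lower, span[1] - 1.0)}
    depths = np.array([rng.uniform(*bands[layer]) for layer in neuron_layers])

    epochs = {}
    for epoch in ("target", "test"):
        rates = np.broadcast_to(baseline[:, None, None], (n, j, k)).copy()
        if epoch == "test" and config.modulation_depth != 0.0:
            effect = (
                signs[:, None, None]
                * (config.modulation_depth / 2.0)
                * labels[None, :, None]
                * in_window[None, None, :]
            )
            rates = rates + effect
        if config.shared_latent_sd > 0.0:
            latent = _smoothed_latent(rng, j, k, config.latent_timescale, config.bin_width)
            rates = rates + config.shared_latent_sd * loadings[:, None, None] * latent[None, :, :]
        epochs[epoch] = SpikeTrainSet(
            spikes=_spike_tensor(rng, rates, config.bin_width),
            labels=labels,
            bin_width=config.bin_width,
            window_start=0.0,
            epoch=epoch,
            session_id=f"synth-{config.seed}",
        )

    truth = {
        "signs": signs,
        "modulation_depths": np.abs(signs) * config.modulation_depth,
        "loadings": loadings,
        "neuron_layers": neuron_layers,
        "neuron_depths": depths,
        "labels": labels,
        **lfp_truth,
    }
    return SyntheticSession(
        target=epochs["target"],
        test=epochs["test"],
        lfp=lfp,
        lfp_time_axis=lfp_time,
        truth=truth,
        config=config,
    )


def generate_laminar_lfp(
    config: SessionConfig,
    rng: np.random.Generator | None = None,
    n_trials: int | None = None,
):
    """Laminar LFP whose trial-averaged CSD shows a G-layer sink with
    flanking sources at 20-100 ms post-onset.

    The clean potential is a negative Gaussian in depth (sink center in
    the middle of the probe, width 2.5 channel spacings) times a
    temporal bump peaking at 60 ms; its second spatial derivative is a
    Mexican hat whose zero crossings — the planted G-layer borders —
    sit one Gaussian width from the sink center.  White noise is added
    per trial; ``config.snr`` is defined on the map the layer method
    actually operates on: it is the ratio of the clean CSD peak to the
    noise standard deviation of the *trial-averaged* CSD (the
    three-point second difference amplifies white noise by sqrt(6) and
    trial averaging attenuates it by sqrt(n_trials); the per-trial LFP
    noise level is derived from that).

    Returns ``(lfp, time_axis, truth)`` with lfp of shape
    (channel x time x trial).
    """
    if config.n_channels < 8:
        raise ValueError("laminar LFP needs >= 8 channels")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_trials is None:
        n_trials = 2 * config.n_trials_per_condition
    h = config.channel_spacing
    depths = h * np.arange(config.n_channels)
    center = h * (config.n_channels // 2 - 1)
    sigma_d = 2.5 * h
    t = config.bin_width * np.arange(config.n_bins)
    temporal = np.exp(-((t - 60.0) ** 2) / (2.0 * 15.0**2))
    profile = -np.exp(-((depths - center) ** 2) / (2.0 * sigma_d**2))
    clean = profile[:, None] * temporal[None, :]
    if config.snr > 0:
        csd_peak_x_h2 = np.abs(profile[:-2] - 2.0 * profile[1:-1] + profile[2:]).max()
        noise_sd = csd_peak_x_h2 / np.sqrt(6.0) * np.sqrt(n_trials) / config.snr
    else:
        noise_sd = 0.0
    lfp = clean[:, :, None] + noise_sd * rng.standard_normal((*clean.shape, n_trials))
    truth = {
        "sink_center_depth": center,
        "sink_channel": int(config.n_channels // 2 - 1),
        "sink_time": 60.0,
        "borders": (center - sigma_d, center + sigma_d),
        "probe_span": (0.0, h * (config.n_channels - 1)),
        "channel_depths": depths,
    }
    return lfp, t, truth
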