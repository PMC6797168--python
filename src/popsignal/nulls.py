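"""Permutation and perturbation null models for the population signal.

The central null is the label permutation: condition labels are shuffled
before weight learning *and* before condition averaging, the whole
read-out is re-run, and the match minus non-match difference is recorded;
repeating this ``nperm`` times yields a per-bin null distribution.
Weight perturbations (random weights, random signs, random moduli,
binary weights) and spike-timing permutation instead remove one specific
source of information from an otherwise intact read-out, to test which
source the discrimination depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SpikeTrainSet, spike_counts_zscored
from .reconstruction import (
    ExponentialKernel,
    center_and_average,
    make_kernel,
    masked_weights,
    reconstruct_trials,
    sign_split,
)
from .weights import SplitSpec, WeightVector, learn_weights

DEFAULT_NPERM = 1000

PERTURBATION_MODES = ("random", "random_sign", "random_modulus", "binary")


@dataclass
class NullEnsemble:
    """nperm replicates of a per-bin statistic under a stated randomization."""

    samples: np.ndarray  # (nperm, n_bins)
    mode: str
    nperm: int
    seed: int

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))


@dataclass
class SignificanceMask:
    """Per-bin empirical p-values and significance flags against a null.

    ``flags`` uses the two-sided empirical p-value with add-one
    correction; ``outside`` is the stricter observed-outside-the-null
    min/max criterion.
    """

    flags: np.ndarray
    p_values: np.ndarray
    alpha: float
    outside: np.ndarray = field(default=None)


def perturb_weights(weights: WeightVector, mode: str, seed=0) -> WeightVector:
    """Remove one source of information from the weight vector.

    * ``random`` — i.i.d. uniform draws on [min w, max w] (the range of
      the original vector): removes all weight information.
    * ``random_sign`` — original moduli, signs taken from a uniform draw.
    * ``random_modulus`` — original signs, moduli of uniform draws.
    * ``binary`` — +a for positive and -a for negative weights with
      a = mean(|w|): keeps only the sign, at a common magnitude.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = weights.weights
    if mode in ("random", "random_weights"):
        new = rng.uniform(w.min(), w.max(), size=w.size)
        mode = "random"
    elif mode == "random_sign":
        draw = rng.uniform(w.min(), w.max(), size=w.size)
        sign = np.where(draw >= 0, 1.0, -1.0)
        new = sign * np.abs(w)
    elif mode == "random_modulus":
        draw = rng.uniform(w.min(), w.max(), size=w.size)
        new = np.sign(w) * np.abs(draw)
    elif mode == "binary":
        a = np.abs(w).mean()
        new = np.sign(w) * a
    else:
        raise ValueError(f"unknown perturbation mode: {mode}")
    return WeightVector(
        weights=new,
        offset=weights.offset,
        method=f"perturbed:{mode}",
        regularization=weights.regularization,
        norm_applied=False,
    )


def permute_spike_timing(spikes_trial: np.ndarray, seed=0) -> np.ndarray:
    """Permute the order of time bins of one trial, identically for all
    neurons, so per-neuron counts and zero-lag coincidences are kept."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spikes_trial = np.asarray(spikes_trial)
    perm = rng.permutation(spikes_trial.shape[-1])
    return spikes_trial[..., perm]


def _difference_for_labels(
    spikes: SpikeTrainSet,
    labels: np.ndarray,
    split: SplitSpec,
    kernel: ExponentialKernel,
    C: float,
    window=None,
    zscore_scope: str = "train",
    statistics=("all",),
) -> dict[str, np.ndarray]:
    """Run the read-out for one split under the given labels; return the
    match - non-match difference for the requested signal groups."""
    stats_trials = split.train_idx if zscore_scope == "train" else None
    cm = spike_counts_zscored(spikes, window=window, stats_trials=stats_trials)
    wv = learn_weights(cm.zscores[:, split.train_idx], labels[split.train_idx], C=C)
    out = {}
    valid_labels = labels[split.valid_idx]
    if "all" in statistics:
        per_trial = reconstruct_trials(spikes, wv, kernel, trials=split.valid_idx)
        out["all"] = center_and_average(per_trial, valid_labels).difference
    if "plus" in statistics or "minus" in statistics:
        plus, minus = sign_split(wv)
        for name, spec in (("plus", plus), ("minus", minus)):
            if name not in statistics:
                continue
            if not spec.valid:
                out[name] = np.zeros(spikes.n_bins)
                continue
            pt = reconstruct_trials(spikes, masked_weights(wv, spec), kernel, trials=split.valid_idx)
            out[name] = center_and_average(pt, valid_labels).difference
    return out


def label_permutation_null(
    spikes: SpikeTrainSet,
    splits: list[SplitSpec],
    kernel: ExponentialKernel | None = None,
    C: float = 0.01,
    nperm: int = DEFAULT_NPERM,
    seed: int = 0,
    window=None,
    zscore_scope: str = "train",
    statistics=("all",),
) -> dict[str, NullEnsemble]:
    """Full label-permutation null of the signal difference.

    Per replicate, one random permutation of the trial labels is used
    both for SVM training and for condition averaging of the validation
    signals; the difference statistic is averaged over the provided
    cross-validation splits.  C is held fixed (pass the session's
    selected value).  Returns one ensemble per requested statistic
    ("all", "plus", "minus").
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    kernel = kernel or make_kernel()
    rng = np.random.default_rng(seed)
    samples = {name: np.empty((nperm, spikes.n_bins)) for name in statistics}
    for r in range(nperm):
        perm_labels = spikes.labels[rng.permutation(spikes.n_trials)]
        acc = {name: np.zeros(spikes.n_bins) for name in statistics}
        for split in splits:
            diffs = _difference_for_labels(
                spikes, perm_labels, split, kernel, C, window, zscore_scope, statistics
            )
            for name in statistics:
                acc[name] += diffs[name]
        for name in statistics:
            samples[name][r] = acc[name] / len(splits)
    return {
        name: NullEnsemble(samples=samples[name], mode="label_perm", nperm=nperm, seed=seed)
        for name in statistics
    }


def significance_mask(observed: np.ndarray, null: NullEnsemble, alpha: float = 0.05) -> SignificanceMask:
    """Two-sided per-bin empirical p-values with add-one correction.

    p = (1 + #{|null| >= |observed|}) / (nperm + 1); bins with p <= alpha
    are flagged.  ``outside`` additionally marks bins where the observed
    value falls outside the raw null min/max envelope.
    """
    observed = np.asarray(observed, dtype=float)
    null_abs = np.abs(null.samples)
    exceed = (null_abs >= np.abs(observed)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (null.nperm + 1.0)
    outside = (observed > null.samples.max(axis=0)) | (observed < null.samples.min(axis=0))
    return SignificanceMask(flags=p <= alpha, p_values=p, alpha=alpha, outside=outside)


def perturbation_ensembles(
    spikes: SpikeTrainSet,
    weights: WeightVector,
    kernel: ExponentialKernel,
    trials: np.ndarray,
    modes=PERTURBATION_MODES + ("timing",),
    nperm: int = DEFAULT_NPERM,
    seed: int = 0,
) -> dict[str, NullEnsemble]:
    """Signal-difference ensembles with one information source removed.

    For each weight-perturbation mode ("random", "random_sign",
    "random_modulus", "binary") the read-out is repeated ``nperm`` times
    with a freshly perturbed weight vector and *true* validation labels;
    "timing" instead keeps the true weights and permutes the order of
    time bins per trial (shared across neurons).  "binary" is
    deterministic and gets a single replicate.
    """
    trials = np.asarray(trials)
    labels = spikes.labels[trials]
    out = {}
    for m, mode in enumerate(modes):
        rng = np.random.default_rng(np.random.SeedSequence([seed, m]))
        reps = 1 if mode == "binary" else nperm
        samples = np.empty((reps, spikes.n_bins))
        for r in range(reps):
            if mode == "timing":
                tensor = spikes.spikes[:, trials, :]
                permuted = np.empty_like(tensor)
                for jj in range(trials.size):
                    permuted[:, jj, :] = permute_spike_timing(tensor[:, jj, :], seed=rng)
                sub = SpikeTrainSet(
                    spikes=permuted,
                    labels=labels,
                    bin_width=spikes.bin_width,
                    window_start=spikes.window_start,
                    epoch=spikes.epoch,
                )
                per_trial = reconstruct_trials(sub, weights, kernel)
            else:
                wv = perturb_weights(weights, mode, seed=rng)
                per_trial = reconstruct_trials(spikes, wv, kernel, trials=trials)
            samples[r] = center_and_average(per_trial, labels).difference
        out[mode] = NullEnsemble(samples=samples, mode=mode, nperm=reps, seed=seed)
    return out


def _pool_ccfs(spikes, w, kernel, trials, labels, lag0_only):
    from .correlation import ccf_trial_averaged  # local import avoids a cycle

    plus, minus = sign_split(w)
    if not (plus.valid and minus.valid):
        return None
    xp = reconstruct_trials(spikes, masked_weights(w, plus), kernel, trials=trials)
    xm = reconstruct_trials(spikes, masked_weights(w, minus), kernel, trials=trials)
    if lag0_only:
        num = (xp * xm).sum(axis=1)
        den = np.sqrt((xp**2).sum(axis=1) * (xm**2).sum(axis=1))
        ok = den > 0
        if not ok.any():
            return None
        return np.array([(num[ok] / den[ok]).mean()])
    res = ccf_trial_averaged(xp, xm, labels, condition="both", pair="plus x minus")
    return res.values if res.valid else None


def random_pool_ccf_null(
    spikes: SpikeTrainSet,
    weights: WeightVector,
    kernel: ExponentialKernel,
    trials: np.ndarray,
    nperm: int = DEFAULT_NPERM,
    seed: int = 0,
    lag0_only: bool = False,
) -> NullEnsemble:
    """Plus x minus CCF null under random assignment to the sign pools.

    Per replicate the weight values are permuted across neurons before
    the sign split, so pool sizes N+/N- are preserved while the
    membership (which neuron carries which weight) is randomized.
    Replicates with an empty pool or all-zero signals are redrawn.
    """
    trials = np.asarray(trials)
    labels = spikes.labels[trials]
    rng = np.random.default_rng(seed)
    rows = []
    attempts = 0
    while len(rows) < nperm:
        attempts += 1
        if attempts > 20 * nperm:
            raise RuntimeError("could not draw valid random pool assignments")
        perm = rng.permutation(weights.weights.size)
        wv = WeightVector(
            weights=weights.weights[perm],
            offset=weights.offset,
            method="perturbed:random_pool_assignment",
            norm_applied=weights.norm_applied,
        )
        vals = _pool_ccfs(spikes, wv, kernel, trials, labels, lag0_only)
        if vals is not None:
            rows.append(vals)
    return NullEnsemble(
        samples=np.asarray(rows), mode="random_pool_assignment", nperm=nperm, seed=seed
    )


def random_layer_ccf_null(
    spikes: SpikeTrainSet,
    weights: WeightVector,
    neuron_layers: np.ndarray,
    pair: tuple,
    kernel: ExponentialKernel,
    trials: np.ndarray,
    nperm: int = DEFAULT_NPERM,
    seed: int = 0,
) -> NullEnsemble:
    """Layer-pair CCF null under random assignment of neurons to layers,
    preserving the three layer sizes."""
    from .correlation import ccf_trial_averaged
    from .reconstruction import layer_split

    trials = np.asarray(trials)
    labels = spikes.labels[trials]
    neuron_layers = np.asarray(neuron_layers)
    rng = np.random.default_rng(seed)
    rows = []
    attempts = 0
    while len(rows) < nperm:
        attempts += 1
        if attempts > 20 * nperm:
            raise RuntimeError("could not draw valid random layer assignments")
        shuffled = neuron_layers[rng.permutation(neuron_layers.size)]
        specs = layer_split(weights, shuffled)
        a, b = specs[pair[0]], specs[pair[1]]
        if not (a.valid and b.valid):
            continue
        xa = reconstruct_trials(spikes, masked_weights(weights, a), kernel, trials=trials)
        xb = reconstruct_trials(spikes, masked_weights(weights, b), kernel, trials=trials)
        res = ccf_trial_averaged(xa, xb, labels, condition="both", pair=f"{pair[0]} x {pair[1]}")
        if res.valid:
            rows.append(res.values)
    return NullEnsemble(
        samples=np.asarray(rows), mode="random_layer_assignment", nperm=nperm, seed=seed
    )


def max_statistic_mask(observed: np.ndarray, null: NullEnsemble, alpha: float = 0.05) -> SignificanceMask:
    """Westfall-Young max-statistic mask controlling the family-wise error
    across time bins (optional stricter alternative to the per-bin mask)."""
    observed = np.asarray(observed, dtype=float)
    max_null = np.abs(null.samples).max(axis=1)
    exceed = (max_null[:, None] >= np.abs(observed)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (null.nperm + 1.0)
    outside = np.abs(observed) > max_null.max()
    return SignificanceMask(flags=p <= alpha, p_values=p, alpha=alpha, outside=outside)
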