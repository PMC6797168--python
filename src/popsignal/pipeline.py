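"""Full-session analysis: weights, signals, nulls, CCFs, layers.

`run_full_analysis` strings the modules together the way a session is
analyzed end to end: Monte-Carlo train/validation splits, per-run SVM
weights (C selected on the training set), single-trial reconstruction of
the validation trials, condition averaging, label-permutation nulls,
sign- and layer-specific read-outs, weight perturbations, univariate
(per-neuron AUC) signals and cross-correlation functions with
random-assignment nulls.  Results are averaged across cross-validation
runs; per-run weights are retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .core import SpikeTrainSet, spike_counts_zscored
from .correlation import ccf_trial_averaged
from .csd import assign_neurons, compute_csd, layer_borders
from .nulls import (
    label_permutation_null,
    perturbation_ensembles,
    random_layer_ccf_null,
    random_pool_ccf_null,
    significance_mask,
)
from .reconstruction import (
    center_and_average,
    layer_split,
    make_kernel,
    masked_weights,
    reconstruct_trials,
    sign_split,
    subpop_signal,
    univariate_signals,
)
from .weights import (
    C_GRID,
    auc_weights,
    balanced_accuracy,
    learn_weights,
    monte_carlo_splits,
    predict,
    select_regularization,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the full analysis.

    Defaults: exponential kernel rate 1/20 per ms, nperm = 1000 null
    replicates, 100 Monte-Carlo cross-validation runs, alpha = 0.05.
    ``null_cv_runs`` bounds how many CV splits each label-permutation
    replicate is averaged over; ``c_selection`` picks the SVM C once per
    session ("session", on the first run's training set) or per run.
    """

    kernel_rate: float = 1.0 / 20.0
    kernel_normalized: bool = False
    nperm: int = 1000
    n_cv_runs: int = 100
    c_grid: tuple = C_GRID
    alpha: float = 0.05
    zscore_scope: str = "train"  # or "all"
    c_selection: str = "session"  # or "per_run"
    null_cv_runs: int = 10
    ccf_max_lag: int = 200
    epochs: tuple = ("target", "test")
    analyses: tuple = ("signal", "sign_split", "perturbations", "univariate", "ccf", "layers")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.zscore_scope not in ("train", "all"):
            raise ValueError("zscore_scope must be 'train' or 'all'")
        if self.c_selection not in ("session", "per_run"):
            raise ValueError("c_selection must be 'session' or 'per_run'")


def _zscores_for_split(spikes, split, scope):
    stats = split.train_idx if scope == "train" else None
    return spike_counts_zscored(spikes, stats_trials=stats)


def _analyze_epoch(config, spikes: SpikeTrainSet, neuron_layers=None):
    kernel = make_kernel(config.kernel_rate, normalized=config.kernel_normalized)
    splits = monte_carlo_splits(spikes.labels, config.n_cv_runs, seed=config.seed)

    cm0 = _zscores_for_split(spikes, splits[0], config.zscore_scope)
    session_c = select_regularization(
        cm0.zscores[:, splits[0].train_idx], spikes.labels[splits[0].train_idx],
        grid=config.c_grid, seed=config.seed,
    )

    n_bins, n_neurons = spikes.n_bins, spikes.n_neurons
    weights_runs = np.empty((len(splits), n_neurons))
    bacs = np.empty(len(splits))
    diff_acc = np.zeros(n_bins)
    match_acc = np.zeros(n_bins)
    nonmatch_acc = np.zeros(n_bins)
    sub_acc = {"plus": np.zeros(n_bins), "minus": np.zeros(n_bins)}
    layer_acc = {layer: np.zeros(n_bins) for layer in ("SG", "G", "IG")} if neuron_layers is not None else None
    uni_acc = np.zeros(n_bins)

    run_weights = []
    for split in splits:
        cm = _zscores_for_split(spikes, split, config.zscore_scope)
        c = session_c
        if config.c_selection == "per_run":
            c = select_regularization(
                cm.zscores[:, split.train_idx], spikes.labels[split.train_idx],
                grid=config.c_grid, seed=config.seed + split.run_id,
            )
        wv = learn_weights(cm.zscores[:, split.train_idx], spikes.labels[split.train_idx], C=c)
        run_weights.append(wv)
        weights_runs[split.run_id] = wv.weights
        pred = predict(wv, cm.zscores[:, split.valid_idx])
        bacs[split.run_id] = balanced_accuracy(pred, spikes.labels[split.valid_idx])

        per_trial = reconstruct_trials(spikes, wv, kernel, trials=split.valid_idx)
        sig = center_and_average(per_trial, spikes.labels[split.valid_idx], kernel=kernel)
        diff_acc += sig.difference
        match_acc += sig.cond_mean_match
        nonmatch_acc += sig.cond_mean_nonmatch

        if "sign_split" in config.analyses:
            plus, minus = sign_split(wv)
            for name, spec in (("plus", plus), ("minus", minus)):
                s = subpop_signal(spikes, wv, spec, kernel, trials=split.valid_idx)
                sub_acc[name] += s.difference
        if layer_acc is not None and "layers" in config.analyses:
            for layer, spec in layer_split(wv, neuron_layers).items():
                s = subpop_signal(spikes, wv, spec, kernel, trials=split.valid_idx)
                layer_acc[layer] += s.difference
        if "univariate" in config.analyses:
            aw = auc_weights(cm.counts[:, split.train_idx], spikes.labels[split.train_idx])
            usigs = univariate_signals(spikes, aw, kernel, trials=split.valid_idx)
            uni_acc += np.mean([u.difference for u in usigs], axis=0)

    n_runs = len(splits)
    result = {
        "C": session_c,
        "n_cv_runs": n_runs,
        "bac_mean": float(bacs.mean()),
        "weights_mean": weights_runs.mean(axis=0),
        "weights_runs": weights_runs,
        "signal": {
            "difference": diff_acc / n_runs,
            "cond_mean_match": match_acc / n_runs,
            "cond_mean_nonmatch": nonmatch_acc / n_runs,
        },
    }
    if "sign_split" in config.analyses:
        result["sign_split"] = {k: v / n_runs for k, v in sub_acc.items()}
    if layer_acc is not None and "layers" in config.analyses:
        result["layer_signals"] = {k: v / n_runs for k, v in layer_acc.items()}
    if "univariate" in config.analyses:
        result["univariate"] = {"difference_mean": uni_acc / n_runs}

    # label-permutation null + per-bin significance
    stat_names = ("all", "plus", "minus") if "sign_split" in config.analyses else ("all",)
    nulls = label_permutation_null(
        spikes,
        splits[: max(1, min(config.null_cv_runs, n_runs))],
        kernel=kernel,
        C=session_c,
        nperm=config.nperm,
        seed=config.seed,
        zscore_scope=config.zscore_scope,
        statistics=stat_names,
    )
    observed = {"all": result["signal"]["difference"]}
    if "sign_split" in config.analyses:
        observed.update(result["sign_split"])
    result["null"] = {}
    result["significance"] = {}
    for name in stat_names:
        mask = significance_mask(observed[name], nulls[name], alpha=config.alpha)
        result["null"][name] = {
            "mode": nulls[name].mode,
            "nperm": nulls[name].nperm,
            "band_low": nulls[name].samples.min(axis=0),
            "band_high": nulls[name].samples.max(axis=0),
        }
        result["significance"][name] = {
            "flags": mask.flags,
            "p_values": mask.p_values,
            "outside": mask.outside,
            "frac_bins_significant": float(mask.flags.mean()),
        }

    wv0, split0 = run_weights[0], splits[0]
    if "perturbations" in config.analyses:
        # time-averaged null distribution for comparing perturbation modes
        ta_null = nulls["all"].samples.mean(axis=1)
        ens = perturbation_ensembles(
            spikes, wv0, kernel, split0.valid_idx, nperm=config.nperm, seed=config.seed
        )
        result["perturbations"] = {}
        for mode, ne in ens.items():
            mean_diff = ne.samples.mean(axis=0)
            ta = float(np.median(ne.samples.mean(axis=1)))
            p = float((1.0 + (np.abs(ta_null) >= abs(ta)).sum()) / (ta_null.size + 1.0))
            result["perturbations"][mode] = {
                "mode": ne.mode,
                "nperm": ne.nperm,
                "difference_mean": mean_diff,
                "time_avg_median": ta,
                "p_time_avg": p,
                "significant": p <= config.alpha,
            }

    if "ccf" in config.analyses:
        plus, minus = sign_split(wv0)
        ccf_block = {}
        if plus.valid and minus.valid:
            xp = reconstruct_trials(spikes, masked_weights(wv0, plus), kernel, trials=split0.valid_idx)
            xm = reconstruct_trials(spikes, masked_weights(wv0, minus), kernel, trials=split0.valid_idx)
            ccf = ccf_trial_averaged(
                xp, xm, spikes.labels[split0.valid_idx], condition="both", pair="plus x minus"
            )
            null = random_pool_ccf_null(
                spikes, wv0, kernel, split0.valid_idx, nperm=config.nperm, seed=config.seed,
                lag0_only=True,
            )
            lag0 = ccf.at_lag(0)
            band = (float(null.samples.min()), float(null.samples.max()))
            cropped = ccf.crop(config.ccf_max_lag)
            ccf_block["plus_minus"] = {
                "lag0": lag0,
                "lags": cropped.lags,
                "values": cropped.values,
                "n_trials": ccf.n_trials,
                "null_mode": null.mode,
                "null_nperm": null.nperm,
                "null_band_lag0": band,
                "outside_null": bool(lag0 < band[0] or lag0 > band[1]),
            }
        else:
            logger.warning("sign pool empty; plus x minus CCF skipped")
        if neuron_layers is not None and "layers" in config.analyses:
            specs = layer_split(wv0, neuron_layers)
            for pair in (("SG", "G"), ("SG", "IG"), ("G", "IG")):
                a, b = specs[pair[0]], specs[pair[1]]
                if not (a.valid and b.valid):
                    continue
                xa = reconstruct_trials(spikes, masked_weights(wv0, a), kernel, trials=split0.valid_idx)
                xb = reconstruct_trials(spikes, masked_weights(wv0, b), kernel, trials=split0.valid_idx)
                ccf = ccf_trial_averaged(
                    xa, xb, spikes.labels[split0.valid_idx], condition="both",
                    pair=f"{pair[0]} x {pair[1]}",
                )
                null = random_layer_ccf_null(
                    spikes, wv0, neuron_layers, pair, kernel, split0.valid_idx,
                    nperm=config.nperm, seed=config.seed,
                )
                zero = ccf.lags.size // 2
                band = (
                    float(null.samples[:, zero].min()),
                    float(null.samples[:, zero].max()),
                )
                cropped = ccf.crop(config.ccf_max_lag)
                ccf_block[f"{pair[0]}_{pair[1]}"] = {
                    "lag0": ccf.at_lag(0),
                    "lags": cropped.lags,
                    "values": cropped.values,
                    "n_trials": ccf.n_trials,
                    "null_mode": null.mode,
                    "null_nperm": null.nperm,
                    "null_band_lag0": band,
                    "outside_null": bool(
                        ccf.at_lag(0) < band[0] or ccf.at_lag(0) > band[1]
                    ),
                }
        result["ccf"] = ccf_block
    return result


def run_full_analysis(
    config: AnalysisConfig,
    data: dict,
    lfp: np.ndarray | None = None,
    channel_spacing: float | None = None,
    depths: np.ndarray | None = None,
    lfp_time_axis: np.ndarray | None = None,
) -> dict:
    """Analyze one session.

    ``data`` maps epoch name ("target"/"test") to its SpikeTrainSet.
    When a laminar LFP (+ channel spacing and per-neuron depths) is
    provided, neurons are assigned to SG/G/IG layers from the CSD and
    layer-specific signals and CCFs are added; otherwise the layer
    analyses are skipped with a warning.
    """
    report = {"config": asdict(config), "session_id": next(iter(data.values())).session_id}

    neuron_layers = None
    if lfp is not None and channel_spacing is not None and depths is not None:
        csd = compute_csd(lfp, channel_spacing, time_axis=lfp_time_axis)
        assignment = layer_borders(csd)
        neuron_layers = assign_neurons(depths, assignment)
        report["laminar"] = {
            "borders": assignment.borders,
            "sink": assignment.sink,
            "channel_layers": assignment.channel_layers,
            "neuron_layers": neuron_layers,
            "border_flags": assignment.border_flags,
        }
    elif "layers" in config.analyses:
        logger.warning("no LFP/depths provided; layer analyses skipped")

    report["epochs"] = {}
    for epoch in config.epochs:
        if epoch not in data:
            logger.warning("epoch %r not in data; skipped", epoch)
            continue
        report["epochs"][epoch] = _analyze_epoch(config, data[epoch], neuron_layers)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def save_report(report: dict, outdir) -> Path:
    """Write the JSON summary (and a run log line) under ``outdir``;
    returns the summary path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = outdir / "summary.json"
    with open(summary, "w") as f:
        json.dump(_jsonable(report), f, sort_keys=True, indent=1)
    with open(outdir / "run_log.jsonl", "a") as f:
        f.write(
            json.dumps(
                {
                    "session_id": report.get("session_id", ""),
                    "seed": report["config"]["seed"],
                    "nperm": report["config"]["nperm"],
                    "n_cv_runs": report["config"]["n_cv_runs"],
                },
                sort_keys=True,
            )
            + "\n"
        )
    return summary


def write_tables(report: dict, outdir) -> None:
    """Delimited-text mirrors of the main report blocks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    rows = []
    for epoch, block in report.get("epochs", {}).items():
        k = len(block["signal"]["difference"])
        for cond in ("difference", "cond_mean_match", "cond_mean_nonmatch"):
            rows.append(
                pd.DataFrame(
                    {
                        "session": report.get("session_id", ""),
                        "epoch": epoch,
                        "group": "all",
                        "condition": cond,
                        "time_ms": np.arange(k),
                        "value": block["signal"][cond],
                    }
                )
            )
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(outdir / "signals.csv", index=False)
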