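"""HDF5 session container and plain-text ingestion.

Container layout::

    /spikes   uint8   (neuron x trial x bin)
    /labels   int8    (trial,)
    /depths   float   (neuron,)              [optional]
    /lfp      float   (channel x time x trial) [optional]
    attrs: bin_width_ms, window_start_ms, epoch, channel_spacing_um

The plain-text alternative is one spike-times file per neuron
(``trial_id<TAB>time_ms`` per line) plus a labels file
(``trial_id<TAB>label``).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import SpikeTrainSet


def save_session(
    path,
    spikes: SpikeTrainSet,
    depths: np.ndarray | None = None,
    lfp: np.ndarray | None = None,
    channel_spacing: float | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("spikes", data=spikes.spikes.astype(np.uint8), compression="gzip")
        f.create_dataset("labels", data=spikes.labels.astype(np.int8))
        if depths is not None:
            f.create_dataset("depths", data=np.asarray(depths, dtype=float))
        if lfp is not None:
            f.create_dataset("lfp", data=np.asarray(lfp, dtype=np.float32), compression="gzip")
        f.attrs["bin_width_ms"] = spikes.bin_width
        f.attrs["window_start_ms"] = spikes.window_start
        f.attrs["epoch"] = spikes.epoch
        f.attrs["session_id"] = spikes.session_id
        if channel_spacing is not None:
            f.attrs["channel_spacing_um"] = float(channel_spacing)


def load_session(path):
    """Load a session container; returns (SpikeTrainSet, extras dict).

    ``extras`` holds ``depths``, ``lfp`` and ``channel_spacing`` when
    present in the file, else None.
    """
    with h5py.File(path, "r") as f:
        sts = SpikeTrainSet(
            spikes=f["spikes"][()],
            labels=f["labels"][()].astype(int),
            bin_width=float(f.attrs.get("bin_width_ms", 1.0)),
            window_start=float(f.attrs.get("window_start_ms", 0.0)),
            epoch=str(f.attrs.get("epoch", "test")),
            session_id=str(f.attrs.get("session_id", "")),
        )
        extras = {
            "depths": f["depths"][()] if "depths" in f else None,
            "lfp": f["lfp"][()].astype(float) if "lfp" in f else None,
            "channel_spacing": (
                float(f.attrs["channel_spacing_um"]) if "channel_spacing_um" in f.attrs else None
            ),
        }
    return sts, extras


def load_spike_times_text(
    neuron_files,
    labels_file,
    n_bins: int = 400,
    bin_width: float = 1.0,
    window_start: float = 0.0,
    epoch: str = "test",
) -> SpikeTrainSet:
    """Build a SpikeTrainSet from per-neuron spike-time text files.

    Each neuron file has lines ``trial_id<whitespace>time_ms``; the
    labels file has lines ``trial_id<whitespace>label`` with label in
    {-1, +1}.  Times outside [window_start, window_start + K * bin)
    are ignored; trials are ordered by trial_id.
    """
    lab = pd.read_csv(labels_file, sep=r"\s+", header=None, names=["trial_id", "label"])
    lab = lab.sort_values("trial_id").reset_index(drop=True)
    trial_index = {t: i for i, t in enumerate(lab["trial_id"])}
    n_trials = len(lab)
    spikes = np.zeros((len(neuron_files), n_trials, n_bins), dtype=np.uint8)
    for n, fn in enumerate(neuron_files):
        if Path(fn).stat().st_size == 0:
            continue
        df = pd.read_csv(fn, sep=r"\s+", header=None, names=["trial_id", "time_ms"])
        for t, time_ms in zip(df["trial_id"], df["time_ms"]):
            if t not in trial_index:
                raise ValueError(f"spike for unknown trial_id {t!r} in {fn}")
            k = int(np.floor((time_ms - window_start) / bin_width))
            if 0 <= k < n_bins:
                spikes[n, trial_index[t], k] = 1
    return SpikeTrainSet(
        spikes=spikes,
        labels=lab["label"].to_numpy(int),
        bin_width=bin_width,
        window_start=window_start,
        epoch=epoch,
        neuron_ids=[Path(f).stem for f in neuron_files],
    )


def weights_table(weight_rows) -> pd.DataFrame:
    """Long-format table of learned weights.

    ``weight_rows`` is an iterable of (session_id, cv_run, WeightVector).
    """
    records = []
    for session_id, run, wv in weight_rows:
        for n, w in enumerate(wv.weights):
            records.append(
                {
                    "session_id": session_id,
                    "cv_run": run,
                    "neuron_id": n,
                    "weight": w,
                    "sign": int(np.sign(w)),
                    "method": wv.method,
                    "C": wv.regularization,
                }
            )
    return pd.DataFrame.from_records(records)


def signal_table(session_id, cv_run, signal) -> pd.DataFrame:
    """Long-format table of one PopulationSignal's condition summaries."""
    k = signal.difference.size
    t = np.arange(k)
    frames = []
    for cond, series in (
        ("match", signal.cond_mean_match),
        ("nonmatch", signal.cond_mean_nonmatch),
        ("difference", signal.difference),
    ):
        frames.append(
            pd.DataFrame(
                {
                    "session": session_id,
                    "cv_run": cv_run,
                    "group": signal.group,
                    "condition": cond,
                    "time_ms": t,
                    "value": series,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def ccf_table(ccf) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair": ccf.pair,
            "condition": ccf.condition,
            "lag_ms": ccf.lags,
            "value": ccf.values,
            "n_trials": ccf.n_trials,
        }
    )
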