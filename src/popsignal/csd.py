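"""Current source density (CSD) from laminar LFP and layer assignment.

The CSD is estimated as the second spatial derivative of the
trial-averaged LFP along the probe (three-point stencil, edge channels
dropped).  A salient stimulus drives a current sink in the granular (G)
input layer flanked by sources in the supragranular (SG) and
infragranular (IG) layers.  The G-layer borders are found from the
spatial covariance of the CSD: the covariance column through the
strongest sink has a peak at the sink and troughs at the flanking
sources; the zero crossings between peak and troughs mark the borders.
Channels and neurons above the upper border are SG, below the lower
border IG, and in between (or exactly on a border) G.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default post-onset window (ms) searched for the strongest sink.
DEFAULT_SINK_WINDOW = (20.0, 100.0)

LAYERS = ("SG", "G", "IG")


@dataclass
class CSDMap:
    """Space x time current-flow map, normalized to [-1, 1].

    ``values[i, j]`` is the current flow at interior channel i and time
    j; under the default sink-positive convention, sinks are positive.
    ``depth_positions`` are the depths of the interior channels along
    the probe (edge channels are consumed by the stencil).
    """

    values: np.ndarray
    depth_positions: np.ndarray
    time_axis: np.ndarray
    spacing: float
    probe_span: tuple
    sign_convention: str = "sink-positive"


@dataclass
class LayerAssignment:
    """G-layer borders and the per-channel layer partition.

    ``borders`` is (upper_depth, lower_depth) of the granular layer;
    ``sink`` is the (depth index, time index) of the strongest sink in
    the CSD map.  ``border_flags`` marks sides where no zero crossing
    was found and the border fell back to the probe end.
    """

    borders: tuple
    channel_layers: np.ndarray
    channel_depths: np.ndarray
    sink: tuple
    probe_span: tuple
    border_flags: dict


def compute_csd(lfp: np.ndarray, spacing: float, sink_positive: bool = True,
                time_axis: np.ndarray | None = None) -> CSDMap:
    """CSD of a laminar LFP array (channel x time [x trial]).

    Trials (if present) are averaged first; the three-point second
    difference (V[i-1] - 2 V[i] + V[i+1]) / h^2 is applied over depth.
    With ``sink_positive`` (default) a local minimum of the potential —
    a current sink — maps to a positive CSD value.  The map is
    normalized by its maximum absolute value.
    """
    lfp = np.asarray(lfp, dtype=float)
    if lfp.ndim == 3:
        v = lfp.mean(axis=2)
    elif lfp.ndim == 2:
        v = lfp
    else:
        raise ValueError("lfp must be (channel x time) or (channel x time x trial)")
    n_ch = v.shape[0]
    if n_ch < 3:
        raise ValueError("CSD needs at least 3 channels")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    csd = (v[:-2] - 2.0 * v[1:-1] + v[2:]) / spacing**2
    if not sink_positive:
        csd = -csd
    m = np.abs(csd).max()
    if m > 0:
        csd = csd / m
    if time_axis is None:
        time_axis = np.arange(v.shape[1], dtype=float)
    depths = spacing * np.arange(1, n_ch - 1)
    return CSDMap(
        values=csd,
        depth_positions=depths,
        time_axis=np.asarray(time_axis, dtype=float),
        spacing=spacing,
        probe_span=(0.0, spacing * (n_ch - 1)),
        sign_convention="sink-positive" if sink_positive else "source-positive",
    )


def locate_strongest_sink(csd: CSDMap, window: tuple = DEFAULT_SINK_WINDOW) -> tuple[int, int]:
    """Indices (depth, time) of the maximal current flow within the window."""
    mask = (csd.time_axis >= window[0]) & (csd.time_axis <= window[1])
    if not mask.any():
        raise ValueError("window outside the time axis")
    sub = csd.values[:, mask]
    if np.abs(csd.values).max() == 0:
        raise ValueError("all-zero CSD map")
    i, j_local = np.unravel_index(np.argmax(sub), sub.shape)
    j = np.flatnonzero(mask)[j_local]
    return int(i), int(j)


def spatial_covariance(csd: CSDMap) -> np.ndarray:
    """Spatial Gram matrix of the CSD, C = A A^T / N_time (space x space).

    The raw (non-mean-subtracted) form is used, so C is symmetric with a
    non-negative diagonal.
    """
    a = csd.values
    return a @ a.T / a.shape[1]


def _zero_crossing(depths, c, i_from, i_to_step):
    """Walk from the peak toward the probe end; return the linearly
    interpolated depth of the first sign change, or None."""
    i = i_from
    while 0 <= i + i_to_step < c.size:
        c0, c1 = c[i], c[i + i_to_step]
        if c0 > 0 >= c1 or (c0 == 0 and c1 < 0):
            if c1 == c0:
                return float(depths[i + i_to_step])
            frac = c0 / (c0 - c1)
            return float(depths[i] + frac * (depths[i + i_to_step] - depths[i]))
        i += i_to_step
    return None


def layer_borders(csd: CSDMap, window: tuple = DEFAULT_SINK_WINDOW,
                  mean_subtract: bool = False) -> LayerAssignment:
    """G-layer borders from the CSD spatial covariance.

    The covariance column through the strongest sink channel peaks at
    the sink; walking outward on each side, the first zero crossing
    (linearly interpolated between channels) marks a border.  A side
    with no crossing gets the probe end as border, flagged.
    """
    sink = locate_strongest_sink(csd, window)
    a = csd.values
    if mean_subtract:
        a = a - a.mean(axis=1, keepdims=True)
        cmat = a @ a.T / a.shape[1]
    else:
        cmat = spatial_covariance(csd)
    c_max = cmat[:, sink[0]]
    depths = csd.depth_positions
    upper = _zero_crossing(depths, c_max, sink[0], -1)
    lower = _zero_crossing(depths, c_max, sink[0], +1)
    flags = {"upper_fallback": upper is None, "lower_fallback": lower is None}
    if upper is None:
        upper = csd.probe_span[0]
    if lower is None:
        lower = csd.probe_span[1]
    layers = np.empty(depths.size, dtype=object)
    layers[depths < upper] = "SG"
    layers[(depths >= upper) & (depths <= lower)] = "G"
    layers[depths > lower] = "IG"
    return LayerAssignment(
        borders=(upper, lower),
        channel_layers=layers.astype(str),
        channel_depths=depths,
        sink=sink,
        probe_span=csd.probe_span,
        border_flags=flags,
    )


def assign_neurons(depths, assignment: LayerAssignment) -> np.ndarray:
    """Layer tag ("SG"/"G"/"IG") per neuron from its depth along the probe.

    Depths exactly on a border go to G; a depth outside the probe span
    is an error.
    """
    depths = np.asarray(depths, dtype=float)
    lo, hi = assignment.probe_span
    if (depths < lo).any() or (depths > hi).any():
        raise ValueError("neuron depth outside the probe span")
    upper, lower = assignment.borders
    out = np.empty(depths.size, dtype=object)
    out[depths < upper] = "SG"
    out[(depths >= upper) & (depths <= lower)] = "G"
    out[depths > lower] = "IG"
    return out.astype(str)
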