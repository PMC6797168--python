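"""Normalized cross-correlation functions between simultaneous population
signals (plus/minus pools or layer pairs).

The raw CCF at lag tau >= 0 is R_xy(tau) = sum_k x(t_k) y(t_k + tau);
negative lags follow from the symmetry R_xy(-tau) = R_yx(tau).  It is
normalized by the geometric mean of the two zero-lag autocorrelations, so
|R| <= 1 with equality for proportional signals.  CCFs are computed per
trial and then averaged within a condition (or over all trials).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate

logger = logging.getLogger(__name__)


@dataclass
class CCFResult:
    """Normalized cross-correlation over lags -(K-1)..(K-1)."""

    lags: np.ndarray
    values: np.ndarray
    pair: str = ""
    condition: str = "both"
    per_trial: np.ndarray | None = None
    n_trials: int = 1
    n_dropped: int = 0
    valid: bool = True

    def crop(self, max_lag: int) -> "CCFResult":
        """Restrict to |lag| <= max_lag bins (for readability of output)."""
        keep = np.abs(self.lags) <= max_lag
        return CCFResult(
            lags=self.lags[keep],
            values=self.values[keep],
            pair=self.pair,
            condition=self.condition,
            per_trial=self.per_trial[:, keep] if self.per_trial is not None else None,
            n_trials=self.n_trials,
            n_dropped=self.n_dropped,
            valid=self.valid,
        )

    def at_lag(self, lag: int) -> float:
        return float(self.values[np.searchsorted(self.lags, lag)])


def _raw_ccf(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # correlate(y, x, "full")[K-1+tau] = sum_k x[k] y[k+tau]
    return correlate(y, x, mode="full", method="auto")


def ccf_single_trial(x: np.ndarray, y: np.ndarray, pair: str = "") -> CCFResult:
    """Normalized CCF of two simultaneous single-trial signals.

    Returns a result flagged invalid if either signal has zero energy
    (the normalization is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("signals must be 1-D, equal length, K >= 2")
    k = x.size
    lags = np.arange(-(k - 1), k)
    rxx0 = float(x @ x)
    ryy0 = float(y @ y)
    denom = np.sqrt(rxx0) * np.sqrt(ryy0)  # sqrt first: avoids underflow of the product
    if denom == 0.0 or not np.isfinite(denom):
        return CCFResult(lags=lags, values=np.full(2 * k - 1, np.nan), pair=pair, valid=False)
    values = _raw_ccf(x, y) / denom
    return CCFResult(lags=lags, values=values, pair=pair)


def ccf_trial_averaged(
    signals_a: np.ndarray,
    signals_b: np.ndarray,
    labels=None,
    condition: str = "both",
    pair: str = "",
) -> CCFResult:
    """Per-trial normalized CCFs averaged within a condition.

    ``signals_a`` and ``signals_b`` are (trial x bin) matrices of the two
    simultaneous signals, aligned trial by trial.  ``condition`` is
    "match", "nonmatch" or "both".  Zero-energy trials are dropped from
    the average with a logged count.
    """
    a = np.asarray(signals_a, dtype=float)
    b = np.asarray(signals_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("signal matrices must be equal-shape (trial x bin)")
    j, k = a.shape
    if condition == "both":
        keep = np.ones(j, dtype=bool)
    else:
        if labels is None:
            raise ValueError("labels required for a condition-specific CCF")
        labels = np.asarray(labels)
        keep = labels == (1 if condition == "match" else -1)
        if not keep.any():
            raise ValueError(f"no trials in condition {condition!r}")
    idx = np.flatnonzero(keep)
    rows, used = [], []
    for jj in idx:
        res = ccf_single_trial(a[jj], b[jj], pair=pair)
        if res.valid:
            rows.append(res.values)
            used.append(jj)
    dropped = idx.size - len(rows)
    if dropped:
        logger.warning("dropped %d zero-energy trial(s) from CCF average", dropped)
    lags = np.arange(-(k - 1), k)
    if not rows:
        return CCFResult(
            lags=lags,
            values=np.full(2 * k - 1, np.nan),
            pair=pair,
            condition=condition,
            n_trials=0,
            n_dropped=dropped,
            valid=False,
        )
    per_trial = np.asarray(rows)
    return CCFResult(
        lags=lags,
        values=per_trial.mean(axis=0),
        pair=pair,
        condition=condition,
        per_trial=per_trial,
        n_trials=len(rows),
        n_dropped=dropped,
    )
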