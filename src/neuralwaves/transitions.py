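"""Metastable transition detection from interpartition synchrony.

The brain (or any bilateral point cloud) is split into two partitions —
hemispheres by default — and the instantaneous coherence of each partition is
tracked over time.  A sliding-window, time-lagged cross-correlation between
the two coherence series carries a stable lag signature while one wave
pattern persists; at a metastable transition the pattern breaks up, the
cross-correlation flattens across lags, and its inverse variance over lags
spikes.  Transition times are the peaks of this inverse variance within each
suprathreshold interval (threshold = its temporal mean), and dwell times are
the gaps between consecutive transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phasefield import PhaseField

logger = logging.getLogger(__name__)

__all__ = [
    "CrossCorrelogram",
    "TransitionSet",
    "DwellTimes",
    "partition_coherence",
    "windowed_lagged_xcorr",
    "detect_transitions",
    "dwell_times",
    "axis_partition",
]


@dataclass
class CrossCorrelogram:
    """Windowed lagged Pearson cross-correlation C(t, l)."""

    C: np.ndarray  # (n_windows, n_lags), entries in [-1, 1]
    window_centers: np.ndarray  # ms
    lags: np.ndarray  # ms, symmetric about 0
    window_ms: float
    overlap: float
    mask: np.ndarray | None = None  # True where the estimate is defined


@dataclass
class TransitionSet:
    times: np.ndarray  # ms, strictly increasing
    threshold: float
    partition: str = "hemispheric"


@dataclass
class DwellTimes:
    durations: np.ndarray  # ms, > 0

    def skewness(self) -> float:
        from scipy.stats import skew

        return float(skew(self.durations))


def axis_partition(positions: np.ndarray, axis: str = "x",
                   split: float = 0.0) -> np.ndarray:
    """Binary labels (0/1) by coordinate sign relative to ``split``.

    ``axis='x'`` gives the hemispheric partition, ``'y'`` anteroposterior,
    ``'z'`` dorsoventral.
    """
    idx = {"x": 0, "y": 1, "z": 2}[axis]
    coord = np.asarray(positions, dtype=float)[:, idx]
    labels = (coord > split).astype(int)
    if labels.min() == labels.max():
        raise ValueError("all nodes fall on one side of the split")
    return labels


def partition_coherence(field: PhaseField, labels: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Order-parameter time series R_A(t), R_B(t) for a binary partition."""
    labels = np.asarray(labels)
    z = np.exp(1j * field.phases)
    out = []
    for cls in (0, 1):
        members = labels == cls
        if not members.any():
            raise ValueError(f"partition class {cls} is empty")
        out.append(np.abs(z[:, members].mean(axis=1)))
    return out[0], out[1]


def windowed_lagged_xcorr(x: np.ndarray, y: np.ndarray, dt: float = 1.0,
                          window_ms: float = 100.0, overlap: float = 0.9,
                          max_lag_ms: float = 30.0) -> CrossCorrelogram:
    """Sliding-window, time-lagged Pearson cross-correlation of two series.

    For a window starting at sample w and lag l (in samples), the Pearson
    correlation is computed between ``x[w : w + W]`` and
    ``y[w + l : w + l + W]``; lagged samples spill over the window edges into
    the full series rather than being zero-padded.  Windows are normalized
    per window (mean removed, unit variance).  Zero-variance windows yield a
    masked 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D series")
    W = int(round(window_ms / dt))
    max_lag = int(round(max_lag_ms / dt))
    if x.size < W + 2 * max_lag:
        raise ValueError("series shorter than window + 2*max_lag")
    hop = max(1, int(round(W * (1.0 - overlap))))
    lags = np.arange(-max_lag, max_lag + 1)
    starts = np.arange(max_lag, x.size - W - max_lag + 1, hop)
    C = np.zeros((starts.size, lags.size))
    mask = np.ones((starts.size, lags.size), dtype=bool)
    # a window is degenerate when its variation is negligible relative to
    # the series as a whole (guards against float noise on constant series)
    scale = max(np.abs(x).max(), np.abs(y).max(), 1e-300)
    tol = 1e-9 * scale * np.sqrt(W)
    for wi, w0 in enumerate(starts):
        xs = x[w0:w0 + W]
        xs = xs - xs.mean()
        sx = np.sqrt((xs**2).sum())
        for li, l in enumerate(lags):
            ys = y[w0 + l:w0 + l + W]
            ys = ys - ys.mean()
            sy = np.sqrt((ys**2).sum())
            if sx <= tol or sy <= tol:
                C[wi, li] = 0.0
                mask[wi, li] = False
            else:
                C[wi, li] = float((xs * ys).sum() / (sx * sy))
    centers = (starts + W / 2.0) * dt
    return CrossCorrelogram(C, centers, lags * dt, window_ms, overlap, mask)


def detect_transitions(cc: CrossCorrelogram,
                       threshold_scale: float = 1.0,
                       partition: str = "hemispheric") -> TransitionSet:
    """Transitions = peaks of 1/Var_l[C(t, l)] within suprathreshold runs.

    The inverse variance across lags spikes when the correlogram is flat
    (no lag structure), i.e. at desynchronizations.  The threshold is the
    temporal mean of the inverse variance, optionally scaled by
    ``threshold_scale`` for robustness checks.  Peak ties within a run are
    broken by the earliest time.
    """
    if cc.C.shape[0] < 10:
        raise ValueError("need at least 10 windows")
    C = cc.C.copy()
    if cc.mask is not None:
        # windows where the correlation itself was undefined carry no
        # evidence of lag structure either way; drop them
        C[~cc.mask] = np.nan
    valid_rows = np.sum(np.isfinite(C), axis=1) >= 3
    var = np.full(C.shape[0], np.nan)
    if valid_rows.any():
        var[valid_rows] = np.nanvar(C[valid_rows], axis=1, ddof=1)
    with np.errstate(divide="ignore"):
        u = 1.0 / var
    finite = np.isfinite(u)
    if not finite.any() or np.ptp(u[finite]) == 0:
        logger.info("inverse variance is constant/undefined; no transitions")
        return TransitionSet(np.array([]), float("nan"), partition)
    thr = threshold_scale * u[finite].mean()
    above = finite & (u > thr)
    u = np.where(finite, u, -np.inf)
    times = []
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j + 1 < above.size and above[j + 1]:
                j += 1
            seg = u[i:j + 1]
            times.append(cc.window_centers[i + int(np.argmax(seg))])
            i = j + 1
        else:
            i += 1
    return TransitionSet(np.asarray(times, dtype=float), float(thr), partition)


def dwell_times(ts: TransitionSet) -> DwellTimes:
    """Durations between consecutive transitions."""
    if ts.times.size < 2:
        raise ValueError("need at least 2 transitions for dwell times")
    return DwellTimes(np.diff(ts.times))
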