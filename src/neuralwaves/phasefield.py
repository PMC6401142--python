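"""Hilbert phases, synchrony order parameters, and phase-velocity fields.

The instantaneous phase of each node's signal is taken from the analytic
signal (Hilbert transform).  Waves are quantified by the phase-gradient
velocity field

    v = -(|dphi/dt| / ||grad phi||^2) grad phi

evaluated on the scattered 3D node cloud.  Spatial gradients are computed
wrap-safely from the complex field g = exp(i*phi) via the identity
dphi/dx = Re[-i * exp(-i*phi) * dg/dx], using per-node linear least-squares
fits of g over the spatial neighborhood of each node.  Speeds in mm/ms are
numerically equal to m/s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .dynamics import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseField",
    "VelocityField",
    "SpeedSummary",
    "hilbert_phase",
    "order_parameter",
    "local_global_synchrony",
    "phase_gradient",
    "velocity_field",
    "speed_summary",
    "speed_vs_connectivity",
]


@dataclass
class PhaseField:
    """Per-node wrapped Hilbert phases over time (radians in (-pi, pi])."""

    phases: np.ndarray  # (T, N)
    times: np.ndarray  # ms
    positions: np.ndarray | None = None  # (N, 3) mm
    valid: np.ndarray | None = None  # (N,) channels with defined phase

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.phases.shape[1], dtype=bool)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class VelocityField:
    """Phase-flow vectors (mm/ms) with a per-(time, node) validity mask."""

    v: np.ndarray  # (T, N, 3)
    mask: np.ndarray  # (T, N) bool, True where the estimate is valid
    times: np.ndarray
    positions: np.ndarray

    def speeds(self) -> np.ndarray:
        """(T, N) Euclidean speeds; NaN where masked out."""
        sp = np.linalg.norm(self.v, axis=2)
        return np.where(self.mask, sp, np.nan)


@dataclass
class SpeedSummary:
    nodal_mean: np.ndarray  # (N,) time-mean speed per node
    median: float
    p10: float
    p90: float
    log10_hist: tuple[np.ndarray, np.ndarray]  # (counts, bin edges)


def hilbert_phase(traj: Trajectory) -> PhaseField:
    """Instantaneous phase of each node via the analytic signal.

    Each channel is mean-centered; no filtering is applied.  Constant
    channels have undefined phase and are masked with a warning.
    """
    x = traj.values
    if x.shape[0] < 64:
        raise ValueError("need at least 64 samples for a stable Hilbert phase")
    centered = x - x.mean(axis=0, keepdims=True)
    const = np.ptp(x, axis=0) == 0
    if np.any(const):
        logger.warning("%d constant channel(s): phase undefined, masked",
                       int(const.sum()))
    analytic = hilbert(centered, axis=0)
    phases = np.angle(analytic)
    return PhaseField(phases, traj.times, valid=~const)


def order_parameter(phases_t: np.ndarray, node_set=None) -> float:
    """Kuramoto order parameter R = |mean of exp(i*phi)| over a node set."""
    phases_t = np.asarray(phases_t, dtype=float)
    if node_set is not None:
        node_set = np.asarray(node_set)
        if node_set.size == 0:
            raise ValueError("empty node set")
        phases_t = phases_t[node_set]
    if phases_t.size == 0:
        raise ValueError("empty node set")
    return float(np.abs(np.exp(1j * phases_t).mean()))


def local_global_synchrony(field: PhaseField, positions: np.ndarray,
                           radius: float = 20.0) -> tuple[float, float]:
    """Local and global synchrony order parameters.

    R_local is the node- and time-average of the order parameter over each
    node's neighborhood (all nodes within ``radius`` mm, including itself);
    R_global is the time-average of the whole-network order parameter.
    """
    positions = np.asarray(positions, dtype=float)
    z = np.exp(1j * field.phases)  # (T, N)
    r_global = float(np.abs(z.mean(axis=1)).mean())
    tree = cKDTree(positions)
    neighborhoods = tree.query_ball_point(positions, r=radius)
    r_loc_nodes = np.empty(positions.shape[0])
    for m, nbrs in enumerate(neighborhoods):
        r_loc_nodes[m] = np.abs(z[:, nbrs].mean(axis=1)).mean()
    return float(r_loc_nodes.mean()), r_global


def _neighborhoods(positions: np.ndarray, radius: float, k_fallback: int):
    """Nodes within ``radius`` of each node; fall back to the ``k_fallback``
    nearest when the ball holds fewer than 4 nodes (3D gradient needs >= 4)."""
    tree = cKDTree(positions)
    balls = tree.query_ball_point(positions, r=radius)
    n = positions.shape[0]
    k = min(k_fallback, n)
    _, knn = tree.query(positions, k=k)
    out = []
    for m in range(n):
        nbrs = balls[m] if len(balls[m]) >= 4 else list(np.atleast_1d(knn[m]))
        out.append(np.asarray(nbrs, dtype=int))
    return out


def phase_gradient(phases_t: np.ndarray, positions: np.ndarray,
                   radius: float = 20.0, k_fallback: int = 8,
                   cond_max: float = 1e6) -> tuple[np.ndarray, np.ndarray]:
    """Wrap-safe spatial phase gradient at every node.

    Phase unwrapping is handled through the complex field g = exp(i*phi):
    for each neighbor n of node m the wrapped phase increment
    ``dphi = angle(g_n * conj(g_m)) = Im log(g_n / g_m)`` is the discrete
    form of the identity dphi/dx = Re[-i exp(-i phi) dg/dx], and the
    gradient is the least-squares fit of these increments against the
    neighbor offsets.  The estimator is exact for any linear phase field
    whose increment stays below pi within the neighborhood (wavelength
    > 2x the neighborhood radius).  Returns ``(grad, mask)`` where grad is
    (N, 3) and mask flags well-conditioned fits (>= 4 neighbors spanning
    3D, condition number below ``cond_max``).
    """
    phases_t = np.asarray(phases_t, dtype=float)
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    g = np.exp(1j * phases_t)
    grad = np.zeros((n, 3))
    mask = np.zeros(n, dtype=bool)
    for m, nbrs in enumerate(_neighborhoods(positions, radius, k_fallback)):
        nbrs = nbrs[nbrs != m]
        if nbrs.size < 4:
            continue
        dx = positions[nbrs] - positions[m]
        sv = np.linalg.svd(dx, compute_uv=False)
        if sv[-1] <= 0 or sv[0] / sv[-1] > cond_max:
            continue
        dphi = np.angle(g[nbrs] * np.conj(g[m]))
        grad[m], *_ = np.linalg.lstsq(dx, dphi, rcond=None)
        mask[m] = True
    return grad, mask


def _wrap_safe_dphidt(phases: np.ndarray, dt: float) -> np.ndarray:
    """Temporal phase derivative via products of conjugate unit phasors."""
    g = np.exp(1j * phases)
    dphidt = np.empty_like(phases)
    dphidt[1:-1] = np.angle(g[2:] * np.conj(g[:-2])) / (2.0 * dt)
    dphidt[0] = np.angle(g[1] * np.conj(g[0])) / dt
    dphidt[-1] = np.angle(g[-1] * np.conj(g[-2])) / dt
    return dphidt


def velocity_field(field: PhaseField, positions: np.ndarray,
                   radius: float = 20.0, k_fallback: int = 8,
                   grad_tol: float = 1e-6) -> VelocityField:
    """Phase-flow velocity v = -(|dphi/dt| / ||grad phi||^2) grad phi.

    The absolute value on the temporal derivative makes v point down the
    phase gradient, i.e. along the direction of wave propagation.  Nodes
    where ``||grad phi|| < grad_tol`` (or where the gradient fit is
    ill-conditioned) are masked.
    """
    if field.phases.shape[0] < 3:
        raise ValueError("need at least 3 time samples")
    positions = np.asarray(positions, dtype=float)
    T, n = field.phases.shape
    dphidt = _wrap_safe_dphidt(field.phases, field.dt)
    v = np.zeros((T, n, 3))
    mask = np.zeros((T, n), dtype=bool)
    for t in range(T):
        grad, gmask = phase_gradient(field.phases[t], positions,
                                     radius=radius, k_fallback=k_fallback)
        norm2 = np.einsum("ij,ij->i", grad, grad)
        ok = gmask & (np.sqrt(norm2) >= grad_tol) & field.valid
        v[t, ok] = -(np.abs(dphidt[t, ok]) / norm2[ok])[:, None] * grad[ok]
        mask[t] = ok
    frames_empty = int((~mask.any(axis=1)).sum())
    if frames_empty:
        logger.warning("%d frame(s) have no valid velocity estimate", frames_empty)
    return VelocityField(v, mask, field.times, positions)


def speed_summary(vel: VelocityField, n_bins: int = 50) -> SpeedSummary:
    """Nodal mean speeds and pooled percentiles over all valid samples."""
    sp = vel.speeds()
    pooled = sp[np.isfinite(sp)]
    if pooled.size == 0:
        raise ValueError("no valid speed samples")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN nodes
        nodal = np.nanmean(sp, axis=0)
    positive = pooled[pooled > 0]
    if positive.size:
        logs = np.log10(positive)
        if np.ptp(logs) > 1e-9 * max(1.0, np.abs(logs).max()):
            hist = np.histogram(logs, bins=n_bins)
        else:  # speeds identical to numerical precision
            v = float(logs[0])
            hist = (np.array([positive.size]), np.array([v - 0.5, v + 0.5]))
    else:
        hist = (np.zeros(n_bins, dtype=int), np.linspace(0, 1, n_bins + 1))
    return SpeedSummary(
        nodal_mean=nodal,
        median=float(np.median(pooled)),
        p10=float(np.percentile(pooled, 10)),
        p90=float(np.percentile(pooled, 90)),
        log10_hist=hist,
    )


def speed_vs_connectivity(summary: SpeedSummary, profile) -> dict:
    """Pearson correlation of nodal mean speed with degree and strength."""
    speed = np.asarray(summary.nodal_mean, dtype=float)
    ok = np.isfinite(speed)
    if ok.sum() < 10:
        raise ValueError("need >= 10 nodes with defined mean speed")
    out = {}
    for name, x in (("degree", profile.degree), ("strength", profile.strength)):
        x = np.asarray(x, dtype=float)[ok]
        y = speed[ok]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"constant {name} or speed: correlation undefined")
        r, p = pearsonr(y, x)
        out[name] = (float(r), float(p))
    return out
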