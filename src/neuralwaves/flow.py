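"""Streamline tracing through phase-flow fields and source/sink detection.

Each frame of a velocity field is treated as a static vector field on the
node cloud.  Streamlines are traced from every node by Euler stepping
through an inverse-distance-weighted interpolant of the nodal vectors
(forward, and backward by inverting the flow), stopping when the path
leaves the cloud, stagnates, or exhausts the step budget.  Endpoints of
long streamlines are clustered with DBSCAN: forward endpoints congregate at
sinks, backward endpoints at sources.  These clusters form the organizing
scaffold of the instantaneous wave pattern; their per-node visit counts and
short-window temporal variability quantify how the scaffold reconfigures at
metastable transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import ranksums
from sklearn.cluster import DBSCAN

from .phasefield import VelocityField
from .transitions import TransitionSet

logger = logging.getLogger(__name__)

__all__ = [
    "Streamline",
    "ClusterSet",
    "FlowSnapshot",
    "VisitRecord",
    "interpolate_velocity",
    "trace_streamline",
    "dbscan",
    "find_sources_sinks",
    "track_and_count",
    "variability_vs_transitions",
]

OUTSIDE = "exited"
MAX_STEPS = "max_steps"
STAGNATED = "stagnated"


@dataclass
class Streamline:
    points: np.ndarray  # (n_points, 3), includes the seed
    direction: str  # "forward" | "backward"
    seed_node: int
    termination: str  # exited | max_steps | stagnated

    @property
    def n_steps(self) -> int:
        return self.points.shape[0] - 1


@dataclass
class ClusterSet:
    """DBSCAN clusters of streamline endpoints for one frame."""

    centroids: np.ndarray  # (n_clusters, 3)
    nodes: np.ndarray  # (n_clusters,) nearest node per centroid
    member_points: list = field(default_factory=list)  # list of (m_i, 3) arrays


@dataclass
class FlowSnapshot:
    time: float
    streamlines: list
    sinks: ClusterSet
    sources: ClusterSet


@dataclass
class VisitRecord:
    source_counts: np.ndarray  # (N,) visits per node over all frames
    sink_counts: np.ndarray
    frame_times: np.ndarray
    source_visits: np.ndarray  # (T, N) 0/1 indicator per frame
    sink_visits: np.ndarray
    window_ms: float = 20.0

    def windowed_variability(self, kind: str = "sink") -> tuple[np.ndarray, np.ndarray]:
        """Per-window SD (over frames in the window) of the nodal visit
        indicator, averaged over nodes; windows are non-overlapping."""
        visits = self.sink_visits if kind == "sink" else self.source_visits
        t = self.frame_times
        dt = t[1] - t[0] if t.size > 1 else 1.0
        per_win = max(1, int(round(self.window_ms / dt)))
        n_win = visits.shape[0] // per_win
        centers = np.empty(n_win)
        var = np.empty(n_win)
        for w in range(n_win):
            chunk = visits[w * per_win:(w + 1) * per_win]
            var[w] = chunk.std(axis=0).mean()
            centers[w] = t[w * per_win:(w + 1) * per_win].mean()
        return centers, var


def interpolate_velocity(point: np.ndarray, positions: np.ndarray,
                         vectors: np.ndarray, valid: np.ndarray | None = None,
                         radius: float = 20.0,
                         tree: cKDTree | None = None) -> np.ndarray | None:
    """Inverse-distance-weighted (power 2) velocity at an arbitrary point.

    Uses valid nodes within ``radius`` mm; returns the exact nodal vector if
    the point coincides with a node, and ``None`` when no valid node lies
    within the radius — the point is outside the cloud ("left the brain").
    """
    point = np.asarray(point, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if valid is None:
        valid = np.ones(positions.shape[0], dtype=bool)
    if tree is None:
        tree = cKDTree(positions)
    nbrs = np.asarray(tree.query_ball_point(point, r=radius), dtype=int)
    nbrs = nbrs[valid[nbrs]] if nbrs.size else nbrs
    if nbrs.size == 0:
        return None
    d = np.linalg.norm(positions[nbrs] - point, axis=1)
    exact = d < 1e-12
    if exact.any():
        return vectors[nbrs[np.argmax(exact)]].astype(float)
    w = 1.0 / d**2
    return (w[:, None] * vectors[nbrs]).sum(axis=0) / w.sum()


def trace_streamline(seed_point: np.ndarray, positions: np.ndarray,
                     vectors: np.ndarray, direction: str = "forward",
                     valid: np.ndarray | None = None, seed_node: int = -1,
                     max_step: float = 8.0, max_steps: int = 200,
                     stagnation_tol: float = 1e-6, radius: float = 20.0,
                     tree: cKDTree | None = None) -> Streamline:
    """Euler-trace one streamline through a single velocity-field frame.

    Each displacement is the interpolated vector rescaled to at most
    ``max_step`` mm (shorter vectors are not upscaled); ``backward`` tracing
    inverts the flow vectors.  Terminates on leaving the cloud, exceeding
    ``max_steps``, or a step shorter than ``stagnation_tol``.
    """
    sign = {"forward": 1.0, "backward": -1.0}[direction]
    if tree is None:
        tree = cKDTree(np.asarray(positions, dtype=float))
    p = np.asarray(seed_point, dtype=float).copy()
    pts = [p.copy()]
    termination = MAX_STEPS
    first = interpolate_velocity(p, positions, vectors, valid, radius, tree)
    if first is None:
        raise ValueError("seed point lies outside the node cloud")
    for _ in range(max_steps):
        v = interpolate_velocity(p, positions, vectors, valid, radius, tree)
        if v is None:
            termination = OUTSIDE
            break
        step = sign * v
        norm = np.linalg.norm(step)
        if norm < stagnation_tol:
            termination = STAGNATED
            break
        if norm > max_step:
            step = step * (max_step / norm)
        p = p + step
        pts.append(p.copy())
    return Streamline(np.asarray(pts), direction, seed_node, termination)


def dbscan(points: np.ndarray, eps: float = 6.0, min_pts: int = 10) -> np.ndarray:
    """Density-based clustering; returns labels with -1 for noise.

    Core points have >= ``min_pts`` neighbors (self included) within ``eps``
    and are expanded through density reachability; the result is
    deterministic given the input order.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] == 0:
        return np.empty(0, dtype=int)
    return DBSCAN(eps=eps, min_samples=min_pts).fit(points).labels_


def _cluster_endpoints(points: np.ndarray, positions: np.ndarray,
                       eps: float, min_pts: int) -> ClusterSet:
    labels = dbscan(points, eps=eps, min_pts=min_pts)
    ids = np.unique(labels[labels >= 0])
    centroids = np.empty((ids.size, 3))
    members = []
    for i, cid in enumerate(ids):
        pts = points[labels == cid]
        centroids[i] = pts.mean(axis=0)
        members.append(pts)
    if ids.size:
        tree = cKDTree(positions)
        _, nodes = tree.query(centroids)
        nodes = np.atleast_1d(nodes).astype(int)
    else:
        nodes = np.empty(0, dtype=int)
    return ClusterSet(centroids, nodes, members)


def find_sources_sinks(vel: VelocityField, frame: int,
                       max_step: float = 8.0, max_steps: int = 200,
                       min_retain_steps: int = 20, last_points: int = 5,
                       eps: float = 6.0, min_pts: int = 10,
                       radius: float = 20.0) -> FlowSnapshot:
    """Trace forward and backward streamlines from every node and cluster
    their endpoints into sinks (forward) and sources (backward).

    Streamlines shorter than ``min_retain_steps`` steps are discarded as
    transients/exits; only the last ``last_points`` points of each retained
    streamline are clustered.  Each cluster is assigned to the node nearest
    its centroid.
    """
    positions = vel.positions
    vectors = vel.v[frame]
    valid = vel.mask[frame]
    tree = cKDTree(positions)
    streamlines: list[Streamline] = []
    tails = {"forward": [], "backward": []}
    if valid.any():
        for node in range(positions.shape[0]):
            for direction in ("forward", "backward"):
                try:
                    sl = trace_streamline(
                        positions[node], positions, vectors, direction,
                        valid, node, max_step, max_steps,
                        radius=radius, tree=tree)
                except ValueError:
                    continue
                streamlines.append(sl)
                if sl.n_steps >= min_retain_steps:
                    tails[direction].append(sl.points[-last_points:])
    else:
        logger.warning("frame %d has no valid velocity vectors", frame)

    def collect(key):
        pts = (np.vstack(tails[key]) if tails[key]
               else np.empty((0, 3)))
        return _cluster_endpoints(pts, positions, eps, min_pts)

    sinks = collect("forward")
    sources = collect("backward")
    if not streamlines:
        logger.info("frame %d: no retained streamlines; empty snapshot", frame)
    return FlowSnapshot(float(vel.times[frame]), streamlines, sinks, sources)


def track_and_count(snapshots: list, n_nodes: int,
                    window_ms: float = 20.0) -> VisitRecord:
    """Accumulate per-node source/sink visits over a sequence of snapshots."""
    if not snapshots:
        raise ValueError("need at least one snapshot")
    T = len(snapshots)
    src = np.zeros((T, n_nodes), dtype=float)
    snk = np.zeros((T, n_nodes), dtype=float)
    times = np.empty(T)
    for t, snap in enumerate(snapshots):
        times[t] = snap.time
        for node in snap.sources.nodes:
            src[t, node] = 1.0
        for node in snap.sinks.nodes:
            snk[t, node] = 1.0
    return VisitRecord(src.sum(axis=0), snk.sum(axis=0), times, src, snk,
                       window_ms)


def variability_vs_transitions(record: VisitRecord, ts: TransitionSet,
                               kind: str = "sink") -> dict:
    """Compare windowed scaffold variability in windows with vs without a
    transition (two-sided Wilcoxon rank-sum)."""
    centers, var = record.windowed_variability(kind)
    t = record.frame_times
    dt = t[1] - t[0] if t.size > 1 else 1.0
    half = record.window_ms / 2.0
    has_transition = np.array([
        bool(np.any(np.abs(ts.times - c) <= half)) for c in centers])
    with_t = var[has_transition]
    without_t = var[~has_transition]
    if with_t.size < 3 or without_t.size < 3:
        raise ValueError("need >= 3 windows in each class")
    stat, p = ranksums(with_t, without_t)
    return {
        "median_with": float(np.median(with_t)),
        "median_without": float(np.median(without_t)),
        "statistic": float(stat),
        "p_value": float(p),
        "n_with": int(with_t.size),
        "n_without": int(without_t.size),
    }
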