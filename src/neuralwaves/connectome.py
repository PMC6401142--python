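"""Spatially embedded weighted networks: synthetic generators, surrogates, I/O.

A brain network is abstracted here as a set of node coordinates (mm) plus a
symmetric nonnegative weight matrix.  Synthetic bilateral point clouds with an
exponential weight–distance kernel stand in for an empirical connectome; the
surrogate transformations (edge randomization, geometric surrogates,
thresholding) probe which features of the network the emergent dynamics
depend on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialNetwork",
    "StrengthProfile",
    "sample_bilateral_positions",
    "exponential_network",
    "randomize_edges",
    "geometric_surrogate",
    "threshold_network",
    "strength_profile",
    "read_network",
    "write_network",
]


@dataclass
class SpatialNetwork:
    """A spatially embedded, undirected, weighted network.

    Parameters
    ----------
    positions : (N, 3) float array
        Node coordinates in mm.  The midline is the plane x = 0.
    weights : (N, N) float array
        Symmetric nonnegative connectivity matrix with zero diagonal.
    names : list of str, optional
        Per-node identifiers.
    """

    positions: np.ndarray
    weights: np.ndarray
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        n = self.positions.shape[0]
        if n < 3:
            raise ValueError("need at least 3 nodes")
        if self.weights.shape != (n, n):
            raise ValueError("weights shape does not match positions")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if not np.allclose(self.weights, self.weights.T, rtol=0, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("weight diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def hemisphere(self) -> np.ndarray:
        """Per-node 'L'/'R' labels from the sign of x; x == 0 goes to 'L'."""
        x = self.positions[:, 0]
        if np.any(x == 0):
            logger.info("nodes on the midline x=0 assigned to hemisphere L")
        return np.where(x > 0, "R", "L")

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distance matrix in mm."""
        return squareform(pdist(self.positions))

    def strengths(self) -> np.ndarray:
        """Node strength s_j = sum_k C_jk."""
        return self.weights.sum(axis=1)

    def with_weights(self, weights: np.ndarray) -> "SpatialNetwork":
        return SpatialNetwork(self.positions.copy(), weights, self.names)


@dataclass
class StrengthProfile:
    """Node strengths and the hub / feeder / non-hub partition."""

    strength: np.ndarray
    degree: np.ndarray
    hub_class: np.ndarray  # per-node labels: "hub" | "feeder" | "non-hub"
    n_hubs: int = 75

    def nodes_of(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.hub_class == label)


def sample_bilateral_positions(
    n_per_hemisphere: int,
    extent: tuple[float, float, float] = (70.0, 130.0, 90.0),
    seed: int | np.random.Generator | None = None,
    midline_gap: float = 15.0,
) -> np.ndarray:
    """Sample a bilateral 3D point cloud mirrored in distribution about x = 0.

    Each hemisphere is a uniform slab: |x| in (midline_gap, midline_gap +
    extent[0]), y and z centered on 0 with widths extent[1] and extent[2].
    The default extent approximates whole-brain dimensions in mm; the
    midline gap emulates the interhemispheric fissure (region centroids sit
    well lateral of x = 0), which weakens interhemispheric relative to
    intrahemispheric coupling under a distance-dependent kernel.

    Returns a (2 * n_per_hemisphere, 3) array; the first half has x < 0
    (left), the second half x > 0 (right).
    """
    if n_per_hemisphere < 2:
        raise ValueError("n_per_hemisphere must be >= 2")
    rng = np.random.default_rng(seed)
    lx, ly, lz = extent
    out = []
    for sign in (-1.0, 1.0):
        x = sign * (midline_gap + rng.uniform(0.0, lx, n_per_hemisphere))
        y = rng.uniform(-ly / 2, ly / 2, n_per_hemisphere)
        z = rng.uniform(-lz / 2, lz / 2, n_per_hemisphere)
        out.append(np.column_stack([x, y, z]))
    return np.vstack(out)


def exponential_network(
    positions: np.ndarray,
    decay_slope: float = -0.023,
    base_weight: float = 1.0,
    seed: int | np.random.Generator | None = None,
    jitter: float = 0.0,
) -> SpatialNetwork:
    """Build a network with a pure exponential weight–distance kernel.

    Weights follow ``w(j, k) = base_weight * 10 ** (decay_slope * d_jk)``,
    i.e. ``decay_slope`` is the slope of the linear log10(weight)-vs-distance
    relationship, in log10 units per mm.  The default -0.023 /mm makes the
    weight fall by 10x over ~43 mm, the order of the empirical
    weight–distance kernel of tractography connectomes.  ``jitter`` applies
    multiplicative lognormal noise ``10 ** N(0, jitter)`` symmetrically.
    """
    if decay_slope > 0:
        raise ValueError("decay_slope must be <= 0 (weights decay with distance)")
    positions = np.asarray(positions, dtype=float)
    d = squareform(pdist(positions))
    w = base_weight * 10.0 ** (decay_slope * d)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, jitter, size=w.shape)
        noise = (noise + noise.T) / np.sqrt(2.0)  # symmetric, sd preserved
        w = w * 10.0**noise
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0
    return SpatialNetwork(positions, w)


def _upper_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def randomize_edges(
    net: SpatialNetwork,
    fraction: float,
    seed: int | np.random.Generator | None = None,
) -> SpatialNetwork:
    """Randomize a fraction of edges while preserving the weight multiset.

    The selected fraction of nonzero edge weights is removed and reassigned
    to uniformly random node pairs that are currently unused, destroying the
    weight–distance relationship (and degree sequence) but keeping the set of
    nonzero weights identical.  ``fraction = 1`` reproduces a fully random
    surrogate with the same number of nodes and same weight distribution.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if fraction == 0.0:
        return net.with_weights(net.weights.copy())
    rng = np.random.default_rng(seed)
    n = net.n_nodes
    iu, ju = _upper_indices(n)
    wvec = net.weights[iu, ju].copy()
    nonzero = np.flatnonzero(wvec > 0)
    n_move = int(round(fraction * nonzero.size))
    moved = rng.choice(nonzero, size=n_move, replace=False)
    moved_weights = wvec[moved]
    wvec[moved] = 0.0
    free = np.flatnonzero(wvec == 0)
    dest = rng.choice(free, size=n_move, replace=False)
    wvec[dest] = rng.permutation(moved_weights)
    w = np.zeros((n, n))
    w[iu, ju] = wvec
    w = w + w.T
    return net.with_weights(w)


def geometric_surrogate(
    net: SpatialNetwork,
    n_distance_bins: int = 10,
    seed: int | np.random.Generator | None = None,
) -> SpatialNetwork:
    """Permute weights among edges of similar length (geometric surrogate).

    Edges are binned by Euclidean distance into ``n_distance_bins``
    equal-count bins and weights are shuffled only within each bin, which
    preserves the binned weight-vs-distance profile exactly while destroying
    all other structure.  Empty bins (possible with ties) are merged into
    their neighbor and logged.
    """
    rng = np.random.default_rng(seed)
    n = net.n_nodes
    iu, ju = _upper_indices(n)
    wvec = net.weights[iu, ju].copy()
    dvec = net.distances()[iu, ju]
    if np.unique(dvec).size < n_distance_bins:
        raise ValueError("fewer distinct edge distances than requested bins")
    # equal-count binning by distance rank
    order = np.argsort(dvec, kind="stable")
    bin_of = np.empty(dvec.size, dtype=int)
    bin_of[order] = np.minimum(
        (np.arange(dvec.size) * n_distance_bins) // dvec.size, n_distance_bins - 1
    )
    for b in range(n_distance_bins):
        members = np.flatnonzero(bin_of == b)
        if members.size == 0:
            logger.warning("empty distance bin %d collapsed into neighbor", b)
            continue
        wvec[members] = rng.permutation(wvec[members])
    w = np.zeros((n, n))
    w[iu, ju] = wvec
    w = w + w.T
    return net.with_weights(w)


def threshold_network(
    net: SpatialNetwork,
    mode: str = "density",
    level: float = 0.1,
    binarize: bool = False,
) -> SpatialNetwork:
    """Remove weak edges by target density or by a weight cutoff.

    In ``density`` mode the strongest ``floor(level * E)`` edges survive
    (E = number of nonzero edges); in ``weight`` mode edges with weight >=
    ``level`` survive.  With ``binarize`` surviving weights are set to 1.
    """
    n = net.n_nodes
    iu, ju = _upper_indices(n)
    wvec = net.weights[iu, ju].copy()
    if mode == "density":
        if not 0.0 < level <= 1.0:
            raise ValueError("density level must be in (0, 1]")
        nonzero = np.flatnonzero(wvec > 0)
        keep_n = int(np.floor(level * nonzero.size))
        order = nonzero[np.argsort(wvec[nonzero], kind="stable")]
        drop = order[: nonzero.size - keep_n]
        wvec[drop] = 0.0
    elif mode == "weight":
        wvec[wvec < level] = 0.0
    else:
        raise ValueError("mode must be 'density' or 'weight'")
    if binarize:
        wvec = (wvec > 0).astype(float)
    w = np.zeros((n, n))
    w[iu, ju] = wvec
    w = w + w.T
    out = net.with_weights(w)
    deg = (w > 0).sum(axis=1)
    if np.any(deg == 0):
        logger.warning("thresholding disconnected %d node(s)", int((deg == 0).sum()))
    return out


def strength_profile(net: SpatialNetwork, n_hubs: int = 75) -> StrengthProfile:
    """Classify nodes into hubs / feeders / non-hubs by anatomical strength.

    The top ``n_hubs`` nodes by strength are hubs, the bottom ``n_hubs`` are
    non-hubs, the remainder are feeders.  Strength ties are broken by node
    index (lower index ranks lower).
    """
    n = net.n_nodes
    if n <= 2 * n_hubs:
        raise ValueError("need N > 2 * n_hubs for a nonempty feeder class")
    s = net.strengths()
    degree = (net.weights > 0).sum(axis=1)
    order = np.argsort(s, kind="stable")  # stable: ties broken by node index
    labels = np.full(n, "feeder", dtype=object)
    labels[order[:n_hubs]] = "non-hub"
    labels[order[-n_hubs:]] = "hub"
    return StrengthProfile(s, degree, np.asarray(labels, dtype=object), n_hubs)


# ---------------------------------------------------------------------------
# I/O: coordinate CSV + dense matrix or 3-column edge list
# ---------------------------------------------------------------------------

def write_network(net: SpatialNetwork, coords_path, weights_path,
                  edge_list: bool = False) -> None:
    """Write coordinates as CSV (``node,x,y,z``) and weights as a dense
    whitespace-delimited matrix, or a 0-based ``i,j,w`` edge list."""
    names = net.names or [str(i) for i in range(net.n_nodes)]
    pd.DataFrame(
        {"node": names,
         "x": net.positions[:, 0],
         "y": net.positions[:, 1],
         "z": net.positions[:, 2]}
    ).to_csv(coords_path, index=False, float_format="%.17g")
    if edge_list:
        iu, ju = _upper_indices(net.n_nodes)
        keep = net.weights[iu, ju] > 0
        pd.DataFrame(
            {"i": iu[keep], "j": ju[keep], "w": net.weights[iu, ju][keep]}
        ).to_csv(weights_path, index=False, float_format="%.17g")
    else:
        np.savetxt(weights_path, net.weights, fmt="%.17g")


def read_network(coords_path, weights_path) -> SpatialNetwork:
    """Read a network written by :func:`write_network`.

    The weight file may be a dense N x N matrix (whitespace or comma
    delimited) or a CSV edge list with header ``i,j,w`` (0-based indices).
    Round-trips with :func:`write_network` to 1e-12 relative.
    """
    coords = pd.read_csv(coords_path)
    positions = coords[["x", "y", "z"]].to_numpy(dtype=float)
    names = [str(v) for v in coords["node"]]
    n = positions.shape[0]
    with open(weights_path) as fh:
        header = fh.readline()
    if header.strip().lower().replace(" ", "") == "i,j,w":
        edges = pd.read_csv(weights_path)
        w = np.zeros((n, n))
        i = edges["i"].to_numpy(int)
        j = edges["j"].to_numpy(int)
        w[i, j] = edges["w"].to_numpy(float)
        w = w + w.T
    else:
        delim = "," if "," in header else None
        w = np.loadtxt(weights_path, delimiter=delim)
    return SpatialNetwork(positions, w, names)
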