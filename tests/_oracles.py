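"""Independent brute-force oracles shared between test modules."""

import numpy as np


def brute_force_dbscan(points, eps, min_pts):
    """Exhaustive density-reachability clustering (quadratic reference)."""
    n = points.shape[0]
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    core = (d <= eps).sum(axis=1) >= min_pts  # self included
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            p = stack.pop()
            if not core[p]:
                continue
            for q in np.flatnonzero(d[p] <= eps):
                if labels[q] == -1:
                    labels[q] = cluster
                    stack.append(q)
        cluster += 1
    return labels


def same_partition(a, b):
    """Labelings equal up to cluster renaming (noise must match exactly)."""
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)
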