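"""Independent reference implementations used only to check the package."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def brute_force_dbscan(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """O(n^2) neighbor-graph DBSCAN.

    Core points have at least ``min_samples`` neighbors within ``eps``
    (counting themselves). Clusters are grown breadth-first from unvisited core
    points in index order; border points join the first cluster that reaches
    them. Noise is -1.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    if n == 0:
        return np.empty(0, int)
    dist = cdist(pts, pts)
    neighbors = [np.flatnonzero(dist[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_samples for nb in neighbors])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        queue = [i]
        labels[i] = cluster
        while queue:
            j = queue.pop(0)
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    queue.append(k)
        cluster += 1
    return labels


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by first occurrence so partitions compare directly."""
    out = np.full(len(labels), -1)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab < 0:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def csr_in_disc(rng: np.random.Generator, n: int, radius: float, center=(0.0, 0.0)) -> np.ndarray:
    """n iid uniform points in a disc."""
    th = rng.uniform(0, 2 * np.pi, n)
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    return np.column_stack([r * np.cos(th), r * np.sin(th)]) + np.asarray(center)
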