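"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (double loops, exhaustive search,
sparse-graph shortest paths) and shares no code with the implementation
paths it checks.
"""

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree


def nw_brute_force(x, v, grid, sigma, topology="linear"):
    """Double-loop Nadaraya-Watson estimate with an untruncated Gaussian."""
    out = np.empty(len(grid))
    for gi, g in enumerate(grid):
        num = den = 0.0
        for xi, vi in zip(x, v):
            d = abs(g - xi)
            if topology == "circular":
                d = min(d, 360.0 - d)
            w = np.exp(-0.5 * (d / sigma) ** 2)
            num += w * vi
            den += w
        out[gi] = num / den
    return out


def geodesic_distance_oracle(field, margin1_points):
    """Multi-source Dijkstra geodesic distance from the visit-1 margin.

    Shortest paths run over the Omega_2 cell graph with a 16-neighbourhood
    (axis, diagonal, and knight moves; metric anisotropy below 1.5%).  A
    virtual source node connects every near-margin cell at its true distance
    to the sub-pixel visit-1 margin, so source quantization does not bias the
    comparison.  Returns a grid of distances (mm), inf off Omega_2.
    """
    nr, nc = field.T.shape
    h = field.h_mm
    nodes = np.argwhere(field.region2)
    idx = -np.ones((nr, nc), dtype=int)
    idx[nodes[:, 0], nodes[:, 1]] = np.arange(1, len(nodes) + 1)  # 0 = source
    offsets = [
        (dr, dc)
        for dr in range(-2, 3)
        for dc in range(-2, 3)
        if (dr, dc) != (0, 0) and (max(abs(dr), abs(dc)) == 1 or abs(dr) + abs(dc) == 3)
    ]
    rows, cols, wts = [], [], []
    for dr, dc in offsets:
        dst = nodes + [dr, dc]
        ok = (dst[:, 0] >= 0) & (dst[:, 0] < nr) & (dst[:, 1] >= 0) & (dst[:, 1] < nc)
        s, d = nodes[ok], dst[ok]
        di = idx[d[:, 0], d[:, 1]]
        ok2 = di > 0
        rows.append(idx[s[ok2, 0], s[ok2, 1]])
        cols.append(di[ok2])
        wts.append(np.full(int(ok2.sum()), np.hypot(dr, dc) * h))
    tree = cKDTree(margin1_points)
    xs = field.origin_mm[0] + (nodes[:, 1] + 0.5) * h
    ys = field.origin_mm[1] + (nodes[:, 0] + 0.5) * h
    dmargin = tree.query(np.column_stack([xs, ys]))[0]
    near = dmargin <= 2 * h
    rows.append(np.zeros(int(near.sum()), dtype=int))
    cols.append(idx[nodes[near, 0], nodes[near, 1]])
    wts.append(
        np.where(field.region1[nodes[near, 0], nodes[near, 1]], 0.0, dmargin[near])
    )
    n = len(nodes) + 1
    graph = coo_matrix(
        (np.concatenate(wts), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    dist = dijkstra(graph, directed=False, indices=0)
    dmap = np.full((nr, nc), np.inf)
    dmap[nodes[:, 0], nodes[:, 1]] = dist[1:]
    return dmap


def exhaustive_nearest(points_from, points_to):
    """Exhaustive nearest-point search (lowest index wins ties)."""
    idx = np.empty(len(points_from), dtype=int)
    dist = np.empty(len(points_from))
    for i, p in enumerate(points_from):
        d = np.hypot(*(points_to - p).T)
        idx[i] = int(np.argmin(d))  # argmin returns the first (lowest) index
        dist[i] = d[idx[i]]
    return dist, idx


def arclength_walk(vertices, spacing):
    """Naive equal-arclength walk along a closed polygon."""
    pts = []
    closed = np.vstack([vertices, vertices[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    total = seg.sum()
    n_points = int(total / spacing + 1e-9)
    target = 0.0
    acc = 0.0
    i = 0
    while target < total - 1e-12 and len(pts) < n_points:
        while acc + seg[i] < target:
            acc += seg[i]
            i += 1
        frac = (target - acc) / seg[i]
        pts.append(closed[i] + frac * (closed[i + 1] - closed[i]))
        target += spacing
    return np.array(pts)
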