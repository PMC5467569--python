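"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own graph machinery
(scipy.sparse.csgraph): a textbook binary-heap Dijkstra over an
explicitly enumerated voxel graph, plus a dense nearest-point midline
search.
"""

import heapq

import numpy as np

_OFFSETS = [
    (di, dj, dk)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    for dk in (-1, 0, 1)
    if (di, dj, dk) != (0, 0, 0)
]


def dijkstra_distances(mask_data, spacing, seeds):
    """Exact shortest-path distances from seed voxels on the 26-connected
    in-mask graph; returns a full-grid array with +inf off-path/off-mask.

    ``seeds`` is a list of integer voxel-index triples.
    """
    m = np.asarray(mask_data).astype(bool)
    sp = np.asarray(spacing, dtype=float)
    dist = np.full(m.shape, np.inf)
    heap = []
    for s in seeds:
        s = tuple(int(v) for v in s)
        if not m[s]:
            raise ValueError(f"seed {s} not in mask")
        dist[s] = 0.0
        heapq.heappush(heap, (0.0, s))
    weights = {o: float(np.sqrt(((np.array(o) * sp) ** 2).sum())) for o in _OFFSETS}
    shape = m.shape
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u]:
            continue
        for o, w in weights.items():
            v = (u[0] + o[0], u[1] + o[1], u[2] + o[2])
            if not (0 <= v[0] < shape[0] and 0 <= v[1] < shape[1] and 0 <= v[2] < shape[2]):
                continue
            if not m[v]:
                continue
            nd = d + w
            if nd < dist[v]:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


def dijkstra_path(mask_data, spacing, start, end):
    """One shortest path (voxel index list) from start to end, with
    lexicographic tie-breaking on the predecessor."""
    m = np.asarray(mask_data).astype(bool)
    sp = np.asarray(spacing, dtype=float)
    start = tuple(int(v) for v in start)
    end = tuple(int(v) for v in end)
    dist = {start: 0.0}
    pred = {}
    heap = [(0.0, start)]
    weights = {o: float(np.sqrt(((np.array(o) * sp) ** 2).sum())) for o in _OFFSETS}
    shape = m.shape
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist.get(u, np.inf):
            continue
        if u == end:
            break
        for o, w in weights.items():
            v = (u[0] + o[0], u[1] + o[1], u[2] + o[2])
            if not (0 <= v[0] < shape[0] and 0 <= v[1] < shape[1] and 0 <= v[2] < shape[2]):
                continue
            if not m[v]:
                continue
            nd = d + w
            if nd < dist.get(v, np.inf) - 1e-12:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd, v))
    if end not in dist:
        raise ValueError("no path")
    path = [end]
    while path[-1] != start:
        path.append(pred[path[-1]])
    path.reverse()
    return np.array(path)


def nearest_midline_frame(points, midline_fn, n_samples=20001):
    """Brute-force nearest midline point: dense sampling + argmin.

    Returns (s_nearest, nearest_points) for each query point.
    """
    ss = np.linspace(0.0, 1.0, n_samples)
    mpts = midline_fn(ss)
    out_s = np.empty(len(points))
    out_p = np.empty((len(points), 3))
    # chunk to bound memory
    for lo in range(0, len(points), 256):
        chunk = points[lo : lo + 256]
        d2 = ((chunk[:, None, :] - mpts[None, :, :]) ** 2).sum(-1)
        j = np.argmin(d2, axis=1)
        out_s[lo : lo + 256] = ss[j]
        out_p[lo : lo + 256] = mpts[j]
    return out_s, out_p
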