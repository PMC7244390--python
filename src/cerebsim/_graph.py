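"""Numba kernels for geodesic graph operations on triangle meshes.

Two operations dominate runtime at realistic mesh sizes (10^5..10^6
vertices): farthest-point sampling for source-grid decimation, and
ring-synchronous breadth-first patch growth.  Both run on a CSR adjacency
(``indptr``/``indices``/edge weights in meters).
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = np.inf


@njit(cache=True)
def _heap_push(heap_d, heap_i, size, d, i):
    heap_d[size] = d
    heap_i[size] = i
    c = size
    while c > 0:
        p = (c - 1) >> 1
        if heap_d[p] > heap_d[c]:
            heap_d[p], heap_d[c] = heap_d[c], heap_d[p]
            heap_i[p], heap_i[c] = heap_i[c], heap_i[p]
            c = p
        else:
            break
    return size + 1


@njit(cache=True)
def _heap_pop(heap_d, heap_i, size):
    d = heap_d[0]
    i = heap_i[0]
    size -= 1
    heap_d[0] = heap_d[size]
    heap_i[0] = heap_i[size]
    p = 0
    while True:
        l = 2 * p + 1
        r = l + 1
        s = p
        if l < size and heap_d[l] < heap_d[s]:
            s = l
        if r < size and heap_d[r] < heap_d[s]:
            s = r
        if s == p:
            break
        heap_d[p], heap_d[s] = heap_d[s], heap_d[p]
        heap_i[p], heap_i[s] = heap_i[s], heap_i[p]
        p = s
    return d, i, size


@njit(cache=True)
def _relax_from(center, cidx, indptr, indices, weights, dist, owner,
                heap_d, heap_i, changed):
    """Truncated Dijkstra from one new center: update ``dist``/``owner``
    only where the new center is strictly closer than the incumbent.
    Vertices whose distance shrank are appended to ``changed``; the count
    is returned (entries may repeat)."""
    size = 0
    n_changed = 0
    dist[center] = 0.0
    owner[center] = cidx
    changed[n_changed] = center
    n_changed += 1
    size = _heap_push(heap_d, heap_i, size, 0.0, center)
    while size > 0:
        d, u, size = _heap_pop(heap_d, heap_i, size)
        if d > dist[u] or owner[u] != cidx:
            continue
        for k in range(indptr[u], indptr[u + 1]):
            v = indices[k]
            nd = d + weights[k]
            if nd < dist[v]:
                dist[v] = nd
                owner[v] = cidx
                if size < heap_d.shape[0] and n_changed < changed.shape[0]:
                    size = _heap_push(heap_d, heap_i, size, nd, v)
                    changed[n_changed] = v
                    n_changed += 1
    return n_changed


@njit(cache=True)
def farthest_point_sample(indptr, indices, weights, n_vertices, n_select, start):
    """Geodesic farthest-point sampling on a weighted vertex graph.

    Returns ``(selected, owner, dist)`` where ``selected`` are the chosen
    vertex ids in selection order, ``owner[v]`` is the index (into
    ``selected``) of the geodesically nearest selected vertex and ``dist[v]``
    the corresponding graph distance.

    The argmax over current distances uses a lazy max-heap (entries are
    invalidated rather than removed when a distance shrinks); a stale-entry
    sweep rebuilds the heap if it overflows.  Ties break toward the entry
    pushed first, which is deterministic for a fixed graph.
    """
    dist = np.full(n_vertices, INF)
    owner = np.full(n_vertices, -1, dtype=np.int64)
    selected = np.empty(n_select, dtype=np.int64)
    cap = 8 * n_vertices + 16
    heap_d = np.empty(cap)
    heap_i = np.empty(cap, dtype=np.int64)

    changed = np.empty(cap, dtype=np.int64)
    selected[0] = start
    _relax_from(start, 0, indptr, indices, weights, dist, owner, heap_d,
                heap_i, changed)

    # lazy max-heap over -dist
    mcap = 8 * n_vertices + 16
    mh_d = np.empty(mcap)
    mh_i = np.empty(mcap, dtype=np.int64)
    msize = 0
    for v in range(n_vertices):
        msize = _heap_push(mh_d, mh_i, msize, -dist[v], v)

    for s in range(1, n_select):
        best = -1
        while msize > 0:
            d, v, msize = _heap_pop(mh_d, mh_i, msize)
            if -d == dist[v] and dist[v] > 0.0:
                best = v
                break
        if best == -1:
            # every remaining vertex is already selected (dist 0)
            return selected[:s], owner, dist
        selected[s] = best
        nch = _relax_from(best, s, indptr, indices, weights, dist, owner,
                          heap_d, heap_i, changed)
        for ci in range(nch):
            v = changed[ci]
            if dist[v] > 0.0:
                if msize >= mcap - 1:
                    msize = _rebuild_maxheap(mh_d, mh_i, dist)
                msize = _heap_push(mh_d, mh_i, msize, -dist[v], v)
    return selected, owner, dist


@njit(cache=True)
def _rebuild_maxheap(mh_d, mh_i, dist):
    size = 0
    for v in range(dist.shape[0]):
        if dist[v] > 0.0:
            size = _heap_push(mh_d, mh_i, size, -dist[v], v)
    return size


@njit(cache=True)
def grow_patch_rings(indptr, indices, kept, areas, seed, target_area):
    """Ring-synchronous BFS patch growth.

    Starting from ``seed``, whole rings of graph neighbors (restricted to
    ``kept`` vertices) are added in graph-distance order until the summed
    vertex area first reaches ``target_area``.  Returns ``(members, n, area)``
    where ``members[:n]`` lists included vertices ring by ring (ascending
    index within each ring) and ``area`` is the realized patch area.
    """
    n_vertices = indptr.shape[0] - 1
    visited = np.zeros(n_vertices, dtype=np.uint8)
    members = np.empty(n_vertices, dtype=np.int64)
    frontier = np.empty(n_vertices, dtype=np.int64)
    nxt = np.empty(n_vertices, dtype=np.int64)

    members[0] = seed
    n = 1
    visited[seed] = 1
    area = areas[seed]
    frontier[0] = seed
    fn = 1
    while area < target_area and fn > 0:
        m = 0
        for fi in range(fn):
            u = frontier[fi]
            for k in range(indptr[u], indptr[u + 1]):
                v = indices[k]
                if visited[v] == 0 and kept[v]:
                    visited[v] = 1
                    nxt[m] = v
                    m += 1
        if m == 0:
            break
        ring = np.sort(nxt[:m])
        for i in range(m):
            members[n] = ring[i]
            area += areas[ring[i]]
            n += 1
        frontier[:m] = ring
        fn = m
    return members, n, area
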