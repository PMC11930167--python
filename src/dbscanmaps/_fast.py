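"""Numba kernel for grid scans: epsilon-sweep DBSCAN labelings at fixed N.

At fixed N everything in DBSCAN is monotone in epsilon: neighborhood counts
grow, the core set grows, and clusters only merge.  Processing the edge
stream in ascending distance order therefore lets a single union-find sweep
produce the labeling at every epsilon of the grid:

* an arriving edge increments both endpoint counts and is appended to the
  endpoints' active adjacency lists;
* a point whose count reaches N becomes core and is unioned with every
  active core neighbor (and advertised as a candidate border anchor to all
  its active neighbors);
* an edge between two existing cores unions their clusters;
* ``minv[u]`` tracks the lowest-index core neighbor of a non-core point u,
  preserving the package's deterministic border rule;
* after all edges with distance <= epsilon_s have been processed, the
  labeling for grid column s is read off the union-find state.

The output labels are union-find root ids (arbitrary integers, -1 = noise);
they are compacted downstream.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency normally
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def sweep_labels(n, ei, ej, prefix, N, indptr):
    """Labels at every epsilon for one N.

    Parameters
    ----------
    n : number of points
    ei, ej : edge endpoints sorted by ascending edge distance
    prefix : number of edges with distance <= epsilon, per grid epsilon
    N : minimum point count (closed neighborhood, counting the point)
    indptr : CSR row pointer of the full adjacency (at the largest epsilon)

    Returns
    -------
    labels : (len(prefix), n) int64, union-find root ids, -1 for noise
    """
    n_eps = prefix.shape[0]
    cnt = np.ones(n, np.int64)
    fill = indptr[:-1].copy()
    adj = np.empty(indptr[n], np.int64)
    core = np.zeros(n, np.uint8)
    minv = np.full(n, n, np.int64)  # n = sentinel for "no core neighbor"
    parent = np.arange(n)
    labels = np.full((n_eps, n), -1, np.int64)

    e = 0
    for s in range(n_eps):
        stop = prefix[s]
        while e < stop:
            a = ei[e]
            b = ej[e]
            adj[fill[a]] = b
            fill[a] += 1
            adj[fill[b]] = a
            fill[b] += 1
            cnt[a] += 1
            cnt[b] += 1
            newly_a = cnt[a] == N
            newly_b = cnt[b] == N
            if cnt[a] >= N:
                core[a] = 1
            if cnt[b] >= N:
                core[b] = 1
            if newly_a:
                for t in range(indptr[a], fill[a]):
                    w = adj[t]
                    if core[w]:
                        x = a
                        while parent[x] != x:
                            parent[x] = parent[parent[x]]
                            x = parent[x]
                        y = w
                        while parent[y] != y:
                            parent[y] = parent[parent[y]]
                            y = parent[y]
                        if x != y:
                            parent[x] = y
                    if a < minv[w]:
                        minv[w] = a
            if newly_b:
                for t in range(indptr[b], fill[b]):
                    w = adj[t]
                    if core[w]:
                        x = b
                        while parent[x] != x:
                            parent[x] = parent[parent[x]]
                            x = parent[x]
                        y = w
                        while parent[y] != y:
                            parent[y] = parent[parent[y]]
                            y = parent[y]
                        if x != y:
                            parent[x] = y
                    if b < minv[w]:
                        minv[w] = b
            if not newly_a and not newly_b and core[a] == 1 and core[b] == 1:
                x = a
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                y = b
                while parent[y] != y:
                    parent[y] = parent[parent[y]]
                    y = parent[y]
                if x != y:
                    parent[x] = y
            if core[a] == 1 and b < n and core[b] == 0 and a < minv[b]:
                minv[b] = a
            if core[b] == 1 and core[a] == 0 and b < minv[a]:
                minv[a] = b
            e += 1
        for u in range(n):
            if core[u] == 1:
                w = u
            elif minv[u] < n:
                w = minv[u]
            else:
                continue
            while parent[w] != w:
                parent[w] = parent[parent[w]]
                w = parent[w]
            labels[s, u] = w
    return labels
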