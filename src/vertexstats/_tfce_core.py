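"""Numba union-find kernel for threshold-free cluster enhancement.

Thresholds are processed in descending order; vertices and edges activate
as the level drops below their height, components merge through a weighted
union-find with path compression, and at every level each active vertex
accumulates ``extent^E * h^H * dh`` from its current component.  One pass
costs O(levels * V + E alpha) rather than one full component labelling per
level.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _find(parent: np.ndarray, v: int) -> int:
    root = v
    while parent[root] != root:
        root = parent[root]
    while parent[v] != root:
        nxt = parent[v]
        parent[v] = root
        v = nxt
    return root


@njit(cache=True)
def tfce_accumulate(
    values: np.ndarray,
    edge_a: np.ndarray,
    edge_b: np.ndarray,
    thresholds: np.ndarray,
    dh: float,
    ext_exp: float,
    height_exp: float,
) -> np.ndarray:
    """Accumulate TFCE scores for a non-negative height map.

    ``thresholds`` must be sorted descending.  Vertices with height below
    the smallest threshold stay zero.
    """
    n = values.shape[0]
    out = np.zeros(n)
    parent = np.full(n, -1, dtype=np.int64)
    size = np.zeros(n, dtype=np.int64)

    vorder = np.argsort(-values)
    ne = edge_a.shape[0]
    emin = np.empty(ne)
    for k in range(ne):
        a = values[edge_a[k]]
        b = values[edge_b[k]]
        emin[k] = a if a < b else b
    eorder = np.argsort(-emin)

    active = np.empty(n, dtype=np.int64)
    n_active = 0
    vi = 0
    ei = 0
    for t_i in range(thresholds.shape[0]):
        h = thresholds[t_i]
        while vi < n and values[vorder[vi]] >= h:
            v = vorder[vi]
            parent[v] = v
            size[v] = 1
            active[n_active] = v
            n_active += 1
            vi += 1
        while ei < ne and emin[eorder[ei]] >= h:
            k = eorder[ei]
            ra = _find(parent, edge_a[k])
            rb = _find(parent, edge_b[k])
            if ra != rb:
                if size[ra] < size[rb]:
                    ra, rb = rb, ra
                parent[rb] = ra
                size[ra] += size[rb]
            ei += 1
        level_weight = h**height_exp * dh
        for j in range(n_active):
            v = active[j]
            r = _find(parent, v)
            out[v] += size[r] ** ext_exp * level_weight
    return out
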