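"""Order-statistic sweep for 2-D dominance counting.

For n points (z_k, t_k) the chi-square threshold search needs, for every
candidate point c, the number of points with z >= z_c and t >= t_c, together
with both marginal counts. A single sweep in decreasing z with a Fenwick
(binary indexed) tree over t-ranks gives all n dominance counts in
O(n log n); groups of tied z values are inserted before any member of the
group is queried so that the >= convention holds exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sweep_counts(order, z, t_rank, n_ranks):  # pragma: no cover - jitted
    n = order.size
    tree = np.zeros(n_ranks + 1, dtype=np.int64)
    dom = np.empty(n, dtype=np.int64)
    z_ge = np.empty(n, dtype=np.int64)
    i = 0
    inserted = 0
    while i < n:
        j = i
        zv = z[order[i]]
        while j < n and z[order[j]] == zv:
            j += 1
        for k in range(i, j):  # insert the whole tie group first
            r = t_rank[order[k]] + 1
            while r <= n_ranks:
                tree[r] += 1
                r += r & (-r)
        inserted += j - i
        for k in range(i, j):
            r = t_rank[order[k]]  # prefix count of t strictly below
            s = 0
            while r > 0:
                s += tree[r]
                r -= r & (-r)
            dom[order[k]] = inserted - s
            z_ge[order[k]] = inserted
        i = j
    return dom, z_ge


def dominance_counts(z: np.ndarray, t: np.ndarray):
    """Per point: (#{z_k >= z_c and t_k >= t_c}, #{z_k >= z_c}, #{t_k >= t_c}).

    Ties are counted inclusively on both axes, matching the quadrant
    definitions used by the threshold search.
    """
    z = np.ascontiguousarray(z, dtype=np.float64)
    t = np.ascontiguousarray(t, dtype=np.float64)
    n = z.size
    uniq_t = np.unique(t)
    t_rank = np.searchsorted(uniq_t, t).astype(np.int64)
    # stable sort by decreasing z keeps tie groups contiguous
    order = np.argsort(-z, kind="stable").astype(np.int64)
    dom, z_ge = _sweep_counts(order, z, t_rank, np.int64(uniq_t.size))
    # #{t_k >= t_c} from the global rank distribution
    counts_below = np.searchsorted(np.sort(t), t, side="left")
    t_ge = n - counts_below
    return dom, z_ge, t_ge.astype(np.int64)
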