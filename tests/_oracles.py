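"""Independent reference implementations used only as test oracles."""

from fractions import Fraction
from math import comb

import numpy as np


def bh_oracle(pvalues) -> np.ndarray:
    """Textbook Benjamini-Hochberg: sort, p*m/rank, cumulative min from the top."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def hypergeom_tail_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) by exact rational combinatorics."""
    denom = comb(N, n)
    total = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return Fraction(total, denom)


def bfs_distances(adjacency: dict, sources) -> dict:
    """Plain breadth-first distances from a source set."""
    from collections import deque

    dist = {s: 0 for s in sources}
    queue = deque(sources)
    while queue:
        node = queue.popleft()
        for neighbor in adjacency.get(node, ()):
            if neighbor not in dist:
                dist[neighbor] = dist[node] + 1
                queue.append(neighbor)
    return dist
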