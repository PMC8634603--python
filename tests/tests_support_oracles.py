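"""Brute-force oracles shared across tests, independent of the package."""

from itertools import combinations, permutations

import numpy as np


def brute_force_triad_partition(a):
    """Counts of 3-node induced subgraphs grouped by canonical form.

    Canonicalization tries all 6 node permutations and keeps the
    lexicographically smallest off-diagonal edge tuple.
    """
    n = a.shape[0]
    counts = {}
    for trip in combinations(range(n), 3):
        sub = a[np.ix_(trip, trip)]
        best = None
        for p in permutations(range(3)):
            m = sub[np.ix_(p, p)]
            code = tuple(
                bool(m[i, j]) for i in range(3) for j in range(3) if i != j
            )
            if best is None or code < best:
                best = code
        counts[best] = counts.get(best, 0) + 1
    return counts


def brute_force_clique_counts(a):
    """Count node subsets whose every ordered pair is connected."""
    n = a.shape[0]
    counts = {}
    for k in range(2, n + 1):
        c = 0
        for sub in combinations(range(n), k):
            if all(a[i, j] and a[j, i] for i, j in combinations(sub, 2)):
                c += 1
        if c:
            counts[k] = c
    return counts
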