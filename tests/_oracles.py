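"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: the hypergeometric tail
is evaluated by enumerating draws, Benjamini-Hochberg by its step-up
definition, and hierarchical clustering by naive O(n^3) agglomeration, so
each serves as an external oracle for the corresponding fast path.
"""

from __future__ import annotations

import itertools

import numpy as np


def hypergeom_tail_by_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P(overlap >= k) by enumerating every size-n draw from an N-universe."""
    marked = set(range(K))
    total = 0
    hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def bh_stepup_by_definition(pvalues: np.ndarray) -> np.ndarray:
    """adj_i = min over j with p_(j) >= p_(i) of min(1, m * p_(j) / rank_j)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for i in range(m):
        adj[i] = min(
            min(1.0, m * p[order[j]] / (j + 1))
            for j in range(m)
            if p[order[j]] >= p[i]
        )
    return adj


def naive_cophenetic(D: np.ndarray, method: str) -> np.ndarray:
    """Cophenetic distances from a naive agglomerative clustering.

    Scans every active-cluster pair at each step (ties broken by the
    smallest lexicographic pair of cluster creation indices) and updates
    inter-cluster distances directly from the linkage definition:
    complete = max, single = min, average = size-weighted mean (UPGMA).
    """
    n = D.shape[0]
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    coph = np.zeros((n, n))
    next_id = n
    while len(members) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        del dist[(a, b)]
        for i in members[a]:
            for j in members[b]:
                coph[i, j] = coph[j, i] = h
        merged = members.pop(a) + members.pop(b)
        for c in list(members):
            da = dist.pop((min(a, c), max(a, c)))
            db = dist.pop((min(b, c), max(b, c)))
            if method == "complete":
                d = max(da, db)
            elif method == "single":
                d = min(da, db)
            elif method == "average":
                d = (da * sizes[a] + db * sizes[b]) / (sizes[a] + sizes[b])
            else:
                raise ValueError(method)
            dist[(min(next_id, c), max(next_id, c))] = d
        members[next_id] = merged
        sizes[next_id] = sizes.pop(a) + sizes.pop(b)
        next_id += 1
    return coph
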