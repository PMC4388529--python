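"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, O(n^2)/O(n^3) loops,
direct formulas) and shares no code with the implementation it checks.
"""

from itertools import combinations
from math import comb

import numpy as np


def hypergeom_upper_tail(N: int, m: int, draws: int, observed: int) -> float:
    """P(X >= observed) for X ~ Hypergeometric(N, m, draws), by enumeration."""
    total = comb(N, draws)
    acc = 0
    for k in range(observed, min(m, draws) + 1):
        if draws - k > N - m:
            continue
        acc += comb(m, k) * comb(N - m, draws - k)
    return acc / total


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted values by the step-up formula, input order."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def pairwise_overlap_keep(segments, masks, max_overlap=0.5):
    """Which segments survive masking, by O(n*m) pairwise interval arithmetic.

    ``segments`` and ``masks`` are (chrom, start, end) tuples.  Overlap with
    the mask union is computed per base to stay independent of any merging
    logic.
    """
    kept = []
    for chrom, s, e in segments:
        covered = np.zeros(e - s, dtype=bool)
        for mc, ms, me in masks:
            if mc != chrom:
                continue
            lo, hi = max(s, ms), min(e, me)
            if lo < hi:
                covered[lo - s : hi - s] = True
        if covered.sum() / (e - s) <= max_overlap:
            kept.append((chrom, s, e))
    return kept


def length2_candidates(edges, altered):
    """All linker candidates by brute-force all-pairs path enumeration.

    Returns {node: set of altered neighbours} for every non-altered node
    adjacent to >= 2 altered genes, scanning all node triples.
    """
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    out = {}
    for node in adj:
        if node in altered:
            continue
        for a, b in combinations(sorted(adj[node] & set(altered)), 2):
            out.setdefault(node, set()).update((a, b))
    return out


def newman_q(edges, assignment) -> float:
    """Newman modularity from an edge list and node->community map."""
    m = len(edges)
    if m == 0:
        return 0.0
    within = {}
    degsum = {}
    for u, v in edges:
        if assignment[u] == assignment[v]:
            within[assignment[u]] = within.get(assignment[u], 0) + 1
        degsum[assignment[u]] = degsum.get(assignment[u], 0) + 1
        degsum[assignment[v]] = degsum.get(assignment[v], 0) + 1
    q = 0.0
    for c in set(assignment.values()):
        q += within.get(c, 0) / m - (degsum.get(c, 0) / (2 * m)) ** 2
    return q


def logrank_statistic(time_a, event_a, time_b, event_b) -> float:
    """Two-group log-rank chi-square by the textbook O/E/V risk table."""
    times = sorted(
        set(t for t, e in zip(time_a, event_a) if e)
        | set(t for t, e in zip(time_b, event_b) if e)
    )
    O = E = V = 0.0
    for t in times:
        na = sum(1 for x in time_a if x >= t)
        nb = sum(1 for x in time_b if x >= t)
        n = na + nb
        da = sum(1 for x, e in zip(time_a, event_a) if x == t and e)
        db = sum(1 for x, e in zip(time_b, event_b) if x == t and e)
        d = da + db
        if n < 2:
            continue
        O += da
        E += d * na / n
        V += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def km_survivor(times, events):
    """Kaplan-Meier step values {event time: S(t)} by the product formula."""
    s = 1.0
    out = {}
    for t in sorted(set(times)):
        at_risk = sum(1 for x in times if x >= t)
        d = sum(1 for x, e in zip(times, events) if x == t and e)
        s *= 1.0 - d / at_risk
        out[t] = s
    return out
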