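"""Independent brute-force oracles used by the test suite.

Each function recomputes a statistic from first principles (enumeration,
explicit loops, closed forms) without touching the implementation under test
or the library call standing behind it.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np


def mi_from_pairs(bx, by) -> float:
    """Plug-in MI in nats from two discrete label vectors, by explicit sums."""
    n = len(bx)
    joint = Counter(zip(bx, by))
    px = Counter(bx)
    py = Counter(by)
    mi = 0.0
    for (i, j), c in joint.items():
        pij = c / n
        mi += pij * math.log(pij / ((px[i] / n) * (py[j] / n)))
    return mi


def hypergeom_table_prob(a: int, b: int, c: int, d: int) -> float:
    """Probability of a 2x2 table under fixed margins (hypergeometric)."""
    n = a + b + c + d
    return (
        math.comb(a + b, a) * math.comb(c + d, c) / math.comb(n, a + c)
    )


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration of tables with the
    observed margins, summing those no more probable than the observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    p_obs = hypergeom_table_prob(a, b, c, d)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = hypergeom_table_prob(x, r1 - x, c1 - x, r2 - (c1 - x))
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def binom_two_sided(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p by enumeration (minimum-likelihood method)."""
    probs = [math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    return min(sum(p for p in probs if p <= probs[k] * (1 + 1e-9)), 1.0)


def gsea_running_sum(metrics, hits, weight: float = 1.0):
    """Step-by-step weighted-KS running sum; returns (es, trace)."""
    n = len(metrics)
    n_hits = sum(hits)
    w_total = sum(abs(m) ** weight for m, h in zip(metrics, hits) if h)
    trace = []
    run = 0.0
    for m, h in zip(metrics, hits):
        if h:
            run += (abs(m) ** weight / w_total) if w_total > 0 else 1.0 / n_hits
        else:
            run -= 1.0 / (n - n_hits)
        trace.append(run)
    # signed maximum deviation, earliest extremum on exact ties
    best = max(abs(v) for v in trace)
    es = next(v for v in trace if abs(v) == best)
    return es, trace


def brute_force_overlap_count(query, reference) -> int:
    """O(n*m) pairwise half-open intersection count of query peaks hitting
    any reference peak."""
    count = 0
    for qc, qs, qe in query:
        for rc, rs, re in reference:
            if qc == rc and qs < re and rs < qe:
                count += 1
                break
    return count


def g_two_cell(o1: float, o2: float, e1_share: float) -> float:
    """Direct 2-cell G: observed (o1, o2) vs expected split (e1_share, 1-e1_share)."""
    t = o1 + o2
    e1, e2 = t * e1_share, t * (1 - e1_share)
    return 2.0 * (o1 * math.log(o1 / e1) + o2 * math.log(o2 / e2))


def ward_partition(points: np.ndarray, k: int) -> set[frozenset]:
    """Ward agglomeration from scratch: repeatedly merge the pair of clusters
    whose merge minimally increases total within-cluster SSE; cut at k."""
    clusters = [[i] for i in range(len(points))]

    def sse(idx):
        pts = points[idx]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    while len(clusters) > k:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            cost = sse(clusters[i] + clusters[j]) - sse(clusters[i]) - sse(clusters[j])
            if best is None or cost < best[0] - 1e-12:
                best = (cost, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return {frozenset(c) for c in clusters}
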