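"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by enumeration or direct formula
evaluation, sharing no code path with the package implementation.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def binom_minlik_exact(k1: int, k2: int, N1: int, N2: int) -> float:
    """Two-sided conditional binomial p by exact rational enumeration."""
    K = k1 + k2
    if K == 0:
        return 1.0
    probs = [
        Fraction(math.comb(K, i)) * Fraction(N1) ** i * Fraction(N2) ** (K - i)
        / Fraction(N1 + N2) ** K
        for i in range(K + 1)
    ]
    obs = probs[k1]
    return float(sum(p for p in probs if p <= obs))


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by summation."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def ranksum_exact_enum(x, y) -> float:
    """One-tailed rank-sum P(sum of x-ranks >= observed) by full enumeration.

    Assumes no ties across the pooled sample.
    """
    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    n, m = len(x), len(y)
    all_ranks = list(range(1, n + m + 1))
    count = total = 0
    for combo in itertools.combinations(all_ranks, n):
        total += 1
        if sum(combo) >= obs:
            count += 1
    return count / total


def complete_linkage_heights_naive(X: np.ndarray) -> list[float]:
    """Merge heights of complete-linkage agglomeration, recomputed naively.

    Clusters are merged greedily by the smallest maximum pairwise
    Euclidean distance between their members.
    """
    clusters = [[i] for i in range(X.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(
                float(np.linalg.norm(X[i] - X[j]))
                for i in clusters[a]
                for j in clusters[b]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


_RC = str.maketrans("ACGT", "TGCA")


def scan_naive(pwm, seq: str, threshold: float):
    """Exhaustive offset x strand PWM scan using scalar window scoring."""
    from rxnet.motif import matrix_similarity

    w = pwm.width
    hits = []
    for off in range(len(seq) - w + 1):
        s = matrix_similarity(pwm, seq[off : off + w])
        if s >= threshold:
            hits.append((off, "+", round(s, 10)))
    rc = seq.translate(_RC)[::-1]
    for off in range(len(rc) - w + 1):
        s = matrix_similarity(pwm, rc[off : off + w])
        if s >= threshold:
            hits.append((len(seq) - w - off, "-", round(s, 10)))
    return sorted(hits)


def pearson_hand(x, y) -> float:
    """Pearson r by direct formula evaluation."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den
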