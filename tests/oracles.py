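"""Independent, deliberately naive reference implementations used as
oracles in the tests. Each is coded from the textbook definition, not from
the package's code paths, so agreement is evidence rather than tautology."""

from __future__ import annotations

import itertools
import math


def average_ranks(values) -> list[float]:
    """Average (midrank) ranks, computed by sorting and sharing ties."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2.0 + 1.0  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def spearman_oracle(x, y) -> float:
    """Rank-then-Pearson Spearman with average ranks for ties."""
    return pearson(average_ranks(x), average_ranks(y))


def pooled_t_oracle(a, b) -> tuple[float, float]:
    """Classical two-sample pooled-variance t-test; returns (t, two-sided p)."""
    from scipy.stats import t as tdist

    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    v1 = sum((v - m1) ** 2 for v in a) / (n1 - 1)
    v2 = sum((v - m2) ** 2 for v in b) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = (m2 - m1) / se
    p = 2.0 * tdist.sf(abs(t), df=n1 + n2 - 2)
    return t, p


def running_es_scan(weights, member, p_exponent=1.0) -> tuple[float, int]:
    """Position-by-position brute-force enrichment score.

    Walks every prefix, summing |w|^P over members (normalized by the total
    member mass) minus the count of non-members (normalized by their total
    count); returns the maximum deviation and its first position.
    """
    n = len(weights)
    n_h = sum(member)
    n_r = sum(abs(weights[j]) ** p_exponent for j in range(n) if member[j])
    best = -math.inf
    best_pos = -1
    for i in range(n):
        hit = sum(abs(weights[j]) ** p_exponent for j in range(i + 1) if member[j]) / n_r
        miss = sum(1 for j in range(i + 1) if not member[j]) / (n - n_h)
        dev = hit - miss
        if dev > best:
            best = dev
            best_pos = i
    return best, best_pos


def hypergeom_tail_enumeration(n_universe, set_size, list_size, k) -> float:
    """P(overlap >= k) by exhaustively enumerating every possible drawn
    list of ``list_size`` elements from a universe whose first ``set_size``
    elements are the gene set."""
    in_set = set(range(set_size))
    total = 0
    hits = 0
    for draw in itertools.combinations(range(n_universe), list_size):
        total += 1
        if len(in_set.intersection(draw)) >= k:
            hits += 1
    return hits / total
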