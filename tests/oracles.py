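"""Independent brute-force oracles used to validate the fast paths.

Everything here works per base over explicit membership sets — slow and
obviously correct, and deliberately independent of the package's sweep
and prefix-sum implementations.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Iterable

Interval = tuple[str, int, int]


def base_set(intervals: Iterable[Interval]) -> set[tuple[str, int]]:
    return {
        (chrom, pos)
        for chrom, start, end in intervals
        for pos in range(start, end)
    }


def runs_from_bases(bases: set[tuple[str, int]]) -> list[Interval]:
    """Maximal sorted runs of consecutive covered bases."""
    out: list[Interval] = []
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in bases:
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        start = prev = positions[0]
        for p in positions[1:]:
            if p != prev + 1:
                out.append((chrom, start, prev + 1))
                start = p
            prev = p
        out.append((chrom, start, prev + 1))
    return out


def intersect_per_base(a: list[Interval], b: list[Interval]) -> list[Interval]:
    return runs_from_bases(base_set(a) & base_set(b))


def union_per_base(a: list[Interval], b: list[Interval]) -> list[Interval]:
    return runs_from_bases(base_set(a) | base_set(b))


def subtract_whole_peak(a: list[Interval], b: list[Interval]) -> list[Interval]:
    bb = base_set(b)
    return [iv for iv in a if not (base_set([iv]) & bb)]


def covered_bp(window: Interval, peaks: list[Interval]) -> int:
    chrom, start, end = window
    covered = base_set(peaks)
    return sum(1 for pos in range(start, end) if (chrom, pos) in covered)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by exact enumeration over all feasible overlap counts."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(n, K) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return float(acc)


def bh_step_up(p_values: list[float]) -> list[float]:
    """Textbook BH step-up: q(i) = min_{j>=i} m p(j)/j on sorted p."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q_sorted = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p_values[i] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return out


def pearson(x: list[float], y: list[float]) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
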