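"""Gene-set overrepresentation: hypergeometric test with BH FDR.

Given a query gene panel (e.g. the top-100 genes by tissue-specific peak
occupancy), each annotated term is tested for overrepresentation with a
one-sided hypergeometric test against a stated gene universe, and
p-values are adjusted across terms by Benjamini-Hochberg step-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import warn

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "hypergeom_pvalue",
    "bh_fdr",
    "enrich",
    "top_terms",
]


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset[str]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    overlap_count: int  # k
    query_size: int  # n
    set_size: int  # K
    universe_size: int  # N
    p_value: float
    fdr: float
    overlap_genes: tuple[str, ...] = ()


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"impossible overlap k={k} for N={N}, K={K}, n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q(i) = min over j >= i of m * p(j) / j on the ascending-sorted
    p-values, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: Iterable[str],
    sets: Sequence[GeneSet],
    universe: Iterable[str],
    min_set_size: int = 2,
    max_set_frac: float = 0.5,
) -> list[EnrichmentResult]:
    """Test every gene set for overrepresentation in the query panel.

    Query genes outside the universe are dropped with a warning; terms
    smaller than ``min_set_size`` or larger than ``max_set_frac`` of the
    universe (after restriction to the universe) are excluded as
    uninformative. Results are sorted ascending by (p, term_id) and carry
    BH-adjusted FDR values computed across all tested terms.
    """
    universe_set = frozenset(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_set = frozenset(query)
    outside = query_set - universe_set
    if outside:
        warn(
            f"{len(outside)} query genes outside the universe were dropped"
        )
    query_set &= universe_set
    if not query_set:
        raise ValueError("query is empty after restriction to the universe")

    N, n = len(universe_set), len(query_set)
    tested = []
    for gs in sets:
        members = gs.members & universe_set
        K = len(members)
        if K < min_set_size or K > max_set_frac * N:
            continue
        overlap = members & query_set
        tested.append((gs, K, overlap))
    if not tested:
        return []
    p_values = [
        hypergeom_pvalue(len(ov), N, K, n) for _, K, ov in tested
    ]
    fdrs = bh_fdr(p_values)
    results = [
        EnrichmentResult(
            term_id=gs.term_id,
            term_name=gs.term_name,
            overlap_count=len(ov),
            query_size=n,
            set_size=K,
            universe_size=N,
            p_value=p,
            fdr=q,
            overlap_genes=tuple(sorted(ov)),
        )
        for (gs, K, ov), p, q in zip(tested, p_values, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def top_terms(
    results: Sequence[EnrichmentResult], n: int = 10
) -> list[EnrichmentResult]:
    """First n results by ascending p (term_id breaks ties)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(results, key=lambda r: (r.p_value, r.term_id))
    return ordered[:n]
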