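"""TSS windows, peak-occupancy rates, top-N ranking, genic classification.

The TSS window is the +/-flank neighbourhood of a gene's transcription
start site (default 3000 bp each side); the occupancy rate of a gene is
the fraction of its window covered by the union of a peak set — the
statistic used to rank genes for gene-ontology analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import GeneModel, GenomicInterval, PeakSet, warn
from .peaks import overlap_bp

__all__ = [
    "TSSWindow",
    "OccupancyRecord",
    "make_tss_windows",
    "occupancy_rates",
    "top_n_by_occupancy",
    "classify_genic_context",
    "GENIC_CATEGORIES",
]

logger = logging.getLogger(__name__)

GENIC_CATEGORIES = ("promoter", "exonic", "intronic", "downstream", "intergenic")


@dataclass(frozen=True)
class TSSWindow:
    """[tss - flank, tss + flank) clipped to chromosome bounds."""

    gene_id: str
    symbol: str
    interval: GenomicInterval
    flank: int
    tss: int

    @property
    def width(self) -> int:
        return self.interval.width


@dataclass(frozen=True)
class OccupancyRecord:
    gene_id: str
    symbol: str
    covered_bp: int
    width: int

    @property
    def occupancy_rate(self) -> float:
        return self.covered_bp / self.width


def make_tss_windows(
    genes: Sequence[GeneModel],
    flank: int = 3000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[TSSWindow]:
    """One symmetric +/-flank window per gene, clipped to the chromosome.

    Strand determines where the TSS sits, not the window symmetry.
    Genes on chromosomes absent from ``chrom_sizes`` (when given) are
    skipped with a warning.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    windows = []
    for g in genes:
        if chrom_sizes is not None and g.chrom not in chrom_sizes:
            warn(f"gene {g.gene_id}: unknown chromosome {g.chrom}, skipped")
            continue
        start = max(0, g.tss - flank)
        end = g.tss + flank
        if chrom_sizes is not None:
            end = min(end, chrom_sizes[g.chrom])
        windows.append(
            TSSWindow(
                gene_id=g.gene_id,
                symbol=g.symbol,
                interval=GenomicInterval(g.chrom, start, end, g.strand),
                flank=flank,
                tss=g.tss,
            )
        )
    return windows


def occupancy_rates(
    windows: Sequence[TSSWindow], peaks: PeakSet
) -> list[OccupancyRecord]:
    """Per-window coverage by the union of peaks (each base counted once)."""
    return [
        OccupancyRecord(
            gene_id=w.gene_id,
            symbol=w.symbol,
            covered_bp=overlap_bp(w.interval, peaks),
            width=w.width,
        )
        for w in windows
    ]


def top_n_by_occupancy(
    records: Sequence[OccupancyRecord], n: int = 100
) -> list[OccupancyRecord]:
    """Top-n records by occupancy rate, zero-occupancy genes excluded.

    Ties are broken by gene symbol (ascending) for determinism; ties
    straddling the cutoff are reported in the log.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    nonzero = [r for r in records if r.covered_bp > 0]
    ranked = sorted(nonzero, key=lambda r: (-r.occupancy_rate, r.symbol))
    if len(ranked) > n and ranked[n].occupancy_rate == ranked[n - 1].occupancy_rate:
        tied = ranked[n - 1].occupancy_rate
        logger.info(
            "top_n cutoff at rate %.4g splits a tie; excluded tied genes: %s",
            tied,
            [r.gene_id for r in ranked[n:] if r.occupancy_rate == tied],
        )
    return ranked[:n]


def _in_exon(pos: int, gene: GeneModel) -> bool:
    if not gene.exons:
        return True  # no block structure: whole body treated as exonic
    return any(s <= pos < e for s, e in gene.exons)


def classify_genic_context(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    promoter_bp: int = 3000,
    promoter_two_sided: bool = True,
) -> tuple[list[str], dict[str, float]]:
    """Assign each peak a genic category by its midpoint.

    Precedence: promoter > exonic/intronic > downstream > intergenic,
    evaluated over all genes. The promoter is +/-promoter_bp around the
    TSS by default, or upstream-only with ``promoter_two_sided=False``;
    downstream is within promoter_bp past the gene's 3' end. Returns
    per-peak categories plus category fractions (which sum to 1).
    """
    if promoter_bp <= 0:
        raise ValueError("promoter_bp must be positive")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    def classify(chrom: str, mid: int) -> str:
        best = "intergenic"
        rank = {c: i for i, c in enumerate(GENIC_CATEGORIES)}
        for g in by_chrom.get(chrom, []):
            if g.strand == "+":
                prom_lo, prom_hi = g.tss - promoter_bp, g.tss + promoter_bp
                if not promoter_two_sided:
                    prom_hi = g.tss
                down_lo, down_hi = g.interval.end, g.interval.end + promoter_bp
            else:
                prom_lo, prom_hi = g.tss - promoter_bp, g.tss + promoter_bp
                if not promoter_two_sided:
                    prom_lo = g.tss + 1
                down_lo, down_hi = g.interval.start - promoter_bp, g.interval.start
            if prom_lo <= mid <= prom_hi:
                cat = "promoter"
            elif g.interval.start <= mid < g.interval.end:
                cat = "exonic" if _in_exon(mid, g) else "intronic"
            elif down_lo <= mid < down_hi:
                cat = "downstream"
            else:
                continue
            if rank[cat] < rank[best]:
                best = cat
        return best

    categories = [classify(p.chrom, p.interval.midpoint) for p in peaks]
    n = len(categories)
    fractions = {
        c: (categories.count(c) / n if n else 0.0) for c in GENIC_CATEGORIES
    }
    return categories, fractions
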