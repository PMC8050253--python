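"""Interval-set algebra over peak sets.

Implements the "sieve" strategy for comparing ChIP peak landscapes
between tissues: replicate consensus, common peaks by per-base
intersection (a peak overlapping k disjoint peaks of the other set is
split into k segments), and tissue-specific peaks by whole-peak
subtraction (bedtools ``-v`` semantics: any shared base disqualifies).
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from .core import GenomicInterval, Peak, PeakSet

__all__ = [
    "merge_union",
    "intersect_common",
    "subtract_specific",
    "consensus_peaks",
    "overlap_bp",
]

ConsensusMode = Literal["intersect_segment", "a_overlapping", "union_component"]


def _require_canonical(ps: PeakSet, auto_merge: bool = False) -> PeakSet:
    if ps.is_canonical:
        return ps
    if auto_merge:
        return merge_union(ps, PeakSet([], label=ps.label))
    raise ValueError(
        f"peak set {ps.label!r} is not canonical "
        "(unsorted or internally overlapping); pass auto_merge=True to coalesce"
    )


def _coalesce(
    starts: np.ndarray, ends: np.ndarray, min_gap: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Coalesce sorted intervals closer than ``min_gap`` apart.

    ``min_gap=0`` merges overlapping and bookended intervals; ``-1``
    merges strictly overlapping ones only.
    """
    order = np.lexsort((ends, starts))
    starts, ends = starts[order], ends[order]
    out_s, out_e = [], []
    for s, e in zip(starts, ends):
        if out_e and s <= out_e[-1] + min_gap:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def merge_union(a: PeakSet, b: PeakSet, coalesce_bookended: bool = True) -> PeakSet:
    """Union of two peak sets with overlapping intervals coalesced.

    By default intervals that merely touch ([0,10) and [10,20)) are also
    coalesced, matching ``bedtools merge``'s default distance of 0.
    """
    min_gap = 0 if coalesce_bookended else -1
    chroms = sorted(set(a.chroms()) | set(b.chroms()))
    a_by, b_by = a.by_chrom(), b.by_chrom()
    empty = (np.empty(0, dtype=np.int64),) * 2
    peaks = []
    for chrom in chroms:
        sa, ea = a_by.get(chrom, empty)
        sb, eb = b_by.get(chrom, empty)
        s, e = _coalesce(
            np.concatenate([sa, sb]), np.concatenate([ea, eb]), min_gap
        )
        peaks.extend(
            Peak(GenomicInterval(chrom, int(x), int(y)))
            for x, y in zip(s, e)
        )
    label = f"{a.label}|{b.label}" if a.label or b.label else ""
    return PeakSet(peaks, label=label)


def _intersect_arrays(
    sa: np.ndarray, ea: np.ndarray, sb: np.ndarray, eb: np.ndarray
) -> list[tuple[int, int]]:
    """Maximal per-base intersection segments of two canonical interval lists."""
    segments = []
    i = j = 0
    while i < len(sa) and j < len(sb):
        lo = max(sa[i], sb[j])
        hi = min(ea[i], eb[j])
        if lo < hi:
            segments.append((int(lo), int(hi)))
        if ea[i] <= eb[j]:
            i += 1
        else:
            j += 1
    return segments


def intersect_common(a: PeakSet, b: PeakSet, auto_merge: bool = False) -> PeakSet:
    """Common peaks: all maximal per-base intersection segments of A and B.

    A single A peak spanning k disjoint B peaks yields k output segments,
    which is why common + specific peak counts need not add up to the
    original count.
    """
    a = _require_canonical(a, auto_merge)
    b = _require_canonical(b, auto_merge)
    a_by, b_by = a.by_chrom(), b.by_chrom()
    peaks = []
    for chrom in sorted(set(a_by) & set(b_by)):
        sa, ea = a_by[chrom]
        sb, eb = b_by[chrom]
        peaks.extend(
            Peak(GenomicInterval(chrom, s, e))
            for s, e in _intersect_arrays(sa, ea, sb, eb)
        )
    return PeakSet(peaks, label=f"{a.label}&{b.label}")


def overlap_bp(window: GenomicInterval, peaks: PeakSet) -> int:
    """Bases of ``window`` covered by the union of ``peaks`` (each base once)."""
    by = peaks.by_chrom()
    if window.chrom not in by:
        return 0
    s, e = by[window.chrom]
    s, e = _coalesce(s.copy(), e.copy(), min_gap=-1)
    lo = np.maximum(s, window.start)
    hi = np.minimum(e, window.end)
    return int(np.clip(hi - lo, 0, None).sum())


def _has_overlap(
    s: int, e: int, sb: np.ndarray, eb: np.ndarray, min_overlap: int
) -> bool:
    """Whether [s,e) shares >= min_overlap bases with any canonical interval."""
    j = int(np.searchsorted(eb, s, side="right"))
    while j < len(sb) and sb[j] < e:
        if min(e, eb[j]) - max(s, sb[j]) >= min_overlap:
            return True
        j += 1
    return False


def subtract_specific(
    a: PeakSet,
    b: PeakSet,
    min_overlap_bp: int = 1,
    min_overlap_frac: float | None = None,
    auto_merge: bool = False,
) -> PeakSet:
    """A-specific peaks: every A peak with no disqualifying overlap in B.

    Whole-peak semantics (``bedtools intersect -v``): a qualifying
    overlap removes the entire A peak; surviving peaks are returned
    unmodified. By default a single shared base (``min_overlap_bp=1``)
    disqualifies; ``min_overlap_frac`` instead requires that fraction of
    the A peak's width to be covered by one B peak.
    """
    a = _require_canonical(a, auto_merge)
    b = _require_canonical(b, auto_merge)
    b_by = b.by_chrom()
    out = []
    for p in a:
        if p.chrom not in b_by:
            out.append(p)
            continue
        sb, eb = b_by[p.chrom]
        threshold = (
            max(1, int(np.ceil(min_overlap_frac * (p.end - p.start))))
            if min_overlap_frac is not None
            else min_overlap_bp
        )
        if not _has_overlap(p.start, p.end, sb, eb, threshold):
            out.append(p)
    return PeakSet(out, label=f"{a.label}-{b.label}")


def consensus_peaks(
    rep_a: PeakSet,
    rep_b: PeakSet,
    mode: ConsensusMode = "intersect_segment",
    auto_merge: bool = False,
) -> PeakSet:
    """Replicate-consensus peaks under one of three overlap conventions.

    ``intersect_segment`` (default): per-base intersection segments.
    ``a_overlapping``: peaks of ``rep_a`` having >=1 bp overlap in ``rep_b``.
    ``union_component``: union of each connected overlapping component
    that contains members of both replicates.
    """
    rep_a = _require_canonical(rep_a, auto_merge)
    rep_b = _require_canonical(rep_b, auto_merge)
    label = f"{rep_a.label}*{rep_b.label}"
    if mode == "intersect_segment":
        ps = intersect_common(rep_a, rep_b)
    elif mode == "a_overlapping":
        b_by = rep_b.by_chrom()
        kept = []
        for p in rep_a:
            if p.chrom in b_by and _has_overlap(
                p.start, p.end, *b_by[p.chrom], 1
            ):
                kept.append(p)
        ps = PeakSet(kept, label=label)
    elif mode == "union_component":
        a_by, b_by = rep_a.by_chrom(), rep_b.by_chrom()
        empty = (np.empty(0, dtype=np.int64),) * 2
        peaks = []
        for chrom in sorted(set(a_by) | set(b_by)):
            sa, ea = a_by.get(chrom, empty)
            sb, eb = b_by.get(chrom, empty)
            # components of strictly-overlapping peaks from A union B
            cs, ce = _coalesce(
                np.concatenate([sa, sb]), np.concatenate([ea, eb]), min_gap=-1
            )
            for s, e in zip(cs, ce):
                in_a = _has_overlap(int(s), int(e), sa, ea, 1)
                in_b = _has_overlap(int(s), int(e), sb, eb, 1)
                if in_a and in_b:
                    peaks.append(Peak(GenomicInterval(chrom, int(s), int(e))))
        ps = PeakSet(peaks, label=label)
    else:
        raise ValueError(f"unknown consensus mode {mode!r}")
    ps.label = label
    return ps
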