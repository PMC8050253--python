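"""Core domain types: genomic intervals, peaks, gene models and signal tracks.

All coordinates are 0-based half-open (BED convention) throughout the
package; 1-based formats (GTF/GFF3) are converted at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "PeakSet",
    "SignalTrack",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a chromosome.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called ChIP enrichment interval, optionally scored."""

    interval: GenomicInterval
    score: float | None = None
    sample_id: str | None = None
    name: str | None = None

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class GeneModel:
    """A gene with a mandatory strand and a strand-aware TSS.

    The TSS is ``interval.start`` on '+' and ``interval.end - 1`` on '-'
    (the 5'-most base of the transcript in genome coordinates). ``exons``
    optionally carries half-open exon blocks for genic classification.
    """

    gene_id: str
    symbol: str
    interval: GenomicInterval
    exons: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-'"
            )

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def _is_canonical(peaks: Sequence[Peak]) -> bool:
    for a, b in zip(peaks, peaks[1:]):
        if a.sort_key() > b.sort_key():
            return False
        if a.chrom == b.chrom and b.start < a.end:
            return False
    return True


class PeakSet:
    """An ordered collection of peaks from one sample or tissue.

    A *canonical* set is sorted by (chrom, start, end) and has no
    within-set overlaps — the form MACS-style callers emit and that
    interval algebra requires.
    """

    def __init__(self, peaks: Iterable[Peak], label: str = ""):
        self.peaks: list[Peak] = sorted(peaks, key=Peak.sort_key)
        self.label = label

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return [
            (p.chrom, p.start, p.end) for p in self.peaks
        ] == [(p.chrom, p.start, p.end) for p in other.peaks]

    def __repr__(self) -> str:
        return f"PeakSet({self.label!r}, n={len(self.peaks)})"

    @property
    def is_canonical(self) -> bool:
        return _is_canonical(self.peaks)

    def chroms(self) -> list[str]:
        return sorted({p.chrom for p in self.peaks})

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, sorted."""
        out: dict[str, tuple[list[int], list[int]]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, ([], []))
            out[p.chrom][0].append(p.start)
            out[p.chrom][1].append(p.end)
        return {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in out.items()
        }

    def total_bp(self) -> int:
        return sum(p.end - p.start for p in self.peaks)


class SignalTrack:
    """Piecewise-constant per-base coverage, stored as sorted runs.

    Runs are non-overlapping, non-negative; gaps mean zero signal.
    ``library_size`` (total signal mass by default) supports per-million
    normalization for cross-sample comparability.
    """

    def __init__(
        self,
        runs: Mapping[str, Sequence[tuple[int, int, float]]],
        library_size: float | None = None,
    ):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}
        mass = 0.0
        for chrom, chrom_runs in runs.items():
            if len(chrom_runs) == 0:
                continue
            arr = sorted(chrom_runs)
            s = np.array([r[0] for r in arr], dtype=np.int64)
            e = np.array([r[1] for r in arr], dtype=np.int64)
            v = np.array([r[2] for r in arr], dtype=float)
            if np.any(v < 0):
                raise ValueError(f"negative signal value on {chrom}")
            if np.any(e <= s):
                raise ValueError(f"empty or inverted run on {chrom}")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping runs on {chrom}")
            self._starts[chrom] = s
            self._ends[chrom] = e
            self._values[chrom] = v
            lengths = (e - s).astype(float)
            # prefix mass up to the start of each run, with a trailing total
            self._cum[chrom] = np.concatenate(
                [[0.0], np.cumsum(v * lengths)]
            )
            mass += float(self._cum[chrom][-1])
        self.total_mass = mass
        self.library_size = library_size if library_size is not None else mass

    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def _mass_before(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integrated signal over [0, pos) for an array of positions."""
        s, e, v, cum = (
            self._starts[chrom],
            self._ends[chrom],
            self._values[chrom],
            self._cum[chrom],
        )
        idx = np.searchsorted(s, pos, side="right") - 1
        out = np.where(idx >= 0, cum[np.maximum(idx, 0)], 0.0)
        inside = idx >= 0
        ii = np.maximum(idx, 0)
        partial = v[ii] * np.clip(np.minimum(pos, e[ii]) - s[ii], 0, None)
        return out + np.where(inside, partial, 0.0)

    def integral(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorized integral of the track over half-open windows."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self._starts:
            return np.zeros(starts.shape, dtype=float)
        return self._mass_before(chrom, ends) - self._mass_before(
            chrom, starts
        )

    def integral_one(self, chrom: str, start: int, end: int) -> float:
        return float(
            self.integral(chrom, np.array([start]), np.array([end]))[0]
        )

    def value_at(self, chrom: str, pos: int) -> float:
        """Point value of the piecewise-constant track (0 in gaps)."""
        if chrom not in self._starts:
            return 0.0
        s, e, v = self._starts[chrom], self._ends[chrom], self._values[chrom]
        idx = int(np.searchsorted(s, pos, side="right")) - 1
        if idx >= 0 and pos < e[idx]:
            return float(v[idx])
        return 0.0

    def runs(self, chrom: str) -> list[tuple[int, int, float]]:
        if chrom not in self._starts:
            return []
        return [
            (int(s), int(e), float(v))
            for s, e, v in zip(
                self._starts[chrom], self._ends[chrom], self._values[chrom]
            )
        ]


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
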