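"""Metagene signal profiles and per-gene peak areas.

Binned, library-normalized (per-million) signal matrices anchored at
TSSs or stretched over gene bodies; expression-tertile grouping; and the
integrated TSS-window "peak area" that feeds the multivariate analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import TSSWindow
from .core import GeneModel, SignalTrack, warn

__all__ = [
    "ProfileMatrix",
    "profile_matrix",
    "gene_body_profile_matrix",
    "average_profile",
    "expression_tertiles",
    "peak_area_matrix",
]


@dataclass
class ProfileMatrix:
    """Anchor x bin matrix of per-base signal, oriented 5'->3'.

    Values are mean signal per base in each bin, scaled to per-million
    of library mass. Minus-strand rows are flipped so bin 0 is always
    the 5'-most bin of the gene.
    """

    anchors: list[str]
    bins: int
    flank: int
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.anchors, name="gene_id"),
            columns=[f"bin{i}" for i in range(self.values.shape[1])],
        )


def _binned_means(
    track: SignalTrack,
    chrom: str,
    edges: np.ndarray,
    chrom_size: int | None,
) -> np.ndarray:
    """Mean per-base signal between consecutive edges, clipped to bounds."""
    lo = np.clip(edges, 0, chrom_size)
    masses = track.integral(chrom, lo[:-1], lo[1:])
    widths = (lo[1:] - lo[:-1]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(widths > 0, masses / np.maximum(widths, 1), 0.0)
    return means


def profile_matrix(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    flank: int = 3000,
    bins: int = 100,
    chrom_sizes: Mapping[str, int] | None = None,
) -> ProfileMatrix:
    """Per-gene binned signal across [tss - flank, tss + flank).

    Each row holds the mean per-base signal in ``bins`` equal-width bins,
    per-million normalized and strand-oriented. Bins clipped by a
    chromosome edge average over the existing bases only; genes fully
    off-chromosome are dropped with a warning.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if flank <= 0:
        raise ValueError("flank must be positive")
    scale = 1.0e6 / track.library_size if track.library_size > 0 else 0.0
    offsets = np.round(np.linspace(-flank, flank, bins + 1)).astype(np.int64)
    anchors, rows = [], []
    for g in genes:
        size = chrom_sizes.get(g.chrom) if chrom_sizes else None
        edges = g.tss + offsets
        if edges[-1] <= 0 or (size is not None and edges[0] >= size):
            warn(f"gene {g.gene_id}: window fully off-chromosome, dropped")
            continue
        means = _binned_means(track, g.chrom, edges, size)
        if g.strand == "-":
            means = means[::-1]
        anchors.append(g.gene_id)
        rows.append(means * scale)
    values = (
        np.vstack(rows) if rows else np.empty((0, bins), dtype=float)
    )
    return ProfileMatrix(anchors=anchors, bins=bins, flank=flank, values=values)


def gene_body_profile_matrix(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    flank: int = 3000,
    flank_bins: int = 30,
    body_bins: int = 40,
    chrom_sizes: Mapping[str, int] | None = None,
) -> ProfileMatrix:
    """Three-segment metagene rows: upstream flank, length-normalized
    gene body resampled to ``body_bins``, downstream flank.

    Used for expression-tertile comparisons over whole transcripts.
    """
    if flank <= 0 or flank_bins < 1 or body_bins < 2:
        raise ValueError("invalid flank/bin configuration")
    scale = 1.0e6 / track.library_size if track.library_size > 0 else 0.0
    anchors, rows = [], []
    for g in genes:
        size = chrom_sizes.get(g.chrom) if chrom_sizes else None
        gs, ge = g.interval.start, g.interval.end
        up = np.round(np.linspace(gs - flank, gs, flank_bins + 1)).astype(np.int64)
        body = np.round(np.linspace(gs, ge, body_bins + 1)).astype(np.int64)
        down = np.round(np.linspace(ge, ge + flank, flank_bins + 1)).astype(np.int64)
        means = np.concatenate(
            [
                _binned_means(track, g.chrom, up, size),
                _binned_means(track, g.chrom, body, size),
                _binned_means(track, g.chrom, down, size),
            ]
        )
        if g.strand == "-":
            means = means[::-1]
        anchors.append(g.gene_id)
        rows.append(means * scale)
    nbins = 2 * flank_bins + body_bins
    values = np.vstack(rows) if rows else np.empty((0, nbins), dtype=float)
    return ProfileMatrix(anchors=anchors, bins=nbins, flank=flank, values=values)


def average_profile(
    matrix: ProfileMatrix,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Column means of the profile matrix, globally or per gene group.

    ``groups`` maps a group label to gene_ids (a partition of a subset
    of the anchors). Without groups, a single row 'all' is returned.
    """
    frame = matrix.to_frame()
    if groups is None:
        return frame.mean(axis=0).to_frame("all").T
    out = {}
    for name, members in groups.items():
        present = [g for g in members if g in frame.index]
        if not present:
            raise ValueError(f"group {name!r} has no genes in the matrix")
        out[name] = frame.loc[present].mean(axis=0)
    return pd.DataFrame(out).T


def expression_tertiles(expr: pd.Series) -> dict[str, list[str]]:
    """Split genes into equal high/medium/low expression groups.

    Genes are ranked by RPKM descending (ties broken by gene_id for
    determinism) and divided into three groups whose sizes differ by at
    most one, largest first.
    """
    m = len(expr)
    if m < 3:
        raise ValueError("need at least 3 genes for tertiles")
    order = sorted(expr.index, key=lambda g: (-expr[g], g))
    if expr.nunique() == 1:
        warn("all RPKM values equal; tertile split is by gene_id only")
    n_high = -(-m // 3)  # ceil(m/3)
    n_mid = -(-(m - n_high) // 2)
    return {
        "high": order[:n_high],
        "medium": order[n_high : n_high + n_mid],
        "low": order[n_high + n_mid :],
    }


def peak_area_matrix(
    tracks: Mapping[str, SignalTrack],
    windows: Sequence[TSSWindow],
) -> pd.DataFrame:
    """Integrated per-million signal over each TSS window, per sample.

    Returns a genes x samples DataFrame of areas (signal . bp). A window
    on a chromosome missing from a track scores 0 with a warning.
    """
    if not windows:
        raise ValueError("no windows supplied")
    data = {}
    for sample, track in tracks.items():
        scale = 1.0e6 / track.library_size if track.library_size > 0 else 0.0
        known = set(track.chroms())
        col = []
        for w in windows:
            if w.interval.chrom not in known:
                warn(
                    f"sample {sample}: no signal on {w.interval.chrom}; "
                    f"area 0 for {w.gene_id}"
                )
                col.append(0.0)
                continue
            col.append(
                track.integral_one(
                    w.interval.chrom, w.interval.start, w.interval.end
                )
                * scale
            )
        data[sample] = col
    return pd.DataFrame(
        data, index=pd.Index([w.gene_id for w in windows], name="gene_id")
    )
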