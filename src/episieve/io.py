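"""Readers and writers for the standard formats the pipeline touches.

BED3+/BED5 for peaks, GTF/GFF3/BED12 for gene models, bedGraph for
coverage, GMT for gene sets, TSV for expression tables. Everything is
normalized to 0-based half-open coordinates on the way in.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, Peak, SignalTrack, warn

__all__ = [
    "ParseError",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "read_signal_bedgraph",
    "write_bedgraph",
    "compute_rpkm",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
]


class ParseError(ValueError):
    """Malformed record in an input file; message names file and line."""


def _apply_alias(chrom: str, alias: Mapping[str, str] | None) -> str:
    if alias is None:
        return chrom
    return alias.get(chrom, chrom)


def read_bed(
    path: str | os.PathLike,
    label: str = "",
    chrom_alias: Mapping[str, str] | None = None,
) -> list[Peak]:
    """Read a BED3+ file into a sorted list of peaks.

    Track/browser/comment/header lines are skipped. Column 4 is taken as
    the peak name, column 5 as the score (absent columns stay ``None``).
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            chrom = _apply_alias(fields[0], chrom_alias)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if end <= start or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric score"
                    ) from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            peaks.append(
                Peak(
                    GenomicInterval(chrom, start, end, strand),
                    score=score,
                    sample_id=label or None,
                    name=name,
                )
            )
    peaks.sort(key=Peak.sort_key)
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in sorted(peaks, key=Peak.sort_key):
            fields = [p.chrom, str(p.start), str(p.end)]
            if p.name is not None or p.score is not None:
                fields.append(p.name if p.name is not None else ".")
            if p.score is not None:
                fields.append(f"{p.score:g}")
            fh.write("\t".join(fields) + "\n")


def _gene_models_from_gff(
    path: str | os.PathLike,
    chrom_alias: Mapping[str, str] | None,
) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        symbol = feat.attributes.get(
            "gene_name", feat.attributes.get("Name", [gene_id])
        )[0]
        if feat.strand not in ("+", "-"):
            warn(f"gene {gene_id}: missing strand, record rejected")
            continue
        if gene_id in seen:
            raise ParseError(f"{path}: duplicate gene_id {gene_id}")
        seen.add(gene_id)
        chrom = _apply_alias(feat.seqid, chrom_alias)
        exons = tuple(
            sorted(
                (ex.start - 1, ex.end)
                for ex in db.children(feat, featuretype="exon")
            )
        )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                symbol=symbol,
                # GTF/GFF3 are 1-based inclusive; convert here
                interval=GenomicInterval(
                    chrom, feat.start - 1, feat.end, feat.strand
                ),
                exons=exons,
            )
        )
    return genes


def _gene_models_from_bed12(
    path: str | os.PathLike,
    chrom_alias: Mapping[str, str] | None,
) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(
                    f"{path}:{lineno}: BED12 needs >=6 columns (strand)"
                )
            chrom = _apply_alias(f[0], chrom_alias)
            start, end = int(f[1]), int(f[2])
            gene_id = f[3]
            strand = f[5]
            if strand not in ("+", "-"):
                warn(f"{path}:{lineno}: missing strand, record rejected")
                continue
            if gene_id in seen:
                raise ParseError(f"{path}: duplicate gene_id {gene_id}")
            seen.add(gene_id)
            exons: tuple[tuple[int, int], ...] = ()
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = tuple(
                    (start + o, start + o + s)
                    for o, s in zip(offsets, sizes)
                )
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    symbol=gene_id,
                    interval=GenomicInterval(chrom, start, end, strand),
                    exons=exons,
                )
            )
    return genes


def read_gene_models(
    path: str | os.PathLike,
    dialect: str = "gtf",
    chrom_alias: Mapping[str, str] | None = None,
) -> list[GeneModel]:
    """Read gene models from GTF, GFF3 or BED12.

    One :class:`GeneModel` per gene, 0-based half-open, TSS computed
    strand-aware. Records without a strand are rejected with a warning;
    duplicate gene identifiers raise.
    """
    if dialect in ("gtf", "gff3"):
        return _gene_models_from_gff(path, chrom_alias)
    if dialect == "bed12":
        return _gene_models_from_bed12(path, chrom_alias)
    raise ValueError(f"unknown gene-model dialect {dialect!r}")


def read_signal_bedgraph(
    path: str | os.PathLike,
    library_size: float | None = None,
    chrom_alias: Mapping[str, str] | None = None,
) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Overlapping runs or negative values raise. When ``library_size`` is
    not given it defaults to the total signal mass (sum of value x length).
    """
    runs: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            chrom = _apply_alias(f[0], chrom_alias)
            try:
                start, end, value = int(f[1]), int(f[2]), float(f[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed record") from exc
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative signal value")
            if end <= start:
                raise ParseError(f"{path}:{lineno}: empty/inverted run")
            runs.setdefault(chrom, []).append((start, end, value))
    try:
        return SignalTrack(runs, library_size=library_size)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            for s, e, v in track.runs(chrom):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def compute_rpkm(
    counts: Mapping[str, float],
    gene_lengths: Mapping[str, float],
    total_mapped: float,
) -> pd.Series:
    """Reads per kilobase per million mapped reads, per gene.

    RPKM = count / (length/1000) / (total_mapped/1e6).
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    missing = [g for g in counts if g not in gene_lengths]
    if missing:
        raise KeyError(f"genes missing a length: {missing[:5]}")
    out = {}
    for gene, c in counts.items():
        length = gene_lengths[gene]
        if length <= 0:
            raise ValueError(f"gene {gene}: non-positive length {length}")
        out[gene] = c / (length / 1000.0) / (total_mapped / 1.0e6)
    return pd.Series(out, name="rpkm", dtype=float)


def read_expression_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Expression table: rows gene_id, columns samples, values RPKM."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ParseError(f"{path}: duplicate gene_ids {dups[:5]}")
    if (df.select_dtypes(include=[np.number]) < 0).any().any():
        raise ParseError(f"{path}: negative expression values")
    return df


def write_expression_tsv(expr: pd.DataFrame, path: str | os.PathLike) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_gmt(path: str | os.PathLike) -> list["GeneSet"]:
    """Read gene sets in GMT format (term, description, members...)."""
    from .enrichment import GeneSet

    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT needs term, description, >=1 member"
                )
            members = frozenset(m for m in f[2:] if m)
            if not members:
                raise ParseError(f"{path}:{lineno}: empty gene set {f[0]}")
            sets.append(GeneSet(term_id=f[0], term_name=f[1], members=members))
    return sets


def write_gmt(sets: Sequence["GeneSet"], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write(
                "\t".join([gs.term_id, gs.term_name, *sorted(gs.members)])
                + "\n"
            )
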