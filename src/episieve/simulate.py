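"""Synthetic multi-tissue ChIP-seq dataset generator with planted truth.

Builds a toy genome with non-colliding genes, per-replicate peak sets in
which a known subset of genes carries tissue-specific peaks and another
subset carries peaks common to all tissues, coverage tracks whose TSS
signal is an asymmetric pair of bumps with a valley at the TSS (the
canonical promoter H3K4me3 shape, taller on the downstream shoulder),
gene-set annotations with one planted enriched term per tissue plus
decoys, and an expression table positively coupled to promoter signal.

Every quantity is drawn from a single seeded generator, so a given
configuration is byte-reproducible; signal values are rounded to four
decimals to keep emitted bedGraphs platform-stable.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, Peak, PeakSet, SignalTrack
from .enrichment import EnrichmentResult, GeneSet
from .io import write_bed, write_bedgraph, write_expression_tsv, write_gmt

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "TruthReport",
    "generate_dataset",
    "truth_report",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic comparison.

    Defaults mirror a two-tissue design with 3 embryonic and 2 somatic
    replicates at toy scale: 2 chromosomes x 1 Mb, 200 genes, 40% of
    genes with peaks common to both tissues and 15% specific to each.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 1_000_000
    n_genes: int = 200
    tissues: tuple[tuple[str, int], ...] = (("blastocyst", 3), ("liver", 2))
    reference_tissue: str = "blastocyst"
    frac_common: float = 0.40
    frac_specific_per_tissue: float = 0.15
    flank: int = 3000
    # gene-set annotation
    planted_term_size: int = 25
    n_decoy_terms: int = 30
    decoy_term_size: tuple[int, int] = (10, 40)
    # peak geometry and replicate noise
    peak_half_width: int = 1500
    peak_jitter_sd: float = 150.0
    peak_dropout: float = 0.03
    background_peaks_per_replicate: int = 15
    background_peak_length: tuple[int, int] = (400, 1500)
    background_height: float = 1.0
    # TSS signal shape
    base_height: float = 8.0
    gene_height_log_sd: float = 0.6
    tissue_effect_log_sd: float = 0.5
    replicate_log_sd: float = 0.1
    bump_offset_bp: int = 600
    bump_sd_bp: int = 350
    downstream_boost: float = 1.5
    signal_noise_sd: float = 0.5
    signal_pad_bp: int = 4000
    step_bp: int = 50
    # expression coupling
    expr_slope: float = 1.0
    expr_noise_sd: float = 0.4
    expr_scale: float = 1.0e-3
    zero_expr_frac: float = 0.03
    baseline_area: float = 50.0

    def noise_free(self) -> "SimulationConfig":
        """The same design with every stochastic nuisance switched off."""
        return replace(
            self,
            peak_jitter_sd=0.0,
            peak_dropout=0.0,
            background_peaks_per_replicate=0,
            gene_height_log_sd=0.0,
            replicate_log_sd=0.0,
            signal_noise_sd=0.0,
            expr_noise_sd=0.0,
            zero_expr_frac=0.0,
        )

    def validate(self) -> None:
        n_tissues = len(self.tissues)
        total = self.frac_common + n_tissues * self.frac_specific_per_tissue
        if not (0 <= self.frac_common <= 1) or total > 1 + 1e-9:
            raise ValueError("peak-bearing gene fractions must jointly be <= 1")
        if self.reference_tissue not in dict(self.tissues):
            raise ValueError("reference_tissue must be one of the tissues")
        if any(r < 1 for _, r in self.tissues) or self.n_genes < 1:
            raise ValueError("all counts must be >= 1")
        slot = (self.n_chroms * self.chrom_length_bp) // self.n_genes
        if slot < 2 * self.flank + 4000:
            raise ValueError(
                "genome too small to place n_genes without TSS-window collisions"
            )


@dataclass
class SyntheticTruth:
    """Planted structure: which genes carry which peaks, and the coupling."""

    common_genes: frozenset[str]
    specific_genes: dict[str, frozenset[str]]  # tissue -> gene_ids
    planted_terms: dict[str, str]  # tissue -> term_id
    expr_slope: float

    def to_json(self) -> dict:
        return {
            "common_genes": sorted(self.common_genes),
            "specific_genes": {
                t: sorted(g) for t, g in self.specific_genes.items()
            },
            "planted_terms": dict(self.planted_terms),
            "expr_slope": self.expr_slope,
        }


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: list[GeneModel]
    peaks: dict[str, PeakSet]  # sample_id -> canonical peak set
    tracks: dict[str, SignalTrack]
    gene_sets: list[GeneSet]
    expression: pd.DataFrame  # genes x tissues, RPKM
    panels: dict[str, list[str]]
    truth: SyntheticTruth
    samples: dict[str, str]  # sample_id -> tissue

    def write(self, outdir: str | os.PathLike) -> dict[str, Path]:
        """Emit the dataset in the formats the pipeline consumes."""
        out = Path(outdir)
        (out / "peaks").mkdir(parents=True, exist_ok=True)
        (out / "signal").mkdir(exist_ok=True)
        (out / "panels").mkdir(exist_ok=True)
        paths: dict[str, Path] = {}
        gtf = out / "genes.gtf"
        _write_gtf(self.genes, gtf)
        paths["genes"] = gtf
        for sid, ps in self.peaks.items():
            p = out / "peaks" / f"{sid}.bed"
            write_bed(ps, p)
            paths[f"peaks/{sid}"] = p
        for sid, tr in self.tracks.items():
            p = out / "signal" / f"{sid}.bedgraph"
            write_bedgraph(tr, p)
            paths[f"signal/{sid}"] = p
        gmt = out / "gene_sets.gmt"
        write_gmt(self.gene_sets, gmt)
        paths["gene_sets"] = gmt
        expr = out / "expression.tsv"
        write_expression_tsv(self.expression, expr)
        paths["expression"] = expr
        for name, members in self.panels.items():
            p = out / "panels" / f"{name}.txt"
            p.write_text("\n".join(members) + "\n")
            paths[f"panels/{name}"] = p
        truth_path = out / "truth.json"
        truth_path.write_text(json.dumps(self.truth.to_json(), indent=1))
        paths["truth"] = truth_path
        return paths


def _write_gtf(genes: Sequence[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.interval.start)):
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            start1, end1 = g.interval.start + 1, g.interval.end
            fh.write(
                f"{g.chrom}\tsim\tgene\t{start1}\t{end1}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            exons = g.exons or ((g.interval.start, g.interval.end),)
            for es, ee in exons:
                fh.write(
                    f"{g.chrom}\tsim\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def _place_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    per_chrom = math.ceil(cfg.n_genes / cfg.n_chroms)
    slot = cfg.chrom_length_bp // per_chrom
    gid = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        for i in range(per_chrom):
            if gid >= cfg.n_genes:
                break
            tss = i * slot + cfg.flank + 1000
            length = int(rng.integers(1000, 3001))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                interval = GenomicInterval(chrom, tss, tss + length, "+")
            else:
                interval = GenomicInterval(chrom, tss - length + 1, tss + 1, "-")
            name = f"G{gid:04d}"
            genes.append(GeneModel(gene_id=name, symbol=name, interval=interval))
            gid += 1
    return genes


def _build_gene_sets(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    planted_members: Mapping[str, frozenset[str]],
    all_genes: Sequence[str],
    rng: np.random.Generator,
) -> list[GeneSet]:
    sets = []
    all_planted: set[str] = set()
    for members in planted_members.values():
        all_planted |= members
    for tissue, term_id in sorted(truth.planted_terms.items()):
        sets.append(
            GeneSet(
                term_id=term_id,
                term_name=f"planted {tissue} process",
                members=planted_members[tissue],
            )
        )
    pool = sorted(set(all_genes) - all_planted)
    lo, hi = cfg.decoy_term_size
    for d in range(cfg.n_decoy_terms):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(pool))
        chosen = rng.choice(len(pool), size=size, replace=False)
        sets.append(
            GeneSet(
                term_id=f"TERM:DECOY_{d:03d}",
                term_name=f"decoy process {d}",
                members=frozenset(pool[i] for i in sorted(chosen)),
            )
        )
    return sets


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic study; deterministic given the seed."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = _place_genes(cfg, rng)
    gene_by_id = {g.gene_id: g for g in genes}
    ids = [g.gene_id for g in genes]

    # role assignment
    perm = list(rng.permutation(len(ids)))
    n_common = round(cfg.frac_common * cfg.n_genes)
    n_spec = round(cfg.frac_specific_per_tissue * cfg.n_genes)
    common = frozenset(ids[i] for i in perm[:n_common])
    specific: dict[str, frozenset[str]] = {}
    cursor = n_common
    tissue_names = [t for t, _ in cfg.tissues]
    for tissue in tissue_names:
        specific[tissue] = frozenset(ids[i] for i in perm[cursor : cursor + n_spec])
        cursor += n_spec
    planted_members: dict[str, frozenset[str]] = {}
    planted_terms: dict[str, str] = {}
    for tissue in tissue_names:
        members = sorted(specific[tissue])
        size = min(cfg.planted_term_size, len(members))
        chosen = rng.choice(len(members), size=size, replace=False) if size else []
        planted_members[tissue] = frozenset(members[i] for i in sorted(chosen))
        planted_terms[tissue] = f"TERM:PLANTED_{tissue.upper()}"
    truth = SyntheticTruth(
        common_genes=common,
        specific_genes=specific,
        planted_terms=planted_terms,
        expr_slope=cfg.expr_slope,
    )
    gene_sets = _build_gene_sets(cfg, truth, planted_members, ids, rng)

    # per-(gene, tissue) amplitudes for peaked genes
    gene_eff = {
        gid: float(rng.normal(0.0, cfg.gene_height_log_sd)) for gid in ids
    }
    amp: dict[tuple[str, str], float] = {}
    for tissue in tissue_names:
        peaked = sorted(common | specific[tissue])
        for gid in peaked:
            amp[(gid, tissue)] = cfg.base_height * math.exp(
                gene_eff[gid] + rng.normal(0.0, cfg.tissue_effect_log_sd)
            )

    genome_len = cfg.chrom_length_bp
    samples: dict[str, str] = {}
    peaks: dict[str, PeakSet] = {}
    tracks: dict[str, SignalTrack] = {}
    nbins = genome_len // cfg.step_bp
    for tissue, n_reps in cfg.tissues:
        peaked = sorted(common | specific[tissue])
        for rep in range(1, n_reps + 1):
            sid = f"{tissue}_{rep}"
            samples[sid] = tissue
            raw_peaks: list[Peak] = []
            grid = {
                f"chr{c + 1}": np.zeros(nbins, dtype=float)
                for c in range(cfg.n_chroms)
            }
            for gid in peaked:
                g = gene_by_id[gid]
                dropped = rng.random() < cfg.peak_dropout
                js = int(round(rng.normal(0.0, cfg.peak_jitter_sd)))
                je = int(round(rng.normal(0.0, cfg.peak_jitter_sd)))
                a = cfg.replicate_log_sd
                rep_mult = math.exp(rng.normal(0.0, a)) if a > 0 else 1.0
                if not dropped:
                    s = max(0, g.tss - cfg.peak_half_width + js)
                    e = min(genome_len, g.tss + cfg.peak_half_width + je)
                    if e > s:
                        raw_peaks.append(
                            Peak(GenomicInterval(g.chrom, s, e), sample_id=sid)
                        )
                # signal bumps (emitted even for a dropped peak call:
                # peak calling and coverage are distinct observations)
                _add_bumps(
                    grid[g.chrom], g, amp[(gid, tissue)] * rep_mult, cfg
                )
            for _ in range(cfg.background_peaks_per_replicate):
                chrom = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
                length = int(
                    rng.integers(*cfg.background_peak_length)
                )
                s = int(rng.integers(0, genome_len - length))
                raw_peaks.append(
                    Peak(GenomicInterval(chrom, s, s + length), sample_id=sid)
                )
                b0, b1 = s // cfg.step_bp, -(-(s + length) // cfg.step_bp)
                grid[chrom][b0:b1] += cfg.background_height
            if cfg.signal_noise_sd > 0:
                for chrom in grid:
                    nz = grid[chrom] > 0
                    grid[chrom][nz] += np.abs(
                        rng.normal(0.0, cfg.signal_noise_sd, int(nz.sum()))
                    )
            peaks[sid] = _canonicalize(raw_peaks, sid)
            tracks[sid] = _grid_to_track(grid, cfg.step_bp)

    expression = _make_expression(cfg, tissue_names, ids, common, specific, amp, rng)

    # gene panels over the commonly-peaked genes, salted with genes that
    # fail the downstream filters to exercise the cascade bookkeeping
    common_sorted = sorted(common)
    spec_pool = sorted(set().union(*specific.values()))
    unpeaked = sorted(set(ids) - common - set(spec_pool))
    big = common_sorted[:48] + spec_pool[:6] + unpeaked[:6]
    small = common_sorted[48:72] + spec_pool[6:9] + unpeaked[6:9]
    panels = {
        "production_panel": sorted(big),
        "imprinted_like_panel": sorted(small),
    }
    # force one panel gene to zero expression in the reference tissue to
    # exercise the log-transform omission path
    if cfg.zero_expr_frac > 0:
        victim = sorted(set(panels["imprinted_like_panel"]) & common)[0]
        expression.loc[victim, cfg.reference_tissue] = 0.0

    return SyntheticDataset(
        config=cfg,
        genes=genes,
        peaks=peaks,
        tracks=tracks,
        gene_sets=gene_sets,
        expression=expression,
        panels=panels,
        truth=truth,
        samples=samples,
    )


def _add_bumps(
    grid: np.ndarray, gene: GeneModel, amplitude: float, cfg: SimulationConfig
) -> None:
    """Two Gaussian bumps flanking the TSS; downstream (5'->3') is taller."""
    step = cfg.step_bp
    tss = gene.tss
    direction = 1 if gene.strand == "+" else -1
    lo = max(0, tss - cfg.signal_pad_bp)
    hi = min(len(grid) * step, tss + cfg.signal_pad_bp)
    b0, b1 = lo // step, hi // step
    centers = (np.arange(b0, b1) + 0.5) * step
    up = tss - direction * cfg.bump_offset_bp
    down = tss + direction * cfg.bump_offset_bp
    sd2 = 2.0 * cfg.bump_sd_bp**2
    vals = amplitude * (
        np.exp(-((centers - up) ** 2) / sd2)
        + cfg.downstream_boost * np.exp(-((centers - down) ** 2) / sd2)
    )
    grid[b0:b1] += vals


def _canonicalize(raw: list[Peak], label: str) -> PeakSet:
    from .peaks import merge_union

    ps = PeakSet(raw, label=label)
    if ps.is_canonical:
        return ps
    return merge_union(ps, PeakSet([], label=label), coalesce_bookended=True)


def _grid_to_track(
    grid: Mapping[str, np.ndarray], step: int
) -> SignalTrack:
    runs: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, arr in grid.items():
        vals = np.round(arr, 4)
        nz = np.nonzero(vals)[0]
        if nz.size == 0:
            continue
        runs[chrom] = [
            (int(i) * step, (int(i) + 1) * step, float(vals[i])) for i in nz
        ]
    return SignalTrack(runs)


def _make_expression(
    cfg: SimulationConfig,
    tissue_names: Sequence[str],
    ids: Sequence[str],
    common: frozenset[str],
    specific: Mapping[str, frozenset[str]],
    amp: Mapping[tuple[str, str], float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    bump_mass = (
        (1.0 + cfg.downstream_boost) * cfg.bump_sd_bp * math.sqrt(2 * math.pi)
    )
    cols = {}
    for tissue in tissue_names:
        vals = []
        for gid in ids:
            if (gid, tissue) in amp:
                area = amp[(gid, tissue)] * bump_mass
            else:
                area = cfg.baseline_area
            noise = (
                math.exp(rng.normal(0.0, cfg.expr_noise_sd))
                if cfg.expr_noise_sd > 0
                else 1.0
            )
            rpkm = cfg.expr_scale * area**cfg.expr_slope * noise
            if cfg.zero_expr_frac > 0 and rng.random() < cfg.zero_expr_frac:
                rpkm = 0.0
            vals.append(round(rpkm, 6))
        cols[tissue] = vals
    return pd.DataFrame(cols, index=pd.Index(ids, name="gene_id"))


@dataclass
class TruthReport:
    """Recovery metrics of pipeline outputs against the planted truth."""

    precision: dict[str, float]
    recall: dict[str, float]
    planted_rank: dict[str, int | None]
    pc1_separated: bool | None
    correlation_positive: dict[str, bool]

    def mean_recall(self) -> float:
        return float(np.mean(list(self.recall.values())))

    def mean_precision(self) -> float:
        return float(np.mean(list(self.precision.values())))


def truth_report(
    truth: SyntheticTruth,
    specific_genes: Mapping[str, Iterable[str]],
    enrichment: Mapping[str, Sequence[EnrichmentResult]] | None = None,
    pc1_scores: Mapping[str, float] | None = None,
    sample_tissues: Mapping[str, str] | None = None,
    correlations: Mapping[str, float] | None = None,
) -> TruthReport:
    """Score recovered tissue-specific gene lists and downstream readouts.

    ``specific_genes`` maps tissue -> genes the sieve called specific;
    ``enrichment`` maps tissue -> ranked enrichment results;
    ``pc1_scores`` maps sample_id -> PC1 score (with ``sample_tissues``
    giving the grouping); ``correlations`` maps a label -> Pearson r.
    """
    unknown = set(specific_genes) - set(truth.specific_genes)
    if unknown:
        raise ValueError(f"tissues not present in the truth: {sorted(unknown)}")
    precision, recall = {}, {}
    for tissue, called in specific_genes.items():
        called_set = set(called)
        true_set = set(truth.specific_genes[tissue])
        tp = len(called_set & true_set)
        precision[tissue] = tp / len(called_set) if called_set else 0.0
        recall[tissue] = tp / len(true_set) if true_set else 1.0
    planted_rank: dict[str, int | None] = {}
    if enrichment is not None:
        for tissue, results in enrichment.items():
            term = truth.planted_terms.get(tissue)
            rank = None
            for i, res in enumerate(results, start=1):
                if res.term_id == term:
                    rank = i
                    break
            planted_rank[tissue] = rank
    pc1_separated: bool | None = None
    if pc1_scores is not None:
        if sample_tissues is None:
            raise ValueError("pc1_scores requires sample_tissues")
        by_tissue: dict[str, list[float]] = {}
        for sid, score in pc1_scores.items():
            by_tissue.setdefault(sample_tissues[sid], []).append(score)
        if len(by_tissue) != 2:
            raise ValueError("PC1 separation check needs exactly 2 tissues")
        (a, b) = (sorted(v) for v in by_tissue.values())
        pc1_separated = a[-1] < b[0] or b[-1] < a[0]
    correlation_positive = {
        label: r > 0 for label, r in (correlations or {}).items()
    }
    return TruthReport(
        precision=precision,
        recall=recall,
        planted_rank=planted_rank,
        pc1_separated=pc1_separated,
        correlation_positive=correlation_positive,
    )
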