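"""End-to-end orchestration of the comparative peak analysis.

Two entry points mirror the study design:

* :func:`run_sieve_analysis` — replicate consensus per tissue, common
  peaks against a reference tissue, tissue-specific peaks by whole-peak
  subtraction (the "sieve"), TSS-window occupancy, top-N gene panels and
  gene-set enrichment.
* :func:`run_common_peak_pca` — restrict a gene panel to genes carrying
  peaks in every tissue, quantify TSS-window peak areas from coverage,
  autoscale, PCA, and (when expression is supplied) signal-expression
  correlations within tissues and as a between-tissue relative
  difference.

Every intermediate is written as BED/TSV so each stage can be validated
independently; a JSON manifest records parameters and input checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .annotation import (
    OccupancyRecord,
    make_tss_windows,
    occupancy_rates,
    top_n_by_occupancy,
)
from .core import PeakSet
from .enrichment import EnrichmentResult, enrich, top_terms
from .io import (
    read_bed,
    read_expression_tsv,
    read_gene_models,
    read_gmt,
    read_signal_bedgraph,
    write_bed,
)
from .multivariate import (
    CorrelationReport,
    PCAResult,
    autoscale,
    correlate_log,
    pca,
    relative_difference_correlation,
)
from .peaks import consensus_peaks, intersect_common, merge_union, subtract_specific
from .profiles import peak_area_matrix

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SieveReport", "CommonPeakReport",
           "run_sieve_analysis", "run_common_peak_pca"]


@dataclass
class PipelineConfig:
    """Inputs and parameters for a full run; loadable from YAML."""

    peaks: dict[str, dict[str, str]]  # tissue -> {sample_id: bed path}
    genes: str
    reference_tissue: str
    out_dir: str
    gene_dialect: str = "gtf"
    signal: dict[str, dict[str, str]] = field(default_factory=dict)
    gmt: str | None = None
    expression: str | None = None
    panel: str | None = None
    flank: int = 3000
    top_n: int = 100
    n_top_terms: int = 10
    bins: int = 100
    consensus_mode: str = "intersect_segment"
    promoter_bp: int = 3000
    min_overlap_bp: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.reference_tissue not in self.peaks:
            raise ValueError(
                f"reference tissue {self.reference_tissue!r} has no peak files"
            )
        if self.flank <= 0 or self.top_n < 1 or self.bins < 2:
            raise ValueError("parameters out of range")
        for tissue, reps in self.peaks.items():
            if not reps:
                raise ValueError(f"tissue {tissue!r} has no replicates")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(cfg: PipelineConfig, out: Path, stage: str) -> Path:
    inputs: dict[str, str] = {"genes": _sha256(cfg.genes)}
    for tissue, reps in cfg.peaks.items():
        for sid, p in reps.items():
            inputs[f"peaks/{sid}"] = _sha256(p)
    for tissue, reps in cfg.signal.items():
        for sid, p in reps.items():
            inputs[f"signal/{sid}"] = _sha256(p)
    for key in ("gmt", "expression", "panel"):
        val = getattr(cfg, key)
        if val:
            inputs[key] = _sha256(val)
    manifest = {
        "stage": stage,
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(cfg).items()
            if not isinstance(v, dict)
        },
        "inputs_sha256": inputs,
    }
    path = out / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def _fold_consensus(
    replicates: Sequence[PeakSet], mode: str
) -> PeakSet:
    """Left-fold the binary replicate consensus over >= 1 replicates."""
    if len(replicates) == 1:
        return replicates[0]
    acc = replicates[0]
    for nxt in replicates[1:]:
        acc = consensus_peaks(acc, nxt, mode=mode)
    return acc


def _occupancy_frame(records: Sequence[OccupancyRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "symbol": [r.symbol for r in records],
            "covered_bp": [r.covered_bp for r in records],
            "width": [r.width for r in records],
            "occupancy_rate": [r.occupancy_rate for r in records],
        }
    )
    df = df.sort_values(
        ["occupancy_rate", "symbol"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank"] = df.index + 1
    return df


def _enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "k": [r.overlap_count for r in results],
            "K": [r.set_size for r in results],
            "n": [r.query_size for r in results],
            "N": [r.universe_size for r in results],
            "p": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
        }
    )


@dataclass
class SieveReport:
    consensus: dict[str, PeakSet]
    common: dict[str, PeakSet]  # tissue vs reference intersections
    specific: dict[str, PeakSet]  # per-tissue specific peaks
    specific_genes: dict[str, list[str]]
    occupancy: dict[str, list[OccupancyRecord]]
    top_genes: dict[str, list[str]]
    enrichment: dict[str, list[EnrichmentResult]]
    stage_counts: list[tuple[str, int]]
    manifest: Path


def run_sieve_analysis(config: PipelineConfig) -> SieveReport:
    """Consensus -> common/specific sieve -> occupancy -> enrichment."""
    cfg = config
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = read_gene_models(cfg.genes, dialect=cfg.gene_dialect)
    windows = make_tss_windows(genes, flank=cfg.flank)
    universe = [w.gene_id for w in windows]
    gene_sets = read_gmt(cfg.gmt) if cfg.gmt else []
    stage_counts: list[tuple[str, int]] = []

    consensus: dict[str, PeakSet] = {}
    for tissue, reps in cfg.peaks.items():
        rep_sets = [
            PeakSet(read_bed(path, label=sid), label=sid)
            for sid, path in sorted(reps.items())
        ]
        for ps in rep_sets:
            stage_counts.append((f"{tissue}:replicate:{ps.label}", len(ps)))
        cons = _fold_consensus(rep_sets, cfg.consensus_mode)
        cons.label = tissue
        consensus[tissue] = cons
        stage_counts.append((f"{tissue}:consensus", len(cons)))
        write_bed(cons, out / f"{tissue}.consensus.bed")

    ref = cfg.reference_tissue
    common: dict[str, PeakSet] = {}
    specific: dict[str, PeakSet] = {}
    for tissue in cfg.peaks:
        if tissue == ref:
            continue
        common[tissue] = intersect_common(consensus[tissue], consensus[ref])
        specific[tissue] = subtract_specific(
            consensus[tissue], consensus[ref], min_overlap_bp=cfg.min_overlap_bp
        )
        stage_counts.append((f"{tissue}:common_vs_{ref}", len(common[tissue])))
        stage_counts.append((f"{tissue}:specific", len(specific[tissue])))
        write_bed(common[tissue], out / f"{tissue}_vs_{ref}.common.bed")
        write_bed(specific[tissue], out / f"{tissue}.specific.bed")
    # reference-specific peaks: subtract the union of all other tissues
    others = [consensus[t] for t in cfg.peaks if t != ref]
    if others:
        merged = others[0]
        for nxt in others[1:]:
            merged = merge_union(merged, nxt)
        specific[ref] = subtract_specific(
            consensus[ref], merged, min_overlap_bp=cfg.min_overlap_bp
        )
        stage_counts.append((f"{ref}:specific", len(specific[ref])))
        write_bed(specific[ref], out / f"{ref}.specific.bed")

    occupancy: dict[str, list[OccupancyRecord]] = {}
    specific_genes: dict[str, list[str]] = {}
    top_genes: dict[str, list[str]] = {}
    enrichment: dict[str, list[EnrichmentResult]] = {}
    for tissue, spec in specific.items():
        records = occupancy_rates(windows, spec)
        occupancy[tissue] = records
        frame = _occupancy_frame([r for r in records if r.covered_bp > 0])
        frame.to_csv(out / f"{tissue}.specific_occupancy.tsv", sep="\t", index=False)
        specific_genes[tissue] = sorted(frame["gene_id"])
        stage_counts.append((f"{tissue}:specific_genes", len(frame)))
        top = top_n_by_occupancy(records, n=cfg.top_n)
        top_genes[tissue] = [r.gene_id for r in top]
        (out / f"{tissue}.top{cfg.top_n}.txt").write_text(
            "\n".join(top_genes[tissue]) + ("\n" if top else "")
        )
        if gene_sets and top:
            results = enrich(top_genes[tissue], gene_sets, universe)
            enrichment[tissue] = results
            _enrichment_frame(top_terms(results, n=cfg.n_top_terms)).to_csv(
                out / f"{tissue}.enrichment_top{cfg.n_top_terms}.tsv",
                sep="\t",
                index=False,
            )
    for stage, count in stage_counts:
        logger.info("sieve stage %s: %d records", stage, count)
    pd.DataFrame(stage_counts, columns=["stage", "count"]).to_csv(
        out / "sieve_stage_counts.tsv", sep="\t", index=False
    )
    manifest = _write_manifest(cfg, out, "sieve")
    return SieveReport(
        consensus=consensus,
        common=common,
        specific=specific,
        specific_genes=specific_genes,
        occupancy=occupancy,
        top_genes=top_genes,
        enrichment=enrichment,
        stage_counts=stage_counts,
        manifest=manifest,
    )


@dataclass
class CommonPeakReport:
    cascade: list[tuple[str, int]]  # monotone filter-step counts
    areas: pd.DataFrame
    scaled: pd.DataFrame
    pca: PCAResult
    sample_tissues: dict[str, str]
    correlations: dict[str, CorrelationReport]
    manifest: Path


def run_common_peak_pca(config: PipelineConfig) -> CommonPeakReport:
    """Panel restriction -> peak areas -> autoscaled PCA -> correlations."""
    cfg = config
    cfg.validate()
    if not cfg.signal:
        raise ValueError("run_common_peak_pca requires signal tracks")
    if not cfg.panel:
        raise ValueError("run_common_peak_pca requires a gene panel file")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = read_gene_models(cfg.genes, dialect=cfg.gene_dialect)
    by_id = {g.gene_id: g for g in genes}
    panel = [
        line.strip()
        for line in Path(cfg.panel).read_text().splitlines()
        if line.strip()
    ]
    cascade = [("panel", len(panel))]
    curated = [g for g in panel if g in by_id]
    cascade.append(("curated", len(curated)))

    consensus: dict[str, PeakSet] = {}
    for tissue, reps in cfg.peaks.items():
        rep_sets = [
            PeakSet(read_bed(p, label=sid), label=sid)
            for sid, p in sorted(reps.items())
        ]
        consensus[tissue] = _fold_consensus(rep_sets, cfg.consensus_mode)

    windows = {
        w.gene_id: w
        for w in make_tss_windows([by_id[g] for g in curated], flank=cfg.flank)
    }
    commonly_peaked = [
        g
        for g in curated
        if all(
            occupancy_rates([windows[g]], cons)[0].covered_bp > 0
            for cons in consensus.values()
        )
    ]
    cascade.append(("commonly_peaked", len(commonly_peaked)))
    if not commonly_peaked:
        raise ValueError(
            "no panel gene carries peaks in every tissue; cascade: "
            + ", ".join(f"{s}={n}" for s, n in cascade)
        )

    tracks = {}
    sample_tissues = {}
    for tissue, reps in cfg.signal.items():
        for sid, path in sorted(reps.items()):
            tracks[sid] = read_signal_bedgraph(path)
            sample_tissues[sid] = tissue
    win_list = [windows[g] for g in commonly_peaked]
    areas = peak_area_matrix(tracks, win_list)
    quantified = areas.index[(areas > 0).all(axis=1)]
    areas = areas.loc[quantified]
    cascade.append(("quantified", len(areas)))
    areas.to_csv(out / "peak_areas.tsv", sep="\t", float_format="%.6g")

    scaled = autoscale(areas)
    result = pca(scaled)
    result.scores.to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.6g")
    result.loadings.to_csv(out / "pca_loadings.tsv", sep="\t", float_format="%.6g")
    pd.Series(
        result.variance_fraction,
        index=result.scores.columns,
        name="variance_fraction",
    ).to_csv(out / "pca_variance.tsv", sep="\t")

    correlations: dict[str, CorrelationReport] = {}
    if cfg.expression:
        expr = read_expression_tsv(cfg.expression)
        tissue_mean_areas = {
            tissue: areas[
                [s for s, t in sample_tissues.items() if t == tissue]
            ].mean(axis=1)
            for tissue in cfg.signal
        }
        rows = []
        for tissue, mean_areas in tissue_mean_areas.items():
            if tissue not in expr.columns:
                continue
            rep = correlate_log(mean_areas, expr[tissue])
            correlations[tissue] = rep
            rows.append((tissue, rep.r, rep.n, rep.p, ";".join(rep.dropped)))
        tissues = [t for t in tissue_mean_areas if t in expr.columns]
        if len(tissues) == 2:
            t1, t2 = tissues
            rep = relative_difference_correlation(
                tissue_mean_areas[t1],
                tissue_mean_areas[t2],
                expr[t1],
                expr[t2],
            )
            correlations["relative_difference"] = rep
            rows.append(
                ("relative_difference", rep.r, rep.n, rep.p, ";".join(rep.dropped))
            )
        pd.DataFrame(
            rows, columns=["comparison", "r", "n", "p", "dropped"]
        ).to_csv(out / "correlations.tsv", sep="\t", index=False)

    pd.DataFrame(cascade, columns=["step", "count"]).to_csv(
        out / "panel_cascade.tsv", sep="\t", index=False
    )
    for step, n in cascade:
        logger.info("panel cascade %s: %d genes", step, n)
    manifest = _write_manifest(cfg, out, "common_peak_pca")
    return CommonPeakReport(
        cascade=cascade,
        areas=areas,
        scaled=scaled,
        pca=result,
        sample_tissues=sample_tissues,
        correlations=correlations,
        manifest=manifest,
    )
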