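"""One-call synthetic study: generate, run the pipeline, score recovery.

Convenience wrapper that materializes a synthetic dataset on disk in the
standard formats, runs both pipeline stages on the files exactly as a
shell user would, and scores the outputs against the planted truth.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

from .pipeline import (
    CommonPeakReport,
    PipelineConfig,
    SieveReport,
    run_common_peak_pca,
    run_sieve_analysis,
)
from .simulate import (
    SimulationConfig,
    SyntheticDataset,
    TruthReport,
    generate_dataset,
    truth_report,
)

__all__ = ["StudyResult", "run_synthetic_study"]


@dataclass
class StudyResult:
    dataset: SyntheticDataset
    sieve: SieveReport
    common_pca: CommonPeakReport
    recovery: TruthReport


def run_synthetic_study(
    config: SimulationConfig,
    workdir: str | Path | None = None,
    panel: str = "production_panel",
) -> StudyResult:
    """Generate a dataset, run sieve + common-peak PCA, score vs truth."""
    dataset = generate_dataset(config)
    if workdir is None:
        with tempfile.TemporaryDirectory(prefix="episieve_") as tmp:
            return _run_on_disk(dataset, Path(tmp), panel)
    return _run_on_disk(dataset, Path(workdir), panel)


def _run_on_disk(
    dataset: SyntheticDataset, root: Path, panel: str
) -> StudyResult:
    dataset.write(root)
    tissues = [t for t, _ in dataset.config.tissues]
    by_tissue = lambda kind, ext: {  # noqa: E731
        t: {
            sid: str(root / kind / f"{sid}.{ext}")
            for sid, tt in dataset.samples.items()
            if tt == t
        }
        for t in tissues
    }
    cfg = PipelineConfig(
        peaks=by_tissue("peaks", "bed"),
        genes=str(root / "genes.gtf"),
        reference_tissue=dataset.config.reference_tissue,
        out_dir=str(root / "out"),
        signal=by_tissue("signal", "bedgraph"),
        gmt=str(root / "gene_sets.gmt"),
        expression=str(root / "expression.tsv"),
        panel=str(root / "panels" / f"{panel}.txt"),
        flank=dataset.config.flank,
    )
    sieve = run_sieve_analysis(cfg)
    common = run_common_peak_pca(cfg)
    recovery = truth_report(
        dataset.truth,
        sieve.specific_genes,
        enrichment=sieve.enrichment,
        pc1_scores=common.pca.scores["PC1"].to_dict(),
        sample_tissues=common.sample_tissues,
        correlations={k: v.r for k, v in common.correlations.items()},
    )
    return StudyResult(
        dataset=dataset, sieve=sieve, common_pca=common, recovery=recovery
    )
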