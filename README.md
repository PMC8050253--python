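# episieve

Comparative analysis of histone-mark ChIP-seq peak landscapes between
tissues — built around the "sieve" idea: the H3K4me3 peaks of one tissue
(for example a preimplantation embryo) can be subtracted from another
tissue's peaks to expose the modifications specific to that tissue and,
separately, the modifications the two tissues share.

The package is aimed at epigenomics analysts who already have called
peaks (BED), gene models (GTF/GFF3/BED12), coverage tracks (bedGraph),
gene-set annotations (GMT) and expression tables (TSV of RPKM), and want
a reproducible, scriptable version of the classic comparative workflow:

1. **Replicate consensus** — overlapping peaks across biological
   replicates (per-base intersection by default; whole-peak and
   union-component conventions available).
2. **Sieve** — *common* peaks as per-base intersection segments between
   two tissues (a peak spanning k disjoint partner peaks splits into k
   segments, so common + specific counts need not add up to the
   original count), and *tissue-specific* peaks by whole-peak
   subtraction: any 1-bp overlap disqualifies, surviving peaks are kept
   unmodified (`bedtools intersect` default and `-v` semantics).
3. **TSS occupancy** — for each gene, the fraction of its ±3000 bp
   TSS window covered by the union of peaks; genes are ranked and the
   top 100 form the query panel.
4. **Enrichment** — one-sided hypergeometric overrepresentation of
   gene sets in the panel with Benjamini–Hochberg FDR:
   p = P(X ≥ k), X ~ Hypergeom(N, K, n) over a stated gene universe.
5. **Profiles and areas** — library-normalized (per-million) binned
   metagene profiles around TSSs and gene bodies, expression tertiles,
   and integrated TSS-window *peak areas*.
6. **Multivariate** — per-gene autoscaling (mean 0, sd 1 across
   samples, ddof = 1), PCA with samples as observations and genes as
   variables (SVD, deterministic sign convention), and Pearson
   correlation of log10 peak area vs log10 RPKM, within tissues and as
   a between-tissue relative difference
   r(log10 A₁/A₂, log10 E₁/E₂).

A first-class synthetic-data generator plants known tissue-specific and
common peaks, the canonical asymmetric bimodal TSS signal with a valley
at the TSS, an enriched gene-set term per tissue, and expression
positively coupled to promoter signal — so the entire pipeline is
testable end to end without any downloads.

## Worked example

```python
from episieve import SimulationConfig, run_synthetic_study

study = run_synthetic_study(SimulationConfig(seed=1))
rec = study.recovery
for t in sorted(rec.precision):
    print(f"{t:<11} precision {rec.precision[t]:.2f}  recall {rec.recall[t]:.2f}")
print("planted term rank:", dict(sorted(rec.planted_rank.items())))
vf = study.common_pca.pca.variance_fraction
print(f"PC1 variance fraction: {vf[0]:.3f}")
for label, r in sorted(study.common_pca.correlations.items()):
    print(f"Pearson r [{label}]: {r.r:.3f} (n={r.n})")
```

prints

```
blastocyst  precision 0.93  recall 0.90
liver       precision 0.74  recall 0.93
planted term rank: {'blastocyst': 1, 'liver': 1}
PC1 variance fraction: 0.854
Pearson r [blastocyst]: 0.889 (n=40)
Pearson r [liver]: 0.883 (n=41)
Pearson r [relative_difference]: 0.774 (n=40)
```

Reading: the sieve recovers ~90% of the genes that truly carry
tissue-specific peaks (imperfect replicate peak calls cost the rest);
the planted tissue-function gene set ranks first in both tissues'
enrichment; PC1 of the autoscaled common-gene peak areas captures the
inter-tissue difference and cleanly separates the sample groups; and
promoter H3K4me3 signal correlates strongly with expression in log-log
space, including as a between-tissue relative difference.

The same analysis is available from the shell:

```bash
episieve simulate --seed 1 --out sim/
episieve sieve --ref sim/peaks/blastocyst_1.bed --tissue sim/peaks/liver_1.bed \
    --out-prefix liver_vs_blast
episieve occupancy --peaks liver_vs_blast.tissue_specific.bed \
    --genes sim/genes.gtf --flank 3000 --top 100 --out occ.tsv
episieve run --config run.yaml   # full pipeline from a YAML config
```

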