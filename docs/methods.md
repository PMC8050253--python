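# Methods notes

## Scope and model

`episieve` implements the comparative peak-landscape workflow for an
active-promoter histone mark (H3K4me3) between two or more tissues:
replicate-consensus peak sets, common/specific peak extraction, TSS
occupancy ranking, gene-set overrepresentation, metagene profiles,
TSS-window peak areas with autoscaled PCA, and signal–expression
correlation. It consumes *called* peaks and *pre-computed* coverage;
alignment, duplicate removal and peak calling are upstream of the
package by design.

All internal coordinates are 0-based half-open (BED convention);
GTF/GFF3 (1-based inclusive) are converted at the I/O boundary, and a
user-supplied chromosome alias map can reconcile naming schemes across
annotation sources. Chromosome matching is otherwise exact string
equality.

## Interval semantics

* **Common peaks** are maximal per-base intersection segments. One peak
  overlapping k disjoint partner peaks yields k segments; consequently
  |common| + |specific| generally exceeds neither bound of the original
  peak count and the counts deliberately do not add up.
* **Specific peaks** use whole-peak subtraction: a peak is removed if it
  shares ≥ 1 bp (default; configurable as bp or as a fraction of the
  peak) with the partner set, and survivors are returned unmodified.
* **Replicate consensus** defaults to the per-base intersection of the
  replicates (folded left-to-right over > 2 replicates, which for this
  mode equals the intersection of all of them and is order-independent).
  Because the field's phrase "overlapping peaks between replicates" is
  ambiguous, two other conventions are selectable: the peaks of one
  replicate that have any overlap in the other (`a_overlapping`), and
  the union of each connected overlapping component present in both
  replicates (`union_component`).
* Merging coalesces bookended intervals ([a,b) + [b,c)) by default,
  matching `bedtools merge` with distance 0; this is configurable.
* Inputs to the algebra must be canonical (sorted, internally
  non-overlapping). Non-canonical sets raise unless `auto_merge` is
  set, which coalesces them first.

## TSS windows, occupancy and genic context

A TSS window is the symmetric ±`flank` (default 3000 bp) neighbourhood
of the strand-aware TSS (`interval.start` on +, `interval.end − 1` on
−), clipped at chromosome bounds. Occupancy is the fraction of the
window covered by the *union* of peaks — each base counted once. The
top-N ranking (default N = 100, the conventional panel size for GO
analysis) excludes zero-occupancy genes, breaks ties by gene symbol for
determinism, and logs ties straddling the cutoff. A peak overlapping
several windows contributes to each; occupancy is a per-gene statistic,
not a partition of peaks.

Genic classification assigns each peak by its midpoint with precedence
promoter > exonic/intronic > downstream > intergenic. The promoter is
two-sided ±`promoter_bp` (default 3000 bp, the window convention) with
an upstream-only switch, since annotation tools differ on sidedness;
genes without exon block structure classify their whole body as exonic.
Midpoint classification is a deliberate simplification of multi-label
annotators, so genic-category fractions are comparable across runs of
this package but not bit-identical to any external tool.

## Enrichment

Overrepresentation uses the standard one-sided hypergeometric upper
tail rather than a modified Fisher variant whose internals and
annotation versions are not reproducible; this package's validation
surface is recovery of planted structure, not matching any historical
term list. The universe is the set of genes possessing a TSS window in
the supplied annotation — conditioning on testable genes — and terms
with K < 2 members in the universe or K > 0.5·N are excluded as
uninformative (both configurable). BH step-up FDR is applied across all
tested terms of a run; results sort by (p, term_id).

## Profiles and peak areas

Coverage is held as sorted non-overlapping runs with prefix-sum mass,
so any window integral is O(log R). Profile rows are mean per-base
signal in `bins` equal-width bins (default 100 over ±3000 bp, i.e.
60 bp granularity) scaled to per-million of library mass
(default library = total signal mass); minus-strand rows are flipped so
bin 0 is always 5'-most. Bins truncated by a chromosome edge average
over their existing bases; fully off-chromosome genes are dropped with
a warning. Gene-body profiles use three segments — upstream flank,
length-normalized body resampled to fixed bins, downstream flank
(defaults 30/40/30 bins, 3000 bp flanks).

Peak area is the integrated per-million signal over the TSS window
(signal·bp). It is additive over disjoint sub-windows and invariant
under joint rescaling of signal and library size, which is what makes
cross-sample comparison and PCA meaningful.

Expression tertiles rank genes by RPKM descending and split them into
three groups whose sizes differ by at most one (largest first), with
gene-id tie-breaking for determinism.
RPKM = count / (length/1000) / (total_mapped/10⁶).

## Autoscaling, PCA, correlations

Autoscaling standardizes each gene across samples to mean 0 and sd 1
with ddof = 1 (the convention of mainstream statistics packages);
zero-variance genes are dropped with a warning. An exact consequence is
that for any grouping of the samples, the group-size-weighted mean of
per-group means is 0 per gene — e.g. with 3 + 2 samples,
3·m₁ + 2·m₂ = 0; the test suite asserts this to 10⁻¹².

PCA treats samples as observations and genes as variables, computed by
SVD of the column-centered observation matrix (the autoscaled matrix is
already variable-standardized, so no further scaling). Score/loading
signs are inherently arbitrary, so each component is oriented to make
its largest-magnitude loading positive; loadings are orthonormal, and
scores × loadingsᵀ reconstructs the centered matrix to 10⁻⁸.

Correlations are Pearson on log10-transformed values. Genes with a zero
on either axis are omitted (no pseudocounts) and reported in a
`dropped` list — the same treatment applied to ratio correlations,
where r is computed between log10(area₁/area₂) and log10(expr₁/expr₂).
Fewer than three usable pairs is an error.

## Synthetic data generator

The generator emulates the statistical structure the pipeline is meant
to detect, at desk scale: 2 chromosomes × 1 Mb, 200 genes on a
collision-free grid (TSS spacing 10 kb, so ±3000 bp windows never
overlap), two tissues with 3 and 2 replicates (an embryo-vs-somatic
design at toy scale). 40% of genes carry peaks in all tissues and 15%
per tissue are tissue-specific; per tissue, one gene set of 25 genes is
planted inside the specific set, alongside 30 decoy sets of 10–40 genes
drawn uniformly from non-planted genes.

Per-replicate peak calls are the true ±1500 bp TSS intervals with
boundary jitter (sd 150 bp), a 3% dropout per replicate (promoter
H3K4me3 peaks are highly reproducible in practice), and 15 spurious
background peaks per replicate (0.4–1.5 kb, height 1). Coverage is laid
on a 50-bp grid: each peak-bearing TSS receives two Gaussian bumps at
±600 bp (sd 350 bp), the downstream (5'→3') bump 1.5× taller — giving
the canonical asymmetric bimodal shape with a nucleosome-free valley at
the TSS — with amplitude
8·exp(g + t + r), where g ~ N(0, 0.6²) is a gene effect, t ~ N(0, 0.5²)
a per-(gene, tissue) effect (the inter-tissue structure PC1 must find)
and r ~ N(0, 0.1²) replicate noise; half-normal noise (sd 0.5) is added
on covered bins and values are rounded to 4 decimals for byte-stable
output. Expression per tissue is proportional to the true bump mass
(slope 1 in log space) with log-normal noise (sd 0.4); 3% of entries
are zeroed to exercise the log-transform omission path, including one
guaranteed gene on the small panel. All draws come from one seeded
`numpy` generator; identical seeds give byte-identical files.

What the generator does **not** emulate: read-level sampling noise,
GC/mappability bias, broad domains and shoulder peaks, peak-caller
artefacts, unbalanced library depths, or biological covariation between
gene sets. Passing tests therefore demonstrate the correctness and
sensitivity of the *analysis*, not robustness to every failure mode of
real ChIP-seq.

With these defaults the expected sieve recall is ≈ 0.93 (a gene is
missed when a replicate dropout removes its consensus peak:
0.97² ≈ 0.94 for the 2-replicate tissue, 0.97³ ≈ 0.91 for the
3-replicate one), and precision ≈ 0.8–0.9 (a common gene whose peak
drops out of the *other* tissue's consensus masquerades as specific).
These operating points are properties of the chosen noise model, not
tuned targets.

## Problem sizes and runtime

The test suite validates the interval algebra against a per-base
brute-force oracle on 1000 random instances (≤ 50 peaks, 2 chromosomes,
coordinates < 10⁴), enumerates the hypergeometric tail exactly for
N ≤ 25, and runs the full pipeline end to end on the 200-gene synthetic
genome for one noise-free and twenty default-noise seeds. The whole
suite completes in well under a minute on one CPU; the acceptance
script in a few seconds.

## Known limitations

* Whole-peak subtraction is asymmetric with per-base intersection: a
  1-bp nick removes an entire specific peak. This mirrors the standard
  `-v` semantics but makes specific-peak counts sensitive to peak-call
  boundary noise.
* The genic-context fractions depend on the midpoint rule and promoter
  sidedness choice; they are internally consistent, not tool-portable.
* Consensus folding across > 2 replicates requires a peak in *every*
  replicate under the default mode; with many replicates this becomes
  conservative, and `a_overlapping` or `union_component` may be more
  appropriate.
* Enrichment ignores gene-set DAG topology (no term propagation).
* Library normalization is per-million of total signal mass; if tracks
  were built with different fragment-extension conventions, areas are
  comparable only within a convention.
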