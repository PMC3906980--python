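# Methods

This note documents the models, procedures and numerical choices behind
`nitroseq`, and what the synthetic validation does and does not establish.

## Study design emulated by the generator

The package analyzes a two-condition root transcriptome experiment: plants
grown nitrate-free, then treated for a short interval with 5 mM KNO₃ or
5 mM KCl (osmotic control), two biological replicates per condition, each
sample sequenced as a stranded 50 bp poly-A+ library and a 35-cycle sRNA
library whose 3′ end runs into the cloning linker `CTGTAGGCACCATCAAT`. The
`simulate` module reproduces this design on a toy genome so every downstream
stage can be tested against known truth.

Generator defaults (all overridable on `GenomeSpec`):

| parameter | default | rationale |
|---|---|---|
| genome_length | 200 kb, one chromosome | exercises all interval logic without scale; multi-chromosome configurable |
| n_genes | 40 | enough for size-factor and DE stages at interactive runtimes |
| gene structure | 5′UTR(100) + 2–4 exons(150–400) with introns(80–250) + 3′UTR(150) | every annotation class the classifier distinguishes exists |
| frac_de_genes / lfc_magnitude | 0.2 / 2.0 log₂ units | strong-but-plausible planted signal for recovery checks |
| nb_dispersion | 0.01 | at gene means of ~200 this yields replicate correlations of ~0.96–0.98 on log₂ normalized counts, matching the near-0.99 agreement biological RNA-seq replicates show in this design |
| planted clusters | 4 antisense (NATs, inside gene spans on the opposite strand) + 13 intergenic, 350–600 bp | the NAT/intergenic split observed for ≥300 bp unannotated clusters in this experimental system; the first NAT is induced 4× in KNO₃ |
| sRNA insert lengths | mixture peaking at 21 nt (0.40) then 24 nt (0.25) | the canonical plant sRNA size structure: 21–22 nt miRNA/ta-siRNA plus 23–24 nt heterochromatic siRNA |
| quality model | two-level Phred (35/10); 5% of reads all-low, else 1% per-base low | simplest model that exercises the Q20/90% rule in both directions |
| read counts | NB(mean, α) per feature and sample; cluster reads half evenly spaced (guaranteed tiling), half uniform | evenly spaced reads make planted-region recovery a deterministic property of correct clustering rather than a coverage lottery |

What the generator does **not** emulate: sequencing substitution errors
(perfect-match mapping would discard them; an unmapped-read path exists and is
tested separately), GC/positional bias, spliced poly-A+ reads across
exon-exon junctions (reads are genomic fragments of the gene span), isoform
structure, and adapter dimers. Passing tests therefore demonstrate the
correctness of the *analysis logic* under the stated statistical model, not
robustness to every artifact of real libraries.

## Read processing

A read passes the quality filter iff ≥ `min_frac_at_phred` (default 0.9) of
its bases have Phred ≥ `phred_min` (default 20). The underlying tool
convention fixes Q20 but not the percentage; 90% is the package's documented
default and is configurable. Reads containing N are booked as quality
failures (they cannot perfectly match the genome). Adaptor trimming cuts at
the leftmost exact occurrence of the full adaptor, or at a 3′-terminal
adaptor prefix of ≥ 5 bases; matching is exact, consistent with
perfect-match mapping downstream. The polynucleotide filter discards reads
whose most frequent base exceeds 80% of the length — the filter is named but
not defined in the source protocols, so the definition here is explicit and
configurable. Size windows: 18–28 nt inclusive (sRNA), ≥ 18 nt (poly-A+).
Untrimmed sRNA reads (insert ≥ cycle length) are retained and left to the
size filter rather than being required to contain the adaptor.

## Mapping

Exact matching only, both strands, all placements reported with
`n_loci` = genome-wide placement count; no multi-mapping cap by default (a
configurable cap exists for pathological inputs and logs what it drops).
Palindromic sites where a read matches both strands count each placement
separately. The index is a k-mer seed table (k = 12) with verification;
queries shorter than the seed fall back to a direct scan; N in the genome
never matches. Coordinates are 1-based inclusive internally; BED export is
0-based half-open.

## Classification

Placement categories are decided by same-strand ≥ 1-base overlap with a
documented priority (mature miRNA > stem-loop > ta-siRNA > rRNA > tRNA >
protein coding > pseudogene > transposon); anything without same-strand
overlap is intergenic, which deliberately includes antisense placements over
genes — those are the input of the NAT stage. The priority order is a design
decision (the source material lists categories without precedence); it is a
function argument. A read mapping to *n* loci contributes multiplicity/*n*
at each placement, so Σ weighted counts = Σ read multiplicities exactly
(asserted to 1e-9); per-locus weighting is applied across categories, i.e. a
single read can contribute fractionally to several categories.

## Rarefaction

Classical subsampling without replacement from the multiplicity-expanded
library, averaged over resamples (default grid: 10 log-spaced depths, 10
resamples, seeded). The saturation statistic is the slope of the final curve
segment divided by the slope from the origin to the first depth point,
clipped to [0, 1]: 0 = plateau (saturated), 1 = every read new. Measuring
the initial slope from the origin makes the all-identical-reads library well
defined (ratio 0) instead of 0/0. This statistic is this package's
operationalization of a qualitative saturation judgement, and is documented
as such.

## Differential expression

A re-implementation of the classical NB exact test for two-condition count
data at low replication — used here as commodity machinery, not claimed as
novel.

- **Normalization**: size factor ŝⱼ = medianᵢ(kᵢⱼ / geometric meanᵥ kᵢᵥ)
  over features positive in all samples. Invariant under global depth
  rescaling (the factor cancels against the reference).
- **Dispersion**: per-feature pooled method-of-moments on normalized counts,
  α̂ᵢ = (v̂ᵢ − q̂ᵢ)/q̂ᵢ², floored at 1e-8. With two replicates per condition
  this estimate has two degrees of freedom, and using it alone makes the
  exact test anti-conservative (measured raw null rejection ~0.12 at
  α = 0.05). The default therefore shares information across features the
  way the classical method does at low replication: a parametric trend
  α(q) = a₀ + a₁/q is least-squares fitted over features, and each feature
  uses max(own estimate, trend) — "maximum" sharing. Measured null behavior
  with sharing: raw rejection ~0.03–0.04 at α = 0.05, BH-0.05 rejections ~0.
  `dispersion_sharing="per-feature"` restores the unshared estimator.
- **Test**: condition sums (kA, kB) with kA + kB = s fixed; each sum is
  modeled NB with mean q̂·Sc and variance q̂·Sc + α̂·q̂²·ΣSc² (Sc = summed
  size factors of condition c); p = Σ of joint probabilities of splits no
  more probable than observed, normalized over all s + 1 splits. Evaluated
  in log space for stability; features with zero total count get p = 1 and
  an undefined ratio.
- **Ratio**: log₂((mean normalized KNO₃ + 0.5)/(mean normalized KCl + 0.5));
  the 0.5 pseudocount keeps condition-specific genes (zero in one condition)
  finite.
- **Calls**: Benjamini–Hochberg, keep adjusted p < 0.05, induced/repressed by
  ratio sign. The filtering convention is "discard adjusted p ≥ 0.05".

The parameter-recovery guarantee is stated for planted ±2 log₂ fold changes
whose *lower* condition mean is ≥ 100: there the log-ratio standard error is
≤ ~0.18 log₂ units and ≥ 90% of planted genes land within ±0.3 of truth
(measured ~93%). Below that regime shot noise alone makes ±0.3 recovery
unattainable at n = 2 (a gene repressed 4× from mean 100 sits at mean 25,
where the ratio sd is ~0.27).

## Cross-platform concordance

AGC = reads × read length / gene length, computed from sense unique-read
counts with the nominal library read length (50 bp); a variable-length
variant (aligned bases / gene length) is available behind a flag. The
correlation curve reports squared Pearson r between platform log₂ ratios
over genes with AGC ≥ threshold (Pearson by choice, configurable);
thresholds with < 3 genes are omitted with a warning, zero-variance inputs
are refused. Array normalization and present-call computation are upstream:
the module consumes a normalized table with present/absent calls.

## Novel transcribed regions

Pooling across all samples precedes calling; only unique-match reads with
zero *same-strand* annotated overlap enter (opposite-strand overlap is
retained — that is the NAT signal). "Continuous" means zero-gap: runs extend
while the next read starts at or before current_end + 1; a `max_gap` knob
(default 0) exists because continuity is not defined in the source
protocols. The length threshold is ≥ 300 bp inclusive (the stricter
exclusive reading is available via `min_cluster_len`); 300 was chosen
upstream as approximately the genome's average exon length, so shorter runs
are indistinguishable from single exons. Cluster spans are outermost read
edges. Classification: antisense to the longest-overlap opposite-strand gene
(ties broken by gene id), else intergenic with nearest flanking genes named.
No multi-sample support filter is imposed. Quantification counts unique
same-strand reads per sample, and cluster rows are appended to the DE matrix
so clusters are tested exactly like genes.

## miRNA context annotation

Hairpin prediction is out of scope; loci arrive as tables. Context priority:
known stem-loop (any-strand overlap with a known precursor span — sequences
inside a precursor belong to the precursor, even when the precursor is
itself intronic) > 5′UTR > intron > pseudogene > intergenic; gene-hosted
contexts require same-strand overlap. Sense-exonic and 3′UTR loci are
reported `unclassifiable` rather than silently binned, since they are not
part of the context taxonomy. Novelty = mature sequence absent from the
known catalog after U↔T and case normalization; counting is per mature
sequence (two mature products of one precursor count twice). The packaged
reference tables are loaded with a per-row validation that logs (not fails)
span-length/mature-length mismatches.

## Pipeline and reproducibility

The orchestrator runs filter → map → classify → rarefaction → counts → novel
regions → DE → cross-platform → miRNA annotation, writes TSV/GFF3/BED/JSON
outputs plus a manifest of sha256 checksums, and aborts with the stage name
on error. Every stochastic step takes an explicit seed; identical config +
inputs reproduce identical checksums, which the test suite asserts by
running the demo twice.

## Problem sizes used in validation

The test suite and acceptance script run the demo at 200 kb genome / 40
genes / ~80 k reads total, the mapper-oracle comparison at 200 reads vs
50 kb, conservation at 10,000 reads, and the NB calibration at 1,500–2,000
genes; these sizes give stable statistics (Monte-Carlo SEs well inside the
asserted tolerances) at interactive runtimes.

## Known limitations

- The NB test's equivalence to any specific historical implementation of the
  cited method is not claimed, only distributional correctness (enumeration
  oracle, calibration, recovery).
- Spliced transcripts, sequencing errors and adapter artifacts are absent
  from the generator (see above), so the pipeline's behavior on such reads
  is limited to the unmapped/filter accounting paths.
- The saturation ratio is a two-point slope statistic; it is not a richness
  extrapolator (no Chao-type estimates).
- `known_srna_expression` is sequence-keyed, not position-keyed: a genomic
  duplicate of a catalog sequence is indistinguishable from the catalog
  locus.
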