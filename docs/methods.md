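# Methods

## Scope

`riboupr` implements the quantification layer of a yeast unfolded-protein-
response (UPR) / longevity study design: gene-level counting of ribosome
footprints and mRNA-seq reads, rpkm and translation-efficiency (TE)
fold-change classification, spliced-fraction quantification of an
intron-containing HAC1-style transcript, and replicative-lifespan (RLS)
survival statistics. Read alignment, GO enrichment, figure rendering and all
wet-lab procedures are out of scope; the package consumes alignments (SAM or
a simple TSV) and emits TSV tables.

## Read counting

A read is attributed to a gene by its **biological 5′ end** (leftmost mapped
position on the + strand, rightmost on −). The 5′ end is the natural anchor
for ribosome footprints, whose 5′ boundary is fixed by the ribosome, and it
makes the 5′-exclusion rule (below) exact rather than approximate. A read is
counted for a gene iff:

1. it maps to a single genomic location (multi-mapped reads are discarded by
   default; `multimapper_policy="keep"` treats them as unique);
2. its 5′ end falls in exactly one gene's spliced CDS on the matching strand;
3. its offset from the gene's 5′ end, in spliced-transcript coordinates,
   exceeds the trim (default 100 nt) — the region of elevated footprint
   density around the start codon is excluded from quantification.

Reads failing any step are tallied under one of six reasons (`multimapper`,
`no_feature`, `wrong_strand`, `intron`, `ambiguous_overlap`,
`five_prime_zone`), in that order of precedence, so that
assigned + unassigned always equals the number of input records
(conservation, asserted after every run). Reads whose 5′ end lies in the
intron of an intron-containing gene are excluded from the gene count and are
instead evidence for the splicing module.

Counting is over the CDS only. Whether quantification should cover whole
transcripts including UTRs is genuinely open for this assay; CDS-only is the
default because UTR annotations are not part of the gene model inputs.

**rpkm** = count / (effective length in kb) / (library size in millions).
Effective length is the spliced CDS length minus the 5′ trim, clamped at
1 nt; clamped genes are flagged (`short_gene`) and should be interpreted with
caution. Library size defaults to the per-sample total of gene-assigned reads
("total mapped reads" is ambiguous between mapped and assigned;
`library_size_mode="mapped"` switches to all input records).

## Translation-efficiency analysis

Per condition, rpkm is averaged over biological replicates (arithmetic mean;
a single replicate passes through). Genes with a replicate-mean rpkm below
10 in either member of a comparison, on the axis being compared, are
excluded; the TE axis requires both the footprint and mRNA axes to pass,
which makes division by zero structurally impossible downstream — no
pseudo-counts are ever added. TE = footprint mean rpkm / mRNA mean rpkm.

A gene is called regulated on an axis when |log2 fold change| versus the
reference condition **strictly exceeds 0.6**. The cut is stated in log2 units
(2^0.6 ≈ 1.52) rather than as exactly 1.5-fold; 0.6 is taken as the
operational threshold. Fold changes are computed on replicate-mean rpkm (not
per-replicate and then averaged), which yields the exact algebraic identity

    log2 TE FC = log2 footprint FC − log2 mRNA FC

asserted to 1e-12 in the test suite. No per-gene statistical test or
multiple-testing correction is applied: the screen is threshold-based by
design, and the pipeline mirrors that and documents it rather than
substituting a differential-expression model.

Replicate QC is the Pearson correlation of log2 rpkm over genes expressed in
both replicates. TE-change matrices (genes × conditions, restricted to genes
with |log2 TE FC| > 0.6 in ≥ 1 condition) are clustered with average-linkage
hierarchical clustering under 1 − Pearson distance; rows are sorted
lexicographically by gene id before clustering, which fixes tie-breaking and
makes the merge tree invariant to input row order. Undefined correlations
(constant profiles) are treated as distance 1 with a warning.

## Splicing quantification

The spliced fraction is 100 × spliced / (spliced + unspliced) — the only
reading under which the spliced and unspliced shares are complementary
percentages. From band intensities the formula is applied directly
(densitometry itself is out of scope; background subtraction is assumed done
upstream). From reads, each alignment over the single-intron gene is
classified as:

* **spliced** — split alignment whose gap removes the intron exactly;
* **unspliced** — 5′ end inside the intron, or a contiguous alignment
  crossing an exon–intron boundary;
* **uninformative** — everything else (excluded from the denominator,
  tallied separately).

The fraction is computed over informative reads only and is NaN (flagged,
never propagated) when there are none. Note the simple 6-column alignment
TSV cannot represent split alignments; the writer adds a CIGAR-style seventh
column when split reads are present, and SAM (N skips) is the recommended
interchange format for junction analysis.

## Lifespan statistics

Every mother cell is followed to senescence, so survival is the empirical
tail function S(d) = fraction of cells with ≥ d divisions (no censoring
model). Mean RLS is the arithmetic mean and equals the area under the
discrete survival curve, an identity asserted on every fixture. Percent
change versus the experiment-matched control is 100 × (mutant − control) /
control, rounded half-away-from-zero to one decimal (the display convention
of the published table). Cohorts dissected for the two mating types are
pooled before analysis via `pool_cohorts`.

Significance uses the two-sided Wilcoxon rank-sum test: exact null
enumeration when min(n₁, n₂) ≤ 12 and the data are tie-free, otherwise the
normal approximation with midranks, tie correction and a 0.5 continuity
correction (screen cohorts have n ≥ 70, squarely asymptotic; the published
analysis does not state whether a continuity correction was used — using one
is the conservative choice). p-values are computed through
`scipy.stats.mannwhitneyu`; the test suite cross-checks the exact branch
against an independent full-enumeration oracle. A strain is **long-lived**
iff its percent change is positive and p < α (default 0.05, raw p-values, no
multiple-testing correction — the only rule that reproduces the published
9-of-14 count), **short-lived** for negative change with p < α, otherwise
unchanged.

The published screen table is bundled (`riboupr.datasets`) as printed:
re-deriving percent change from the printed means reproduces the printed
value for 15 of 16 strains; the ero1-DAmP row is internally inconsistent
(27.7 recomputed vs 28.1 printed, presumably rounding of unprinted means).
The package reports the recomputed value and keeps the row flagged in its
tests rather than matching the printed cell.

## Synthetic data

The study's raw sequencing and per-cell lifespan data were not deposited, so
the generators stand in for them with known ground truth (always emitted as
a sidecar table so tests never re-infer the design).

* **Genome**: non-overlapping genes on both strands of one synthetic
  chromosome; spliced-CDS lengths are multiples of 3; designated genes carry
  one interior intron (placed past the 5′ third so junction reads clear the
  trim zone); designated homolog pairs share a tag and their simulated reads
  are emitted as 2-hit multi-mappers.
* **Counts**: negative binomial with a single shared dispersion
  (variance = μ + φμ²). Nothing is stated about count noise in this assay;
  NB is the field-standard minimal overdispersion model. The default
  φ = 0.01 reflects the near-unity replicate correlations typical of yeast
  ribosome profiling. Footprint counts are generated conditionally on the
  same latent mRNA abundance as the mRNA counts, so TE is the only
  translational degree of freedom — mirroring the footprint/mRNA definition
  of TE. Default depth is 5×10⁶ reads/sample, a typical yeast library scale;
  the end-to-end pipeline demo uses 2×10⁴ so that per-read alignment
  simulation stays fast.
* **Alignments**: one record per counted read, 5′ ends uniform over the
  trimmed spliced CDS; configurable fractions land in the 5′ trim zone or are
  multi-mapped. For intron genes each read derives from the spliced transcript
  (junction-spanning split record) with the configured probability, else from
  the unspliced precursor (contiguous, 5′ end in the intron) — a binomial
  mixture, so the junction estimator's error shrinks as 1/√n.
* **Lifespan cohorts**: division counts are a discretised gamma matched to
  (mean, shape). Only means and cohort sizes are published, so any unimodal
  non-negative family is admissible; gamma gives independent control of mean
  and spread. Default shape 7 ≈ (26/10)², matching the ≈26 ± 10 division
  spread of wild-type BY4741 cohorts.

What the generators do **not** emulate: nucleotide sequences, sequencing
error, rRNA/adapter contamination, library-prep and positional bias within
genes, codon-level periodicity, and mortality curves more complex than a
two-parameter unimodal family. Passing recovery tests therefore demonstrates
the correctness of the quantification rules under the stated generative
model, not robustness to every artefact of real libraries.

A property worth knowing when interpreting recovery results: rpkm is
compositional. Planting a 2-fold TE increase in 50 of 1,000 genes inflates
the footprint library total by a few percent, which shifts every null gene's
apparent log2 TE change slightly negative (≈ −0.07 at the default design)
and costs the planted genes the same margin. At the default dispersion the
recovery scenario (2 replicates, 5×10⁶ depth) detects ≈ 94% of planted
genes on average with < 2% false flags; individual simulation seeds can land
a few points either side of that.

## Pipeline and determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; per-stage sub-seeds are derived with
`numpy.random.SeedSequence` and kept below 2³¹. Reports and manifests carry
no timestamps, so a config and seed reproduce a byte-identical bundle. The
manifest records a SHA-256 hash of all parameters (changing any threshold or
seed changes the hash), plus per-stage record counts from which the
conservation invariants can be audited without re-running.

Problem sizes for the bundled demo configuration — 150 genes, 2 replicates ×
4 conditions at 2×10⁴ reads/sample, cohorts of 300 mothers — were chosen so
a full end-to-end run completes in seconds while every regulated set and
screen call remains non-trivially populated.

## Known limitations

* One intron per gene in the alignment simulator and junction classifier
  (the HAC1 case); multi-intron genes are rejected explicitly.
* Whole-transcript (UTR-inclusive) counting is not implemented, only
  CDS-based counting with the trim.
* The screen's exact rank-sum branch enumerates only tie-free samples;
  integer division counts always tie, so real cohorts use the asymptotic
  path (appropriate at n ≥ 70).
* Fold-change classification has no error model; near-threshold calls are
  sensitive to depth, as the directional-balance tests document.
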