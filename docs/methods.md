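# Methods

`cnvpop` implements a population-scale, read-depth workflow for copy-number
variation: window depths are normalized to diploid copy numbers, merged into
copy-number-variable regions (CNVRs), genotyped by 1-D clustering, annotated
against a gene model, and compared across populations by PCA and the V_ST
differentiation statistic. A synthetic cohort generator with a known truth
set makes every stage testable without sequencing data.

## Depth model and normalization

The unit of analysis is a fixed-size window (default 800 bp) tiled at a step
of the window size or half of it (default 400 bp, i.e. half-overlapping
windows). The raw observation is the read count per window per individual.
Under a pure read-depth model the expected count is proportional to

    E[count] ∝ depth · (copy number / 2) · gc_bias(GC),

so normalization has to remove two nuisance factors, per individual:

1. **GC bias** — counts are grouped into GC bins (default width 0.01, bins
   with fewer than 20 windows pooled with their nearest neighbour) and each
   bin is rescaled so its median equals the individual's global median. This
   binned-median correction inverts any multiplicative, smoothly varying
   bias without assuming its functional form, and because it uses medians it
   is insensitive to the minority of windows that carry real CNVs.
2. **Depth of coverage** — each individual's counts are divided by their
   median over unmasked windows and multiplied by 2, anchoring the diploid
   state at copy number 2. The full chain is exactly invariant to scaling
   any individual's counts by a positive constant.

A quantile mask (`mask_windows`) can exclude windows whose cross-sample
median count is extreme, as a window-level stand-in for the read-level
repeat/mappability handling that alignment-based callers perform upstream.
**Masking is off by default** (`low_q=0`, `high_q=1`): in a cohort without
alignment artifacts both tails of the median distribution are real biology —
the low tail is exactly where high-frequency deletions live and the high
tail is where high-frequency duplications live — and masking them fragments
true CNVRs. On real cohorts, where collapsed repeats inflate the high tail,
`high_q≈0.995` is a reasonable setting.

## CNVR discovery and genotyping

Candidate windows follow the standard population-caller rule with parameters
`f` (minimum deviant-individual fraction, default 0.1), `h` (minimum
deviant-individual count, default 3): a window is a candidate iff
`max(n_loss, n_gain) ≥ max(h, ceil(f·n))`, where an individual is a loss at
copy number ≤ 1.5 and a gain at ≥ 2.5 (the midpoints between the diploid
state and single-copy loss / single-copy gain).

Candidates are merged by scanning each chromosome in order: the next
candidate extends the current region iff its gap is at most `max_gap`
window-steps (default 1) **and** the Pearson correlation between the two
windows' copy-number vectors is at least `r` (default 0.1) — the correlation
requirement keeps accidental neighbours carried by different individuals
apart. Regions require at least `min_windows = 2` candidate windows: with
half-overlapping windows any real event at least one window long spans two
windows, while isolated single-window excursions are almost always noise
(at the default noise level a window clears the deviant-count rule by chance
at ~10⁻³–10⁻², which across 25,000 windows would otherwise dominate the
call set; demanding two *adjacent, correlated* candidates squares that
probability).

Each region is genotyped on the per-individual **mean** copy number over its
windows (regions are short, so the mean preserves dosage better than a
median over a handful of windows). 1-D k-means is run for k ∈ {2, 3} with
deterministic quantile-spaced initial centers (single run, 300 iterations,
tolerance 1e-6); the k with the larger mean silhouette wins, ties to the
smaller k. Cluster centers below 1.5 label their members "loss", above 2.5
"gain"; the region kind is deletion / duplication / both according to the
deviant classes present. The silhouette is computed with absolute distances;
points in singleton clusters contribute 0, and a region whose values cannot
support any k (fewer distinct values than every candidate k) gets silhouette
−1. Retained CNVRs must have silhouette strictly greater than 0.6, length
≤ 50 kb for deletion/both regions, and length strictly < 500 kb for
duplications.

## Annotation

Each CNVR gets exactly one feature category from its overlaps with a gene
model (GFF3 or BED12; GFF3 is 1-based inclusive on disk and converted to the
package's 0-based half-open convention on read), resolved by the
conventional precedence

    exonic_and_splicing > exonic > splicing > ncRNA_exonic > UTR5 > UTR3 >
    ncRNA_intronic > intronic > upstream_and_downstream > upstream >
    downstream > intergenic.

"Exonic" means overlap with the translated part of a coding exon; UTRs are
untranslated exon parts 5′/3′ of the CDS, strand-aware; "splicing" is an
intronic overlap within 2 bp (configurable) of an exon boundary; flanks are
1 kb strand-aware. The precedence resolution is independent of transcript
order by construction. Set-level summaries (length histogram with half-open
bins, per-chromosome counts and total bp by kind, category fractions) are
plain tallies.

## Population structure

PCA operates on the individuals × CNVRs matrix of per-CNVR mean copy
numbers, restricted to the deletion ({deletion, both}), duplication
({duplication, both}), both-only, or combined subsets. Columns are
mean-centered and by default variance-standardized (zero-variance columns
dropped with a recorded count, echoing SNP-style normalization); the
decomposition is a full SVD, and each component is oriented so its loading
vector sums non-negative, making coordinates reproducible across platforms.
With identical rows the result is defined as all-zero coordinates rather
than an error.

## V_ST scan

For one CNVR and two populations with copy-number values a and b,

    V_ST = (V_T − V_S) / V_T,

where V_T is the variance of the pooled values and V_S the
population-size-weighted mean of the within-population variances. Variances
use the population denominator n (ddof = 0): this makes the size-weighting
exact — pooling two identical distributions gives V_T = V_S and V_ST = 0
identically — and the unbiased n−1 variant is exposed as an option. A
monomorphic CNVR (V_T = 0) is defined to score 0, so invariant regions do
not poison the outlier quantile, and negative values are reported as
computed. V_T is assembled from per-group moments so that the statistic is
bit-for-bit symmetric in its arguments.

Outliers are records at or above the (1 − q) linear-interpolation quantile
of the V_ST distribution, default q = 0.01 (top 1%), applied per population
pair; ties at the threshold are all included, ranks are assigned by
descending V_ST with genomic-order tie-breaks. Outlier CNVRs map to genes by
any ≥ 1 bp overlap with transcript bodies (flanks excluded), deduplicated
per pair with each gene's best V_ST.

## Synthetic cohorts

The generator emulates the window-level footprint of a multi-population
resequencing cohort; its defaults are the package's study conditions:
2 populations × 20 individuals, one 10-Mb chromosome, 800-bp windows at
400-bp step, 12× mean depth, 50 implanted events of 2–50 kb.

* **Reference GC** — a stationary AR(1) chain (lag-1 correlation 0.98,
  mean 0.42, sd 0.05) reflected into [0.30, 0.55]. Mammalian windows are
  AT-rich and sit mostly below the coverage optimum, so the realized
  depth–GC relation is predominantly monotone, as in real libraries.
* **Events** — non-overlapping deletion/duplication alleles with
  coordinates snapped to the window step (the truth track is
  window-granular), each segregating at a per-population allele frequency.
  Carrier frequencies convert to allele frequencies via 1 − √(1 − cf).
* **Genotypes** — each individual draws Binomial(2, freq) allele copies per
  event; the copy-number track is 2 + Σ(alleles · copy_change), floored at
  0 (a homozygote for a −2 allele cannot go negative).
* **Counts** — negative binomial with mean
  `mean_depth · window_size / read_length · (cn/2) · gc_bias(gc)` and size
  `dispersion` (variance = μ + μ²/size; `inf` gives the Poisson limit).
  Defaults `read_length = 100` and `dispersion = 300` give a per-window
  copy-number standard deviation of ≈ 0.23 at the diploid state. These are
  engineering choices fixed by a pre-implementation power analysis: they
  keep single-window false candidates rare (so two adjacent correlated false
  candidates are rarer than ~1 per genome) while leaving heterozygous
  carriers detectable per window with probability near 1 — i.e. mild
  overdispersion typical of PCR-free short-read libraries.
* **GC bias** — multiplicative factor `clip(1 − a·((gc − 0.5)/0.2)², 0.1, 1)`;
  `a` is the fractional depth loss at |GC − 0.5| = 0.2. Default amplitude
  0.2; the GC-stress checks use 0.4, under which the uncorrected
  copy-number–GC Spearman correlation exceeds 0.3.

A second, CNVR-level generator (`simulate_cnvr_cohort`) skips the window
machinery and draws per-CNVR mean copy numbers directly (carrier draws plus
Gaussian noise, sd 0.15), for differentiation-scan and stratification
studies where window detail is irrelevant.

**What the generator does not emulate:** mappability and repeat structure
(no artifact windows, hence masking defaults off), correlated counts between
overlapping windows (adjacent windows draw independently, which makes the
two-window region requirement slightly conservative relative to real data),
linkage between events, sex chromosomes, and reference errors. Passing the
recovery checks therefore demonstrates the statistical machinery under a
clean read-depth model, not robustness to alignment artifacts.

## Numerical and interface conventions

* Coordinates are 0-based half-open everywhere internally and in BED-like
  output; GFF3 converts on read/write.
* All scaling statistics are medians; all randomness flows from explicit
  integer seeds through `numpy` generators, and reruns are bit-identical
  (the pipeline manifest records SHA-256 checksums of every output).
* Floats serialize at `%.17g` and parse with round-trip precision, so
  write/read cycles are exact.
* Boundary resolution is quantified in window steps; with half-overlapping
  windows the truth track is window-granular, so one step is the intrinsic
  quantization limit of the representation.

## Known limitations

* Absolute integer copy numbers beyond the three genotype classes are not
  estimated; a CN-4 homozygous duplication and a CN-3 heterozygote both
  read "gain".
* The quantile mask is a crude surrogate for read-level repeat handling;
  results in repeat-dense regions of real genomes will differ from callers
  that operate on alignments.
* No kinship handling before V_ST: all individuals are treated as
  unrelated, as no pruning procedure is defined for the statistic.
* The top-1% cutoff is applied per population pair, not pooled across
  pairs.
* Pathway/GO enrichment of outlier genes is out of scope; the pipeline
  stops at the per-pair outlier gene table.
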