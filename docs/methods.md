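# Methods

## Problem and model

High-throughput sequencing count data carry a technical-noise floor: below
some abundance, the number of reads assigned to a gene in a sample is
dominated by stochastic sampling and mis-assignment rather than by the
underlying transcript concentration. The operational signature of this floor
is the loss of *cross-sample reproducibility*: above it, relative abundances
of a gene agree between samples of the same experiment; below it, they are
essentially independent draws.

`denoiseq` turns this signature into a per-sample abundance threshold
θ<sub>j</sub>. Two detectors estimate the abundance–similarity relation:

**Count-matrix approach.** For the sample of interest *j*, genes are sorted
by descending abundance and scanned with a sliding window (length *L*, step
*s*). For each window, the similarity between the window's abundances in *j*
and in every other sample is computed and averaged with the arithmetic mean;
the window's mean abundance in *j* is the x-coordinate. Windows are always
defined on the reference sample's ordering — other samples contribute the
same gene subset, not their own ranking — so the curve reflects how sample
*j*'s quantification at a given abundance reproduces elsewhere.

**Transcript approach.** From coordinate-sorted, indexed BAM files and an
exon annotation, a positional coverage profile is built per transcript and
sample (point sum of read abundances over transcript coordinates; exons
concatenated in rank order, minus-strand transcripts reversed). The
point-to-point Pearson correlation (p2pPCC) between sample *j*'s profile and
every other sample's profile of the same transcript, averaged, plays the
role of the window similarity; the transcript's total assigned abundance is
the x-coordinate. This detector is slower but finer-grained: it sees whether
the reads are distributed *across* the transcript reproducibly, not merely
whether totals agree.

**Thresholding.** Given a similarity threshold *c*, θ<sub>j</sub> is the
abundance above which similarity consistently stays above *c*:

* line method — centered moving average (default width 5 windows) of the
  similarity ordered by ascending abundance; θ is the first window from
  which the smoothed curve never drops below *c* (condition ≥ *c*).
* boxplot methods — observations binned on log₂ abundance ranges; θ is the
  lower bound of the first populated bin from which the median
  (boxplot-median) or first quartile (boxplot-IQR) stays *strictly* above
  *c* across all populated higher bins. Empty bins are skipped, not treated
  as failures; zero-abundance observations occupy a dedicated lowest bin and
  can never raise θ.

"Consistently remains above" is formalized as a suffix condition: it must
hold at the candidate and at every populated higher-abundance window/bin.
A sample with no qualifying position gets the sentinel `NaN`
("undetermined") and is excluded — with a warning — from the threshold mean
and from the CV below; an all-undetermined configuration is an error.

**Choosing c.** *c* is scanned over a grid (default 0.05…0.95, step 0.01,
suitable for correlation measures) and the value minimizing the coefficient
of variation (population standard deviation / arithmetic mean) of the
θ<sub>j</sub> is selected; ties break toward smaller *c*. A grid value is
eligible only if at least two samples have determined thresholds. With a
sample grouping (replicates, time points), the mean within-group CV is
minimized instead. For measures with unknown output range,
`quarter_range_threshold` (min + ¼ of the observed range) provides the
first-cut value around which a grid can be placed.

**Noise removal.** A gene is removed iff its count is strictly below
θ<sub>j</sub> in *every* sample with a determined threshold — one confident
sample rescues the gene everywhere. The mean of the determined thresholds is
then added to every retained entry. The offset keeps fold-change-based
downstream methods from amplifying ratios between near-zero counts; it
preserves all pairwise entry differences exactly. Output counts are
real-valued; a `--round` flag (round-half-even) exists for integer-only
consumers. BAM filtering applies the same every-sample rule to reads: a read
is dropped only if every annotated gene it overlaps fails the rule;
unassigned reads are kept and counted.

## Similarity measures

Pearson correlation is the default; Spearman, Euclidean distance,
symmetrized Kullback–Leibler divergence, and Jensen–Shannon divergence are
registered. All measures obey one contract — larger means more similar.
Distances/divergences are inverted as 1/(1+d): defined at d = 0, bounded in
(0, 1], strictly decreasing. KL is symmetrized (½(KL(p‖q)+KL(q‖p))) so every
registered measure is symmetric in its arguments; KL and JS renormalize the
vectors to probability simplices after adding a 10⁻¹² pseudo-count, since
count windows legitimately contain zeros. Correlation measures return 0 on
zero-variance input: an all-constant (typically all-zero) window carries no
evidence of consistent signal, which is exactly the treatment noise should
get.

## Window-length selection

Defaults: *L* = round(10% × #genes), *s* = max(1, round(5% × *L*)). Two
data-driven alternatives:

* monotony — for each candidate *L*, count sign changes of successive
  differences of the similarity curve (averaged over samples; differences
  below 10⁻⁹ are treated as flat to ignore float jitter). Short windows
  oscillate; long windows flatten. The smallest candidate within a tolerance
  of the minimum count is chosen (tolerance: 10% of the minimum, floored at
  one change), favoring granularity among equally stable lengths.
* entropy/stability — pool all window similarities per candidate length;
  compare consecutive candidates with Welch's two-sample t-test on the raw
  values (the JSD of their 50-bin histograms on [−1, 1] is computed and
  logged alongside). The first candidate whose comparison with the next is
  non-significant at α = 0.05 is returned; if none, the largest candidate
  with a warning. Literally identical distributions (e.g. duplicated
  samples) short-circuit to p = 1.

## Single-cell path

Individual cells are too shallow for the window profile to leave its weakly
positive plateau, so cells are grouped into pseudo-samples — randomly
(shuffled, dealt into groups whose sizes differ by at most one; remainder
one-per-group to the earliest groups) or by a metadata key such as donor —
and summarized by per-gene arithmetic means. Thresholds are estimated on the
pseudo-sample (mean) scale; the removal decision is made there and the same
mean-threshold offset is added to the cell-level matrix. Group-level BAM
pooling is supported by passing several alignment files per sample to the
profile builder, which sums their coverage.

## Network robustness assessment

Weighted adjacency matrices from inference tools are compared across
processing variants (filtered/normalized combinations, conventionally
−F−N, +F−N, −F+N, +F+N). Off-diagonal weights are min–max rescaled to
[0, 100] for cross-tool display; binarization thresholds at the network's
own off-diagonal median (strictly above → 1, equal or below → 0), making it
invariant to affine rescaling. Self-edges are excluded from the median,
degrees, and distances. A gene's edge vector is its adjacency row with the
diagonal dropped; per-gene Hamming distances between variants count gained
or lost connections, and a Kruskal–Wallis rank test across the pairwise
distance distributions gives the global assessment. If every distance is
identical (e.g. four identical networks) the test is degenerate and reported
as "no variation" rather than a p-value.

## Synthetic data

The generators realize the statistical structure the method assumes —
nothing more:

* Noise-floor count matrix: per-gene base abundance λ log-uniform on
  [1, 2¹⁴] (spanning the dynamic range of bulk RNA-seq counts); genes with
  λ ≥ F get Poisson counts around a shared mean with lognormal wobble
  (σ = 0.1 by default — replicate-level variation), hence correlated across
  samples; genes with λ < F are independent log-uniform-Poisson draws per
  sample at sub-floor magnitudes, hence uncorrelated. Defaults (5 000 genes,
  4 samples, F = 32) are the conditions the acceptance checks run at.
* Coverage experiment: one smooth positive shape per transcript (Gaussian-
  smoothed noise, exponentiated, normalized), shared across samples; each
  sample places its assigned read count (from the depth ladder 5/50/500/
  5 000, assigned cyclically) multinomially over admissible start positions;
  fixed read length 50 on 400–500 nt single-exon transcripts. Emits valid
  coordinate-sorted SAM plus the exact pileup ground truth.
* Network variants: off-diagonal weights from two separated clouds
  (U(0, 0.2) and U(0.8, 1.0)) in equal numbers, so the median sits in the
  gap and binarization is exact; planted flips swap a low-cloud and a
  high-cloud value, preserving the weight multiset (hence the median) while
  flipping exactly two binary entries per swap — flip counts must be even.

What these generators do *not* emulate: library-size differences,
overdispersion beyond the lognormal wobble, GC/positional bias, spliced
multi-exon coverage, multi-mapping ambiguity, and single-cell zero
inflation. Passing tests therefore demonstrate that the estimators recover
designed noise structure under the model's own assumptions, not performance
on any particular real dataset.

## Numerical choices and degenerate inputs

* Descending abundance sort is stable; ties keep input gene order, so runs
  are reproducible across platforms.
* Window enumeration appends a tail window ending exactly at the last gene
  when the final stride falls short, so every gene is covered.
* Abundance bins use `digitize` on precomputed edges rather than
  floor-of-log, keeping boundary abundances in the correct bin.
* Quartiles use linear interpolation (numpy default).
* CV uses the population standard deviation.
* Undetermined thresholds are NaN sentinels throughout; any mean/CV is over
  determined values only.
* The boxplot comparison is strict (> c); the line comparison is ≥ c at the
  smoothed curve.
* Binarization maps weights equal to the median to 0.
* Degenerate guards: single-sample matrices, constant off-diagonal weight
  matrices, all-identical similarity values (quarter-range), and zero-mean
  CV inputs are validation errors, not silent results.

## Problem sizes

Default test and acceptance computations use 5 000 genes × 4 samples for
count-matrix runs, 24 transcripts × 400 nt × 3 samples for coverage runs
(plus a 4-transcript run at depth 10⁵), 20-gene networks with 100-repeat
test calibration, and ≤200×8 instances for brute-force oracle comparisons —
sizes at which the brute-force references remain exact and fast while
exercising every code path.

## Known limitations

* The transcript approach assigns a read to every transcript whose exons it
  overlaps; no NH-weighting or isoform deconvolution is attempted.
* CIGAR handling uses aligned blocks (M/=/X); clipped bases are ignored, and
  no partial-position weighting is applied.
* The similarity registry is intentionally small (5 measures); it is
  extensible via `register_measure`.
* Thresholds are per-sample, never per-gene; experiments with strongly
  heterogeneous per-gene technical behavior are out of scope.
* The offset step emits real-valued matrices; whether to offset before or
  after a downstream normalization is left to the consumer.
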