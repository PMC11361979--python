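# Methods

## Generative model of the simulator

The simulator emulates a pooled sex-contrast experiment on a sibship:
`n_males` XY (or ZW) and `n_females` XX (or ZZ/WW) diploid individuals,
sequenced as one equimolar pool per sex. Genotypes are never
materialized; the pipeline only ever observes pooled counts, so the
simulator draws pool-level quantities directly:

- **SNP placement.** Each chromosome of length L receives
  Binomial(L, `snp_rate`) distinct biallelic SNP positions (default
  rate 1/500 bp). Reference and variant bases are uniform.
- **Background sites.** A population frequency p ~ Uniform(0.05, 0.95)
  is shared by both sexes; each pool's chromosome-sample frequency is
  Binomial(2n, p)/2n for its n individuals. This reproduces the
  binomial sampling noise that makes small pools leak false
  sex-patterned SNPs.
- **Fully sex-linked sites.** Inside the SDR interval, a fraction
  `sdr_linked_fraction` (default 0.3) of SNPs is fully linked: in an XY
  system every male is heterozygous for the Y allele and no female
  carries it, so the male pool's chromosome frequency is exactly 0.5 and
  the female pool's exactly 0 *before* read sampling. ZW mirrors the
  sexes.
- **Reads.** Depth per pool per site is Poisson(`coverage`) (default
  100×); variant reads are Binomial(depth, pool frequency); each read is
  then miscalled with probability `error_rate` (default 0.002) to a
  uniformly random other base. Zero-depth sites are emitted on purpose —
  the depth filter downstream must handle them.

Defaults (23 males, 26 females, 100×, 400-kb SDR, 30% linked) are the
study conditions the package targets. The per-pool depth at SNP sites is
not separately calibrated; 100× matches the genome-wide coverage scale
of the motivating datasets.

**What the simulator does not model:** linkage disequilibrium and
recombination gradients, partially sex-linked sites (every linked site
is fully linked), reference-mapping artifacts, demography, and
chromosome-scale heterogeneity of SNP density. Passing recovery tests
therefore shows the scan detects a clean narrow SDR against exchangeable
background noise — not that it is robust to alignment artifacts or
diffuse ancient sex-linkage (see Limitations).

## Per-site scan

- **F_ST estimator.** Wright/Nei style (H_T − H_S)/H_T on the two pool
  frequencies, unweighted by depth, defined as 0 when H_T = 0 and
  clipped to [0, 1]. No named estimator is mandated for two-pool
  sex contrasts; this is the simplest choice and it is isolated behind
  `fst_site` so a depth-corrected pool estimator can be swapped in.
- **Interval conventions.** "Fixed" is strict (< 0.1); "polymorphic" is
  inclusive (0.3 ≤ f ≤ 0.7). Both thresholds are configuration
  (`ClassifyParams`), and fixation is tested for the variant allele and
  its complement, since fixation of either allele in one sex carries the
  same signal.
- **Frequencies** use the four nucleotide counts only; N and deletion
  counts are not alleles.
- **Biallelic reduction.** The two highest-count bases across both pools
  (combined) are major/variant; a third base above 10% of the site's
  depth drops the site as triallelic; ties in counts break
  deterministically in base order A, T, C, G.
- **Depth filter defaults** (≥ 10 per pool, ≤ 3× the dataset's mean
  per-pool depth) are pragmatic guards against low-confidence and
  repeat-collapsed sites, applied before classification; both bounds are
  configurable.

## Window scan

Windows are 0-based half-open 100-kb tiles; the final partial window is
kept, so window tilings always cover each chromosome exactly once. The
log2(XY:ZW) density ratio uses pseudocount c = 1 because zero-count
windows dominate genome-scale data; c is configurable. Top-percentile
selection ranks anchored windows (those on chromosome-scale sequences)
by the combined count n_XY + n_ZW and takes the ceiling of q·n windows,
labelling each selected window by its dominant pattern afterwards; an
alternative mode ranks the XY and ZW densities separately and unions the
selections. Cutoff ties break by input (chromosome, start) order so
results are deterministic.

## Chromosome tests and regions

The Kruskal–Wallis statistic is tie-corrected with midranks (the
all-observations-equal corner is defined as H = 0) and referred to a
chi-square with (groups − 1) degrees of freedom, as standard
implementations do; an exhaustive permutation oracle backs this
approximation in the test suite for N ≤ 8. Observations are the
log2 ratios of **all** anchored windows by default (a flag restricts to
the top selection). Dunn's z uses the same midranks and tie correction,
with two-sided normal p-values adjusted by Benjamini–Hochberg in a
single family over all chromosome pairs, and is only run when the
omnibus test is significant at α.

Candidate regions merge selected windows on one chromosome across at
most `max_gap` = 1 unselected window — tolerating a single
sub-threshold window inside a true SDR — and are ranked by total
patterned-SNP count; the system call is the sign of n_XY − n_ZW.

## Protein-change classification

Outgroup consensus requires unanimity (min_support = 1.0) among
species with a non-gap residue at the column; isoforms of one species
count as a single witness and any matching isoform suffices. Columns
with a disagreeing or all-gap outgroup block are skipped as not
well-conserved, which also means insertions private to X/Y relative to
the outgroups are not called. Per column with consensus c: X=Y≠c is a
shared derived change; X≠c with Y=c is X-specific (mirrored for Y); and
X≠c, Y≠c, X≠Y yields one X-specific and one Y-specific call. A gap in X
or Y against a consensus residue opens an indel event; adjacent indel
columns on the same haplotype merge into one event whose notation lists
each deleted consensus residue ("E535Del, K536Del, E537Del" style).

Substitutions are conservative when the substitution-matrix score of
(consensus, derived) is ≥ 0 under BLOSUM62; matrix and threshold are
configuration, since "non-conserved" has no single field-wide
definition, and the reporting layer records the rule used. Residue
numbering follows the ungapped X sequence; for a deletion on X the
deleted residues take the positions they would occupy in X, a
convention chosen because no universal coordinate system exists for
gapped positions.

## Numerical and degenerate-input choices

- Site tables and windows use int64 counts and float64 frequencies; all
  randomness flows through one `numpy.random.Generator` per simulation,
  making output byte-reproducible for a fixed config.
- BH adjustment is the step-up formula; note it is *not* idempotent
  (re-adjusting adjusted values re-scales them — e.g. [0.25, 1.0] →
  [0.5, 1.0] → [1.0, 1.0]), so adjusted p-values are computed exactly
  once per family.
- Empty groups, single groups, out-of-range frequencies or p-values,
  non-positive window sizes and pseudocounts, and overlapping planted
  changes all raise `ValueError` rather than propagating NaNs.

## Test problem sizes

The recovery and null suites run on a scaled-down genome of 24
chromosomes × 5 Mb (≈ 240,000 SNPs per replicate) with the full-scale
study design otherwise (pool sizes, coverage, SNP rate, 400-kb SDR,
30% linked fraction): the SDR signal is local, so shrinking the
background genome preserves the detection problem while keeping a
20-replicate recovery suite and a 40-replicate null suite fast.

## Limitations

- **Chromosome-level rank tests are insensitive to narrow SDRs.** A
  400-kb SDR elevates only ~4 of a chromosome's windows; under the clean
  generative model those cannot shift the whole-chromosome rank
  distribution, so Kruskal–Wallis (and hence Dunn) stays null even while
  window ranking and region calling recover the SDR perfectly. On real
  data these tests gain power from diffuse chromosome-wide signal
  (older linkage, mapping artifacts) that the simulator deliberately
  omits. The test suite therefore exercises KW/Dunn power on a fully
  sex-linked chromosome and treats the narrow-SDR case as what it is:
  a job for the window scan, with KW/Dunn as a chromosome-scale
  corroboration.
- Pool-frequency F_ST ignores unequal pool sizes and depth; a
  depth-aware pool-seq estimator would sharpen per-site values.
- The protein module classifies an existing alignment; alignment
  construction, gene models, and structural annotation are out of scope.
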