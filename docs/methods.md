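# Methods

methtk implements the downstream half of a two-group bisulfite-sequencing
study: per-cytosine methylation calling from aligned reads, coverage and
context filtering, group summarization, differentially methylated region
(DMR) detection, aggregation over annotation regions, and DMR–expression
correlation.  This note records the models, the numerical choices, and
the places where the design was genuinely open.

## Methylation calling

Bisulfite treatment converts unmethylated cytosine to uracil (read as T)
and leaves 5-methylcytosine intact, so methylation is read out as C-vs-T
at reference cytosines.  In a directional paired-end protocol each
fragment derives from one of the two original strands: "CT" fragments
report forward-strand cytosines (reference C; read C = methylated,
T = unmethylated), "GA" fragments report reverse-strand cytosines
(reference G; read G = methylated, A = unmethylated).  The caller takes
the protocol strand from the aligner's `XG` tag when present and
otherwise infers it from read orientation (read 1 forward / read 2
reverse → CT).

The caller walks fragments rather than pileup columns so the
overlapping part of a properly paired fragment is counted once.  This
overlap clipping is built in (`clip_overlap`, default on) rather than
delegated to an external BAM rewriter; within an overlap the mate with
the higher base quality wins and ties go to read 1, which makes the
output deterministic.  Remaining per-base rules:

* bases below `min_base_quality` (default 20) and reads below
  `min_mapping_quality` (default 10) are ignored;
* `trim_ends` (default 0) drops a fixed number of bases at both read
  ends — a blunt mitigation for positional (M-)bias at read ends in
  place of a data-driven bias model;
* deletions contribute nothing to the deleted positions; soft-clipped
  bases and insertions contribute nothing anywhere;
* secondary, supplementary and duplicate-flagged alignments are skipped
  for calling but counted in the alignment-multiplicity QC histogram;
* a read base other than C/T (CT strand) or G/A (GA strand) at a
  cytosine is uninformative: it occupies the position for overlap
  resolution but increments neither count.

Sequence context (CpG / CHG / CHH, H ∈ {A,C,T}) is read in the 5'→3'
direction of the cytosine's own strand; cytosines within two bases of a
contig end, or whose context window contains an ambiguous base, are not
emitted.  The per-position error rate reported by the mapping QC is the
aligner's `NM` mismatch count divided by aligned (M/=/X) bases over
primary alignments carrying the tag.

## Filtering

Positions are kept when `min_coverage ≤ coverage ≤ max` and the context
is allowed (default: CpG only).  "Very highly covered" positions are
usually collapsed repeats, so the default upper cutoff adapts to the
library: the 99.9th percentile of the sample's own coverage
distribution, overridable by an absolute cap.  Both bounds are
inclusive; filtering is idempotent and monotone in `min_coverage`.
Rate histograms use 100 bins over [0,1], left-closed right-open with
the last bin closed so a rate of exactly 1 is counted.

Forward and reverse records of a symmetric CpG are kept separate by
default; `destrand` optionally sums the counts of a +strand CpG at
position p with its −strand mate at p+1 into one record.

## Group summarization

The sample matrix is the union of positions across samples; an entry is
missing — explicitly NaN, never 0, because a rate of 0 is biologically
meaningful — when the sample's coverage at that position is below
`min_coverage_per_sample` (default 10).  A position enters the group
summary only if each group has at least `min_samples` covered samples
there.  Group means are unweighted means of the available sample rates;
coverage-weighted means would down-weight exactly the samples the
coverage gate was designed to protect, but are a reasonable variant.
The difference signal is mean(group 1) − mean(group 2), so swapping the
group labels negates it exactly.

Sample clustering uses complete linkage on Euclidean distance computed
over the positions each pair of samples shares; pairs sharing fewer
than two positions have undefined distance and such samples are
excluded from the tree with a warning.  No imputation is performed.
The genome-wide view is a per-sample binned mean-rate table (default
bin 1 Mb), a plain-text equivalent of a genome-wide heatmap.

## Annotation aggregation

A region × sample cell is the mean of the sample's defined rates at
positions inside the region (BED 0-based half-open overlap).  Cells
with fewer than `min_positions` (default 3) contributing positions are
withheld: a 1-CpG region mean is noise-dominated.  Overlapping regions
are scored independently, so one position may serve several regions.
Row/column clustering of the heatmap reuses the complete-linkage
Euclidean metric, with pairwise-complete comparison when cells are
missing.  Because the question "per-region means pooled over samples,
or per-sample means pooled over regions?" has two defensible answers,
both tables are emitted.

## DMR detection

The difference signal is first cut into windows at gaps larger than
`max_gap` (default 300 bp): methylation is spatially correlated only
over short distances, so distant positions carry no evidence about one
another.  Within a window, segmentation follows the circular-binary-
segmentation idea on a linear signal: the contiguous sub-interval of at
least `min_cpg` positions whose mean difference deviates most (in
absolute value) from the window mean is selected — on a linear signal
searching all contiguous sub-intervals is equivalent to the circular
formulation.  The recursion accepts the split and descends into the
selected segment and its flanks while a two-sample two-dimensional
Kolmogorov–Smirnov test between the groups' per-position rates improves
(p decreases) relative to the enclosing window; when improvement stops,
the current window is a terminal candidate.  Ties in segment selection
are broken leftmost-then-shortest, making the output deterministic.

Each candidate is scored twice:

* **Mann–Whitney U**, two-sided, comparing the per-position group-mean
  vectors.  For combined n ≤ 20 the exact permutation distribution of
  the rank sum is computed by a shift-algorithm dynamic program over
  doubled midranks, which handles ties exactly; larger candidates use
  the normal approximation with tie correction (no continuity
  correction — in the n > 10-per-group regime this branch serves, the
  uncorrected statistic tracks the exact p more closely across the
  whole p range; relative accuracy degrades in the extreme tail, as for
  any normal approximation).
* **2-D two-sample KS** on the point sets {(position rank, group mean
  rate)}, using the quadrant statistic averaged over both samples'
  points as origins and the classical correlation-corrected asymptotic
  significance.  Zero-variance coordinates get correlation 0.

One designated p keeps the false-discovery semantics clean:
Benjamini–Hochberg correction is applied to the Mann–Whitney p across
all candidates genome-wide (the 2-D KS p is reported alongside).
Reported DMRs satisfy q ≤ `max_q` (default 0.05), |mean difference| ≥
`min_diff` (default 0.1), at least `min_cpg` positions (default 10) and
optionally a minimum length in nt.  The defaults mirror common WGBS
screening practice and are all exposed.

Selection bias is inherent to segmentation-then-test procedures: the
tested intervals were chosen to look extreme.  The effect-size filter
and the BH step keep the genome-wide false discovery rate controlled in
practice; the null-simulation test measures exactly this (50 replicates
of 4 vs 4 samples over ~10,000 CpG positions with no planted
difference, empirical FDR within binomial error of the nominal 0.05).

## Correlation with expression

For each user-supplied (DMR, gene) pair, per-sample DMR methylation is
the mean of the sample's rates over the DMR's positions (missing when
fewer than 2 positions are covered), correlated with expression over
the samples present in both data sets.  Pearson r is the linear
coefficient; Spearman rank correlation is the "non-linear" coefficient
— the standard monotone-invariant choice.  Pairs with fewer than 3
usable samples, or a zero-variance vector, are flagged and their
coefficients withheld rather than propagated as NaN.  A pair is a
correlating DMR (cDMR) when max(|r|, |ρ|) ≥ 0.8; with the handful of
samples typical here, coefficients are reported without p-values.

## Synthetic data

The generator emulates a small case-control WGBS study — two groups of
four samples, the shape of the workflow's intended use — with known
truth at every level.

* **Reference**: random sequence with CpG dinucleotides planted at a
  controlled per-step density (default 0.02, one CpG per ~50 bp — the
  CpG-rich end of genomic sequence, chosen so a 255 kb reference yields
  ~10,000 CpG positions); accidental CpGs are suppressed so the density
  knob fully controls CpG content.
* **Baseline rates**: bimodal, like mammalian CpG methylation — 70%
  high (Beta(9,1)), 20% low (Beta(1,9)), 10% uniform.
* **Counts**: coverage ~ Poisson(30); n_meth | coverage ~ beta-binomial
  with intra-class correlation `dispersion` (default 0.1, mid-range for
  WGBS replicates).  Var(rate | coverage c) = p(1−p)(1+(c−1)ρ)/c, which
  the moment tests check in closed form.
* **Planted DMRs**: default 20 non-overlapping runs of 10 consecutive
  CpGs with group difference δ = 0.5, alternating sign.  DMR baselines
  are redrawn uniformly from [δ/2, 1−δ/2] so the ±δ/2 shift never clips
  at 0 or 1 and the planted effect size is exact.
* **Reads**: paired-end fragments (default 160 bp, 80 bp reads) from a
  random bisulfite strand; each cytosine's state is sampled once per
  fragment so overlapping mates agree; conversion failures and uniform
  substitution errors are parameterized; output is a sorted, indexed
  BAM with flags, mates, `NM` and `XG` tags.
* **Expression**: linked genes follow a + b·methylation + N(0, σ) with
  the planted sign on b (defaults a = 5, |b| = 4 keep expression
  positive without clipping); unlinked genes are independent noise.

What the generator does **not** emulate: positional M-bias along reads,
adapter contamination and realistic error profiles, SNPs (a C→T variant
is indistinguishable from conversion without SNP-aware calling),
non-uniform fragment coverage, and long-range correlation of
methylation beyond the planted blocks.  Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
robustness to these real-data artifacts.

All randomness flows through `numpy.random.default_rng` with explicit
integer seeds; fixed seeds make every simulation reproducible across
platforms.

## Problem sizes used by the test and acceptance runs

The packaged benchmarks run on a 255 kb single-chromosome reference
(~10,000 CpG positions), 4 vs 4 samples at coverage 30: large enough
for the FDR and recovery statistics to be meaningful, small enough to
iterate on.  Null FDR uses 50 count replicates over one fixed
reference; recovery uses 20 planted DMRs at δ = 0.5.  Read-level checks
use a 6–12 kb reference with a few thousand fragments.

## Known limitations

* Two-group designs only; no covariates, no paired designs.
* The exact Mann–Whitney branch is limited to combined n ≤ 20; beyond
  that the normal approximation's tail accuracy is the usual limit.
* The 2-D KS significance is asymptotic and approximate for n ≲ 20 per
  group; it steers the recursion and is reported, but the designated
  inferential p is the Mann–Whitney one.
* Pipeline `--threads` parallelism is not implemented; stages are fast
  at the intended scale and run serially regardless of the flag.
* bigWig export is optional (extra dependency); bedGraph is canonical.
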