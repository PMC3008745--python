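# Methods

This note records the models, parameter choices and numerical decisions
behind `exosnv`, and what the synthetic experiments do and do not
demonstrate about real tumor exomes.

## Read-sampling model of the generator

Each simulated site is an independent candidate position with a true
normal genotype (reference-homozygous, heterozygous at rate
`heterozygosity_rate`, alternate-homozygous at a Hardy-Weinberg-like
`(het/2)²` default) and an optional somatic event planted only at
germline-reference sites at rate `somatic_rate`.  Somatic events are
heterozygous in the tumor-cell population, so their expected allele
fraction is `0.5 × tumor_purity`; purity defaults to 0.8, matching the
dissection target of > 80% tumor cell content that the pipeline assumes
upstream.

Per-site coverage is Poisson around the configured mean (default 20, the
regime the rule thresholds were designed for).  Given coverage `c` and
allele fraction `f`, variant-supporting reads are Binomial(c, f);
reference-drawn reads convert to the site's designated alternate allele
with probability `error_rate` (default 10⁻³).  This folds the three
possible erroneous bases into the one alternate allele under test, so it
is a conservative (upper-bound) error model at the site level.  Strands
are assigned per read with probability 0.5.  Per-read qualities follow a
two-point low/high mixture (Q15/Q35, 90% high) — chosen only so that
both the strand-count and the quality branch of the caller are exercised;
no claim is made about real quality distributions.  The per-site maximum
alternate quality is drawn from the closed form
`P(all low) = (1 − p_high)^alt` rather than by materializing reads.

The MSI and MSS presets fix somatic rates of 0.008 and 0.001 per site.
The 8 : 1 ratio is the biologically meaningful quantity (hypermutation
of mismatch-repair-deficient tumors); the absolute values are desk-scale
so that cohorts of 10⁴–10⁵ sites yield somatic counts large enough for
stable statistics.  Real per-base somatic rates are orders of magnitude
smaller and would need genome-scale site counts.

What the generator deliberately does **not** model: alignment and
mapping artifacts, indels (excluded from the analysis by design),
strand bias, overdispersed coverage, linked errors at homopolymers
(homopolymer context is simulated or taken from the reference, but
errors stay independent), tumor subclonality, and contamination of the
normal.  Passing tests therefore demonstrate the correctness and the
statistical behaviour of the decision rules under their stated model,
not performance on real reads.

## Calling and classification

The caller implements: coverage strictly greater than 10, and (≥ 3
variant reads with both strands represented) OR (best supporting quality
strictly over 20, or strictly over 30 when a homopolymer run of ≥ 5
bases contains or is adjacent to the site).  Open choices and their
resolutions:

* the quality branch requires at least one supporting read
  (`quality_branch_min_reads`, configurable);
* "coverage > 10×" and "quality over 20/30" are read as strict
  inequalities; the boundary cases are pinned by tests;
* a single per-site `max_alt_quality` stands in for read-level
  qualities, which the rule text never resolves further.

The bimodal classifier keeps tumor calls with VAF ≥ 15% (inclusive
boundary, configurable), then labels each call by the matched normal:
coverage < 5 → undetermined, ≥ 5 with any variant read → germline,
≥ 5 with none → somatic.  A separately stated rule for coverages above
30-fold ("one variant read accepted") is redundant under this reading
and is implemented as the single rule; sites absent from the normal
pileup count as coverage 0 and are never called somatic.  The design
goal is minimizing false somatic calls, so every ambiguity fails toward
non-somatic.

`benign_false_negative_rate(c, f) = (1 − f)^c` is the closed-form miss
probability used to justify the 5× cutoff (0.5⁵ ≈ 3.1% < 10%).

## Consequence annotation

Interchange files are 1-based inclusive; internal intervals are 0-based
half-open, converted once at the I/O boundary.  Variants are annotated
against every overlapping transcript and never collapsed at this layer;
downstream consumers use a fixed severity order (nonsense > start_lost >
stop_lost > missense > splice_site > utr5 > utr3 > mirna > synonymous >
intronic > intergenic) to pick one class per variant.  The splice window
is the 2 intronic bases flanking each exon (configurable; the underlying
workflow never states its window).  Any change in the first codon is
start-lost since ATG is the unique methionine codon.  Codon extraction
reverse-complements on minus-strand transcripts; translation uses the
standard genetic code via Biopython.

## Prioritization cascade

Stage order: impact-class gate → population-frequency filter (keep
absent-from-table or frequency < 0.01; strict, since entries at or above
1% are known polymorphisms) → damaging filter (≥ 1 of two predictors by
default, both in `all` mode) → conservation stage (score ≥ 2.0
inclusive; the threshold can also be derived as the 0.975 empirical
quantile of the score table, linearly interpolated) → expression stage
(genewise mean across samples ≥ first quartile of those means,
inclusive).  Conservation and expression are real stages by default
because the reported narrowing treats them as successive cuts; both can
be switched to reporting-only.  Category/catalogue memberships are
always flags, and the categorized count is reported without filtering.
Missing annotations fail closed (variant dropped, warning logged),
consistent with the false-positive-minimizing design.

## CNV segmentation

Counts are scaled to equal library totals before the log2 ratio, bins
with a zero count on either side are masked, and the median of unmasked
ratios is subtracted so copy-neutral sits at 0.  Changepoints come from
recursive *circular* binary segmentation: the statistic is the best
contiguous arc versus its complement,
`|mean(arc) − mean(rest)| / sqrt(1/d + 1/(n−d))`.  A single-boundary
(prefix/suffix) split statistic was evaluated first and rejected: an
amplification in the interior of a chromosome is nearly invisible to one
boundary, and recovery of planted 20-bin segments dropped to ~78%,
versus ≥ 95% for the arc statistic.  The segment standard deviation is
permutation-invariant, so it cancels from the permutation test and is
omitted from the statistic.  Significance is a seeded permutation test
(default alpha 0.01, B = 1000, drawn in chunks with early rejection once
the exceedance budget is spent); minimum segment length is 3 bins; both
arc boundaries are introduced at once and the three resulting pieces are
re-tested recursively.

The ± 2 SD gain/loss rule estimates the SD from bin-level residuals
around segment means, robustly via MAD × 1.4826 by default (plain SD
available), because the rule's reference distribution is otherwise
unspecified; the robust choice keeps single outlier bins from inflating
the threshold.

## Concordance evaluation

Eligibility is array p-value strictly < 0.1 and sequencing coverage
strictly > 3.  The diploid genotype caller used for the comparison maps
alternate-allele fractions < 0.15 to reference-homozygous, > 0.85 to
alternate-homozygous, and het between — a documented stand-in, since the
upstream workflow never specifies its diploid caller.  Zero-denominator
rates are reported as 0.  Haploid concordance recodes het to
alternate-homozygous on both sides, so it can never fall below diploid
accuracy.

## Problem sizes and determinism

Simulation-backed tests use 1.5 × 10³ – 10⁵ sites, 100-replicate CNV
experiments on 300-bin profiles, and two-patient cohorts of 3–4 × 10⁴
sites — sizes at which the binomial/Poisson oracles have tight error
bands while a full suite run stays in the tens of seconds.  Every source
of randomness flows from `numpy.random.default_rng` seeded with the
config seed plus a per-generator tag, so each generator is independently
reproducible and full pipeline reruns are byte-identical (no timestamps
enter any artifact; the manifest records content hashes).

## Known limitations

* The generator's independence assumptions (sites, reads, errors) make
  every oracle exact but understate the correlated failure modes of
  real sequencing.
* The annotation layer handles substitutions only; indel consequences
  are out of scope by design.
* The CNV path has no GC correction, no allele-specific state, and no
  purity/ploidy adjustment; states are relative to the median-centered
  baseline.
* Somatic classification deliberately refuses zygosity statements; the
  somatic label means "no variant evidence in an adequately covered
  normal", nothing stronger.
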