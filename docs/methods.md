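# Methods

## Coordinate conventions

All genomic coordinates are 0-based, half-open (BED convention). Two
intervals overlap iff each starts before the other ends; abutting
intervals do not overlap. The TSS of a minus-strand transcript is its
`txEnd` and its TES is `txStart`. TSS windows are 2 kb and TES windows
4 kb, centered on the anchor and clamped at chromosome position 0
(a clamped window is shorter, never shifted).

## Non-redundant gene list

Gene clusters on chrM or `*_random` scaffolds, and clusters without any
RefSeq-linked isoform, are discarded. Within a cluster, one isoform per
time point is chosen by a cascade, each step applied only to the
survivors of the previous step's tie:

1. strict maximum of RNAPII-S5p reads in the TSS window;
2. strict maximum of RNAPII-S2p reads in the TES window — *optional*:
   S2p libraries are often unavailable, and when no S2p counts are
   supplied the cascade skips to step 3;
3. the uniquely flagged canonical isoform (the isoform with the most
   coding bases);
4. a seeded random draw. Survivors are sorted lexicographically before
   the draw and the generator is keyed on (seed, cluster, time point),
   so the "random" step is reproducible and invariant to input row
   order. If several survivors carry the canonical flag (inputs may
   violate uniqueness), the draw is made among those; if none does,
   among all survivors.

## Promoter positivity and the eight states

A promoter is positive for a mark at a time point when

1. its TSS window intersects an enriched region for that mark, and
2. its window read count is above a threshold.

The threshold is the 5th percentile (linear interpolation between order
statistics) of the window counts of *all overlapping* promoters for
that (mark, time point) — computed independently per mark and per time
point, so library-depth differences never leak across data sets. "Above"
is strict (`count > threshold`) by default and configurable to
inclusive; the two differ only at exact-threshold ties. The strict
reading also gives the tail cut a clean interpretation: promoters that
touch an enriched region but hold no more reads than the bottom 5% of
overlapping promoters are discounted as spurious overlaps.

Two geometric filters then set ambiguous positives to NA, in order and
with snapshot semantics (NA sets are computed from the incoming calls
and applied at once, which makes each filter idempotent):

* **window overlap** — positive TSS windows of different genes
  overlapping by more than 200 bp (10% of the window). Both genes are
  removed by default; a `lower_count` policy that keeps the
  stronger-signal gene is available.
* **internal gene** — a positive gene whose body lies entirely within
  another positive gene's body is removed (the internal gene only).

The (H3K27me3, S5p, S7p) status triple then maps through an exhaustive
truth table to Active (−,+,+), Inactive (−,−,−), PRC Only (+,−,−),
PRC/S5p (+,+,−), PRC/Active (+,+,+), PRC/S7p (+,−,+), S5p Only (−,+,−)
or S7p Only (−,−,+). Any NA status yields state NA, and a gene NA for
any mark at any time point is excluded from every downstream analysis.

## Trajectory groups

With the five states of a gene ordered in time, H3K27me3 positivity
flags define: Maintained (positive everywhere), Lost (positive at the
first time point but not everywhere), Acquired (negative at the first
time point, positive later), NeverPRC (never positive). A gene that
loses the mark and regains it later (without holding it everywhere)
counts as Lost — the unique reading under which
|Maintained| + |Lost| = first-time-point positives and, adding
|Acquired|, the genes positive anywhere; both identities are enforced
by property tests. Acquired genes are further split by first
acquisition time point and by whether the mark persists to the end
(retained) or not (transient). Genes starting as PRC/S5p are tracked to
their final state, with "Always PRC/S5p" flagging genes poised at every
time point.

## Expression analyses

* z-scores standardize each gene's TPM row across the five time points
  using the sample standard deviation (ddof = 1; configurable to
  population sd — at n = 5 the 1.75 cut is sensitive to this choice,
  so it is explicit). Rows constant up to floating-point cancellation
  (sd ≤ 1e−12 × the row's magnitude) are flagged degenerate and return
  zeros.
* Peaking genes: z > 1.75 in exactly one time point (multi-peak rows
  are not single-time-point peaks) and > 1 TPM somewhere. The one-spike
  pattern with four equal off-peak values has z = 4/√5 ≈ 1.789
  regardless of scale, which is how the synthetic generator plants
  unambiguous peaks.
* log-TPM uses a pseudo-count of 1e−4, mapping 0 to −4.
* Knockout derepression: fold change = KO / max(WT, 1e−6) — the epsilon
  floor keeps genes silent in wild type callable without dividing by
  zero — with upregulation iff FC > 2 and KO > 1 FPKM. Per-state
  fractions exclude repressed-state genes (PRC/S5p, PRC Only, Inactive)
  already expressed > 1 FPKM in wild type from numerator and
  denominator, since their promoter state cannot match the expression
  data.

## Genomic features

* H3K27me3 breadth is the full length of the longest enriched region
  overlapping the TSS window (0 when none; log plots conventionally add
  a pseudo-count of 1).
* GC content excludes N bases from the denominator (assembly gaps would
  otherwise bias promoters near contig edges); configurable.
* CpG-island coverage merges islands before measuring, so overlapping
  annotations are not double-counted.
* Metagene profiles average coverage in non-overlapping 10-bp bins over
  ±5 kb windows centered on TSS or TES anchors; minus-strand windows
  are reversed so bins run 5′→3′, and bins extending past a chromosome
  end are dropped from that gene's contribution.
* DMVs: hypomethylated regions are proximity-clustered by transitive
  merging at gap ≤ 1 kb (the clustering distance is not a settled
  community constant, so it is an explicit parameter), then filtered at
  length ≥ 5 kb (inclusive — a 5,000-bp valley passes; both knobs are
  configurable). DMV *territory* is monotone: non-decreasing in the
  merge gap, non-increasing in the length cutoff (interval counts may
  drop when valleys fuse, so counts are not the monotone quantity).
* Promoter methylation class: DMV if the TSS window overlaps a DMV,
  else hypomethylated if it overlaps any HMR, else methylated.

## Enrichment statistics

* Hypergeometric tests are one-sided with both directions reported
  (`p_enrich` = P(X ≥ k), `p_deplete` = P(X ≤ k)); no multiple-testing
  correction is applied across states.
* Influence ranks (lower = more influential for driving a cell-type
  conversion) are averaged per TF across conversions into the target
  cell type.
* Preranked GSEA: the ranking score is `max_rank − rank + 1` so highly
  influential TFs sit at the top of the list. The running sum
  increments by |score|^p (p = 1 by default; p = 0 gives the
  Kolmogorov–Smirnov form) normalized over set members at hits and
  decrements by 1/(N − m) at misses; ES is the signed maximum
  deviation. The null distribution draws random gene sets of the same
  size (label permutations — the only scheme available for preranked
  input), 1,000 by default; NES divides ES by the mean |null ES| of the
  same sign, and FDR follows the standard pooled positive/negative-null
  procedure. Ties in the ranked list are broken stably by identifier.

## The synthetic cohort

The generator plants a trajectory archetype per gene
(always-PRC/S5p, poised→PRC-Only, poised→Inactive, poised→Active,
always PRC Only, acquired-retained, acquired-transient, always Active,
always Inactive, S5p-only, PRC/Active) with default fractions chosen so
that roughly a third of genes are Polycomb-marked at the start, half
never, and each fate group is large enough for stable fractions at
1,000 genes. From the planted states it derives, per (mark, time
point):

* an enriched region covering the TSS window for every planted
  positive, with width log-normal around 3 kb (clipped to 2.2–3.8 kb)
  and 3× broader for always-poised genes on H3K27me3/S5p;
* a window count from a negative binomial with mean 200 (dispersion
  10, floored at 1 read) for positives; planted negatives receive,
  with probability 0.3, a *decoy* region overlapping the window with a
  zero count — regions whose reads fall outside the window — and
  otherwise no region and a mean-2 background count.

The decoys make zero-count promoters a sizable share (> 5%) of every
overlapping-promoter distribution, so the empirical 5th-percentile
threshold lands at 0 and, under the strict positivity rule, every
planted positive is called positive and every decoy negative — this is
what makes exact planted-truth recovery a meaningful end-to-end test
rather than a coincidence of thresholds. Expression is log-normal (high
component for S7p-positive states, near-zero otherwise) with planted
peaking genes given a flat base and one 100× time point; knockout
tables flip planted derepressed genes (probability 0.30 for PRC/S5p,
0.05 for PRC Only, 0.02 otherwise) deterministically above the FC > 2
and KO > 1 thresholds. Always-poised promoters receive wide CpG islands
and three HMRs that merge into a 6-kb hypomethylated block (probability
0.65, vs 0.02 for poised→Inactive genes), and poised TFs draw
non-neuronal conversion ranks uniformly from the top fifth of the scale.

Gene bodies are packed with ≥ 8 kb gaps on two 10-Mb chromosomes so
that, at default settings, no TSS windows overlap, no enriched region
reaches a neighbor's window, and no HMR cluster merges across genes;
configurable fractions of deliberately window-overlapping and nested
gene pairs exist to exercise the exclusion filters. chrM, `*_random`
and RefSeq-free decoy clusters exercise the annotation filters. One
seed drives named child RNG streams (`SeedSequence.spawn`) per
component, so outputs are byte-identical across runs.

What the generator does *not* emulate: read-level noise and mapping
artifacts, fragment-size effects, enriched-region calls that only
partially overlap promoters, copy-number or GC bias, biological
correlation between neighboring genes, and partial or drifting
states between time points. Passing recovery tests therefore
demonstrates the correctness of the decision logic and statistics, not
robustness to the full noise structure of real sequencing data.

## Problem sizes and runtimes

Default analyses use 1,000 genes × 5 time points × 3 marks; the full
test suite (including a complete end-to-end recovery run, a 500-set DMV
oracle sweep, the exhaustive ≤ 25-universe hypergeometric comparison
and a 200-set GSEA null calibration) completes in well under a minute
on one CPU, and the acceptance script in about 15 s. These sizes give
binomial standard errors of a few percent on every planted fraction,
which is the resolution at which the recovery claims are made.

## Known limitations

* The window-overlap filter removes both genes of an offending pair by
  default; whether one-sided removal is more faithful is genuinely
  ambiguous, hence the configurable policy.
* The HMR proximity-clustering distance is a free parameter (default
  1 kb); DMV calls should be reported with the gap used.
* GSEA FDR uses the pooled-null procedure and is approximate for very
  small set counts; p-values are not corrected across promoter states
  in the hypergeometric module.
* Isoform selection depends on S5p/S2p counts; with neither signal the
  cascade reduces to canonical-then-random, which is annotation-driven
  rather than data-driven.
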