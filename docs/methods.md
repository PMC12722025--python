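# Methods

This note documents the models and conventions implemented in ibrkit, the
parameters that matter, what the synthetic generator does and does not
emulate, and the design choices made where the problem was genuinely open.

## Coordinates and linkage

Internal coordinates are 0-based half-open everywhere; GTF is read and
written 1-based closed and BED 0-based half-open. A gene's TSS is the 5'
end of the gene record (`start` on +, `end − 1` on −); per-transcript TSSs
are out of scope. A region's center is the floor midpoint of its interval
and its quantification window is the 1 kb centered there.

Each region is linked to the gene minimising |center − TSS| on the same
chromosome. Ties break by smaller gene start, then lexicographic gene id,
so assignment is deterministic. The signed distance is center − TSS for +
strand genes and TSS − center for − strand genes: negative always means
upstream of the gene. Regions on chromosomes without genes are dropped with
a warning. The alternative of gene-body distance would change tie behaviour
near long genes; center-to-TSS distance is what the downstream spatial
profile is built on, so one metric serves both.

## Gene architecture features

* length = end − start; intron length = length − merged-exon length; the
  exon-to-intron ratio is undefined (NaN) for intronless genes and such
  genes are excluded from group comparisons rather than given an infinity.
* CpG frequency counts CG dinucleotides over L − 1 windows,
  case-insensitively on the given strand; windows containing N are removed
  from numerator and denominator. CG is its own reverse complement, so the
  statistic is strand-symmetric.
* The promoter is the 1000 nt immediately upstream of the TSS,
  strand-aware and clipped at chromosome ends.
* Gene density counts other genes whose body overlaps the ±100 kb flank of
  the focal gene (focal gene excluded) divided by 200,000 nt. Whether
  neighbours should count by body overlap or TSS containment was open; body
  overlap was chosen as the more inclusive reading of "within the flanking
  window" and is what the brute-force oracle tests pin down.
* Regulator counts are distinct transcription factors per target in a
  tf/target edge table; absent genes count 0.

## Quantification conventions

Filters run in the order the analysis narrative implies: mapped-fraction
filter (threshold 0.5) → one-shot correlation-outlier removal → expressed-
feature filter. Outliers are samples whose mean off-diagonal Pearson
correlation on log2(count + 1) falls more than k = 2 SD below the mean of
those means; only the low side is flagged (a sample cannot be an outlier
for correlating too well) and the rule is applied once, not iterated. The
correlation scale (raw vs normalized counts) was unstated; log2(raw + 1)
was chosen so the QC does not depend on the size factors it precedes.

A feature is transcribed iff it has ≥ min_reads (1) in ≥ min_samples (3)
samples. Size factors follow the median-of-ratios rule over features with
nonzero counts in every sample, then are rescaled to geometric mean 1 so
normalized values share a scale; with no all-nonzero feature the code falls
back to upper-quartile factors with a warning. Note a mathematical
subtlety: scaling one sample's counts by c scales its factor by c relative
to the others, but every sample's normalized values pick up a common
c^(1/n) factor under any median-of-ratios variant — invariance holds up to
one global constant, and that is what the tests assert.

Two-group comparisons use the Wilcoxon rank-sum test: exact by full
enumeration of group labelings (tie-safe) when n + m ≤ 16, otherwise the
normal approximation with tie and continuity corrections. The effect size
is rank-biserial, 1 − 2U/(nm), reported alongside p.

## Group codes and strata

Each gene gets a 3-character code: digit 1 gene transcribed, digit 2 any
linked region transcribed, digit 3 linked at all; a transcribed linked
region implies linkage, so 010 and 110 cannot occur. Digit 2 uses ANY
linked region because genes average several linked regions; a
`nearest_only` switch restricts it to the region closest to the TSS.
Quantile strata are rank-based with stable ties (input order), keeping the
five bins within one element of each other even with many zeros; the
alternative of value-collapsing ties would put every zero feature in one
giant bin.

## TSS-relative profile and peaks

The ±20 kb window around each linked TSS is split into 147 equal bins
(~272 nt, roughly nucleosome scale). Each transcribed region's 1-kb window
is mapped to strand-corrected offset space and its abundance score (mean of
size-factor-normalized counts) is added, unweighted, to every bin the
window overlaps — the literal "overlapping the bin" rule; a
`length_weighted` option pro-rates by overlap fraction, and a `moving_sum`
option reproduces a running-sum smoothing variant for comparison. Windows
entirely outside ±20 kb are excluded; straddling windows contribute only to
inside bins. Total profile mass therefore equals Σ score_i × (bins
overlapped by window i), which the tests check to 1e−9.

No published algorithm defines the upstream peaks, so peak calling is an
explicit, documented heuristic: candidate apices are local maxima among
bins at or above the 0.75 quantile of nonzero bins; extents grow from the
apex while the score stays ≥ 0.5 × apex and monotone non-increasing;
overlapping extents merge keeping the higher apex; labels e1…eK follow
increasing |apex offset|. Members are regions whose center offset falls in
a peak's extent; genes are the distinct linked genes of members and may
appear in several peaks.

## Coordination screen and set enrichment

For every pair of a transcribed region and its transcribed nearest gene,
Spearman's ρ (Pearson of midranks, two-sided t-approximation p) and a
least-squares slope are computed on log2(normalized + 1) — a variance-
stabilising transform for negative-binomial counts. P-values are BH-adjusted
over the whole screen; pairs are positive/negative at padj < α = 0.05 by
the sign of ρ (the slope is reported for effect direction only). The
published analysis does not state its significance criterion; BH FDR across
the screen is the standard choice and the planted-truth tests quantify its
operating characteristics (sensitivity ≥ 0.9 at coupling 0.8 with 60
samples; null false-positive fraction ≤ 0.05).

Preranked set enrichment uses the weighted Kolmogorov–Smirnov running sum
(weight exponent 1 on |score|): hits advance by normalized |score|^w,
misses retreat uniformly; ES is the signed extreme. The null comes from
permutations of set membership over the ranked labels; NES divides ES by
the mean |ES| of same-sign permutations and the FDR is the fraction of
same-sign permutation NES at least as extreme. A set equal to the universe
has ES = 0 by definition.

## Motif enrichment

A motif's affinity for a sequence is the arithmetic mean over all start
positions on both strands of ∏_k p_k(b)/q(b), with N-containing windows
skipped; PWMs get a 0.01 pseudocount and the background q is either
uniform or the 0-order composition of the background pool. Group
enrichment compares the mean of per-sequence affinities with resampled
length-matched background sets (a random same-length substring of a random
background sequence per group member); because mean affinities are
heavy-tailed and approximately lognormal, z is computed on log scores with
a one-sided upper normal-tail p. A degenerate (uniform) motif yields zero
background variance and is reported as z = 0, p = 1. Panel size is a
configuration choice; calibration tests run ~100-motif panels.

## Synthetic generator

The generator emulates the structure the analysis assumes, with one seeded
`numpy` Generator driving every draw so identical configurations give
byte-identical outputs.

* **Genome/annotation.** Two chromosomes of 5 Mb i.i.d. sequence at GC
  0.41. Each chromosome holds a sparse zone of "linked-class" genes —
  log-normal lengths, median 15 kb, few short exons (low exon-to-intron
  ratio), gaps of 20–30 kb — followed by a dense zone of "unlinked-class"
  genes (median 2 kb, exon-dense, gaps 0.2–2 kb). The 15 kb/2 kb medians
  keep the two-class contrast (longer, intron-rich, isolated vs short,
  exon-dense, clustered) while fitting 400 genes into 10 Mb; class
  promoters are rewritten with planted CpG rates (0.01 linked vs 0.12
  unlinked), mirroring the low-CpG-promoter character of enhancer-linked
  genes.
* **Regions.** 85 % of 1200 regions are planted in clusters at −1.5, −3.5,
  −6.5 and −9 kb upstream of linked-class TSSs (Gaussian jitter, SD
  120 nt) with cluster abundance means 50/30/15/8 decreasing away from the
  TSS; lengths are capped so regions stay > 1 kb clear of the TSS. Every
  planted region is verified at generation to win the nearest-gene rule
  for its intended gene and re-drawn otherwise. The remaining 15 % are
  uniform distal decoys kept ≥ 12 kb from any TSS so near-TSS bins carry
  only planted signal.
* **Counts.** 60 samples in two 30/30 cohorts. Gene means are log-normal
  (median 200); counts are negative-binomial with dispersion 10 and
  per-sample library factors (log-normal, SD 0.15). Coupled pairs share a
  per-gene latent factor z ~ N(0,1) across samples: the gene loads with
  coefficient 1 and the region with ±γ (default 0.8, the planted coupling
  on log2 scale); uncoupled features are independent. A differential
  subset carries a +1 log2 fold-change in the case cohort. Silent features
  are all-zero apart from sub-threshold noise (a read in ≤ 2 samples), so
  they deterministically fail the expressed filter; transcribed features
  are guaranteed ≥ 8 nonzero samples, so a few outlier-sample removals
  cannot flip their status. Region silencing clusters by locus (20 % of
  anchor genes have ~90 % of their regions silent, with the base rate
  adjusted to keep the marginal silent fraction at 30 %): without this,
  codes 001 and 101 — genes whose linked regions are all untranscribed —
  would almost never arise.

What the generator does **not** emulate: read-level artefacts (mappability,
GC bias, duplication), transcript isoforms and overlapping genes, genuine
chromatin state, distance-decaying coupling strength, and realistic
library-size heterogeneity. Passing recovery tests therefore demonstrate
the pipeline's correctness on data satisfying its own model assumptions —
linkage, binning, classification and screening logic — not robustness to
the full messiness of real RNA-seq.

## Numerical choices and degenerate inputs

Fisher's exact test returns p = 1 for an all-zero table; the permutation z
falls back to 0/±∞ when shuffled hit counts have zero spread. Spearman's ρ
is NaN with p = 1 under zero variance. The quantile stratifier requires at
least k values. The profile rejects non-positive window or bin counts and
returns an empty peak set on an all-zero profile. All permutation and
resampling operations take explicit seeds. Report percentages are rounded
half-up to 2 decimals via `Decimal`, matching conventional printed style.

## Problem sizes

Defaults are sized for quick desk-scale runs: the standard dataset
(2 × 5 Mb, 400 genes, 1200 regions, 60 samples) generates in a few seconds
and the full pipeline adds about one more. The coupling-recovery
experiment uses 1600 regions with 500 planted couplings; the null screens
use ≥ 1000 uncoupled pairs; calibration panels use ~100 motifs and
60–80-set enrichment batches. These sizes give the recovery and
calibration tests stable operating points across seeds.

## Known limitations

* The nearest-gene rule is deliberately simple; it cannot represent
  skipped-gene or multi-target regulation and is wrong wherever real
  enhancers bypass the closest promoter.
* Peak calling is a heuristic with two tunables; very broad or overlapping
  clusters merge into single peaks.
* The coordination screen tests marginal association only — no
  conditioning on cohort or latent structure — so strong batch effects
  would inflate couplings on real data.
* The motif null uses a lognormal approximation of the background mean;
  for very short or degenerate motifs the `--empirical`-style resampled p
  (exposed via the same background draws) is more trustworthy.
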