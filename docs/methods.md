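# Methods

This note documents the statistical procedures implemented in `lincscreen`,
the choices made where the methods literature leaves room, what the
synthetic-data generators do and do not emulate, and the package's known
limitations.

## Coordinate and data conventions

All genomic coordinates are 0-based half-open (BED convention) internally;
1-based dialects must be converted at the reader boundary. The TSS of an
interval is its `start` on the plus strand (and for unstranded records) and
its `end` on the minus strand. Differential tables follow a Cuffdiff2-like
TSV dialect (`gene_id, locus, test_stat, log2fc, p_value, q_value, status`);
`NOTEST` rows are retained on read but excluded from rankings and
significance counts. Expression matrices are FPKM (non-negative) with an
optional per-gene biotype label; `log10p1` applies the display transform
log10(FPKM + 1).

## ORF enumeration and the ribosome release score

An ORF runs from an ATG to the first in-frame stop codon (TAA/TAG/TGA),
**stop included**, so the CDS length is a multiple of 3 and at least 6 nt
(one sense codon plus the stop); no longer-ORF threshold is applied. The
putative 3′-UTR runs from the base after the stop to the next ATG at any
offset in any frame, or to the transcript end. Codons containing N never
match start or stop — a deliberately conservative call on ambiguous bases.

The RRS for one ORF is `(F_cds/F_utr) / (R_cds/R_utr)` with `F` the
ribosome-footprint and `R` the total-RNA per-base coverage sums over the CDS
and 3′-UTR spans. Reads are counted as per-position coverage sums; counting
by 5′-end position would be an equally defensible convention and is not
claimed to be equivalent. The score is *undefined* — a sentinel, not an
error, and not 0 or ∞ — when the 3′-UTR is empty or any denominator sum is
zero; undefined ORFs are skipped when taking the per-transcript maximum, and
ties at the maximum resolve to the 5′-most ORF for determinism. Two
consequences worth knowing: the score is invariant to scaling both tracks by
a common factor (sequencing depth cancels), and uniform tracks give RRS = 1
for every ORF regardless of span lengths.

## Candidate selection

Filters run as a cascade (annotation overlap → CSF → mass-spec → RRS →
boolean criteria) with a per-candidate trace; because each filter is a pure
predicate, cascade membership equals the intersection of the individual
keeps — short-circuiting only shortens traces. Conventions: annotation
exclusion is strand-agnostic any-overlap (≥1 bp) against non-lncRNA
features; the CSF cut is a strict `< −200`, so the boundary value is
excluded; the mass-spec cut keeps ≤2 tags; a candidate is flagged
coding-like when its max RRS exceeds a configurable percentile (default
5th) of a user-supplied coding-gene RRS distribution — the source analysis
compared distributions without naming a cutoff, so the percentile makes the
screen executable and is deliberately exposed as a knob. CSF scores, tag
counts, synteny and chromatin flags are consumed as precomputed inputs;
computing them is out of scope.

The temporal induction filter takes per-gene, per-contrast q-values labelled
`adjacent` (consecutive time points) or `vs_day0`, and returns genes with
q < 0.01 in ≥1 adjacent contrast plus the subset that is also significant
*and* upregulated against day 0 — one coherent threshold for both parts.

## Rank-based set enrichment and guilt-by-association

Genes are ranked by the signed differential test statistic, descending, ties
broken lexicographically by gene id. Each set present in the ranking (≥5
mapped members by default) is compared against all remaining genes with a
two-sided Mann-Whitney U-test; the two-sided choice reflects that both
enrichment and depletion are of interest, with direction carried by the
z-score's sign. Mode selection: the exact permutation distribution is used
when `|set|·|complement| ≤ 10 000` — via the exact U distribution when the
values are tie-free, or full enumeration of label splits when ties are
present and `C(n, k) ≤ 2·10⁵` — otherwise the normal approximation with tie
and continuity corrections. All-identical values return p = 1 by convention.
BH correction runs across the tested sets of the collection.

The set z-score standardises the set mean against all genes:
`z = (mean_set − mean_all) / (sd_all/√|set|)` with population sd. This is
one standard formalisation of "z-score of the statistic relative to all
genes"; it is isolated in `set_zscore` so it can be swapped. It is invariant
under positive affine transforms of the scores.

Guilt-by-association computes Pearson r between the focal lincRNA row and
every coding gene row (≥3 samples required; zero-variance rows excluded with
a recorded reason; a zero-variance focal row is an error), ranks coding
genes by r, and applies the same set test to the r values. Significance is
called on the **raw** p at 1e−6 — matching how such screens are typically
thresholded — while BH q-values are always computed and reported for
stricter use. Mouse→human identifier mapping, where needed, is a two-column
table supplied by the user, never computed.

## Cis-enhancer bootstrap

The observed statistic is the number of OK-status genes with q ≤ 0.05 whose
TSS lies in the closed window `[TSS_focal − 1 Mb, TSS_focal + 1 Mb]`,
clipped to the chromosome; the focal gene itself never counts. Membership is
decided by the TSS point, not interval overlap — unambiguous at window
edges. The null resamples 1000 windows of the same size (2 Mb + 1 positions)
genome-wide: chromosome chosen proportional to its number of eligible start
positions, start uniform among them, the window always fitting entirely; no
focal-gene exclusion applies in null windows. Then

```
p = #(null counts ≥ observed) / n_iterations
```

which can legitimately be 0; the add-one variant `(k+1)/(n+1)` is emitted
alongside as the conservative estimate (also serving as the resampling-based
false-discovery figure, which the source procedure mentions without
defining). Null windows are **not** matched for gene density; p is reported
exactly as defined and never interpreted as density-adjusted.

## Phenotype statistics

Mendelian expectations redistribute the observed census total at the cross's
proportions — 1:2:1 for an autosomal het×het cross; uniform quarters over
(F+/+, F+/−, M+/Y, M−/Y) for the X-linked preset, which covers a
heterozygous-female × wild-type-male design (arbitrary ratio vectors are
accepted for other designs). Goodness of fit is the classical
`Σ(obs−exp)²/exp` with df = classes − 1. Lethality penetrance is
`max(0, 1 − observed/expected)` homozygotes, clamped because sampling noise
can push observed above expected; when estimating from a census alone, the
expected homozygote count is inferred from the lethality-unaffected classes
(e.g. `(wt + het)/3`), which is unbiased where the census-total convention
is not. Survival proportions and penetrance are reported as percents rounded
to integers; morphometric percent changes to two decimals. Group summaries
are mean ± SEM (sample sd, n−1); comparisons use the pooled-variance
two-sample t-test, two-sided, with the conventions t=0, p=1 for identical
constant groups and an infinite-t sentinel with p=0 for distinct constant
groups. Longitudinal survival modelling and repeated-measures growth-curve
analysis are out of scope; per-time-point group comparisons cover the
body-weight use case.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of their arguments and a seed; each draws
from its own fixed substream (`SeedSequence(seed, spawn_key=(k,))`) so
adding a generator never perturbs another's output. They emulate the
*downstream products* of an RNA-Seq study, never raw reads, alignment
artifacts or library-size effects.

- **Genome/catalog**: random chromosome sizes, non-overlapping genes within
  a strand, biotype labels, strand-aware TSS.
- **Ribosome profiles**: Poisson counts with mean `depth` inside the first
  ORF and `depth/drop_factor` elsewhere for coding transcripts (uniform for
  noncoding); total RNA uniform at `depth` in both cases. This plants
  exactly the stop-codon drop-off the RRS detects, with no reading-frame
  periodicity or 5′-ramp structure.
- **Expression compendium**: module members share a latent per-sample
  profile, `member = μ + σ·(r·z + √(1−r²)·ε) (+ noise)`, so the
  member–lincRNA Pearson correlation approaches the requested r as samples
  grow; values are truncated at zero after noise (the baseline sits several
  σ above zero so truncation is rare and the mean approximately preserved).
  Real compendia have heavier tails, batch structure and correlated
  backgrounds that this deliberately omits.
- **Differential tables**: exactly `n_local` significant genes planted
  within ±1 Mb of a focal TSS and `n_global` elsewhere, q drawn below/above
  the significance line, statistics consistent with the labels, and p never
  above q.
- **Cross counts**: multinomial genotypes at Mendelian proportions, then
  each mutant-null individual dies independently with probability equal to
  the penetrance before the census.
- **Morphometry**: normal draws per group.

Passing the planted-recovery suite therefore shows the *procedures* are
correct under their own model assumptions; it does not certify performance
on real data with confounding structure the generators omit.

## Calibration-study design choices

The null-calibration suite checks that GSEA, bootstrap and chi-square
p-values are uniform under their nulls (KS at α = 0.01, ≥500 replicates).
Three design points matter and were fixed from first principles:

- **Mann-Whitney uniformity** is checked at n = 400 (asymptotic mode). At
  small n the exact two-sided p is discrete and a KS test against the
  continuous uniform rejects for discreteness alone.
- **Bootstrap calibration** uses 20 000 genes (5 000 DE) on a 100 Mb
  chromosome so window counts have sd ≈ 8.7 and the tie mass of the
  empirical p stays well below the KS critical distance; the gene layout is
  redrawn every replicate so replicates are independent, and the focal point
  is a uniform random position, making observed and null counts
  exchangeable by construction.
- **Chi-square calibration** uses censuses of 2000 so the large-sample
  chi-square reference is accurate.

The planted cis-power condition uses an 8 × 100 Mb genome: the probability
that a random 2 Mb window re-captures a planted cluster scales as
window/genome, so the genome must dwarf the window for p ≤ 0.01 to be
reachable at all (~0.25% hit probability here).

## Known limitations

- **Penetrance recovery at small censuses.** With a census of n = 500 and
  mid-range penetrance π ≈ 0.65, the estimator
  `π̂ = 1 − 3·hom/(wt + het)` has sampling sd ≈ 0.05 (homozygote survivors
  are Binomial(500, 0.0875)), so |π̂ − π| ≤ 0.05 holds in only ~60–68% of
  crosses — no estimator of a count this small does materially better. The
  recovery suite reports this rate honestly; at n = 5000 the same estimator
  recovers π within ±0.05 essentially always, and the property suite
  verifies that.
- Exact Mann-Whitney with ties falls back to the normal approximation when
  the label-split count exceeds ~2·10⁵, even inside the nominal exact
  regime.
- The equal-variance t-test tracks the exhaustive permutation p only to
  within ~0.1 per trial at n = 5 per group (mean discrepancy ≪ 0.05); this
  is a property of the t reference at that sample size, not of the
  implementation.
- The RRS read-counting convention (coverage sums) is one of two defensible
  choices; results at very low coverage depend on it.
- Percent changes recomputed from rounded group means can differ in the
  second decimal from values computed on unrounded means; the package
  reports what its inputs imply.
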