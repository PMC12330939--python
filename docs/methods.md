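# Methods

`circrbp` implements the downstream half of a circRNA / RNA-binding-protein
(RBP) tumor study: everything after circRNA detection and read counting.
This note records the models, the defaults and why they hold, what the
synthetic data generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Data model

All coordinates are 0-based half-open, BED-style, end to end.  All
sequence is stored as DNA (U folded to T on input) so the genome, the
extracted regions and the PWM columns live in one alphabet; RBPs bind RNA,
so every scan is single-strand in transcript orientation — minus-strand
circRNAs are reverse-complemented at extraction time, never during
counting.  N bases are allowed in the genome; any k-mer or PWM window
containing an N is excluded from both the numerator and the total, so
ambiguity codes can neither create nor dilute enrichment.

## Sequence regions

Five region classes drive the motif analysis of a circRNA with backsplice
interval [start, end):

- **body** — the spliced circRNA sequence (exon blocks concatenated 5'→3'
  when present, otherwise the genomic span);
- **flank5 / flank3** — fixed windows (default 1000 nt) immediately
  up-/downstream of the backsplice acceptor/donor in transcript
  orientation, truncated and flagged at chromosome ends.  These stand in
  for the flanking introns; the definition is deliberately
  coordinate-window based rather than gene-model based, because the
  analysis it supports is itself window-based;
- **boundary5 / boundary3** — 100-nt junction windows: the last 50 nt of
  the flank plus the first 50 nt of the body (and symmetrically at the
  donor end).  The body side is taken from the spliced body when exon
  blocks exist, since that is the sequence a junction-spanning RBP would
  contact on the mature circle.

Whether published flank definitions are strand-oriented or genomic
left/right is often unstated; strand-oriented was chosen because RBP
binding is an RNA-level event, and the strand-involution property (flip
the genome, flip the strand, get identical sequences) is enforced by test.

## Normalization and differential expression

Library composition is normalized by TMM (trimmed mean of M-values): the
reference sample is the one whose upper-quartile count fraction is closest
to the mean; per sample, log-ratios (M) and log-abundances (A) over
features positive in both sample and reference are trimmed by double-sided
ranks (30% on M, 5% on A) and the factor is 2 to the precision-weighted
mean of the surviving M values, with factors rescaled to geometric mean 1.
The implementation agrees with the Bioconductor reference to ~1e-6 on
random NB matrices (cross-checked in the test suite).

Differential expression is a conditional negative-binomial exact test with
a single common dispersion: counts are scaled to a common effective
library size, dispersion is estimated by method-of-moments on the pooled
within-group variance (median across features, clipped to [1e-4, 20]),
and per feature the two-sided p-value sums the conditional probabilities
of all foreground/background splits no more likely than the observed one,
given the total.  BH controls the FDR, applied separately per feature
kind (circRNAs vs genes).  This is intentionally simpler than a
quasi-likelihood GLM: at the cohort sizes this package targets the
operating characteristics are what matter, and they are verified by
simulation — on null NB data the fraction of raw p < 0.05 sits in
[0.03, 0.07] over 20 seeds, and planted 4-fold features at n = 20/group
are recovered with sensitivity ≥ 0.9 at FDR 0.05.

**Known property:** under strongly asymmetric DE (e.g. 20% of features
down, 5% up), TMM's trimmed middle is slightly off-center and null
features acquire a small positive log2FC bias, which inflates the
realized false-discovery fraction above the nominal FDR.  The reference
implementation behaves identically (verified numerically); this is a
property of the normalization model, not of this re-implementation.  At
the DE fractions typical of real cohorts (a few percent) the effect is
negligible.

The circular-to-linear ratio is CLR = circ/(circ + lin) on pooled raw
counts (normalized counts are available via an option; which convention a
given study used is rarely stated).  CLR is undefined when circ + lin = 0
and values above 0.5 mean the circle outnumbers its linear host.

RBP gene results are the DE table intersected with a user-supplied human
RBP list by case-insensitive symbol match.  Expression correlation is
Spearman's rho with average ranks for ties and the t approximation on
n − 2 degrees of freedom, computed by rank-then-Pearson matrix algebra and
verified against the scalar definition to 1e-12.

## k-mer enrichment and motif attribution

Enrichment compares total k-mer occurrences (sliding window, stride 1,
k = 6 by default) between a foreground set (up- or down-DE circRNA
sequences) and the non-DE background.  Per k-mer, a 2×2 table of
(occurrences, remaining windows) in each set feeds a two-sided Fisher
exact test, computed by direct hypergeometric enumeration with the
conventional (1 + 1e-7) relative slack on the probability comparison; the
implementation matches an exact rational-arithmetic oracle to 1e-10 on
all tables with margins ≤ 60.  Occurrence counting (rather than
per-sequence presence) matches the sliding-window semantics; presence
mode is available as a flag.  The log2 enrichment uses a +0.5 pseudocount
on both rates.  BH runs over the k-mers observed in either set;
unobserved k-mers carry p = 1 by construction and are reported as such.
"Enriched" = FDR < 0.1 and positive log2 enrichment.

A k-mer matches a PWM when the best sliding alignment of the shorter over
the longer achieves ≥ 0.8 of the maximum attainable summed log2(p/0.25)
score at that alignment, with probabilities floored at 1e-3.  The floor
(rather than an additive pseudocount) makes the uniform PWM degenerate —
its maximum attainable score is 0, so it matches nothing — which is the
behaviour a motif scanner should have.  The 0.8 threshold and both
pseudocounts are exposed in the configuration; none is dictated by the
underlying statistics.

RBP attribution is a hypergeometric over-representation test: universe =
all 4^k k-mers, marked = k-mers matching the PWM, drawn = enriched
k-mers, with BH across the PWM library and significance at FDR < 0.1.
Region-resolved motif profiles count sliding-window PWM matches per
region class, normalized to matches per kb scanned, and the dual-role set
is the intersection of RBPs significant in both the body and the flank
analyses.

## Stratification

Subtype assignment is nearest-centroid-style: signature genes are
z-scored across samples, a sample's score per subtype is the mean z over
that subtype's genes, and the label is the argmax (ties broken by sorted
subtype name and flagged).  This is declared plumbing — the point is a
reasonable, testable assignment, validated by ≥ 95% recovery of planted
2-sigma subtype shifts — not a re-derivation of any published classifier.

The RBP stratification workflow is: (1) per RBP, a seeded 25-restart 1-D
2-means split; the RBP "can discretize" the cohort when the
between/within sum-of-squares ratio exceeds 3.0.  This threshold is a
calibration, not a convention: the B/W ratio of a 2-means split of *any*
continuous sample exceeds ~1.4 by construction (i.i.d. normal data gives
a median near 1.9 and a 95th percentile near 2.5 at n = 60, measured by
simulation), while a 4-sigma bimodal mixture stays above 3.3 in 95% of
draws; 3.0 separates the two regimes.  (2) RBPs whose split associates
with the known molecular subtypes are dropped (Pearson chi-square without
continuity correction, kept iff p > 0.01; under independence the
false-drop rate is ~1%, verified over 200 simulations).  (3) Samples are
clustered by k-means (Euclidean, 25 seeded restarts) on per-RBP
standardized expression for each k in 2..6; the mean silhouette picks k.
A k whose best labeling contains a singleton cluster is skipped — a
singleton makes the downstream ANOVA undefined, so such a k is not an
admissible stratification.  A best silhouette below 0.25 flags weak
structure.  (4) Discriminant RBPs are those with BH-adjusted one-way
ANOVA p ≤ 0.05 across the chosen clusters.

## Survival

Expression grouping is by rank-interpolated (type-7) quartiles: values ≤
Q1 are "low", values > Q3 "high", the rest "medium"; ties at a cut fall
to the lower group, so no sample straddles groups under heavy ties.  The
Kaplan-Meier estimator and the Mantel-Haenszel log-rank test are
implemented from first principles (product-limit survival; per-event-time
hypergeometric expectation and variance, simultaneous-event tie
convention; chi-square on g − 1 degrees of freedom via the covariance
pseudo-inverse for g > 2) and are cross-checked in the tests against
lifelines, a hand-worked censored table, and a 10^5-draw permutation
oracle.  The screen tests low vs high only (medium excluded), reports raw
and BH-adjusted p, and calls significance on raw p < 0.05; the BH column
is there for transparency.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions every recovery test runs under:

| parameter | default | meaning |
|---|---|---|
| chrom_len / n_circ | 6 Mb / 1000 | one chromosome, non-overlapping circRNAs with ≥ 1 kb spacing |
| circ length | U[200, 2000] bp | covers the length range typical of exonic circRNAs |
| frac_down / frac_up | 0.20 / 0.05 | down-skewed DE, echoing the strong downregulation of circRNAs in tumors |
| planted motifs | TTTTTT (down), GGCGGC (up) | U-rich marks the down set, G/C-rich the up set |
| insert rates | 6 /kb fg, 0.5 /kb bg | Poisson-placed, overwrite-not-insert, never overlapping |
| NB dispersion / base mean | 0.1 / 100 | moderate biological variability at sequencing-typical depth |
| n per group | 20 | tumor and control |
| library sizes | 3-fold log-uniform | recorded as true size factors |
| clusters / drivers | 3 / 15 RBPs, ±2 log2 | non-constant ±1 patterns per driver |
| subtypes | 4, 10 genes each, +2 log2 | classical/mesenchymal/neural/proneural signatures |
| survival | HR 3, baseline median 445 d, horizon 5 y | exponential times, administrative censoring |

Motif planting overwrites sequence (coordinates never shift), records
every insertion in the truth tables, refuses configurations whose
expected overwrite density exceeds 5% of the sequence, and never lets two
insertions collide — across motifs, region classes, or the adjacent
flanks of neighbouring circRNAs.  The survival-driver RBP is deliberately
distinct from the cluster drivers so hazard-quartile structure is not
confounded with cluster structure.  Host-gene (linear) counts are
independent of circ counts by default; a correlation knob couples their
fold changes to exercise both CLR regimes.

What the generator does **not** emulate — and hence what passing recovery
tests do and do not show about real data: the genome background is
i.i.d. uniform (no repeats, no Alu elements, no GC structure), circRNAs
are single-exon by default (a flag adds 2–4-exon structures to exercise
the BED12 paths), there is no read-level error model, no isoform
diversity, no batch structure, and motif placement is positionally
uniform within a region.  Recovery under these conditions demonstrates
the statistics and the bookkeeping are correct; it does not certify power
or error rates on real sequencing data, where background sequence
composition alone can dominate k-mer statistics.

## Problem sizes used in the shipped checks

The test-suite and `scripts/acceptance.py` run at desk scale, chosen as
the smallest sizes at which every statistical claim is comfortably
testable: 20 seeds × 1000 circRNAs of 1 kb for motif recovery; 20 seeds ×
1000 features × 40 samples for DE calibration; 20 seeds × 60 samples for
stratification; 200 seeds for the chi-square and log-rank null
calibrations; 10^5 permutations for the log-rank oracle; and a 120-circRNA
demo cohort for the end-to-end determinism check.

## Known limitations

Two-group designs only (no GLM design matrices, no batch correction); a
common dispersion rather than per-feature empirical Bayes moderation; the
TMM composition bias under heavily asymmetric DE noted above; flanking
"introns" are coordinate windows, not gene-model introns; no
secondary-structure context in motif scoring; TCGA-style external cohorts
are read through the same TSV interfaces but no downloader is provided.
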