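# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind `dcde`, in the order the pipeline runs them.

## Differential expression

The DE variable is the unpooled (Welch-form) two-sample t statistic with
sample standard deviations (ddof = 1). No variance moderation or pooling
is offered: the statistic is intended for large-sample designs (hundreds
of samples per class), where the ordinary t is stable. Genes with zero
variance in both classes would make the statistic 0/0; they are assigned
t = 0 and flagged degenerate rather than dropped, which keeps every
vector aligned with the dataset's gene order.

## Differential co-expression

The DC variable for a pair is the absolute difference of the per-class
Fisher transforms, scaled by `sqrt(1/(n_N−3) + 1/(n_D−3))`. The transform
is `arctanh(r)` with |r| clamped at 1 − 1e−12, so correlations of exactly
±1 (duplicated or affinely dependent genes) stay finite instead of
overflowing. Genes constant within a class have no defined correlation
there; they contribute r = 0, are flagged, and are excluded from serving
as threshold candidates (they remain as points so that contingency counts
stay interpretable). The n − 3 denominators require more than 3 samples
per class; the DC stage raises otherwise.

The variance approximation 1/(n − 3) makes the null Z approximately
standard normal; the test suite checks this empirically (KS test on
10 000 simulated pairs with equal population correlation).

## Threshold selection

For focal gene i, the candidate set is exactly the observed
(|Z_ij|, |t_j|) pairs — thresholds are never interpolated. "High" is
inclusive (≥) on both axes. The focal gene is not a point in its own
scatter (its self-DC is undefined), so a dataset of m genes yields m − 1
points; all contingency arithmetic uses the table's own grand total.

### Candidate validity

A candidate is admissible when no margin is zero (otherwise chi-square is
undefined) and every expected cell is at least `min_expected`. Without a
floor, corner candidates isolating one or two points produce chi-square
spikes approaching n that reflect nothing but the scan itself; with a
floor the null distribution of the maximum stabilizes. The customary
floors for a 2×2 chi-square test are 3 or 5. **The default is 3**: in the
package's own null calibration at m = 10 000 (5000 replicates) the floor
of 3 gives a mean maximum chi-square of 11.36, an upper-5% quantile of
about 17.4, and a 1.4 % Bonferroni-stage survival rate, whereas a floor
of 5 shifts all three down (11.22 / ~17.0 / 1.1 %). The floor is
configurable (5 or 0) through `ChimaxConfig`.

### Search algorithm

The naive scan is O(m²) per gene. The default path sorts points by
decreasing |Z| and counts, for each candidate, the points dominating it
in both coordinates with a Fenwick tree over |t|-ranks — O(m log m) with
tie groups inserted before being queried so the ≥ convention is exact.
Both paths compute the chi-square from identical integer counts through
the identical closed form `n(ad − bc)² / (r₁r₂c₁c₂)`, so fast and naive
results are bit-identical (a tested invariant up to m = 2000).

Ties in the maximal chi-square are resolved to the lexicographically
smallest (z, t) pair, making results platform-independent. If no
candidate is admissible (e.g. all points identical) the gene is flagged
and excluded downstream.

### Significance cascade and direction

The selected maximum is referred to the chi-square distribution with one
degree of freedom. Because the maximum was taken over m candidate tests,
stage 1 multiplies the p-value by m (capped at 1); because m such maxima
are compared, stage 2 applies Benjamini–Hochberg across genes. The
Bonferroni multiplier is the nominal candidate count m even when fewer
candidates are admissible — a deliberate, slightly conservative choice;
`bonferroni_by_valid` switches to the admissible count.

Direction comes from the adjusted residual of the HDC_HDE cell,
`d = (obs − exp)/sqrt(exp(1 − row/n)(1 − col/n))`; for a 2×2 table
d² equals the Pearson chi-square (a tested identity). Its one-sided
upper-tail normal p-value, BH-corrected across genes, tests
over-population of the high/high cell specifically. Genes enter
enrichment when the stage-2 p is below alpha *and* the direction is
positive.

## Enrichment and functional information

The enrichment universe is the set of genes in the expression dataset
(minus the focal gene); gene sets are intersected with it, and sets
falling below `min_set_size` (default 2) are dropped. The test is the
usual two-tailed Fisher exact test (sum of point hypergeometric
probabilities not exceeding the observed one), via `scipy`.

Per focal gene, only the *best associated* set of the combined HDC_HDE
partition — smallest Bonferroni(×k)-adjusted p, ties broken by set id —
is carried forward. The same set is then scored on the HDC-only and
HDE-only partitions (unions of base quadrants at the same thresholds).
Each of the three partition families is corrected identically: Bonferroni
×k within the gene, then BH across the m′ selected genes. Adjusting only
the combined family would bias every FI gain negative by exactly the BH
inflation, which is why the correction is applied symmetrically.

FI is −log2 of the final adjusted p, with p floored at 1e−300 to keep FI
finite under underflow (the floor corresponds to ~997 bits, far above any
value the pipeline produces). Negative FI gains are reported as such:
they mean a single criterion carried more enrichment signal than the
combination.

## Null simulation

Each replicate plays the role of one focal gene: m independent (|t|, |Z|)
pairs with |t| from a Student t (default df = 100) and |Z| standard
normal, run through the identical threshold search. The maximum
chi-square statistic is rank-based under independence, so the t marginal's
df is irrelevant (a tested property); df = 100 is kept as a neutral
default. The Bonferroni stage multiplies by m; the BH stage runs across
replicates. The simulation is bit-reproducible given a seed.

## Sample-size utility

Power for the two-sided two-sample t-test is computed from the noncentral
t distribution (noncentrality `d·sqrt(n/2)`, df = 2n − 2) and scanned for
the smallest per-group n reaching the target. The noncentral-t route —
rather than the normal approximation, which lands on 126 — gives a total
of 128 at alpha = 0.05, power = 0.8, d = 0.5. The test suite checks the
routine against statsmodels' independent implementation.

## Synthetic data

The generator emulates the joint DC + DE phenomenon with a single-factor
block model: `block_size` genes are, in the case class only,
`sqrt(rho)·f + sqrt(1−rho)·ε` plus a mean shift `delta` (in noise-SD
units), giving pairwise case correlation rho and zero control
correlation. Two distractor groups make the planted set identifiable
*specifically* by the combined criterion: DE-only genes carry the shift
without the factor (so any high-DE partition is diluted by genes outside
the set) and DC-only genes load on the same factor without the shift
(diluting high-DC partitions). Without distractors the high-DE partition
of a block focal gene equals the block and all FI gains are ≤ 0 — the
combined criterion has nothing to add. Decoy gene sets are drawn from the
background only.

Defaults (m = 1000, block 50, distractors 2× block each, rho = 0.8,
delta = 1.5, 100 + 100 samples) represent a clearly detectable module in
a moderately sized two-class study; with them the planted set tops the
mean-minimum-FI-gain ranking in 20/20 seeded runs, with mean gains of
roughly 20–90 bits.

What the generator does **not** emulate: probe-level noise, batch
effects, heavy-tailed expression distributions, correlated background
structure, or sets that partially overlap the planted block. Passing
recovery tests therefore demonstrate correctness of the machinery on its
intended signal, not robustness to microarray artifacts.

One emergent behavior worth knowing: genes *outside* the block can
acquire a genuine DC–DE dependency (all block genes' correlations to any
focal gene co-move through the shared factor), so the selected-gene count
exceeds the block size. This is a property of the statistic, not a bug;
such partitions still best-associate with the planted set.

## Problem sizes used in the tests

The acceptance-level checks run the null simulation at m = 10 000 with
1000 replicates (tests) / 4000 replicates (acceptance script), the
fast-vs-naive equivalence up to m = 2000, and the 20-seed recovery study
at the generator defaults (m = 1000). The full suite completes in about
a minute on one CPU.

## Known limitations

- The ordinary t statistic is inappropriate below ~10 samples per class;
  no moderated variant is provided.
- Pearson correlation only; no rank-based DC option.
- Gene sets are flat lists; no ontology-graph propagation.
- The per-focal-gene loop is single-threaded (results are defined to be
  independent of any parallel scheduling; the m ≲ few-thousand scale it
  targets runs in seconds).
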