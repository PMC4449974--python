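# dcde

Integrated **differential co-expression (DC)** and **differential
expression (DE)** analysis of two-class gene expression data, with
per-gene thresholds chosen by chi-square maximization and a
functional-information score for the resulting gene partitions.

## The problem

DE analysis ranks genes by how much their mean expression changes between
two conditions (e.g. tumor vs normal); DC analysis ranks gene *pairs* by
how much their co-expression changes. Each misses what the other sees: a
regulator can rewire its partners without changing its own level, and a
shifted gene need not rewire anything. This package scores both aspects
jointly, per gene, and asks whether the genes that are highly
differentially co-expressed with a focal gene also tend to be highly
differentially expressed — and whether that joint criterion selects more
functionally coherent gene sets than either criterion alone.

## The method

For a dataset of *m* genes with *n_D* case and *n_N* control samples:

1. **DE.** Each gene *i* gets an unpooled (Welch-form) t statistic
   `t_i = (x̄_D − x̄_N) / sqrt(s²_D/n_D + s²_N/n_N)`; its magnitude |t_i|
   is the DE variable.
2. **DC.** Each pair (i, j) gets
   `Z_ij = |z^N_ij − z^D_ij| / sqrt(1/(n_N−3) + 1/(n_D−3))`, where
   `z = arctanh(r)` is the Fisher transform of the per-class Pearson
   correlation. Under equal population correlation Z is approximately
   standard normal.
3. **Thresholds.** For a focal gene *i*, every other gene is a point
   (|Z_ij|, |t_j|) and simultaneously a candidate threshold pair. Each
   candidate splits the scatter into four quadrants
   (HDC_HDE / HDC_LDE / LDC_HDE / LDC_LDE, "high" inclusive); the
   candidate maximizing Pearson's chi-square of the 2×2 table is the
   gene's optimal pair (z\*_i, t\*_i). The search is O(m log m) per gene
   (sweep + Fenwick tree), bit-identical to the quadratic scan.
   Significance of the selected table is corrected Bonferroni-style for
   the m candidate tests, then Benjamini–Hochberg across genes; the
   adjusted residual of the HDC_HDE cell signs the association.
4. **Enrichment.** For each significant, positively associated gene, the
   HDC_HDE partition (and the single-criterion HDC / HDE partitions at
   the same thresholds) is scored against functional gene sets with a
   two-tailed Fisher exact test. Functional information is
   `FI = −log2(adjusted p)` bits, and the minimum FI gain
   `Δ* = min(FI_HDC_HDE − FI_HDE, FI_HDC_HDE − FI_HDC)` is positive
   exactly when the combined criterion beats both single criteria.
   Gene sets are ranked by the mean Δ* over the partitions they best
   associate with.

A null simulation module calibrates the maximum-chi-square statistic
under DC ⟂ DE, and a synthetic-data module plants a case-only correlated,
mean-shifted block (plus DE-only and DC-only distractors) so the whole
pipeline is testable without external data.

## Worked example

Generate a synthetic dataset with a 25-gene planted block and analyze it:

```sh
$ dcde generate --out-dir demo -m 400 --block-size 25 \
      --n-case 100 --n-control 100 --seed 7
wrote 400 genes x 200 samples with a 25-gene planted block to demo

$ dcde run --matrix demo/matrix.tsv --labels demo/labels.tsv \
      --gmt demo/gene_sets.gmt --out-dir demo/out
80 of 400 genes have a significant positive DC-DE association (adjusted p < 0.05)

$ head -3 demo/out/gene_set_summary.tsv
set_id	n_partitions	mean_min_fi_gain
PLANTED_BLOCK	78	26.118277
DECOY_03	1	0.16143691
```

80 genes (the 25-gene block plus genes pulled in by the induced
dependency) survive the two-stage correction with a positive association;
the planted set tops the ranking with a mean minimum FI gain of ~26 bits,
i.e. the combined high-DC/high-DE criterion carries ~26 bits more
enrichment signal than the better of the two single criteria. Random
decoy sets sit at ~0.

The null calibration and the power utility:

```sh
$ dcde simulate -m 10000 --replicates 200 --seed 1
{ "mean_max_chi2": 11.27, "q95_max_chi2": 16.57,
  "n_sig_raw": 200, "n_sig_bonferroni": 2, "n_sig_bh": 0, ... }

$ dcde power
minimum total sample size (two equal groups): 128 (64 per group)
```

Every replicate's *raw* maximum chi-square is "significant" (the scan
maximizes over 10000 candidates), the Bonferroni stage cuts that to ~1%,
and the BH stage to ~0 — the cascade controls the scan's false positives.

## Input formats

- expression matrix: TSV, first column `gene_id`, remaining columns
  sample ids;
- labels: TSV with columns `sample_id`, `class` (tokens configurable,
  default `case`/`control`);
- gene sets: standard GMT.

See `docs/methods.md` for the model details, parameter defaults, and
known limitations.
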