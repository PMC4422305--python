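# Methods

This note records the statistical conventions, defaults and numerical
choices behind cubkit, and what the synthetic-data validation does and
does not demonstrate.

## Sequence QC

A CDS passes QC iff it uses only A/C/G/T, its length is a multiple of 3
and at least `min_length_nt` (default 300, the conventional cutoff below
which index estimates are too noisy), it begins with ATG, ends with
TAA/TAG/TGA, and contains no in-frame internal stop. All failure reasons
are enumerated per sequence, never short-circuited, so QC tables can be
audited. Conventions that the underlying data formats leave open:

- the terminal stop codon counts toward gene length (GenBank CDS
  convention) but is excluded from all downstream codon counting;
- "greater than 300 nucleotides" is implemented as ≥ 300 with the
  threshold exposed, since 300 is the only defensible printed value and
  the strictness of the boundary is not resolvable;
- mitochondrial or otherwise unwanted genes are removed by an explicit
  id blacklist (reported with a `BLACKLISTED` code), never by sequence
  inspection.

## Index conventions

**RSCU.** Computed per synonymous family; families absent from a gene are
undefined (NaN) rather than 0, and are zero-filled only when building the
ordination matrix, so the gene set stays identical across stages. Met and
Trp have RSCU ≡ 1 when present. Stop codons are excluded unless
explicitly requested (as a 3-fold family).

**ENc.** Wright's estimator. An amino acid contributes only with n ≥ 2
observed codons; F values of exactly 0 are excluded from their
degeneracy-class average with the contributing-family count reduced
(codonW convention — a monomorphic 2-fold family observed twice yields
F = 0, which carries no information about homozygosity). A missing 3-fold
class (Ile rare or all-F-zero) is imputed as F̄₃ = (F̄₂ + F̄₄)/2; if any
other class average is missing the gene's ENc is undefined. The estimate
is capped at 61. These conventions make results reproducible bit-for-bit
and match the codonW lineage of published analyses.

**Silent-site composition.** The default ("simple") definition is the
fraction of synonymous-family codons carrying base *x* at position 3;
GC3s = C3s + G3s. codonW's historical A3s/T3s/C3s/G3s divide instead by
per-base *opportunity* (only codons from families offering an *x*-ending
synonym); this is available as `method="opportunity"`. The two agree on
GC3s but differ on individual bases for restricted families; the simple
definition is used throughout the pipeline because it is the one whose
simplex constraint (A3s+T3s+C3s+G3s = 1) holds exactly.

**CAI.** Relative adaptiveness w = RSCU/RSCU_max from the pooled
reference set; codons unseen in the reference receive a floor weight of
0.01 (configurable) so log-weights stay finite — the standard remedy for
sparse reference sets. CAI is the geometric mean of w over the gene's
codons, excluding Met, Trp and stops, and is therefore invariant to gene
duplication and bounded by 1.

**GRAVY / aromaticity** use the Kyte–Doolittle hydropathy scale and the
Phe/Tyr/Trp fraction of the conceptual translation.

## Correspondence analysis

Classical CA in the chi-squared metric (SVD of the standardized residual
matrix), run on the genes × 59 RSCU table — not raw counts — so that
amino-acid composition effects are removed from the synonymous-usage
ordination; amino-acid effects are examined separately on the genes × 20
frequency matrix. Numerical choices:

- axis signs are arbitrary in CA; each axis is oriented so that the
  column (codon) with the largest absolute coordinate is positive, making
  runs and tests reproducible;
- singular values below 1e-12 of the leading one are treated as zero
  (rank-deficient and perfectly homogeneous tables are legal inputs; a
  fully degenerate table returns a single all-zero axis);
- zero rows/columns are dropped with a warning, as their profiles are
  undefined;
- 20 axes are retained by default for the inertia report.

Total inertia equals the table's Pearson chi-squared statistic divided by
its grand total; this identity, and agreement of the axis inertias with a
brute-force eigendecomposition, are the test oracles.

## Selection diagnostics

The ENc plot uses the mutation-only expectation ENc(S) = 2 + S +
29/(S²+(1−S)²); the relative deviation (ENc_exp − ENc_obs)/ENc_exp
summarises the departure. The neutrality fit is ordinary least squares of
GC12 on GC3 (not major-axis regression), because the conventional reading
of slope × 100 as the mutation-pressure percentage presumes the
GC12-on-GC3 OLS slope. Correlation matrices use Spearman rank correlation
with mid-rank ties, two-tailed p values, pairwise-complete observations,
and no multiple-testing correction (reports annotate p < 0.01 as `**`,
p < 0.05 as `*`). Histogram bin widths default to 0.05 on both the GC and
the ENc-deviation scale and are parameters, not conventions.

## Optimal codons

Genes are ranked by axis-1 coordinate, ties broken lexicographically by
id; each tail holds ⌈fraction·n⌉ genes (default fraction 0.05, exposed as
a parameter). The tail with the lower mean ENc is the putatively highly
expressed pool. Each sense codon is tested in a 2×2 table (codon vs other
synonyms × high vs low) with Pearson chi-squared, no Yates correction
(counts in practice are large; a flag enables it) and no multiple-testing
adjustment; a codon is optimal iff p < alpha (default 0.01) **and** its
relative synonymous frequency is higher in the high pool. The direction
condition is scale-invariant; significance deliberately is not. At most
k−1 codons of a k-fold family can be optimal, which is asserted on every
result. Stops and Met/Trp are never tested.

One caveat is inherent to the published procedure itself: because axis 1
is the direction of maximal usage variation, its extreme tails differ by
construction, and on perfectly uniform (null) data the screen can still
flag a handful of codons. The null-calibration test therefore compares
classes defined *independently* of the ordination, where the flagged
fraction stays near alpha.

## Species comparison

Kazusa-format tables (triplet, per-1000 frequency, count) are parsed
strictly: all 64 codons required, malformed lines and duplicates named.
Own counts are converted to per-1000 frequencies over all counted codons,
stop codons included in the normalization as Kazusa does (this shifts
ratios by ~0.3 %); a within-family alternative is available behind
`method="family"`. Indicative codons use strict thresholds (> 2 or
< 0.5), so a ratio of exactly 2 is not indicative.

## Synthetic data

The generator emulates a curated CDS collection: ATG + sense codons + one
stop, amino acids i.i.d. from a composition that by default is uniform
over the 18 degenerate amino acids with Met/Trp down-weighted 5×
(populating every ENc degeneracy class), codons drawn per family either
uniformly, from explicit preferences, or from a GC3 target that splits
each family's mass between G/C- and A/T-ending codons. Gene lengths are
uniform on 100–500 total codons (≥ 300 nt, typical CDS scale). A
configurable high-expression fraction (default in validation runs: 0.1)
samples with a planted codon set — by default all G/C-ending codons of
degenerate families — up-weighted by an enrichment factor. One integer
seed drives everything; each gene uses a counter-derived substream so
earlier genes are unchanged when n_genes grows.

What it does **not** emulate: real amino-acid composition, length/GC
correlations, expression-level gradients (expression is a two-class
structure), isochores, introns/UTRs, or phylogenetic correlation between
genes. Validation on this generator therefore demonstrates the
correctness and statistical power of the *procedures* (index arithmetic,
ordination, pool selection, contingency testing) under known truth — not
that any particular biological dataset will show the same effect sizes.

## Validation problem sizes

The test and acceptance runs use 30 genes of 500–600 codons for the
no-bias ENc limit (mean ENc in [59, 61]), 1,000 simulated points for
neutrality-slope recovery at slopes 0.15/0.5/1.0 (tolerance ±0.05), and
1,000 genes at enrichment factor 3 for end-to-end planted-optimal
recovery (≥ 90 % sensitivity; in practice recovery is complete with no
false flags across seeds). The embedded published *B. mori* extreme-pool
codon counts serve as an exact numeric oracle for RSCU and the
optimal-codon screen (27 optimal codons, all G/C-ending; 3 for Ser, 2 for
Gly).

## Known limitations

- Standard genetic code only (NCBI table 1); no alternative codes, tRNA
  adaptation index, or codon-pair statistics.
- CAI requires a user-supplied reference set; without one the CAI column
  is empty rather than silently self-referential.
- The mutation/selection percentages from the neutrality slope inherit
  that interpretation's assumptions (directional mutation pressure acting
  equally across positions); the package reports the numbers, not the
  causal claim.
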