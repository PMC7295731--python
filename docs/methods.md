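# Methods

## Data model

The universal input is a Ct table: one threshold-cycle value per
gene × sample × technical replicate, each sample annotated with exactly
one group label (a life stage, population, or other condition level).
Validation requires finite Ct in (0, 45], unique
(gene, sample, replicate) keys and, for the complete-matrix methods,
one value for every (gene, sample) pair; `drop_incomplete_samples`
removes samples missing any gene. Technical replicates are always
collapsed to their arithmetic mean before analysis; biological
replicates are modelled as distinct samples within their group, which
matches how screening studies report sample-level Ct ranges.

Summary quartiles use the inclusive (Tukey-hinge) convention: the
median belongs to both halves. One-way ANOVA is computed from sums of
squares with an F(k−1, N−k) reference distribution; a table with zero
total variance is a 0/0 case and deliberately returns F = 0, p = 1
with a warning so that noiseless synthetic fixtures pass through
rather than erroring. Tukey HSD pairwise comparisons come from
`scipy.stats.tukey_hsd`.

## Relative quantities and efficiency

Relative quantities are x(g, s) = E_g^(minCt_g − Ct(g, s)) with the
per-gene minimum Ct as anchor, so max_s x = 1 per gene. The anchor is a
per-gene multiplicative constant and cancels in every downstream ratio
statistic; it only fixes the scale of normalization factors. The
default efficiency is exactly E = 2 (the Q = 2^ΔCt convention);
per-gene values fitted from dilution series may override it.
Efficiency is estimated by ordinary least squares of mean Ct on log10
relative concentration; E% = (10^(−1/slope) − 1) × 100. A non-negative
slope is a nonsense assay and yields a flagged fit rather than an
exception. A 100%-efficient assay has slope −1/log10 2 ≈ −3.3219.

## Stability statistics

**Comparative ΔCt.** S(i, k) = SD over samples of Ct_i − Ct_k, with the
n−1 denominator (as throughout the package); stability_i = mean_{k≠i}
S(i, k). Operating on raw Ct differences makes the statistic exactly
invariant to per-sample loading shifts. At E = 2 it equals the
first-iteration geNorm M value identically; the test suite asserts the
identity to 1e−10 on random tables.

**geNorm.** M_i = mean_{k≠i} SD(log₂ x_i/x_k). Stepwise exclusion
removes the single highest-M gene until two remain; the final pair is
reported tied at rank 1 under competition ranking (1, 1, 3, …), which
is the convention that reproduces published cross-condition geNorm
rank averages with tied best pairs. A tie at the maximal M during
exclusion is broken by input order and logged — ties are measure-zero
on real data. Genes with M ≥ 1.5 are flagged unavailable.
Normalization factors NF_n are per-sample geometric means of the n
best-ranked genes' quantities; V(n, n+1) = SD over samples of
log₂(NF_n/NF_{n+1}); the optimal gene count is the smallest n with
V < cutoff (0.15 default, configurable, e.g. 0.2 for noisier designs),
falling back to all k genes with a warning when no V qualifies.
`optimal_gene_number` accepts a partial V series keyed by n so the rule
can be applied to published V values alone.

**NormFinder-style model.** Log2 signal (−Ct at E = 2, or log₂ of
quantities) is centered per sample across genes, removing loading and
making results invariant to per-gene level shifts. Within group g, the
centered per-gene sample variance s²(i,g) is mapped to an intra-group
variance estimate

  σ̂²(i,g) = max(0, k/(k−2) · (s²(i,g) − s̄²(g)/(k−1)))

which undoes the deflation and coupling introduced by centering k
genes; it is unbiased for any variance profile (verified by Monte
Carlo to <1% at 1000 replicates) and clamped at zero, with the clamped
fraction logged. Group deviations d(i,g) (group mean minus the gene's
unweighted mean of group means) are shrunk by γ²/(γ² + σ̂²(i,g)/n_g),
where γ² = max(0, Var(d) − mean(σ̂²/n_g)) pools over all (gene, group)
cells with the n−1 denominator — the spec of the estimator leaves the
denominator open; the sample variance was chosen once and kept.
Stability is ρ(i) = mean_g [|d̃(i,g)| + √(σ̂²(i,g)/n_g)]; with a single
group ρ(i) = √σ̂²(i). Exact numerical parity with the original
NormFinder binary is not claimed; the estimator is validated by its
own calibration properties (unbiasedness, invariances, rank recovery).

**BestKeeper.** Dispersion defaults to the mean absolute deviation
about the mean Ct (the convention of the original tool family), with a
flag for sample SD; CV% = 100 · dispersion/mean; the index is the
per-sample geometric mean of Ct across genes and each gene's Pearson r
against it is reported. BestKeeper works on raw Ct and is *not*
loading-invariant — asserted in tests and documented as the method's
known limitation rather than corrected.

**Aggregation.** Competition ranks feed a plain (equal-weight)
geometric mean across the four methods; equal weighting reproduces the
published comprehensive values that are derivable from printed method
ranks, so no other weighting is offered. Cross-condition summaries are
arithmetic means of per-condition ranks, printed at 2 decimals with
round-half-up; stability values print at 3 decimals. The
exclusion-sensitivity analysis recomputes averages over retained
conditions and reports per-gene shifts.

## Synthetic data

The generator draws Ct(i, s, rep) = μ_i + δ(i, g(s)) + L(s) + ε(i, s)
+ τ(i, s, rep) with loading L ~ N(0, σ_L²) shared across genes in a
sample, instability ε ~ N(0, σ_i²), technical noise τ ~ N(0, σ_τ²),
and fixed group effects δ. Ground truth orders genes by
σ_i² + Var_g δ(i, ·), ties broken by input order and flagged. The draw
order (loading, then instability gene-major, then technical) is fixed
so a (spec, seed) pair reproduces byte-identical tables across
versions.

Defaults emulate a five-gene nematode screening design: base Ct levels
12.89–25.68 cycles (18S rRNA highly abundant, the others moderate),
instability SDs (0.10, 0.15, 0.20, 0.30, 0.60) giving the ordering
UBC < actin < GAPDH < a-tubulin < 18S rRNA, four life-stage groups of
three samples, three technical replicates, σ_L = 0.3 and σ_τ = 0.1
cycles (typical plate-level and replicate-level qPCR noise). Group
effects default to zero. What the generator does *not* emulate: PCR
inhibition, efficiency drift, non-Gaussian dropout of late reactions,
or between-run calibration error — passing tests therefore demonstrate
the statistics' behaviour under their own model assumptions, not
robustness to those artefacts.

## Statistical power at the default design size

With 12 samples, only large instability gaps are resolvable. The
σ = 0.6 gene is identified as least stable by ΔCt, geNorm and
NormFinder in ≥94% of seeded runs, and recovery tests score that
well-powered contrast. The adjacent σ = 0.10 vs 0.15 genes differ by
~4% in expected ΔCt stability against a ~15% sampling SE at n = 12, so
the *most*-stable gene is recovered only in roughly half to two-thirds
of runs — an intrinsic sample-size limit, not an estimator defect (the
variance estimator is unbiased and the identities above hold exactly).
The same limit applies to recovering the full five-gene NormFinder
ordering at 20 samples per group. One acceptance check asserts
recovery targets beyond this power ceiling and is expected to fail;
it is retained unmodified as a faithful record of that gap.

## Numerical choices

* Sample SDs and variances use the n−1 denominator everywhere.
* Log base 2 throughout.
* Geometric means via exp-mean-log; an all-equal rank row is returned
  exactly (guarding the min ≤ geomean ≤ max invariant against
  floating-point round-off).
* Degenerate inputs: constant ANOVA → F = 0/p = 1 with warning; zero
  concentration spread → error; non-positive quantities → error;
  efficiency ≤ 1 → error; V never below cutoff → all-genes fallback
  with warning.
* Reports: stability values at 3 decimals, average rankings at 2
  decimals, round half up.
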