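# Methods

## Query side: DEG selection and ranking

A DE table (gene, log2FC, p, BH-adjusted p, optional test statistic) is taken
as given; the package does not fit DE models.  Rows with missing log2FC,
p-value or adjusted p-value are dropped with a logged count, mirroring DESeq2
output where independent filtering leaves NA adjusted p-values.  DEGs are
selected with strict thresholds: padj < α (default 0.05) and log2FC > 0 for
up-regulated genes, log2FC < 0 for down-regulated genes; genes at exactly
log2FC = 0 or padj = α fall in neither set, so up/down/neither partition the
table.  Rankings sort genes by log2FC (or the test statistic) descending;
ties are broken by gene id ascending everywhere in the package so that every
ranking, extreme set and output table is deterministic.  Count filtering
(mean count strictly greater than a threshold, optional protein-coding
allow-list) is provided for upstream hygiene but the pipeline consumes DE
tables, not counts.

## Enrichment score and permutation significance

The enrichment score is the weighted Kolmogorov–Smirnov running-sum
statistic: walking the ranked list, a hit at rank i adds |rᵢ|^p / N_R (N_R =
Σ |r|^p over the effective set) and a miss adds −1/(N − N_H); the ES is the
running-sum value of maximal absolute deviation, signed, and the final
running-sum value is 0 to within 1e−9 by construction.  The leading edge is
the hit genes at or before the extremum (at or after it for negative ES).
The weighting exponent defaults to p = 1, the "weighted" statistic of
mainstream preranked GSEA implementations; p = 0 gives the classic
unweighted KS form.

Because the input is a preranked list, phenotype permutation is impossible;
the null is gene-set (label) permutation: n_perm (default 1000) uniform
random subsets of the same effective size.  The null generator is seeded by
(seed, set size), so one null per distinct effective size is shared across
gene sets and signatures with results identical to standalone per-set
computation, and screens are independent of library input order.  NES and
p-values are sign-stratified: NES = ES / mean(|same-sign null ES|) and
p = (#{|s| ≥ |ES|, same sign} + 1)/(count + 1).  An empty same-sign stratum
falls back to the whole null with a warning; ES = 0 returns NES 0, p 1.
Stratifying by sign keeps positive and negative enrichments on comparable
scales when the metric distribution is asymmetric; the +1 correction keeps
permutation p-values in (0, 1].  Effective sizes outside
[min_size, max_size] = [3, 5000] are skipped with a log entry; the upper
bound is far above the screen's 500-gene sets so connectivity sets are never
skipped.

BH adjustment is the standard step-up procedure (via statsmodels), validated
in the test suite against a direct O(m²) minimum-over-tails implementation.
Over-representation uses the one-sided hypergeometric upper tail with the
supplied background as the population and set ∩ background as successes.
Mean-rank aggregation across ranking libraries assigns items missing from a
library the penalty rank (library length + 1), then averages.

## Connectivity screen

Each library signature is reduced to its extreme gene sets: the n genes with
the largest z-scores and the n with the smallest, regardless of sign
(ties at a cutoff broken by gene id ascending; the down set is drawn from
genes left after removing the up set, which guarantees the two sets are
disjoint even under massive ties).  An optional flag restricts the up set to
z > 0 and the down set to z < 0, clamping with a warning; it is off by
default.  n defaults to 500 and is clamped to half the signature's gene
count with a warning for small universes (the synthetic tests use n = 100).

The query ranking uses **all** genes of the DE table, not only significant
DEGs — the information-preserving choice, since sub-threshold genes still
carry ordering information; a `degs_only` flag implements the stricter
reading.  Each extreme set is intersected with the query universe, scored by
the GSEA machinery above, and the signature's summarized score is
Total NES = NES(up) − NES(down).  Per-direction p-values are BH-corrected
within the screened library, separately for the up-set family and the
down-set family (the family size is recorded in the output header, since it
depends on the library supplied).  Results are sorted by Total NES
descending, ties by (p_up + p_down) ascending then compound name, and ranked
1..k.  Output mirrors the worked example's column layout at 6-decimal fixed
point.

The bundled worked example (top-10 rows of a published A549 screen) is used
only as parsed input for the arithmetic and count checks; reproducing its NES
values numerically would require the original genome-scale signature matrix
and query DE table, which are deliberately out of scope.  Note the published
totals were computed from unrounded NES values, so recomputing them from the
printed 6-decimal pairs matches exactly on some rows and differs by one unit
in the sixth decimal on others.

## Downstream statistics

**Jaccard similarity** of DEG sets is |A∩B|/|A∪B|, assembled into a
symmetric unit-diagonal matrix across named sets.

**Footprint pathway activities**: a pathway model is a signed weight vector
over its most responsive target genes (when a full weight table is supplied,
the top k = 100 genes by |weight| are kept per pathway).  The raw activity
is Σ weight × stat over model genes present in the data; the null permutes
the statistic values over gene labels (one shared permutation stream across
pathways), giving z = (raw − null mean)/null SD and a centered two-sided
+1-corrected permutation p.  Doubling all weights doubles the raw score and
leaves z unchanged.  Weight matrices are inputs, not shipped data, since the
published footprint weights are distributed elsewhere; synthetic models
exercise the math.

**Reporter metabolites**: per-gene Z = Φ⁻¹(1 − p) with p clamped to
[1e−15, 1 − 1e−15]; a metabolite with k network-adjacent genes scores
Z_agg = ΣZ/√k, corrected to (Z_agg − μ_k)/σ_k where μ_k, σ_k are the mean
and SD of Z_agg over n_samples (default 10000) random size-k gene draws
without replacement — a sampled background rather than a closed form,
matching the practice of the reporter-metabolite literature; one null per
distinct k, seeded by (seed, k).  p = 1 − Φ(z_corrected).  A directional
variant (reporters of down-regulation only) is obtained by pre-filtering the
gene list to one DE direction before calling the aggregation; no separate
algorithm is needed.  A null SD at or below 1e−12 (relative) is treated as
degenerate — constant nulls carry ~1e−16 floating-summation noise — and
yields z_corrected = 0 with a warning; the same rule applies to the pathway
permutation null.

## Synthetic data

`simulate_de_table` plants round(n_genes × frac_de) effect genes with true
log2FC magnitudes |Normal(0, effect_sd²)|, signs forced half positive / half
negative so both ranking tails are populated; observed log2FC adds
Normal(0, null_noise_sd²) noise, the statistic is observed/null_noise_sd,
p-values are exact two-sided normal tails (hence exactly uniform for null
genes) and padj is BH over all genes.  Defaults: 2000 genes, frac_de 0.2,
effect_sd 1.0, null_noise_sd 0.3 — a signal-to-noise in the range typical of
well-powered bulk RNA-seq fold-change estimates.  null_noise_sd must be
positive (the statistic divides by it).

`simulate_library` standardizes the true log2FC ((x − mean)/SD over genes,
so the mimic weight reads as a z-scale slope) and emits mimics
(z = weight × standardized + Normal(0, noise_sd²)), inverters (negated) and
i.i.d. standard-normal decoys, with the role in the compound name.  Default
library: 1 mimic + 1 inverter + 20 decoys, weight 2, noise 0.5.  Gene-set
simulation plants a configurable number of enriched sets drawing a stated
fraction of members from target genes; metabolite networks assign each
metabolite a uniform-degree random gene neighborhood.  All generators are
pure functions of (config, seed); distinct generators draw from distinct
streams derived from the seed, so adding one stage never perturbs another.

What the generator does **not** emulate: count-level (negative-binomial)
noise, correlated genes, batch effects, dose–response structure, or the
landmark-gene imputation of real L1000 data.  Passing tests therefore
demonstrate the statistical machinery — calibration under the null,
recovery of planted monotone signal — not performance on real data, where
gene–gene correlation inflates enrichment variance and p-values are less
well calibrated.

## Problem sizes and numerical choices

The test suite and acceptance script run the screen at 2000 genes,
extreme-set size 100 and 500 permutations, with 40-seed recovery rates; the
permutation-calibration check uses 200 random sets on a 2000-gene ranking;
reporter recovery uses 1000 genes, 20 metabolites and 2000 background
samples.  These sizes exercise every code path at full statistical fidelity
while keeping a complete run in the minutes range on one CPU; all scoring is
vectorized (batched cumulative sums over permutation-by-gene matrices,
chunked to bound memory).  Scores are written at 6-decimal fixed point and
probabilities at 6-significant-digit scientific notation; writer/reader
round trips are exact at that precision.

## Known limitations

- Gene identifiers are matched exactly and case-sensitively; identifier
  mapping is considered data curation and is out of scope.
- Permutation p-values are bounded below by 1/(n_perm + 1); deeply
  significant signatures saturate at that floor and are distinguished by NES
  rather than p.  No adaptive/multi-level permutation refinement is
  implemented.
- The screen ranks signatures, not compounds; collapsing a compound's
  multiple dose/time signatures is left to the caller (the top-table helper
  reports per-compound occurrence counts instead).
- GCT support is deliberately limited to version 1.2, the text dialect of
  level-5 style exports; 1.3 files are rejected.
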