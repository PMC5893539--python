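# Methods

## Pipeline model

`tricoord` integrates three per-gene expression parameters measured on the
same cells — transcription rate (TR), mRNA abundance (RA) and translation
activity (TA) — all on the RPKM scale
(RPKM_g = count_g / (exon_kb_g) / (mapped_reads / 10⁶)). Genes are called
expressed when at least `min_params` (default 1) of the three parameters
reach `cutoff` RPKM (default 1, boundary inclusive). By default the
library size is the in-table sum of exon counts, which keeps the pipeline
self-contained when only the count tables are available; an externally
determined mapped-read total can be passed instead (`total_mapped`), since
published totals usually count all mapped reads rather than exon-assigned
ones. Replicates are pooled into the per-assay value by the mean of
replicate RPKMs; summing counts before conversion is available
(`pooling="pooled_counts"`) and agrees with the mean when replicate depths
are equal.

All regression is ordinary least squares on log₂ values (via
`scipy.stats.linregress`), with a gene dropped from a given fit only when
either of that pair's values is non-positive. The two-slope test follows
the classical construction: two separate Student-t intervals with
one-sided tail 0.0125 (per-interval coverage 97.5%, a Bonferroni-style
pair whose non-overlap implies a difference at the joint 5% level), plus
the normal score t = (β̂₂−β̂₁)/√(σ̂²(β̂₂)+σ̂²(β̂₁)). The two-sided p-value is
evaluated as log₁₀ p = (ln 2 + logΦ̄(|t|))/ln 10 using `norm.logsf`, whose
asymptotic branch stays accurate far beyond the ~1e-308 underflow floor of
a naive CDF call; for |t| ≈ 34 this yields log₁₀ p ≈ −253. No
errors-in-variables correction is applied: RA is deliberately treated as
the fixed regressor in both panels, matching the design being reimplemented.

The stability index log₂(RA/TR) and translation index log₂(TA/RA) are
defined only for genes with all three parameters positive; excluded genes
are logged. A pseudocount option exists but is off by default — log ratios
of zeros are a data-quality signal, not something to paper over. The
indices obey the exact identity stability + translation = log₂(TA/TR),
which the tests use as an invariant.

### Permutation null

"Permuting TR and TA simultaneously" is implemented as two *independent*
gene-label permutations per replicate — one for TR, one for TA, RA fixed.
A single shared permutation would preserve the TR–TA pairing and weaken
the null; it is available as `shared_permutation=True` for comparison.
Randomness comes from one `numpy` Generator seeded with the user's integer
seed; results are bit-reproducible given (seed, n_reps, gene order). For
sample variances V_TR, V_RA, V_TA of the log₂ profiles, the expected null
correlation is −V_RA/√((V_RA+V_TR)(V_RA+V_TA)) exactly in the numerator
(E[cov] terms vanish under uniform permutation) and to O(1/n) in the
ratio; the acceptance checks verify the empirical mean against it to
within three standard errors.

### Standardization experiment

Each log₂ profile is z-scored across genes (population sd, tolerance
1e-12) and returned as 2^z, so the result is still a profile on a linear
scale and the downstream index machinery applies unchanged — the indices
of a standardized profile are z-score differences. The operation is
idempotent and rank-preserving. Because the index coupling partly rides on
the cross-parameter dispersion differences (sd rises TR → RA → TA),
standardization attenuates the index correlation; this is the basis of
the attenuation check and also a caution against applying
distribution-equalizing normalizations before multi-parameter analyses.

### UTR stratification

UTR proportion = (5′UTR + 3′UTR)/mRNA length. From a GTF, one canonical
transcript per gene is chosen deterministically: longest CDS, then longest
mRNA, then lexicographically smallest transcript id. Coordinates are
1-based inclusive per the GTF standard; exonic bases genomically before
the first CDS base are 5′UTR on + strand and 3′UTR on − strand, so a stop
codon annotated outside the CDS features is counted with the 3′UTR (a
3-base effect, negligible at transcript scale). The binned association
curve uses width-0.1 bins over [0,1] with a minimum occupancy of 50 genes
per reported bin; a single [0,1] bin reproduces the global association
exactly on the same gene set.

Defiers — stable yet poorly translated mRNAs — are selected by a closed
rectangle with defaults stability_index ≥ 0 (at least as abundant as
production predicts) and translation_index ≤ −1 (polysome signal below
half of abundance). The thresholds are explicit parameters because no
canonical numeric boundary exists for this selection. Group UTR summaries
use Student's pooled-variance two-sample t-test by default with Welch as
an option.

### Similarity strata

Index-plane distances are Euclidean. The background (unrelated-pair)
stratum is enumerated exactly for ≤ 200 genes; above that it is estimated
from a seeded uniform subsample of unordered, unlisted pairs (default cap
10⁶, configurable), which the tests verify is unbiased against full
enumeration on small instances. Strata are compared to the background by
a one-sided Mann–Whitney rank-sum test (alternative: stratum distances
smaller); a rank test is used because distance distributions are
right-skewed.

## Synthetic data: what it emulates, and what it does not

Per gene: u ~ Beta(2.2, 2.2) (unimodal UTR proportions, mean 0.5);
e ~ N(0,1) the latent translation effect; s = ρ(u)·e + √(1−ρ(u)²)·z the
stability effect; log₂TR ~ N(mu_tr, sd_tr); log₂RA = log₂TR + sd_s·s;
log₂TA = log₂RA + sd_t·e. Defaults: n_genes = 12000, mu_tr = 3 (median
≈ 8 RPKM), sd_tr = 1.0, sd_s = 0.8, sd_t = 0.6, rho0 = 0.4,
sd_rep = 0.15, two replicates. Closed forms used by the tests:
Var log₂RA = sd_tr² + sd_s²; Var log₂TA = Var RA + sd_t² +
2·sd_s·sd_t·E[ρ]; global index correlation = E[ρ(u)]; replicate
R² = (σ_p²/(σ_p²+sd_rep²))², which at sd_tr = 1, sd_rep = 0.15 gives
≈ 0.956 for TR (the binding case) — above the 0.94 repeatability bar.

The coupling curve ρ(u) is either constant or "linear decay": full
coupling ρ₀ for u ≤ u* (default 0.2), declining linearly to 0 at u = 1 —
coupling is optimal at low UTR proportion and attenuates as regulatory
sequence accrues. With the default Beta(2.2, 2.2) UTR distribution this
puts the population correlation E[ρ(u)] near 0.25·ρ₀/0.4 ≈ 0.24 at
ρ₀ = 0.4; the observed default-conditions correlation is ≈ 0.14 because
planted defiers (3% of genes, overriding the copula with s ≈ +1.2 sd,
e ≈ −2.3 sd, u ~ Beta(7,3)) are anti-coupled by construction.
Recovery metrics therefore score the copula genes against E[ρ(u)] and
report the all-gene correlation separately, and the ρ₀-sweep recovery
experiment runs with defier planting and group structure disabled — those
are separate planted structures, not part of the coupling being recovered.

Functional groups (default 20 groups of 25) share a fraction
`group_weight` (default 0.6) of their (s, e) variance, which pulls group
members together in the index plane without changing marginal variances;
the pair-score table draws a score ~ U(0,1) per candidate pair and makes
it a true same-group pair with probability equal to the score, so
higher-score strata are enriched for genuinely related genes — a noisy
confidence ranking.

Generated RPKM columns are rescaled so Σ RPKM_g·length_g = 10⁹, the
normalisation identity true RPKM satisfies; Poisson count sampling
(`counts_from_rpkm`) followed by RPKM conversion is then an unbiased round
trip. The profile's pooled values are the noise-free truth and replicates
observe them with N(0, sd_rep) log₂ noise, keeping the closed forms exact.

Not emulated: count overdispersion (Poisson only — no claim here depends
on count-level variance structure), batch effects, isoform structure, UTR
sequence content, and any real annotation release. Passing tests
demonstrate that the *statistical machinery* behaves as designed under a
model whose assumptions are known and favourable (log-normal profiles,
Gaussian coupling, independent replicate noise); they do not certify
real-data values such as a particular correlation magnitude, which depend
on measurement platform and annotation.

## Numerical and design choices

* Student-t quantiles from scipy; at df ≈ 1.3·10⁴ the t and normal
  0.9875-quantiles differ by < 3·10⁻⁴.
* Perfect fits (collinear data) are allowed: slope_se = 0 and the CI
  collapses to the point estimate.
* Pearson correlation is the default association measure (the indices are
  approximately jointly Gaussian under the model); Spearman is available.
* Sub-seeds for multi-run experiments are derived affinely from the user
  seed and kept below 2³¹.
* Problem sizes in the test-suite and acceptance experiments (12000 genes,
  1000 permutation replicates, 20-seed repetitions) match the generator's
  default study conditions; smaller configurations (~2000 genes) are used
  for unit-level checks where only correctness, not power, is at stake.

## Known limitations

* The stability index conflates mRNA stability with RNA-processing
  effects; no correction is attempted, and no absolute half-lives are
  estimated (that requires metabolic labeling).
* RPKM is within-sample normalisation; cross-sample comparability relies
  on the assays profiling the same cell population.
* The GTF reader handles the standard gene/transcript/exon/CDS dialect
  with `gene_id`/`transcript_id` attributes; exotic dialects should be
  pre-converted to the four-column UTR length table.
* The defier rectangle is a hard threshold; mRNAs just outside it are not
  scored, and precision depends on how aggressive the thresholds are
  relative to the population spread.
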