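# tricoord

Coordination analysis of three simultaneously measured transcriptome
parameters: **transcription rate** (TR, GRO-seq), **mRNA abundance** (RA,
RNA-seq) and **translation activity** (TA, polysome-profiling RNA-seq).

`tricoord` is for computational biologists who have per-gene exon read
counts (or RPKM) for the three assays and want to quantify how mRNA
stability couples to translation across the transcriptome — in particular
the *stabilization-by-translation* mechanism, in which actively translated
mRNAs are shielded from degradation.

## The statistics at its core

For each expressed gene (RPKM ≥ 1 in at least one parameter) with all
three parameters positive, two log-ratio indices are formed:

* **stability index** = log₂(RA / TR) — how far abundance deviates from
  production; an operational proxy for mRNA stability,
* **translation index** = log₂(TA / RA) — polysome loading normalised to
  abundance.

Stabilization-by-translation predicts a **positive correlation** between
the two indices. Because RA enters the two ratios with opposite signs, a
spurious *negative* correlation is the null expectation — the package
quantifies it by simultaneously permuting the TR and TA columns across
genes (RA fixed) and recomputing the association per replicate. Analytic
expectation of the null: −Var(log₂RA)/√((Var+Var_TR)(Var+Var_TA)).

Pairwise discrepancies between parameters are measured by OLS on the log2
scale, e.g. log₂(TA) = μ₁ + β₁·log₂(RA) + ε₁, with the replicate
regression log₂(RA2) = μ₂ + β₂·log₂(RA1) + ε₂ as the experimental-noise
baseline. Two slopes are compared by separate 97.5% Student-t intervals
(β̂ ± t₀.₀₁₂₅,df·σ̂(β̂)) and by the normal score
t = (β̂₂−β̂₁)/√(σ̂²(β̂₂)+σ̂²(β̂₁)), whose two-sided p-value is computed in
log space so values below 1e-300 remain exact.

Downstream, the package stratifies the index association by each mRNA's
**UTR proportion** (UTR length / mRNA length — the coupling attenuates as
regulatory UTR sequence accrues), selects "defier" mRNAs (stable yet
poorly translated) with a rectangular index threshold and tests their UTR
shift, and compares index-plane distances of gene pairs stratified by
GO-fingerprint similarity or protein-interaction confidence.

A synthetic-data generator (`tricoord.synthetic_data`) emulates all of
this with known ground truth — tunable coupling ρ(u), rising dispersion
TR→RA→TA, Beta-distributed UTR proportions, replicate noise, planted
defiers and functional groups — so the whole pipeline is testable without
any download.

## Worked example

```python
from tricoord import data_io, indices, regression_stats
from tricoord.synthetic_data import SyntheticTruth, generate

ds = generate(SyntheticTruth(seed=1))                 # 12000 genes, defaults
profile, report = data_io.filter_expressed(ds.profile)

panel = regression_stats.pairwise_panel(profile)
cmp_ = regression_stats.compare_slopes(panel["ta_vs_ra"], panel["ra2_vs_ra1"])
table = indices.compute_indices(profile)
assoc = indices.index_association(table)
perm = indices.permutation_null(profile, n_reps=1000, seed=1)
```

prints (via the obvious `print` calls):

```
expressed genes: 12000
tr_vs_ra: slope 0.604 (se 4.51e-03, R^2 0.599)
ta_vs_ra: slope 1.042 (se 4.51e-03, R^2 0.816)
ra2_vs_ra1: slope 0.985 (se 1.50e-03, R^2 0.973)
TA~RA vs RA2~RA1: t = -11.9, log10 p = -31.9, CIs overlap: False
index correlation r = 0.138 (slope 0.176)
permutation null: 1000/1000 negative, max r = -0.500
after standardization: r = 0.026
parameter       sd  value_range
       tr 0.999004     8.027843
       ra 1.280435     9.344796
       ta 1.476585    10.453092
```

Reading: the TR~RA slope (0.60) is well below the replicate baseline
(0.99) and the TA~RA slope (1.04) is significantly above it — dispersion
rises from transcription to abundance to translation (sd 1.00 → 1.28 →
1.48), i.e. gene expression becomes more selective down the cascade. The
observed index correlation (+0.14) sits far above a permutation null that
is *always* negative (max −0.50), and standardizing the three profiles
first collapses it (0.14 → 0.03): the coupling lives in the
cross-parameter dispersion differences that standardization removes.

The same analysis is available from the shell:

```sh
tricoord synth --seed 1 --out data/
tricoord run-all --config run.yaml --seed 1 --out results/
```

`run-all` writes every stage's tables plus `manifest.json` (config hash,
seed, per-stage gene counts, headline statistics); re-running with the
same config and seed reproduces every output byte-identically.

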