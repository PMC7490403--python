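# Methods

## Problem setting

Two haploid isolates of one fungal species colonize the same root
system. Bulk RNA-seq of the root mixes transcripts from both. After
mapping to the reference isolate's genome and variant calling at
ploidy 1 (minimum coverage 10 reads, as a caller like freebayes is run
for haploid organisms), three kinds of samples exist per host-plant
genotype: single inoculations of the reference isolate, single
inoculations of the alternative isolate, and coinoculations. The
package answers two questions per host: *in what proportion do the two
isolates coexist in each coinoculated sample*, and *which genes are
induced only when they coexist*.

## Diagnostic-site filter

Per host, per-sample VCFs are merged into one table over the union of
positions; samples lacking a record at a position get a missing call.
Mock-inoculated samples never enter the merge. Multiallelic sites are
dropped (the downstream frequency model is defined for one alternative
allele), and by default sites are restricted to single-nucleotide
ref/alt (`snv_only`, configurable). The three keep-rules are applied in
order, with survivor counts recorded: (1) a `GT=1` call somewhere, (2)
no missing genotype anywhere, (3) `GT=1` in the alternative-isolate
single samples. Rule 3 defaults to *all* such samples (`rule3 = "all"`),
which makes retained sites strictly diagnostic between the parents; the
`any` reading is available because replicated single inoculations leave
the strict/loose choice genuinely open.

Rule 2 checks the genotype field only; read-depth thresholds belong to
the calling step upstream and are not re-applied.

## Mixture model and estimators

At a retained site, a read drawn from the mixed transcript pool carries
the alternative allele with probability `q = p(1 − 2e) + e`, where `p`
is the alternative isolate's proportion and `e` a symmetric per-read
error rate. With site depth `d`, the alternative-read count is
Binomial(d, q), so the per-site frequency `AO/(RO+AO)` scatters around
`p` and the per-sample frequency distribution concentrates there.
Within-sample frequencies require per-allele observation counts
(`RO`/`AO`); genotype and total depth alone cannot produce an
intermediate frequency at a single site for a single sample, so those
caller fields are a hard input requirement. Sites with zero informative
reads for a sample are skipped for that sample and counted.

Estimators of `p` per sample:

* **peak** (headline): Gaussian KDE with Silverman's bandwidth
  `0.9·min(sd, IQR/1.34)·n^(−1/5)`, floored at 0.01 so degenerate
  (zero-spread) series stay well-defined, evaluated on the closed grid
  `{0, 0.001, …, 1}`; the estimate is the grid argmax, with tied maxima
  averaged (densities are quantized to 1e−9 before the argmax so
  analytically tied points tie despite float rounding). A fixed grid
  makes the estimate deterministic and resolution-controlled; a
  histogram mode would inherit bin-origin sensitivity.
* **mean**: arithmetic mean of the frequencies. At equal site depths
  this equals pooled alternative reads over pooled reads.
* **hist**: center of the fullest 0.02-wide histogram bin, for
  sensitivity analysis; it resolves only to half a bin (a pure sample
  reads 0.99, not 1.0).

The peak is preferred because the frequency distribution of a real
mixed sample can be skewed by expression differences between genes; the
mode is less sensitive to such tails than the mean. Ratios are printed
as `round(100·(1−p))`:`100 − round(100·(1−p))`. Evenness `1 − |2p − 1|`
is this package's quantitative form of "how even is the coexistence";
it is reported descriptively.

Measured on synthetic data at the validation scale (2000 sites, Poisson
depth mean 30, e = 0.001, 20 seeds per proportion), the peak estimator's
mean absolute error is ≈ 0.012 across true p ∈ {0.1, …, 0.9}, and
seed-averaged estimates are strictly monotone in the true proportion.
Near the boundaries the KDE mode is biased slightly inward (≈ 0.015 at
p = 0.1), the usual kernel boundary effect.

## Differential-expression stage

This stage is a deliberately small NB testing machine, not a DESeq2
re-implementation; its purpose is to feed the intersection criterion
with honest per-contrast p-values while keeping the pipeline free of
external statistics engines. Externally computed contrast tables can be
fed directly to `intersect` when a full DESeq2 analysis is preferred.

* **Size factors**: median-of-ratios over genes with strictly positive
  geometric mean across samples, rescaled to geometric mean 1; a
  `poscounts`-style fallback handles matrices with no everywhere-
  positive gene. This corrects library size and RNA composition bias.
* **Group means**: for each contrast (coinoculation vs one single
  inoculation), the group mean solves the offset log-link estimating
  equation, `μ̂ = Σy / Σs`. A group with zero total counts is given half
  a read so fold changes and standard errors stay finite.
* **Dispersion**: per-gene method of moments on the pooled within-group
  residuals, solving `E[(y − sμ)²] = sμ + α(sμ)²` with an `n/(n−2)`
  small-sample factor. Raw gene-wise estimates at 3+3 replicates are so
  noisy that chance under-dispersion (negative moment estimates floored
  at the Poisson limit) masquerades as significance, inflating the
  type-I error ≈ 2.6-fold. Each gene's estimate is therefore floored at
  the median positive estimate across genes — a minimal cross-gene
  moderation in the spirit of dispersion shrinkage — and finally at
  1e−8 (Poisson limit). Measured on null simulations (1000 genes, 3 vs
  3): rejection at raw p < 0.05 is ≈ 0.05–0.07 and the p-value KS
  distance from uniform ≈ 0.02–0.03. A Student-t reference with raw
  gene-wise dispersions is equally well calibrated but costs most of
  the power at BH-corrected thresholds; the moderated-dispersion route
  keeps both calibration and ≈ 0.88 recall of 4-fold planted effects.
* **Wald test**: `z = (log μ̂_coin − log μ̂_single) / SE` with the
  delta-method standard error from the NB variance; two-sided p from
  the standard normal; BH adjustment across genes (undefined p counts
  as 1). Genes with all-zero counts in both groups get NaN statistics
  and raw p = 1.
* **Intersection**: `genes_both` = adjusted p < α (default 0.1) in both
  contrasts; `genes_up_both` additionally requires log2 fold change
  > 0 in both. Both sets are emitted because significance-only and
  concordant-up readings of "different in both comparisons" are both
  defensible; the up-set is the headline, as induction is the
  biological signal of interest. Lists are ordered by the worse of the
  two adjusted p-values.

Known behavioral differences from DESeq2: no trended dispersion prior or
MAP shrinkage, no independent filtering, no Cook's outlier handling, no
log-fold-change shrinkage. With few replicates and moderate effects this
machine is somewhat conservative (realized false-discovery proportion of
the intersection ≈ 0.01 at the validation settings).

## Synthetic-data generator

The generator is the package's stand-in for deposited sequencing data
and defines its validation conditions:

* Variant tables: Poisson per-site depths (mean 30 by default, chosen
  for statistical power at typical RNA-seq coverage of expressed
  transcripts rather than fidelity to any particular dataset), symmetric
  read-error rate 0.001, binomial alternative-read counts, haploid
  genotype = majority allele (ties toward reference, mirroring a
  ploidy-1 caller's output shape), missing call when depth < 10 —
  emulating the upstream caller's minimum-coverage rule at generation
  time. Single-inoculation samples are constrained to p = 0 or 1.
* Count matrices: gamma–Poisson (NB) counts, gene baseline means
  log-uniform on [5, 500], common dispersion 0.1, per-sample size
  factors uniform on [0.7, 1.4], three treatments × 3 replicates
  (matching the replication level of the motivating experiment), and a
  designated gene set multiplied by `2^log2_effect` (default 2, a
  4-fold induction) in the coinoculation condition only.
* Seeds are mandatory; identical configs give byte-identical VCFs and
  matrices. Orchestrated runs derive per-host child seeds from the
  top-level seed via `SeedSequence`.

What the generator does **not** emulate: linkage between sites on one
transcript (site frequencies are drawn independently, whereas reads from
one gene share the expression level of whichever isolate transcribed
it), expression-weighted site coverage, mapping bias against the
non-reference isolate, nuclear heterogeneity within an isolate,
contamination, and batch structure in the count matrix. Passing the
validation suite therefore demonstrates correctness of the algorithms
under the stated model, not robustness to those real-data effects — on
real data the allele-frequency distribution is wider and more skewed
than binomial, which is exactly why the peak estimator, not the mean, is
the headline.

## Numerical and degenerate-input conventions

Grid resolution 0.001 bounds the peak estimator's quantization error;
ties average. Empty frequency series, designs without the required
roles, samples missing from a design, conflicting reference alleles at
one position, and count matrices with a group of fewer than two
replicates all raise typed errors before any statistics are computed.
Filtering an already-filtered table is a no-op; permuting rows or
columns never changes the retained set.

## Validation scales

The test suite and the acceptance script run entirely on synthetic data
at these sizes, chosen to keep the full validation under a minute while
leaving the Monte-Carlo tolerances comfortably resolvable: 1000 random
tables (≤ 50 sites × ≤ 8 samples) for the filter oracle; 9 proportions
× 20 seeds × 2000 sites for mixture recovery; 1000 genes × (3 vs 3)
for null calibration and 20 seeds of the same size for power/FDP; three
hosts × 2000 sites × 1000 genes end to end.
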