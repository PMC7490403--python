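# coexseq

Quantify the coexistence of two genetically different haploid fungal
genotypes inside the same plant roots from bulk RNA-seq, and detect the
genes they switch on only when they meet.

Arbuscular mycorrhizal fungi such as *Rhizophagus irregularis* colonize
roots as mixtures of closely related isolates. When RNA-seq reads from a
coinoculated plant are mapped to one isolate's genome and variants are
called at haploid ploidy, sites where the two isolates carry different
fixed alleles become *diagnostic*: the alternative-allele read fraction
at such a site estimates the fraction of fungal material contributed by
the non-reference isolate. `coexseq` implements this deconvolution and
the companion differential-expression criterion for genes induced
specifically during coexistence, plus a synthetic-data generator so the
whole pipeline can be validated without any sequencing data.

The package is aimed at people analysing mixed-genotype colonization —
of plants by fungal symbionts or any comparable two-strain haploid
system — who have per-sample VCFs (haploid `GT`, `DP`, `RO`/`AO`) and a
gene-level count matrix.

## The method

**Diagnostic-site filter.** Per host genotype, multi-sample VCFs are
merged (union of positions) and sites are kept when

1. a variant call (`GT=1`) appears in at least one sample,
2. every sample has a genotype call (no missing data), and
3. the alternative-isolate single-inoculation samples all carry `GT=1`.

**Mixture deconvolution.** For sample *s* at retained site *i*, the
alternative-allele frequency is `f_si = AO / (RO + AO)`. Under binomial
read sampling, `f_si ≈ p_s`, the proportion of the alternative isolate
in sample *s*. The headline estimator is the mode of a Gaussian KDE of
`{f_si}` (Silverman bandwidth, floored at 0.01) on a fixed grid over
[0, 1]; the arithmetic mean and a fixed-width histogram mode are
reported alongside. Results are expressed as `ref:alt` integer percents
(e.g. `55:45`) and as coexistence evenness `1 − |2p − 1|` (1 at 50:50,
0 at purity).

**Coexistence-induced genes.** Per gene, a negative-binomial Wald test
(median-of-ratios size factors, moderated method-of-moments dispersion)
contrasts the coinoculation treatment against *each* single-inoculation
treatment; p-values are Benjamini–Hochberg adjusted, and a gene is
called coexistence-induced only when adjusted p < 0.1 with a positive
log2 fold change in **both** contrasts. Requiring both contrasts
excludes genes that merely differ between the two isolates.

**Host summary.** Per host: mixture ratios, mean evenness of the
coinoculated samples, and the induced-gene count — the cross-host
pattern of interest being that more even coexistence accompanies more
induced genes.

## Worked example

`examples/02_estimate_mixture.py` simulates one host with pure controls
and three coinoculated samples planted at 59%, 45% and 34% alternative
isolate, filters the sites and deconvolves every sample:

```
sample    true p   peak   mean  ratio    evenness
ref_1       0.00  0.000  0.001  100:0    0.00
alt_1       1.00  1.000  0.999  0:100    0.00
coin_1      0.59  0.571  0.587  43:57    0.86
coin_2      0.45  0.453  0.452  55:45    0.91
coin_3      0.34  0.313  0.344  69:31    0.63
```

The pure single-inoculation samples anchor the scale at exactly 0 and 1;
each coinoculated sample's peak estimate lands within ~0.03 of the
planted proportion at 2000 sites and 30× depth.

`examples/04_full_pipeline.py` runs three hosts end to end and prints
the evenness/induced-gene association:

```
host_genotype  mean_evenness  n_genes_up_both
        hostA       0.930667               45
        hostB       0.408667               18
        hostC       0.132000                7

Spearman(evenness, induced genes) = 1.00
```

Hosts planted with 50/20/8 induced genes and decreasing evenness are
recovered in the planted order; recall is below 100% because the
intersection criterion is conservative at three replicates.

The same stages are available as shell commands (`coexseq simulate`,
`coexseq filter-vcf`, `coexseq estimate-mixture`, `coexseq diffexpr`,
`coexseq intersect`, `coexseq report`) for use on real VCF/TSV inputs.

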