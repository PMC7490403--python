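"""Estimate each sample's isolate mixture from allele-frequency peaks.

At diagnostic sites the alternative-allele read fraction of a sample
tracks the proportion of the alternative isolate.  Single inoculations
peak at 0 or 1; coinoculated plants peak in between.  Three coinoculated
samples are planted at 41:59, 55:45 and 66:34 (reference:alternative).
"""

from coexseq import apply_filters, estimate_mixture, frequency_series, simulate_variants
from coexseq.synthetic import VariantSampleSpec, VariantSimConfig, design_from_variant_config

cfg = VariantSimConfig(
    n_sites=2000,
    depth_mean=30.0,
    depth_model="poisson",
    error_rate=0.001,
    sample_specs=[
        VariantSampleSpec("ref_1", "single_ref", 0.0),
        VariantSampleSpec("alt_1", "single_alt", 1.0),
        VariantSampleSpec("coin_1", "coinoculation", 0.59),
        VariantSampleSpec("coin_2", "coinoculation", 0.45),
        VariantSampleSpec("coin_3", "coinoculation", 0.34),
    ],
    seed=11,
)
table, truth = simulate_variants(cfg)
retained, _ = apply_filters(table, design_from_variant_config(cfg))

print(f"{'sample':8s} {'true p':>7s} {'peak':>6s} {'mean':>6s}  ratio    evenness")
for sample in table.samples:
    series = frequency_series(retained, sample)
    peak = estimate_mixture(series, method="peak")
    mean = estimate_mixture(series, method="mean")
    p = truth.true_alt_proportion[sample]
    print(f"{sample:8s} {p:7.2f} {peak.p_alt:6.3f} {mean.p_alt:6.3f}  "
          f"{peak.ratio_text:7s}  {peak.evenness:.2f}")
# 'ratio' is reference:alternative in integer percents; evenness is
# 1 - |2p - 1|, i.e. 1.0 at a 50:50 mixture and 0.0 for a pure sample.
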