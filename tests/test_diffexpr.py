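"""Size factors, the NB Wald test, BH adjustment and the intersection criterion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import oracle_bh, oracle_median_of_ratios

from coexseq.design import DesignError, SampleDesign, SampleSpec
from coexseq.diffexpr import (
    DEComparison,
    NormalizationError,
    bh_adjust,
    intersect,
    nb_wald_test,
    read_contrast_tsv,
    run_host_de,
    size_factors,
    write_comparison_tsv,
)
from coexseq.synthetic import CountSimConfig, simulate_counts


def design_3v3v3(host="H"):
    specs = []
    for role in ("single_ref", "single_alt", "coinoculation"):
        for k in (1, 2, 3):
            specs.append(SampleSpec(f"{role}_{k}", role, host))
    return SampleDesign(specs)


def counts_frame(array, design):
    return pd.DataFrame(array, index=[f"g{i}" for i in range(len(array))],
                        columns=design.sample_ids)


class TestSizeFactors:
    def test_doubled_sample_gives_sqrt2_split(self):
        counts = pd.DataFrame({"A": [10, 50, 7], "B": [20, 100, 14]})
        sf = size_factors(counts)
        assert sf["B"] / sf["A"] == pytest.approx(2.0)
        assert sf["A"] == pytest.approx(1 / np.sqrt(2))

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"A": [3, 9, 1], "B": [3, 9, 1], "C": [3, 9, 1]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            x = rng.integers(1, 400, size=(20, 4))
            counts = pd.DataFrame(x, columns=list("abcd"))
            sf = size_factors(counts).to_numpy()
            raw = np.asarray(oracle_median_of_ratios(x.tolist()))
            rescaled = raw / np.exp(np.mean(np.log(raw)))
            assert np.allclose(sf, rescaled)

    def test_column_scaling_scales_its_factor_relative_to_the_others(self):
        # scaling sample j's column by c moves every gene's pseudo-reference
        # by c^(1/m) as well, so the clean invariant is on factor ratios:
        # sf_j/sf_k gains exactly a factor c for every other sample k
        rng = np.random.default_rng(8)
        x = rng.integers(1, 300, size=(30, 3)).astype(float)
        c = 3.7
        raw = np.asarray(oracle_median_of_ratios(x.tolist()))
        x2 = x.copy()
        x2[:, 1] *= c
        raw2 = np.asarray(oracle_median_of_ratios(x2.tolist()))
        for k in (0, 2):
            assert raw2[1] / raw2[k] == pytest.approx(c * raw[1] / raw[k])
        # the package's rescaled factors shift by the same ratio
        sf = size_factors(pd.DataFrame(x))
        sf2 = size_factors(pd.DataFrame(x2))
        assert (sf2[1] / sf[1]) / (sf2[0] / sf[0]) == pytest.approx(c)

    def test_no_everywhere_positive_gene_needs_fallback(self):
        counts = pd.DataFrame({"A": [0, 5], "B": [5, 0]})
        with pytest.raises(NormalizationError):
            size_factors(counts)
        sf = size_factors(counts, fallback="poscounts")
        assert (sf > 0).all()


class TestBHAdjust:
    def test_worked_example(self):
        adj = bh_adjust([0.01, 0.02, 0.05, 0.5])
        assert np.allclose(adj, [0.04, 0.04, 0.05 * 4 / 3, 0.5])

    def test_all_equal_p_stay_equal(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]).tolist() == [0.37]

    def test_nan_is_treated_as_one(self):
        adj = bh_adjust([0.01, np.nan])
        assert adj[1] == 1.0

    def test_out_of_range_p_is_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                    min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_textbook_oracle(self, pvals):
        assert np.allclose(bh_adjust(pvals), oracle_bh(pvals), atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=40)
        perm = rng.permutation(40)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestNbWaldTest:
    def test_equal_group_means_give_near_zero_statistic(self):
        design = design_3v3v3()
        rng = np.random.default_rng(1)
        # large, equal Poisson means: the contrast should be null
        x = rng.poisson(500, size=(300, 9))
        comp = nb_wald_test(counts_frame(x, design), design, "coin_vs_single_ref")
        assert np.nanmedian(np.abs(comp.results["wald_stat"])) < 1.5
        assert comp.results["p_raw"].median() > 0.2

    def test_all_zero_gene_gets_undefined_stats_and_p_one(self):
        design = design_3v3v3()
        x = np.vstack([np.zeros(9, dtype=int), np.full(9, 50)])
        comp = nb_wald_test(counts_frame(x, design), design, "coin_vs_single_ref")
        assert np.isnan(comp.results.loc["g0", "wald_stat"])
        assert comp.results.loc["g0", "p_raw"] == 1.0

    def test_null_type_one_error_within_envelope(self):
        cfg = CountSimConfig(n_genes=1000, n_reps=3, seed=13, log2_effect=0.0)
        counts, design, _ = simulate_counts(cfg)
        comp = nb_wald_test(counts, design, "coin_vs_single_ref")
        frac = (comp.results["p_raw"] < 0.05).mean()
        assert 0.03 <= frac <= 0.09

    def test_null_p_values_are_roughly_uniform(self):
        from scipy import stats

        cfg = CountSimConfig(n_genes=1000, n_reps=3, seed=13, log2_effect=0.0)
        counts, design, _ = simulate_counts(cfg)
        comp = nb_wald_test(counts, design, "coin_vs_single_ref")
        ks = stats.kstest(comp.results["p_raw"], "uniform").statistic
        assert ks < 0.05

    def test_under_replicated_group_is_a_design_error(self):
        specs = [SampleSpec("a", "single_ref", "H"), SampleSpec("b", "single_ref", "H"),
                 SampleSpec("c", "coinoculation", "H")]
        design = SampleDesign(specs)
        counts = pd.DataFrame(np.full((5, 3), 10), columns=design.sample_ids)
        with pytest.raises(DesignError):
            nb_wald_test(counts, design, "coin_vs_single_ref")

    def test_induced_genes_rank_above_null_genes(self):
        # all-pairs AUC of induced vs non-induced genes on the worst p_adj
        cfg = CountSimConfig(n_genes=500, n_reps=3, seed=21, log2_effect=2.0,
                             coexistence_gene_ids=tuple(range(1, 26)))
        counts, design, truth = simulate_counts(cfg)
        ref, alt, _ = run_host_de(counts, design)
        worst = np.maximum(ref.results["p_adj"], alt.results["p_adj"])
        induced = counts.index.isin(truth.induced_gene_ids)
        from scipy.stats import mannwhitneyu

        u = mannwhitneyu(worst[~induced], worst[induced]).statistic
        auc = u / (induced.sum() * (~induced).sum())
        assert auc > 0.9


def comparison_from(genes, p_adj, lfc, contrast="c"):
    df = pd.DataFrame({"log2_fold_change": lfc, "p_adj": p_adj, "p_raw": p_adj},
                      index=genes)
    return DEComparison(contrast=contrast, results=df, size_factors=pd.Series(dtype=float))


class TestIntersect:
    def test_gene_significant_in_one_contrast_only_is_excluded(self):
        a = comparison_from(["g1"], [0.01], [2.0])
        b = comparison_from(["g1"], [0.5], [2.0])
        res = intersect(a, b, alpha=0.1)
        assert res.genes_both == [] and res.genes_up_both == []

    def test_gene_significant_and_up_in_both_is_included(self):
        a = comparison_from(["g1"], [0.05], [1.2])
        b = comparison_from(["g1"], [0.09], [0.8])
        res = intersect(a, b, alpha=0.1)
        assert res.genes_up_both == ["g1"]

    def test_discordant_direction_is_both_but_not_up(self):
        a = comparison_from(["g1"], [0.01], [1.0])
        b = comparison_from(["g1"], [0.01], [-1.0])
        res = intersect(a, b, alpha=0.1)
        assert res.genes_both == ["g1"] and res.genes_up_both == []

    def test_matches_brute_force_set_logic_on_random_tables(self):
        rng = np.random.default_rng(99)
        genes = [f"g{i}" for i in range(200)]
        for _ in range(30):
            pa, pb = rng.uniform(size=200), rng.uniform(size=200)
            la, lb = rng.normal(size=200), rng.normal(size=200)
            res = intersect(comparison_from(genes, pa, la),
                            comparison_from(genes, pb, lb), alpha=0.3)
            expect_both = {g for g, x, y in zip(genes, pa, pb) if x < 0.3 and y < 0.3}
            expect_up = {g for g, x, y, u, v in zip(genes, pa, pb, la, lb)
                         if x < 0.3 and y < 0.3 and u > 0 and v > 0}
            assert set(res.genes_both) == expect_both
            assert set(res.genes_up_both) == expect_up

    def test_commutative_and_monotone_in_alpha(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(100)]
        a = comparison_from(genes, rng.uniform(size=100), rng.normal(size=100))
        b = comparison_from(genes, rng.uniform(size=100), rng.normal(size=100))
        r1 = intersect(a, b, alpha=0.2)
        r2 = intersect(b, a, alpha=0.2)
        assert set(r1.genes_both) == set(r2.genes_both)
        prev: set = set()
        for alpha in (0.01, 0.05, 0.2, 0.5, 1.0):
            cur = set(intersect(a, b, alpha=alpha).genes_both)
            assert prev <= cur
            prev = cur

    def test_mismatched_gene_universe_is_an_error(self):
        a = comparison_from(["g1"], [0.1], [1.0])
        b = comparison_from(["g2"], [0.1], [1.0])
        with pytest.raises(ValueError):
            intersect(a, b)

    def test_sorted_by_worst_adjusted_p(self):
        a = comparison_from(["g1", "g2"], [0.01, 0.05], [1, 1])
        b = comparison_from(["g1", "g2"], [0.09, 0.02], [1, 1])
        res = intersect(a, b, alpha=0.1)
        assert res.genes_up_both == ["g2", "g1"]  # worst p: 0.05 vs 0.09

    def test_external_contrast_tsv_round_trip(self, tmp_path):
        a = comparison_from(["g1", "g2"], [0.01, 0.4], [1.0, -0.5])
        write_comparison_tsv(a, tmp_path / "a.tsv")
        back = read_contrast_tsv(tmp_path / "a.tsv")
        res = intersect(back, back, alpha=0.1)
        assert res.genes_up_both == ["g1"]
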