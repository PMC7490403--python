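import numpy as np
import pytest

from coexseq.design import SampleDesign, SampleSpec
from coexseq.variants import VariantTable


def make_table(genotypes, samples=None, ref_obs=None, alt_obs=None, depth=None,
               alt=None, ref=None):
    """Build a small VariantTable from a genotype matrix (rows = sites).

    Observation counts default to something consistent with the genotype
    (20 reads of the called allele) so frequency code can run on toys.
    """
    gt = np.asarray(genotypes, dtype=np.int8)
    n, m = gt.shape
    if samples is None:
        samples = [f"s{j}" for j in range(m)]
    if ref_obs is None:
        ref_obs = np.where(gt == 0, 20, 0)
    if alt_obs is None:
        alt_obs = np.where(gt == 1, 20, 0)
    ref_obs = np.asarray(ref_obs, dtype=np.int32)
    alt_obs = np.asarray(alt_obs, dtype=np.int32)
    if depth is None:
        depth = ref_obs + alt_obs
    return VariantTable(
        contig=["tig1"] * n,
        pos=np.arange(1, n + 1, dtype=np.int64) * 10,
        ref=ref if ref is not None else ["A"] * n,
        alt=alt if alt is not None else [("T",)] * n,
        samples=list(samples),
        genotype=gt,
        depth=np.asarray(depth, dtype=np.int32),
        ref_obs=ref_obs,
        alt_obs=alt_obs,
    )


def random_table_and_design(rng, max_sites=50, max_samples=8):
    """Random haploid table plus a design with >=1 sample of each role."""
    n = rng.integers(1, max_sites + 1)
    m = rng.integers(3, max_samples + 1)
    gt = rng.choice([-1, 0, 1], size=(n, m), p=[0.1, 0.45, 0.45]).astype(np.int8)
    roles = ["single_ref", "single_alt", "coinoculation"]
    roles += list(rng.choice(["single_ref", "single_alt", "coinoculation"], size=m - 3))
    rng.shuffle(roles)
    samples = [f"s{j}" for j in range(m)]
    design = SampleDesign(
        SampleSpec(s, role, "HOST") for s, role in zip(samples, roles)
    )
    return make_table(gt, samples=samples), design


@pytest.fixture
def toy_design():
    return SampleDesign([
        SampleSpec("ref_1", "single_ref", "HOST"),
        SampleSpec("ref_2", "single_ref", "HOST"),
        SampleSpec("alt_1", "single_alt", "HOST"),
        SampleSpec("alt_2", "single_alt", "HOST"),
        SampleSpec("coin_1", "coinoculation", "HOST"),
    ])


# ---------------------------------------------------------------------------
# Independent straight-line oracles (deliberately naive; no package calls)
# ---------------------------------------------------------------------------

def oracle_filter(genotypes, alt_sample_cols, rule3="all"):
    """The three keep-rules, re-implemented site by site.

    1. a variant (genotype 1) in at least one sample;
    2. no sample missing;
    3. the alternative-isolate single samples show genotype 1.
    Returns (kept_row_indices, n1, n2, n3) with sequential counts.
    """
    kept, n1 = [], 0
    n2 = 0
    for i, row in enumerate(genotypes):
        r1 = any(g == 1 for g in row)
        r2 = all(g != -1 for g in row)
        alt_gts = [row[j] for j in alt_sample_cols]
        if rule3 == "all":
            r3 = all(g == 1 for g in alt_gts)
        else:
            r3 = any(g == 1 for g in alt_gts)
        if r1:
            n1 += 1
            if r2:
                n2 += 1
                if r3:
                    kept.append(i)
    return kept, n1, n2, len(kept)


def oracle_bh(pvals):
    """Textbook BH adjustment: p_(i) * m / i, cumulative minimum from the top."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


def oracle_median_of_ratios(matrix):
    """Unrescaled median-of-ratios size factors on a genes x samples array."""
    import math

    rows = [r for r in matrix if all(v > 0 for v in r)]
    factors = []
    for j in range(len(matrix[0])):
        ratios = []
        for r in rows:
            geomean = math.exp(sum(math.log(v) for v in r) / len(r))
            ratios.append(r[j] / geomean)
        ratios.sort()
        k = len(ratios)
        med = ratios[k // 2] if k % 2 else 0.5 * (ratios[k // 2 - 1] + ratios[k // 2])
        factors.append(med)
    return factors
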