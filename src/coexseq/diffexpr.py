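"""Coexistence-specific differential expression: NB Wald tests and intersection.

A gene counts as induced by coexistence only if it is significant
(BH-adjusted p below ``alpha``, default 0.1) in *both* pairwise
contrasts: coinoculation vs the reference-isolate single inoculation,
and coinoculation vs the alternative-isolate single inoculation.  The
intersection guards against calling genes that merely differ between the
two isolates.

The per-contrast test is a deliberately small NB machine, not a DESeq2
re-implementation: median-of-ratios size factors, gene-wise
method-of-moments dispersion with a Poisson floor (no shrinkage across
genes), group means fitted by the offset log-link estimating equation
(sum of counts over sum of size factors), and a normal-approximation
Wald statistic on the log fold change.  Externally computed per-contrast
tables (gene_id, log2_fold_change, p_adj) can be fed straight to
:func:`intersect` instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import DesignError, SampleDesign

DISPERSION_FLOOR = 1e-8
ALPHA_DEFAULT = 0.1

CONTRASTS = ("coin_vs_single_ref", "coin_vs_single_alt")
_BASELINE_ROLE = {"coin_vs_single_ref": "single_ref", "coin_vs_single_alt": "single_alt"}


class NormalizationError(ValueError):
    pass


def size_factors(counts: pd.DataFrame, fallback: str | None = None) -> pd.Series:
    """Median-of-ratios library size factors, rescaled to geometric mean 1.

    For each sample, the factor is the median over genes (restricted to
    genes with a strictly positive geometric mean across samples) of the
    gene's count divided by its across-sample geometric mean.  This
    corrects for both sequencing depth and RNA composition bias.
    ``fallback='poscounts'`` computes gene geometric means over positive
    counts only, for matrices where no gene is positive everywhere.
    """
    x = counts.to_numpy(dtype=float)
    if fallback is None:
        positive = (x > 0).all(axis=1)
        if not positive.any():
            raise NormalizationError(
                "no gene has positive counts in every sample; "
                "retry with fallback='poscounts'"
            )
        logx = np.log(x[positive])
        log_geomean = logx.mean(axis=1)
        ratios = np.exp(logx - log_geomean[:, None])
        log_sf = np.log(np.median(ratios, axis=0))
    else:
        if fallback != "poscounts":
            raise ValueError(f"unknown fallback {fallback!r}")
        with np.errstate(divide="ignore"):
            logx = np.log(x)
        log_geomean = np.array(
            [row[np.isfinite(row)].mean() if np.isfinite(row).any() else -np.inf
             for row in logx]
        )
        usable = np.isfinite(log_geomean)
        if not usable.any():
            raise NormalizationError("count matrix is all zeros")
        log_sf = np.empty(x.shape[1])
        for j in range(x.shape[1]):
            lr = logx[usable, j] - log_geomean[usable]
            lr = lr[np.isfinite(lr)]
            if lr.size == 0:
                raise NormalizationError(f"sample {counts.columns[j]!r} has no usable gene")
            log_sf[j] = np.log(np.median(np.exp(lr)))
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (undefined inputs count as 1)."""
    p = np.asarray(p_raw, dtype=float).copy()
    p[np.isnan(p)] = 1.0
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        bad = p[(p < 0) | (p > 1)][0]
        raise ValueError(f"p-value {bad} outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEComparison:
    """Per-gene statistics for one pairwise contrast.

    ``results`` has columns base_mean_single, base_mean_coin,
    log2_fold_change (coinoculation over single), wald_stat, p_raw, p_adj,
    indexed by gene id.
    """

    contrast: str
    results: pd.DataFrame
    size_factors: pd.Series

    @property
    def gene_ids(self) -> pd.Index:
        return self.results.index

    def significant(self, alpha: float = ALPHA_DEFAULT) -> pd.Index:
        return self.results.index[self.results["p_adj"] < alpha]


def nb_wald_test(
    counts: pd.DataFrame,
    design: SampleDesign,
    contrast: str,
    sf: pd.Series | None = None,
    sf_fallback: str | None = None,
) -> DEComparison:
    """Two-group NB Wald test of coinoculation against one single inoculation.

    Size factors are computed on the full matrix (all samples given),
    then the two groups named by ``contrast`` are compared gene by gene.
    Genes with zero counts in every compared sample get NaN statistics
    and raw p = 1.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {CONTRASTS}, got {contrast!r}")
    for s in counts.columns:
        if s not in design:
            raise DesignError(f"sample {s!r} in count matrix is absent from design")
    if sf is None:
        sf = size_factors(counts, fallback=sf_fallback)

    base_role = _BASELINE_ROLE[contrast]
    group_a = [s for s in counts.columns if design.role_of(s) == base_role]
    group_b = [s for s in counts.columns if design.role_of(s) == "coinoculation"]
    for role, grp in ((base_role, group_a), ("coinoculation", group_b)):
        if len(grp) < 2:
            raise DesignError(f"group {role!r} has {len(grp)} replicate(s); need >= 2")

    y_a = counts[group_a].to_numpy(dtype=float)
    y_b = counts[group_b].to_numpy(dtype=float)
    sf_a = sf[group_a].to_numpy()
    sf_b = sf[group_b].to_numpy()

    all_zero = (y_a.sum(axis=1) == 0) & (y_b.sum(axis=1) == 0)
    mu_a = _group_mean(y_a, sf_a)
    mu_b = _group_mean(y_b, sf_b)
    alpha_hat = _mom_dispersion(y_a, y_b, sf_a, sf_b, mu_a, mu_b)

    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mu_b / mu_a)
        se2 = _log_mean_var(mu_a, sf_a, alpha_hat) + _log_mean_var(mu_b, sf_b, alpha_hat)
        wald = (np.log(mu_b) - np.log(mu_a)) / np.sqrt(se2)
    p_raw = 2.0 * stats.norm.sf(np.abs(wald))
    lfc[all_zero] = np.nan
    wald[all_zero] = np.nan
    p_raw[all_zero] = 1.0

    results = pd.DataFrame(
        {
            "base_mean_single": mu_a,
            "base_mean_coin": mu_b,
            "log2_fold_change": lfc,
            "wald_stat": wald,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
        },
        index=counts.index,
    )
    return DEComparison(contrast=contrast, results=results, size_factors=sf)


def _group_mean(y: np.ndarray, sf: np.ndarray) -> np.ndarray:
    # MLE of the group mean in the offset log-link model; a group with no
    # reads gets half a read so the log fold change and Wald stay finite.
    total = y.sum(axis=1)
    return np.where(total > 0, total, 0.5) / sf.sum()


def _mom_dispersion(y_a, y_b, sf_a, sf_b, mu_a, mu_b) -> np.ndarray:
    """Moderated gene-wise method-of-moments NB dispersion.

    Per gene, solves E[(y - sf*mu)^2] = sf*mu + alpha*(sf*mu)^2 for alpha
    using the pooled within-group residuals, with an n/(n-2) small-sample
    factor for the two fitted group means.  With few replicates the raw
    gene-wise estimate is noisy and frequently negative, which would let
    chance under-dispersion masquerade as significance, so each gene's
    dispersion is floored at the median positive estimate across genes
    (a minimal cross-gene moderation in the spirit of dispersion
    shrinkage) and finally at the Poisson limit.
    """
    fitted = np.concatenate([sf_a[None, :] * mu_a[:, None],
                             sf_b[None, :] * mu_b[:, None]], axis=1)
    y = np.concatenate([y_a, y_b], axis=1)
    n = y.shape[1]
    resid2 = (y - fitted) ** 2
    num = (resid2 - fitted).sum(axis=1) * (n / max(n - 2, 1))
    den = (fitted ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = num / den
    alpha[~np.isfinite(alpha)] = DISPERSION_FLOOR
    central = np.median(alpha[alpha > 0]) if (alpha > 0).any() else DISPERSION_FLOOR
    return np.clip(np.maximum(alpha, central), DISPERSION_FLOOR, None)


def _log_mean_var(mu: np.ndarray, sf: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    # Var(log mu_hat) by the delta method; mu_hat = sum(y)/sum(sf)
    var_mu = (sf[None, :] * mu[:, None]
              + alpha[:, None] * (sf[None, :] * mu[:, None]) ** 2).sum(axis=1)
    var_mu = var_mu / sf.sum() ** 2
    return var_mu / mu ** 2


@dataclass
class IntersectionResult:
    """Genes significant in both contrasts at the given threshold."""

    alpha: float
    genes_both: list[str] = field(default_factory=list)
    genes_up_both: list[str] = field(default_factory=list)

    @property
    def n_genes_both(self) -> int:
        return len(self.genes_both)

    @property
    def n_genes_up_both(self) -> int:
        return len(self.genes_up_both)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_genes_both": self.n_genes_both,
            "n_genes_up_both": self.n_genes_up_both,
            "genes_both": list(self.genes_both),
            "genes_up_both": list(self.genes_up_both),
        }


def intersect(
    comparison_ref: DEComparison,
    comparison_alt: DEComparison,
    alpha: float = ALPHA_DEFAULT,
) -> IntersectionResult:
    """Genes with adjusted p < alpha in both contrasts.

    ``genes_up_both`` additionally requires a positive log2 fold change
    (higher in coinoculation) in both contrasts.  Gene lists are sorted
    by the larger of the two adjusted p-values (most confident first).
    """
    a, b = comparison_ref.results, comparison_alt.results
    if not a.index.equals(b.index):
        if set(a.index) != set(b.index):
            raise ValueError("comparisons cover different gene universes")
        b = b.loc[a.index]
    sig = (a["p_adj"] < alpha) & (b["p_adj"] < alpha)
    up = sig & (a["log2_fold_change"] > 0) & (b["log2_fold_change"] > 0)
    worst_p = np.maximum(a["p_adj"], b["p_adj"])

    def ordered(mask):
        genes = a.index[mask]
        return list(genes[np.argsort(worst_p[mask].to_numpy(), kind="stable")])

    return IntersectionResult(
        alpha=alpha, genes_both=ordered(sig), genes_up_both=ordered(up)
    )


def run_host_de(
    counts: pd.DataFrame,
    design: SampleDesign,
    alpha: float = ALPHA_DEFAULT,
    sf_fallback: str | None = None,
) -> tuple[DEComparison, DEComparison, IntersectionResult]:
    """Both coinoculation contrasts plus their intersection for one host."""
    sf = size_factors(counts, fallback=sf_fallback)
    comp_ref = nb_wald_test(counts, design, "coin_vs_single_ref", sf=sf)
    comp_alt = nb_wald_test(counts, design, "coin_vs_single_alt", sf=sf)
    return comp_ref, comp_alt, intersect(comp_ref, comp_alt, alpha=alpha)


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative values")
    return counts


def read_contrast_tsv(path: str | Path, contrast: str = "external") -> DEComparison:
    """Load an externally computed contrast (gene_id, log2_fold_change, p_adj)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {"log2_fold_change", "p_adj"}
    if not required <= set(df.columns):
        raise ValueError(f"contrast table needs columns {sorted(required)}")
    if "p_raw" not in df.columns:
        df["p_raw"] = np.nan
    return DEComparison(
        contrast=contrast,
        results=df,
        size_factors=pd.Series(dtype=float),
    )


def write_comparison_tsv(comp: DEComparison, path: str | Path) -> None:
    comp.results.to_csv(path, sep="\t", index_label="gene_id")
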