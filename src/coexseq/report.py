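"""End-to-end orchestration: per-host pipeline runs and the coexistence summary.

For each host-plant genotype the pipeline runs variant filtering, mixture
deconvolution and the dual-contrast differential-expression stage, then
summarizes how evenly the two isolates coexisted and how many genes were
induced specifically during coexistence.  Across hosts the summary table
pairs mean coexistence evenness with the induced-gene count — the
headline association: hosts where the isolates coexist near 50:50 show
more coexistence-induced genes than hosts dominated by one isolate.
The association is reported descriptively (rank ordering and a Spearman
coefficient); with a handful of hosts no significance is claimed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .design import DesignError, SampleDesign, SampleSpec
from .diffexpr import ALPHA_DEFAULT, run_host_de, write_comparison_tsv
from .mixture import GRID_STEP_DEFAULT, MixtureEstimate, estimate_mixture, frequency_series
from .synthetic import (
    CountSimConfig,
    CountTruth,
    VariantSampleSpec,
    VariantSimConfig,
    VariantTruth,
    design_from_variant_config,
    simulate_counts,
    simulate_variants,
)
from .variants import apply_filters, drop_multiallelic, merge_samples, read_vcf, restrict_to_snv

logger = logging.getLogger(__name__)


@dataclass
class HostSummary:
    """One host genotype's coexistence and induction summary."""

    host_genotype: str
    estimates: list[MixtureEstimate]
    mean_evenness: float
    n_retained_sites: int
    n_genes_both: int
    n_genes_up_both: int
    genes_up_both: list[str]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "host_genotype": self.host_genotype,
            "coinoculation_estimates": [e.to_dict() for e in self.estimates],
            "mean_evenness": self.mean_evenness,
            "n_retained_sites": self.n_retained_sites,
            "n_genes_both": self.n_genes_both,
            "n_genes_up_both": self.n_genes_up_both,
            "genes_up_both": self.genes_up_both,
            "provenance": self.provenance,
        }


@dataclass
class PipelineResult:
    summaries: list[HostSummary]
    association: pd.DataFrame | None
    rank_correlation: float | None
    variant_truth: dict[str, VariantTruth] = field(default_factory=dict)
    count_truth: dict[str, CountTruth] = field(default_factory=dict)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_config(path: str | Path) -> dict:
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage for every host named in the config.

    The config is a TOML file or an equivalent dict with either a
    ``[simulate]`` block (synthetic inputs drawn from the package's own
    generators) or an ``[inputs]`` block naming VCF, count-matrix and
    design files, plus optional ``[filters]``, ``[mixture]`` and
    ``[diffexpr]`` blocks.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    chash = config_hash(config)
    seed = config.get("seed")
    if seed is None:
        raise DesignError("config must set a top-level seed")

    filters_cfg = config.get("filters", {})
    mixture_cfg = config.get("mixture", {})
    de_cfg = config.get("diffexpr", {})
    alpha = float(de_cfg.get("alpha", ALPHA_DEFAULT))
    method = mixture_cfg.get("method", "peak")
    grid_step = float(mixture_cfg.get("grid_step", GRID_STEP_DEFAULT))
    provenance = {"config_hash": chash, "seed": int(seed), "version": __version__}

    if "simulate" in config:
        host_inputs, variant_truths, count_truths = _simulate_inputs(config)
    elif "inputs" in config:
        host_inputs = _load_inputs(config)
        variant_truths, count_truths = {}, {}
    else:
        raise DesignError("config needs a [simulate] or an [inputs] block")

    summaries = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for host, (table, vdesign, counts, cdesign) in host_inputs.items():
        table = drop_multiallelic(table)
        if filters_cfg.get("snv_only", True):
            table = restrict_to_snv(table)
        retained, report = apply_filters(
            table, vdesign, host_genotype=host, rule3=filters_cfg.get("rule3", "all")
        )
        coin = vdesign.samples_with_role("coinoculation", host)
        if not coin:
            raise DesignError(f"host {host!r} has no coinoculation samples")
        estimates = [
            estimate_mixture(frequency_series(retained, s), method=method, grid_step=grid_step)
            for s in coin
        ]
        comp_ref, comp_alt, inter = run_host_de(
            counts, cdesign, alpha=alpha, sf_fallback=de_cfg.get("sf_fallback")
        )
        summary = HostSummary(
            host_genotype=host,
            estimates=estimates,
            mean_evenness=float(np.mean([e.evenness for e in estimates])),
            n_retained_sites=retained.n_sites,
            n_genes_both=inter.n_genes_both,
            n_genes_up_both=inter.n_genes_up_both,
            genes_up_both=inter.genes_up_both,
            provenance=provenance,
        )
        summaries.append(summary)
        logger.info(
            "host %s: %d retained sites, %d genes significant in both contrasts",
            host, retained.n_sites, inter.n_genes_both,
        )
        if out is not None:
            host_dir = out / host
            host_dir.mkdir(exist_ok=True)
            (host_dir / "filter_report.json").write_text(
                json.dumps(report.to_dict(), indent=1, sort_keys=True)
            )
            (host_dir / "summary.json").write_text(
                json.dumps(summary.to_dict(), indent=1, sort_keys=True)
            )
            write_comparison_tsv(comp_ref, host_dir / "contrast_coin_vs_single_ref.tsv")
            write_comparison_tsv(comp_alt, host_dir / "contrast_coin_vs_single_alt.tsv")
            (host_dir / "intersection.json").write_text(
                json.dumps(inter.to_dict(), indent=1, sort_keys=True)
            )

    association, rho = (None, None)
    if len(summaries) >= 2:
        association, rho = evenness_gene_association(summaries)
        if out is not None:
            association.to_csv(out / "evenness_gene_association.tsv", sep="\t", index=False)
    return PipelineResult(
        summaries=summaries,
        association=association,
        rank_correlation=rho,
        variant_truth=variant_truths,
        count_truth=count_truths,
    )


def evenness_gene_association(
    summaries: list[HostSummary],
) -> tuple[pd.DataFrame, float | None]:
    """Hosts ordered by coexistence evenness, with induced-gene counts.

    Returns the table plus the Spearman rank correlation between mean
    evenness and the number of coexistence-induced genes; ``None`` when
    the correlation is undefined (fewer than two hosts would be an
    error; constant evenness or counts make it undefined).
    """
    if len(summaries) < 2:
        raise ValueError("association needs at least two host summaries")
    df = pd.DataFrame(
        {
            "host_genotype": [s.host_genotype for s in summaries],
            "mean_evenness": [s.mean_evenness for s in summaries],
            "n_genes_up_both": [s.n_genes_up_both for s in summaries],
        }
    ).sort_values("mean_evenness", ascending=False, ignore_index=True)
    ev = df["mean_evenness"].to_numpy()
    ng = df["n_genes_up_both"].to_numpy(dtype=float)
    if np.all(ev == ev[0]) or np.all(ng == ng[0]):
        return df, None
    rho = float(stats.spearmanr(ev, ng).statistic)
    return df, rho


# ---------------------------------------------------------------------------
# Input preparation
# ---------------------------------------------------------------------------

def _simulate_inputs(config: dict):
    sim = config["simulate"]
    hosts = sim.get("hosts")
    if not hosts:
        raise DesignError("[simulate] block must define at least one [simulate.hosts.*]")
    seed_seq = np.random.SeedSequence(int(config["seed"]))
    child_seeds = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in seed_seq.spawn(2 * len(hosts))
    ]
    n_reps = int(sim.get("n_reps", 3))
    host_inputs: dict[str, tuple] = {}
    vtruths: dict[str, VariantTruth] = {}
    ctruths: dict[str, CountTruth] = {}
    for k, (host, hcfg) in enumerate(hosts.items()):
        props = hcfg.get("coin_proportions", [])
        if not props:
            raise DesignError(f"host {host!r} has no coinoculation samples configured")
        specs = [
            VariantSampleSpec(f"{host}_single_ref_{i + 1}", "single_ref", 0.0)
            for i in range(n_reps)
        ] + [
            VariantSampleSpec(f"{host}_single_alt_{i + 1}", "single_alt", 1.0)
            for i in range(n_reps)
        ] + [
            VariantSampleSpec(f"{host}_coinoculation_{i + 1}", "coinoculation", float(p))
            for i, p in enumerate(props)
        ]
        vcfg = VariantSimConfig(
            n_sites=int(sim.get("n_sites", 2000)),
            depth_mean=float(sim.get("depth_mean", 30.0)),
            depth_model=sim.get("depth_model", "poisson"),
            error_rate=float(sim.get("error_rate", 0.001)),
            sample_specs=specs,
            min_coverage=int(sim.get("min_coverage", 10)),
            seed=child_seeds[2 * k],
            host_genotype=host,
        )
        table, vtruth = simulate_variants(vcfg)
        vdesign = design_from_variant_config(vcfg)

        n_genes = int(sim.get("n_genes", 1000))
        n_induced = int(hcfg.get("n_induced", sim.get("n_induced", 0)))
        ccfg = CountSimConfig(
            n_genes=n_genes,
            n_reps=n_reps,
            seed=child_seeds[2 * k + 1],
            dispersion=float(sim.get("dispersion", 0.1)),
            coexistence_gene_ids=tuple(range(1, n_induced + 1)),
            log2_effect=float(sim.get("log2_effect", 2.0)),
            host_genotype=host,
        )
        counts, cdesign, ctruth = simulate_counts(ccfg)
        host_inputs[host] = (table, vdesign, counts, cdesign)
        vtruths[host] = vtruth
        ctruths[host] = ctruth
    return host_inputs, vtruths, ctruths


def _load_inputs(config: dict):
    from .diffexpr import read_counts_tsv
    from .design import read_design

    inputs = config["inputs"]
    design = read_design(inputs["design"])
    vcf_map = inputs.get("vcf", {})
    counts_map = inputs.get("counts", {})
    hosts = inputs.get("hosts") or sorted(set(vcf_map) & set(counts_map))
    if not hosts:
        raise DesignError("[inputs] must map at least one host to both vcf and counts")
    host_inputs: dict[str, tuple] = {}
    for host in hosts:
        hdesign = design.subset_host(host)
        hdesign.require_analysis_roles(host)
        paths = vcf_map[host]
        if isinstance(paths, (str, Path)):
            paths = [paths]
        table = merge_samples([read_vcf(p) for p in paths], hdesign)
        counts = read_counts_tsv(counts_map[host])
        host_inputs[host] = (table, hdesign, counts, hdesign)
    return host_inputs


def plot_frequency_distributions(table, sample_ids, path: str | Path) -> None:
    """Optional per-sample allele-frequency density panels (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        len(sample_ids), 1, figsize=(6, 2 * len(sample_ids)), sharex=True, squeeze=False
    )
    for ax, s in zip(axes.ravel(), sample_ids):
        series = frequency_series(table, s)
        ax.hist(series.freqs, bins=50, range=(0, 1), density=True, color="#4878a8")
        est = estimate_mixture(series)
        ax.axvline(est.p_alt, color="firebrick", lw=1)
        ax.set_ylabel(s, rotation=0, ha="right", fontsize=8)
    axes.ravel()[-1].set_xlabel("alternative-allele read frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
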