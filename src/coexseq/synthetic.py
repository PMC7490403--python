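"""Synthetic variant tables and count matrices with the pipeline's assumed structure.

Two haploid parental genotypes differ at every simulated diagnostic site:
the reference parent carries the reference allele, the alternative parent
the alternative allele.  A sample that mixes the parents in proportion
``p`` (fraction of the alternative parent) yields, at a site of depth
``d``, an alternative-allele read count drawn Binomial(d, q) with

    q = p * (1 - 2e) + e,

where ``e`` is a symmetric per-read error rate: a reference-parent read
is misread as alternative with probability ``e`` and vice versa.  The
haploid genotype emitted for the site is the majority allele (ties break
toward reference), mirroring what a ploidy-1 caller reports for a mixed
sample; the mixture signal lives in the per-allele observation counts.
Calls at sites whose depth falls below ``min_coverage`` are emitted as
missing, emulating the caller's minimum-coverage threshold.

Gene-level counts follow a negative-binomial (gamma–Poisson) model with
per-sample library size factors; a designated gene set is induced only
in the coinoculation condition, by a fixed log2 effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import ROLES, SampleDesign, SampleSpec
from .variants import VariantTable, write_vcf  # noqa: F401  (re-export)

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """A simulation configuration value is missing, non-finite or out of range."""


@dataclass(frozen=True)
class VariantSampleSpec:
    sample_id: str
    role: str
    true_alt_proportion: float

    def __post_init__(self):
        if self.role not in ROLES:
            raise ConfigError(f"sample_specs: unknown role {self.role!r}")


@dataclass
class VariantSimConfig:
    """Configuration for simulating a multi-sample diagnostic-site table."""

    n_sites: int
    depth_mean: float
    sample_specs: Sequence[VariantSampleSpec]
    seed: int
    depth_model: str = "poisson"
    error_rate: float = 0.001
    min_coverage: int = 10
    contig: str = "contig_1"
    host_genotype: str = "HOST"

    def __post_init__(self):
        if not isinstance(self.n_sites, (int, np.integer)) or self.n_sites < 1:
            raise ConfigError(f"n_sites must be a positive integer, got {self.n_sites!r}")
        if not math.isfinite(self.depth_mean) or self.depth_mean <= 0:
            raise ConfigError(f"depth_mean must be finite and positive, got {self.depth_mean!r}")
        if self.depth_model not in ("fixed", "poisson"):
            raise ConfigError(f"depth_model must be 'fixed' or 'poisson', got {self.depth_model!r}")
        if not (0 <= self.error_rate < 0.5):
            raise ConfigError(f"error_rate must lie in [0, 0.5), got {self.error_rate!r}")
        if self.min_coverage < 0:
            raise ConfigError(f"min_coverage must be >= 0, got {self.min_coverage!r}")
        if self.seed is None:
            raise ConfigError("seed is required (no silent time-based seeding)")
        if not self.sample_specs:
            raise ConfigError("sample_specs must name at least one sample")
        specs = [
            s if isinstance(s, VariantSampleSpec) else VariantSampleSpec(*s)
            for s in self.sample_specs
        ]
        self.sample_specs = specs
        for s in specs:
            p = s.true_alt_proportion
            if not (isinstance(p, (int, float)) and math.isfinite(p) and 0 <= p <= 1):
                raise ConfigError(
                    f"true_alt_proportion for sample {s.sample_id!r} must lie in [0, 1], got {p!r}"
                )
            if s.role == "single_ref" and p != 0:
                raise ConfigError(
                    f"single_ref sample {s.sample_id!r} must have true_alt_proportion 0"
                )
            if s.role == "single_alt" and p != 1:
                raise ConfigError(
                    f"single_alt sample {s.sample_id!r} must have true_alt_proportion 1"
                )


@dataclass
class VariantTruth:
    """Ground truth accompanying a simulated variant table."""

    true_alt_proportion: dict[str, float]
    error_rate: float
    host_genotype: str


def simulate_variants(cfg: VariantSimConfig) -> tuple[VariantTable, VariantTruth]:
    """Draw a multi-sample variant table under the binomial mixing model."""
    rng = np.random.default_rng(cfg.seed)
    n = int(cfg.n_sites)
    samples = [s.sample_id for s in cfg.sample_specs]
    p = np.array([s.true_alt_proportion for s in cfg.sample_specs])
    q = p * (1 - 2 * cfg.error_rate) + cfg.error_rate

    pos = np.sort(rng.choice(np.arange(1, max(50 * n, 1000)), size=n, replace=False))
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4  # distinct base

    if cfg.depth_model == "fixed":
        depth = np.full((n, len(samples)), int(round(cfg.depth_mean)), dtype=np.int64)
    else:
        depth = rng.poisson(cfg.depth_mean, size=(n, len(samples)))
    alt_obs = rng.binomial(depth, q[None, :])
    ref_obs = depth - alt_obs
    genotype = (alt_obs > ref_obs).astype(np.int8)  # majority allele; ties -> reference
    genotype[depth < cfg.min_coverage] = -1

    table = VariantTable(
        contig=[cfg.contig] * n,
        pos=pos.astype(np.int64),
        ref=[str(_BASES[i]) for i in ref_idx],
        alt=[(str(_BASES[i]),) for i in alt_idx],
        samples=samples,
        genotype=genotype,
        depth=depth.astype(np.int32),
        ref_obs=ref_obs.astype(np.int32),
        alt_obs=alt_obs.astype(np.int32),
    )
    truth = VariantTruth(
        true_alt_proportion=dict(zip(samples, map(float, p))),
        error_rate=cfg.error_rate,
        host_genotype=cfg.host_genotype,
    )
    return table, truth


def design_from_variant_config(cfg: VariantSimConfig) -> SampleDesign:
    return SampleDesign(
        SampleSpec(s.sample_id, s.role, cfg.host_genotype) for s in cfg.sample_specs
    )


# ---------------------------------------------------------------------------
# Gene-count simulation
# ---------------------------------------------------------------------------

@dataclass
class CountSimConfig:
    """Configuration for the negative-binomial gene-count simulator.

    ``dispersion`` is the NB overdispersion alpha in Var = mu + alpha*mu^2,
    either a scalar (shared by all genes) or one value per gene.
    ``coexistence_gene_ids`` are 1-based gene indices induced (by
    ``log2_effect`` log2 units) only in the coinoculation condition.
    """

    n_genes: int
    n_reps: int
    seed: int
    baseline_mean_range: tuple[float, float] = (5.0, 500.0)
    dispersion: float | Sequence[float] = 0.1
    coexistence_gene_ids: Sequence[int] = field(default_factory=tuple)
    log2_effect: float = 2.0
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    host_genotype: str = "HOST"

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigError(f"n_genes must be >= 1, got {self.n_genes!r}")
        if self.n_reps < 2:
            raise ConfigError(
                f"n_reps must be >= 2 (a contrast needs replication), got {self.n_reps!r}"
            )
        disp = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
        if disp.size not in (1, self.n_genes) or (disp <= 0).any():
            raise ConfigError("dispersion must be positive, scalar or one value per gene")
        if not math.isfinite(self.log2_effect):
            raise ConfigError(f"log2_effect must be finite, got {self.log2_effect!r}")
        lo, hi = self.baseline_mean_range
        if not (0 < lo <= hi):
            raise ConfigError(f"baseline_mean_range invalid: {self.baseline_mean_range!r}")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ConfigError(f"size_factor_range invalid: {self.size_factor_range!r}")
        ids = set(int(i) for i in self.coexistence_gene_ids)
        if ids and not ids <= set(range(1, self.n_genes + 1)):
            raise ConfigError("coexistence_gene_ids must be 1-based indices <= n_genes")
        self.coexistence_gene_ids = tuple(sorted(ids))
        if self.seed is None:
            raise ConfigError("seed is required")


@dataclass
class CountTruth:
    induced_gene_ids: tuple[str, ...]
    log2_effect: float
    size_factors: dict[str, float]
    baseline_means: np.ndarray

    @property
    def n_induced(self) -> int:
        return len(self.induced_gene_ids)


_COUNT_ROLES = ("single_ref", "single_alt", "coinoculation")


def simulate_counts(
    cfg: CountSimConfig,
) -> tuple[pd.DataFrame, SampleDesign, CountTruth]:
    """Draw a genes x samples count matrix with coexistence-specific induction."""
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"g{i:05d}" for i in range(1, cfg.n_genes + 1)]
    lo, hi = cfg.baseline_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_genes))
    disp = np.broadcast_to(
        np.atleast_1d(np.asarray(cfg.dispersion, dtype=float)), (cfg.n_genes,)
    ).copy()

    samples, roles = [], []
    for role in _COUNT_ROLES:
        for r in range(1, cfg.n_reps + 1):
            samples.append(f"{cfg.host_genotype}_{role}_{r}")
            roles.append(role)
    sf = rng.uniform(*cfg.size_factor_range, size=len(samples))

    induced = np.zeros(cfg.n_genes, dtype=bool)
    if cfg.log2_effect != 0:
        induced[[i - 1 for i in cfg.coexistence_gene_ids]] = True
    mu = np.tile(base[:, None], (1, len(samples)))
    coin_cols = [j for j, role in enumerate(roles) if role == "coinoculation"]
    mu[np.ix_(induced, coin_cols)] *= 2.0 ** cfg.log2_effect
    mu = mu * sf[None, :]

    # gamma-Poisson draw: numerically safe as dispersion -> 0 (Poisson limit)
    lam = rng.gamma(shape=1.0 / disp[:, None], scale=disp[:, None] * mu)
    counts = rng.poisson(lam)

    matrix = pd.DataFrame(counts, index=gene_ids, columns=samples)
    design = SampleDesign(
        SampleSpec(s, role, cfg.host_genotype) for s, role in zip(samples, roles)
    )
    truth = CountTruth(
        induced_gene_ids=tuple(gene_ids[i] for i in np.flatnonzero(induced)),
        log2_effect=cfg.log2_effect,
        size_factors=dict(zip(samples, map(float, sf))),
        baseline_means=base,
    )
    return matrix, design, truth


# ---------------------------------------------------------------------------
# Truth-record I/O (plain TSV so runs can be audited without the package)
# ---------------------------------------------------------------------------

def write_variant_truth(truth: VariantTruth, design: SampleDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#error_rate\t{truth.error_rate}\n")
        fh.write(f"#host_genotype\t{truth.host_genotype}\n")
        fh.write("sample_id\trole\ttrue_alt_proportion\n")
        for s in design:
            fh.write(f"{s.sample_id}\t{s.role}\t{truth.true_alt_proportion[s.sample_id]}\n")


def read_truth(path: str | Path) -> VariantTruth:
    """Read a variant truth record written by :func:`write_variant_truth`."""
    meta: dict[str, str] = {}
    props: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                k, v = line[1:].split("\t", 1)
                meta[k] = v
            elif line and not line.startswith("sample_id"):
                sid, _role, p = line.split("\t")
                props[sid] = float(p)
    return VariantTruth(
        true_alt_proportion=props,
        error_rate=float(meta.get("error_rate", "nan")),
        host_genotype=meta.get("host_genotype", ""),
    )


def write_count_truth(truth: CountTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#log2_effect\t{truth.log2_effect}\n")
        fh.write("gene_id\n")
        for g in truth.induced_gene_ids:
            fh.write(g + "\n")
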