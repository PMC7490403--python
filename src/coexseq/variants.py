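"""Multi-sample variant tables: VCF I/O, merging and diagnostic-site filtering.

The analysis consumes haploid variant calls (ploidy-1 genotypes, as a
caller like freebayes emits for a haploid organism) with per-sample read
depth (``DP``) and per-allele observation counts (``RO``/``AO``).  Sites
that pass the three-rule filter below separate the two parental isolates:
the reference isolate carries the reference allele, the alternative
isolate the alternative allele, so in a mixed sample the alternative-read
fraction at these sites tracks the mixture proportion.

The three keep-rules, applied in order:

1. a variant was detected in at least one sample (some genotype is 1);
2. every sample has a genotype call (no missing data);
3. the alternative-isolate single-inoculation samples carry the
   alternative allele (genotype 1) — by default all of them, which makes
   the retained sites strictly diagnostic between the two parents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .design import DesignError, SampleDesign

logger = logging.getLogger(__name__)

MISSING = -1  # genotype sentinel


class VariantInputError(ValueError):
    """Input VCFs are inconsistent with each other or with the design."""


@dataclass
class VariantTable:
    """Columnar multi-sample variant table.

    ``genotype`` holds the haploid allele index per site and sample
    (0 reference, 1.. alternative, -1 missing).  ``alt`` is a tuple of
    alternative alleles per site; the table is biallelic when every tuple
    has length one.  ``ref_obs``/``alt_obs`` are read-observation counts
    for the reference and the *first* alternative allele; multiallelic
    sites are dropped before any frequency computation, so observation
    counts for further alternative alleles are never consumed.
    """

    contig: list[str]
    pos: np.ndarray  # 1-based, VCF convention
    ref: list[str]
    alt: list[tuple[str, ...]]
    samples: list[str]
    genotype: np.ndarray  # (n_sites, n_samples) int8
    depth: np.ndarray  # (n_sites, n_samples) int32
    ref_obs: np.ndarray
    alt_obs: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_keys(self) -> list[tuple[str, int]]:
        return list(zip(self.contig, (int(p) for p in self.pos)))

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in table") from None

    def take_sites(self, mask_or_idx) -> "VariantTable":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return VariantTable(
            contig=[self.contig[i] for i in idx],
            pos=self.pos[idx],
            ref=[self.ref[i] for i in idx],
            alt=[self.alt[i] for i in idx],
            samples=list(self.samples),
            genotype=self.genotype[idx],
            depth=self.depth[idx],
            ref_obs=self.ref_obs[idx],
            alt_obs=self.alt_obs[idx],
        )

    def take_samples(self, sample_ids: Sequence[str]) -> "VariantTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return VariantTable(
            contig=list(self.contig),
            pos=self.pos.copy(),
            ref=list(self.ref),
            alt=list(self.alt),
            samples=list(sample_ids),
            genotype=self.genotype[:, idx],
            depth=self.depth[:, idx],
            ref_obs=self.ref_obs[:, idx],
            alt_obs=self.alt_obs[:, idx],
        )

    def equals(self, other: "VariantTable") -> bool:
        return (
            self.contig == other.contig
            and np.array_equal(self.pos, other.pos)
            and self.ref == other.ref
            and self.alt == other.alt
            and self.samples == other.samples
            and np.array_equal(self.genotype, other.genotype)
            and np.array_equal(self.depth, other.depth)
            and np.array_equal(self.ref_obs, other.ref_obs)
            and np.array_equal(self.alt_obs, other.alt_obs)
        )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Write the table as a VCF 4.2 file with haploid GT, DP, RO and AO."""
    import pysam

    if table.n_samples == 0:
        raise VariantInputError("cannot write a VCF with an empty sample list")
    if table.n_sites == 0:
        raise VariantInputError("cannot write a VCF with no sites")
    header = pysam.VariantHeader()
    for ctg in dict.fromkeys(table.contig):
        length = max(int(p) for c, p in zip(table.contig, table.pos) if c == ctg)
        header.contigs.add(ctg, length=length + 1000)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line(
        '##FORMAT=<ID=RO,Number=1,Type=Integer,'
        'Description="Reference allele observation count">'
    )
    header.add_line(
        '##FORMAT=<ID=AO,Number=A,Type=Integer,'
        'Description="Alternate allele observation count">'
    )
    for s in table.samples:
        header.add_sample(s)
    order = np.lexsort((table.pos, np.asarray(table.contig, dtype=object)))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in map(int, order):
            rec = out.new_record(
                contig=table.contig[i],
                start=int(table.pos[i]) - 1,
                alleles=(table.ref[i], *table.alt[i]),
            )
            n_alt = len(table.alt[i])
            for j, s in enumerate(table.samples):
                gt = int(table.genotype[i, j])
                rec.samples[s]["GT"] = (None,) if gt == MISSING else (gt,)
                rec.samples[s]["DP"] = int(table.depth[i, j])
                rec.samples[s]["RO"] = int(table.ref_obs[i, j])
                ao = [0] * n_alt
                ao[0] = int(table.alt_obs[i, j])
                rec.samples[s]["AO"] = tuple(ao)
            out.write(rec)


def read_vcf(path: str | Path) -> VariantTable:
    """Read a VCF into a :class:`VariantTable`.

    Haploid genotype calls are expected; a diploid homozygous call is
    accepted and collapsed to its allele, anything heterozygous raises.
    Missing DP/RO/AO values are read as zero.
    """
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    contig, pos, ref, alt = [], [], [], []
    gts, dps, ros, aos = [], [], [], []
    for v in vcf:
        contig.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(tuple(v.ALT))
        row_gt = []
        for g in v.genotypes:
            alleles = [a for a in g[:-1] if a is not None]
            uniq = set(alleles)
            if not alleles or uniq == {-1}:
                row_gt.append(MISSING)
            elif len(uniq) == 1:
                row_gt.append(alleles[0])
            else:
                raise VariantInputError(
                    f"heterozygous call at {v.CHROM}:{v.POS}; haploid calls expected"
                )
        gts.append(row_gt)
        dps.append(_format_column(v, "DP", len(samples)))
        ros.append(_format_column(v, "RO", len(samples)))
        ao = v.format("AO")
        if ao is None:
            aos.append([0] * len(samples))
        else:
            aos.append([max(int(x[0]), 0) for x in ao])
    vcf.close()
    if not pos:
        logger.warning("VCF %s contains no variant records", path)
    n = len(pos)
    m = len(samples)
    return VariantTable(
        contig=contig,
        pos=np.asarray(pos, dtype=np.int64),
        ref=ref,
        alt=alt,
        samples=samples,
        genotype=np.asarray(gts, dtype=np.int8).reshape(n, m),
        depth=np.asarray(dps, dtype=np.int32).reshape(n, m),
        ref_obs=np.asarray(ros, dtype=np.int32).reshape(n, m),
        alt_obs=np.asarray(aos, dtype=np.int32).reshape(n, m),
    )


def _format_column(variant, key: str, n_samples: int) -> list[int]:
    arr = variant.format(key)
    if arr is None:
        return [0] * n_samples
    return [max(int(x[0]), 0) for x in arr]


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_samples(
    vcf_paths: Sequence[str | Path],
    design: SampleDesign,
    exclude_mock: bool = True,
) -> VariantTable:
    """Merge per-sample (or multi-sample) VCFs into one table.

    The merged table holds the union of positions; a sample without a
    record at a position gets a missing call with zero depth.  Mock
    samples are excluded: only inoculated samples enter the analysis.
    Sites whose reference allele differs between inputs at the same
    position are an input error; alternative alleles are unioned, which
    can create multiallelic sites (dropped later by
    :func:`drop_multiallelic`).
    """
    tables = [t if isinstance(t, VariantTable) else read_vcf(t) for t in vcf_paths]
    samples: list[str] = []
    for t in tables:
        for s in t.samples:
            if s not in design:
                raise DesignError(f"sample {s!r} in VCF is absent from the design")
            if s in samples:
                raise DesignError(f"sample {s!r} appears in more than one input VCF")
            samples.append(s)
    if exclude_mock:
        samples = [s for s in samples if design.role_of(s) != "mock"]
    if not samples:
        raise DesignError("no non-mock samples to merge")

    # site key -> (ref, [alts...]) and per-sample call rows
    sites: dict[tuple[str, int], dict] = {}
    for t in tables:
        keep = [s for s in t.samples if s in samples]
        if not keep:
            continue
        cols = [t.samples.index(s) for s in keep]
        for i in range(t.n_sites):
            key = (t.contig[i], int(t.pos[i]))
            entry = sites.get(key)
            if entry is None:
                entry = sites[key] = {"ref": t.ref[i], "alts": [], "calls": {}}
            elif entry["ref"] != t.ref[i]:
                raise VariantInputError(
                    f"conflicting reference alleles at {key[0]}:{key[1]}: "
                    f"{entry['ref']!r} vs {t.ref[i]!r}"
                )
            # map this record's allele indices into the merged alt list
            remap = {0: 0}
            for ai, a in enumerate(t.alt[i], start=1):
                if a not in entry["alts"]:
                    entry["alts"].append(a)
                remap[ai] = entry["alts"].index(a) + 1
            for s, c in zip(keep, cols):
                gt = int(t.genotype[i, c])
                entry["calls"][s] = (
                    remap.get(gt, MISSING) if gt != MISSING else MISSING,
                    int(t.depth[i, c]),
                    int(t.ref_obs[i, c]),
                    int(t.alt_obs[i, c]),
                )

    keys = sorted(sites)
    n, m = len(keys), len(samples)
    gt = np.full((n, m), MISSING, dtype=np.int8)
    dp = np.zeros((n, m), dtype=np.int32)
    ro = np.zeros((n, m), dtype=np.int32)
    ao = np.zeros((n, m), dtype=np.int32)
    for i, key in enumerate(keys):
        calls = sites[key]["calls"]
        for j, s in enumerate(samples):
            if s in calls:
                gt[i, j], dp[i, j], ro[i, j], ao[i, j] = calls[s]
    if n == 0:
        logger.warning("merge produced an empty table")
    return VariantTable(
        contig=[k[0] for k in keys],
        pos=np.asarray([k[1] for k in keys], dtype=np.int64),
        ref=[sites[k]["ref"] for k in keys],
        alt=[tuple(sites[k]["alts"]) for k in keys],
        samples=samples,
        genotype=gt,
        depth=dp,
        ref_obs=ro,
        alt_obs=ao,
    )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def drop_multiallelic(table: VariantTable) -> VariantTable:
    """Keep only biallelic sites (exactly one alternative allele)."""
    mask = np.asarray([len(a) == 1 for a in table.alt], dtype=bool)
    dropped = table.n_sites - int(mask.sum())
    if dropped:
        logger.info("dropped %d multiallelic site(s)", dropped)
    if mask.size and not mask.any():
        logger.warning("all sites were multiallelic; table is now empty")
    return table.take_sites(mask)


def restrict_to_snv(table: VariantTable) -> VariantTable:
    """Keep only single-nucleotide ref/alt sites (no indels or MNPs)."""
    mask = np.asarray(
        [len(r) == 1 and all(len(a) == 1 for a in alts)
         for r, alts in zip(table.ref, table.alt)],
        dtype=bool,
    )
    return table.take_sites(mask)


@dataclass
class FilterReport:
    """Counts of sites surviving each keep-rule, in application order."""

    host_genotype: str
    n_input_sites: int
    n_after_rule1: int
    n_after_rule2: int
    n_after_rule3: int
    retained_sites: list[tuple[str, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "host_genotype": self.host_genotype,
            "n_input_sites": self.n_input_sites,
            "n_after_rule1": self.n_after_rule1,
            "n_after_rule2": self.n_after_rule2,
            "n_after_rule3": self.n_after_rule3,
            "retained_sites": [[c, p] for c, p in self.retained_sites],
        }


def apply_filters(
    table: VariantTable,
    design: SampleDesign,
    host_genotype: str = "",
    rule3: str = "all",
) -> tuple[VariantTable, FilterReport]:
    """Apply the three keep-rules and report per-rule survivor counts.

    ``rule3`` selects whether *all* alternative-isolate single samples
    must carry genotype 1 at a retained site (strictly diagnostic,
    default) or *any* of them.
    """
    if rule3 not in ("all", "any"):
        raise ValueError(f"rule3 must be 'all' or 'any', got {rule3!r}")
    alt_samples = [
        s for s in table.samples
        if s in design and design.role_of(s) == "single_alt"
    ]
    if not alt_samples:
        raise DesignError(
            "no single_alt sample in the design: the diagnostic-site rule is undefined"
        )
    gt = table.genotype
    m1 = (gt == 1).any(axis=1) if table.n_sites else np.zeros(0, dtype=bool)
    m2 = (gt != MISSING).all(axis=1) if table.n_sites else np.zeros(0, dtype=bool)
    cols = [table.sample_index(s) for s in alt_samples]
    alt_gt = gt[:, cols] == 1
    m3 = alt_gt.all(axis=1) if rule3 == "all" else alt_gt.any(axis=1)
    keep = m1 & m2 & m3
    retained = table.take_sites(keep)
    report = FilterReport(
        host_genotype=host_genotype,
        n_input_sites=table.n_sites,
        n_after_rule1=int(m1.sum()),
        n_after_rule2=int((m1 & m2).sum()),
        n_after_rule3=int(keep.sum()),
        retained_sites=retained.site_keys(),
    )
    return retained, report
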