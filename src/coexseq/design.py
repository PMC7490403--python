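"""Sample designs: which RNA-seq sample plays which role on which host plant.

Every stage of the pipeline needs to know, for each sequencing sample,
whether the plant was inoculated with the reference isolate alone
(``single_ref``), the alternative isolate alone (``single_alt``), both
isolates together (``coinoculation``) or nothing (``mock``), and which
host-plant genotype it grew in.  In the motivating experiment the
reference isolate is the one the reads were mapped to, so its single
inoculations carry the reference allele at every diagnostic site and the
alternative isolate's single inoculations carry the alternative allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

ROLES = ("single_ref", "single_alt", "coinoculation", "mock")


class DesignError(ValueError):
    """The sample design is inconsistent with the data or with itself."""


@dataclass(frozen=True)
class SampleSpec:
    """One sample: its identifier, treatment role and host genotype."""

    sample_id: str
    role: str
    host_genotype: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DesignError(
                f"role {self.role!r} for sample {self.sample_id!r} is not one of {ROLES}"
            )


class SampleDesign:
    """An ordered collection of :class:`SampleSpec` with unique sample ids."""

    def __init__(self, specs: Iterable[SampleSpec]):
        specs = list(specs)
        ids = [s.sample_id for s in specs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DesignError(f"duplicate sample ids in design: {dupes}")
        self._specs = specs
        self._by_id = {s.sample_id: s for s in specs}

    def __iter__(self):
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __getitem__(self, sample_id: str) -> SampleSpec:
        try:
            return self._by_id[sample_id]
        except KeyError:
            raise DesignError(f"sample {sample_id!r} not present in design") from None

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self._specs]

    def role_of(self, sample_id: str) -> str:
        return self[sample_id].role

    def samples_with_role(self, role: str, host: str | None = None) -> list[str]:
        return [
            s.sample_id
            for s in self._specs
            if s.role == role and (host is None or s.host_genotype == host)
        ]

    def hosts(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self._specs:
            seen.setdefault(s.host_genotype, None)
        return list(seen)

    def subset_host(self, host: str) -> "SampleDesign":
        sub = [s for s in self._specs if s.host_genotype == host]
        if not sub:
            raise DesignError(f"no samples for host genotype {host!r}")
        return SampleDesign(sub)

    def require_analysis_roles(self, host: str | None = None) -> None:
        """Check a host has at least one sample of every analysed role."""
        for role in ("single_ref", "single_alt", "coinoculation"):
            if not self.samples_with_role(role, host):
                where = f" for host {host!r}" if host else ""
                raise DesignError(f"design has no {role} sample{where}")


def read_design(path: str | Path) -> SampleDesign:
    """Read a tab-separated design sheet (sample_id, role, host_genotype)."""
    specs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "role", "host_genotype"]
        if header != expected:
            raise DesignError(f"design header {header} != {expected}")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise DesignError(f"malformed design line: {line!r}")
            specs.append(SampleSpec(*fields))
    return SampleDesign(specs)


def write_design(design: SampleDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\trole\thost_genotype\n")
        for s in design:
            fh.write(f"{s.sample_id}\t{s.role}\t{s.host_genotype}\n")
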