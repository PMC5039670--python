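"""Core record types shared across pipeline stages.

Coordinates are 1-based inclusive throughout the package; BED input is
converted on read. Chromosome names are normalised to the ``chr``-prefixed
form (``chr1`` .. ``chr22``, ``chrX``, ``chrY``).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Effect(str, enum.Enum):
    """Functional class of a variant with respect to the coding sequence."""

    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    UNKNOWN = "unknown"


class SampleClass(str, enum.Enum):
    SINGLE_CELL = "single_cell"
    BULK_CANCER = "bulk_cancer"
    BULK_NORMAL = "bulk_normal"


class Caller(str, enum.Enum):
    GATK = "gatk"
    SAMTOOLS = "samtools"
    GEMS = "gems"


#: canonical chromosome set (human autosomes + sex chromosomes)
CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")


def normalize_chrom(name: str) -> str:
    """Map chromosome aliases (``1``, ``Chr1``, ``chr1``) to the canonical form."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return f"chr{s.upper() if s.lower() in ('x', 'y') else s}"


@dataclass(frozen=True)
class SnpRecord:
    """One filtered (or to-be-filtered) variant call in one cell.

    ``depth`` is the number of reads covering the site in this cell;
    ``effect`` the coding consequence class. One record per ALT allele.
    """

    cell_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    gene_id: str
    effect: Effect = Effect.UNKNOWN
    caller: Caller = Caller.GATK

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with 1-based inclusive coordinates.

    ``gene_length_bases`` (GL) defaults to the genomic span end-start+1 and
    is the denominator of the per-megabase gene SNP frequency.
    """

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    gene_length_bases: int = 0
    go_terms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if self.gene_length_bases <= 0:
            object.__setattr__(self, "gene_length_bases", self.end - self.start + 1)
        if self.gene_length_bases < 1:
            raise ValueError(f"{self.gene_id}: gene_length_bases must be >= 1")


@dataclass(frozen=True)
class ManifestEntry:
    cell_id: str
    vcf_path: str
    sample_class: SampleClass = SampleClass.SINGLE_CELL


@dataclass
class CohortManifest:
    """Sample sheet for a cohort: one VCF per cell plus its sample class."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.cell_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate cell_id(s) in manifest: {dup}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def cell_ids(self) -> list[str]:
        return [e.cell_id for e in self.entries]

    def subset(self, cell_ids) -> "CohortManifest":
        keep = set(cell_ids)
        return CohortManifest([e for e in self.entries if e.cell_id in keep])

    def of_class(self, sample_class: SampleClass) -> "CohortManifest":
        return CohortManifest([e for e in self.entries if e.sample_class == sample_class])


class Location(str, enum.Enum):
    """Breakpoint location class of a fusion partner."""

    EXONIC = "exonic"
    INTRONIC = "intronic"
    INTRAEXONIC = "intraexonic"
    INTERGENIC = "intergenic"


@dataclass(frozen=True)
class FusionRecord:
    """One fusion-transcript candidate; partner order is 5' then 3'."""

    cell_id: str
    gene5: str
    gene3: str
    chrom5: str
    chrom3: str
    breakpoint5: int
    breakpoint3: int
    location5: Location
    location3: Location
    supporting_reads: int = 0

    def __post_init__(self) -> None:
        if self.supporting_reads < 0:
            raise ValueError("supporting_reads must be non-negative")

    @property
    def pair(self) -> frozenset:
        """Unordered partner pair, for recurrence counting."""
        return frozenset((self.gene5, self.gene3))
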