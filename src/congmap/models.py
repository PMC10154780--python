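"""Shared in-memory data model for congenic-strain variant analysis.

All internal genomic intervals are 0-based half-open. VCF positions are
1-based at the I/O edge only (``VariantCall.pos``); every interval operation
in the package goes through :class:`GenomicInterval`.

Chromosome names are stored without a ``chr`` prefix ("13", not "chr13");
readers accept both dialects and writers emit the prefix-less form.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Genotype(enum.Enum):
    """Diploid genotype state of one strain at one biallelic site.

    Inbred strains are expected to be homozygous; half-missing diploid
    calls collapse to MISSING.
    """

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class Phenotype(str, enum.Enum):
    PRONE = "prone"
    RESISTANT = "resistant"


class Role(str, enum.Enum):
    DONOR_PARENT = "donor_parent"
    RECIPIENT_PARENT = "recipient_parent"
    DERIVED = "derived"
    REFERENCE_ASSEMBLY = "reference_assembly"


def normalize_chrom(name: str) -> str:
    """Strip a leading 'chr'/'Chr' prefix so both dialects compare equal."""
    if name[:3].lower() == "chr" and len(name) > 3:
        return name[3:]
    return name


def chrom_sort_key(name: str) -> tuple:
    """Natural chromosome order: 1..19 numerically, then X, Y, then others."""
    n = normalize_chrom(name)
    if n.isdigit():
        return (0, int(n), "")
    return (1, 0, n)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            normalize_chrom(self.chrom) == normalize_chrom(other.chrom)
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    def contains_pos(self, chrom: str, pos0: int) -> bool:
        return (
            normalize_chrom(self.chrom) == normalize_chrom(chrom)
            and self.start <= pos0 < self.end
        )


class VariantType(str, enum.Enum):
    SNV = "snv"
    INDEL = "indel"


@dataclass
class VariantCall:
    """One normalized biallelic site with per-strain genotypes.

    ``pos`` is the 1-based position of the first REF base (VCF convention);
    ``pos0`` exposes the 0-based coordinate used internally.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: dict[str, Genotype]
    var_id: str | None = None
    vtype: VariantType = VariantType.SNV

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValueError("empty allele")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        self.chrom = normalize_chrom(self.chrom)
        is_snv = len(self.ref) == 1 and len(self.alt) == 1
        self.vtype = VariantType.SNV if is_snv else VariantType.INDEL

    @property
    def pos0(self) -> int:
        return self.pos - 1

    def sort_key(self) -> tuple:
        return (*chrom_sort_key(self.chrom), self.pos, self.alt)


class SvType(str, enum.Enum):
    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"
    INS = "INS"
    BND = "BND"


@dataclass
class StructuralVariant:
    """One structural-variant call; span is 0-based half-open."""

    chrom: str
    start: int
    end: int
    svtype: SvType
    genotypes: dict[str, Genotype]
    sv_id: str | None = None

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        self.svtype = SvType(self.svtype)
        if self.svtype in (SvType.DEL, SvType.DUP, SvType.INV):
            if not self.start < self.end:
                raise ValueError(
                    f"{self.svtype.value} needs start < end "
                    f"({self.chrom}:{self.start}-{self.end})"
                )
        elif self.svtype is SvType.INS:
            self.end = self.start + 1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    def sort_key(self) -> tuple:
        return (*chrom_sort_key(self.chrom), self.start, self.svtype.value)


@dataclass(frozen=True)
class StrainEntry:
    name: str
    phenotype: Phenotype
    role: Role


@dataclass
class StrainPanel:
    """Strain names with phenotype and breeding role.

    Sequenced strains carry genotypes in the VCF; REFERENCE_ASSEMBLY
    strains only take part in presence/absence segregation scans.
    """

    entries: list[StrainEntry] = field(default_factory=list)

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate strain names in panel")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def sequenced(self) -> list[StrainEntry]:
        return [e for e in self.entries if e.role is not Role.REFERENCE_ASSEMBLY]

    def _one(self, role: Role) -> StrainEntry:
        found = [e for e in self.entries if e.role is role]
        if len(found) != 1:
            raise ValueError(
                f"panel needs exactly one {role.value} strain, found {len(found)}"
            )
        return found[0]

    @property
    def donor_parent(self) -> StrainEntry:
        return self._one(Role.DONOR_PARENT)

    @property
    def recipient_parent(self) -> StrainEntry:
        return self._one(Role.RECIPIENT_PARENT)

    def prone(self, sequenced_only: bool = True) -> list[StrainEntry]:
        pool = self.sequenced if sequenced_only else self.entries
        return [e for e in pool if e.phenotype is Phenotype.PRONE]

    def resistant(self, sequenced_only: bool = True) -> list[StrainEntry]:
        pool = self.sequenced if sequenced_only else self.entries
        return [e for e in pool if e.phenotype is Phenotype.RESISTANT]

    def derived(self) -> list[StrainEntry]:
        return [e for e in self.entries if e.role is Role.DERIVED]

    def phenotype_of(self, name: str) -> Phenotype:
        for e in self.entries:
            if e.name == name:
                return e.phenotype
        raise KeyError(f"strain {name!r} not in panel")
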