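"""Recessive-model candidate selection, SV specificity, segregation scoring.

Hereditary catalepsy behaves as a homozygous recessive trait, so candidate
variants inside the mapped locus must be homozygous-alt in every
catalepsy-prone sequenced strain and homozygous-ref in every resistant
one; a missing genotype in any required strain is never evidence and drops
the call. Structural variants are compared across strains by reciprocal
overlap (breakpoint distance for INS/BND) and the clusters screened for
the same prone-specific pattern. Finally, candidates are scored for
phenotype segregation across a wider strain panel using presence/absence
calls (reference assemblies provide a single haplotype, so zygosity is
not available there).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import (
    GenomicInterval,
    Genotype,
    Phenotype,
    StrainPanel,
    StructuralVariant,
    SvType,
    VariantCall,
    chrom_sort_key,
)


def recessive_filter(
    calls: list[VariantCall], panel: StrainPanel, locus: GenomicInterval
) -> list[VariantCall]:
    """Keep calls inside the locus with every prone strain hom_alt and
    every resistant strain hom_ref (sequenced strains only)."""
    prone = [e.name for e in panel.prone()]
    resistant = [e.name for e in panel.resistant()]
    if not prone or not resistant:
        raise ValueError("panel must contain prone and resistant sequenced strains")
    out = []
    for c in calls:
        if not locus.contains_pos(c.chrom, c.pos0):
            continue
        if all(c.genotypes.get(s) is Genotype.HOM_ALT for s in prone) and all(
            c.genotypes.get(s) is Genotype.HOM_REF for s in resistant
        ):
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# structural-variant clustering


@dataclass
class SvParams:
    min_reciprocal_overlap: float = 0.8
    bnd_tolerance_bp: int = 50


@dataclass
class SvCluster:
    svtype: SvType
    members: list[StructuralVariant]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.members[0].chrom,
            min(m.start for m in self.members),
            max(m.end for m in self.members),
        )

    def present_in(self) -> set[str]:
        """Strains with a supporting (het or hom_alt) call in any member."""
        out: set[str] = set()
        for m in self.members:
            for s, g in m.genotypes.items():
                if g in (Genotype.HET, Genotype.HOM_ALT):
                    out.add(s)
        return out


def reciprocal_overlap(a: StructuralVariant, b: StructuralVariant) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / (a.end - a.start), ov / (b.end - b.start))


def _same_sv(a: StructuralVariant, b: StructuralVariant, params: SvParams) -> bool:
    if a.svtype is not b.svtype or a.chrom != b.chrom:
        return False
    if a.svtype in (SvType.INS, SvType.BND):
        return abs(a.start - b.start) <= params.bnd_tolerance_bp
    return reciprocal_overlap(a, b) >= params.min_reciprocal_overlap


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def match_sv_across_strains(
    svs: list[StructuralVariant], params: SvParams | None = None
) -> list[SvCluster]:
    """Cluster SVs that represent the same event across strains.

    Same svtype + reciprocal overlap >= min_reciprocal_overlap (DEL, DUP,
    INV) or breakpoint distance <= bnd_tolerance_bp (INS, BND); linkage is
    transitive. A sorted sweep only compares pairs that can possibly match,
    so the result equals the all-pairs transitive closure.
    """
    params = params or SvParams()
    order = sorted(range(len(svs)), key=lambda i: svs[i].sort_key())
    uf = _UnionFind(len(svs))
    tol = params.bnd_tolerance_bp
    for a_i in range(len(order)):
        i = order[a_i]
        for b_i in range(a_i + 1, len(order)):
            j = order[b_i]
            if svs[j].chrom != svs[i].chrom:
                break
            if svs[j].start > max(svs[i].end, svs[i].start + tol):
                break
            if _same_sv(svs[i], svs[j], params):
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in order:
        groups.setdefault(uf.find(i), []).append(i)
    clusters = [
        SvCluster(svs[members[0]].svtype, [svs[i] for i in members])
        for members in groups.values()
    ]
    clusters.sort(key=lambda c: c.members[0].sort_key())
    return clusters


def sv_specificity(clusters: list[SvCluster], panel: StrainPanel) -> list[SvCluster]:
    """Clusters supported in every prone strain and no resistant strain."""
    prone = {e.name for e in panel.prone()}
    resistant = {e.name for e in panel.resistant()}
    out = []
    for c in clusters:
        present = c.present_in()
        if prone <= present and not (present & resistant):
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# phenotype segregation across a strain panel


@dataclass
class SegregationResult:
    variant: VariantCall
    n_consistent: int
    violations: list[tuple[str, bool, bool]] = field(default_factory=list)
    # (strain, observed present, expected present)

    @property
    def fully_concordant(self) -> bool:
        return not self.violations


def segregation_scan(
    candidates: list[VariantCall],
    presence: dict[str, dict[str, bool]],
    phenotypes: dict[str, Phenotype],
) -> list[SegregationResult]:
    """Score candidates against per-strain presence/absence of the allele.

    ``presence`` maps var_id -> {strain: present}; the expected pattern
    under the recessive model is present iff the strain is catalepsy-prone.
    Results sort fully-concordant first (fewest violations, then position).
    """
    out = []
    for c in candidates:
        if c.var_id not in presence:
            raise KeyError(f"candidate {c.var_id!r} missing from presence table")
        row = presence[c.var_id]
        violations = []
        n_ok = 0
        for strain in row:
            if strain not in phenotypes:
                raise ValueError(f"strain {strain!r} has no phenotype assigned")
            expected = phenotypes[strain] is Phenotype.PRONE
            observed = bool(row[strain])
            if observed == expected:
                n_ok += 1
            else:
                violations.append((strain, observed, expected))
        out.append(SegregationResult(c, n_ok, violations))
    out.sort(
        key=lambda r: (
            len(r.violations),
            chrom_sort_key(r.variant.chrom),
            r.variant.pos,
        )
    )
    return out


def read_presence_table(tsv_source) -> dict[str, dict[str, bool]]:
    """Wide TSV: first column var_id, one 0/1 column per strain."""
    from .io import xopen

    with xopen(tsv_source) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "var_id":
            raise ValueError("presence table must start with a var_id column")
        strains = header[1:]
        table: dict[str, dict[str, bool]] = {}
        for i, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ValueError(f"presence table line {i}: column count mismatch")
            table[parts[0]] = {
                s: v not in ("0", "", "absent", "False")
                for s, v in zip(strains, parts[1:])
            }
    return table
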