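"""Minimal coding-consequence annotation.

Places variants on gene models (gene/mRNA/CDS from GFF3), rebuilds the
affected codon across exon junctions — reverse-complemented for minus-strand
genes — translates it with the standard nuclear code, and reports
missense / synonymous / stop_gained / stop_lost / noncoding / cds_indel with
protein-change notation like "H148R". Precomputed substitution-tolerance
(SIFT-style) scores are attached from a lookup table, never computed.

Only the first transcript of each gene is annotated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import gffutils
from Bio.Seq import Seq

from .models import GenomicInterval, VariantCall, VariantType, normalize_chrom


class Impact(str, enum.Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    NONCODING = "noncoding"
    CDS_INDEL = "cds_indel"


SIFT_DELETERIOUS_BELOW = 0.05  # strict inequality, SIFT convention


@dataclass(frozen=True)
class SiftAnnotation:
    score: float
    label: str  # "deleterious" | "tolerated"

    @staticmethod
    def from_score(score: float) -> "SiftAnnotation":
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"SIFT score {score} outside [0, 1]")
        label = "deleterious" if score < SIFT_DELETERIOUS_BELOW else "tolerated"
        return SiftAnnotation(score, label)


@dataclass
class ConsequenceCall:
    variant: VariantCall
    gene_id: str
    impact: Impact
    protein_change: str = ""
    sift: SiftAnnotation | None = None


@dataclass
class GeneModel:
    """CDS structure of one gene (first transcript).

    ``cds_exons`` are genomic-coordinate intervals, sorted by position and
    non-overlapping; ``phase`` is the GFF3 phase of the first CDS base in
    transcription order (bases to skip before the first complete codon).
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str  # '+' | '-'
    cds_exons: list[GenomicInterval]
    phase: int = 0

    def __post_init__(self):
        self.chrom = normalize_chrom(self.chrom)
        self.cds_exons = sorted(self.cds_exons, key=lambda e: e.start)
        for a, b in zip(self.cds_exons, self.cds_exons[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping CDS exons in {self.gene_id}")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.cds_exons[0].start, self.cds_exons[-1].end
        )

    @property
    def cds_length(self) -> int:
        return sum(len(e) for e in self.cds_exons)

    def cds_offset(self, pos0: int) -> int | None:
        """0-based offset within the spliced CDS in transcription order,
        or None when pos0 is not in any CDS exon. Phase-adjusted."""
        off = 0
        if self.strand == "+":
            for e in self.cds_exons:
                if e.start <= pos0 < e.end:
                    return off + (pos0 - e.start) - self.phase
                off += len(e)
        else:
            for e in reversed(self.cds_exons):
                if e.start <= pos0 < e.end:
                    return off + (e.end - 1 - pos0) - self.phase
                off += len(e)
        return None

    def genomic_pos(self, cds_off: int) -> int:
        """Inverse of :meth:`cds_offset` (phase-adjusted CDS offset -> pos0)."""
        off = cds_off + self.phase
        if self.strand == "+":
            for e in self.cds_exons:
                if off < len(e):
                    return e.start + off
                off -= len(e)
        else:
            for e in reversed(self.cds_exons):
                if off < len(e):
                    return e.end - 1 - off
                off -= len(e)
        raise IndexError(f"CDS offset {cds_off} beyond {self.gene_id}")


def read_gene_models(gff3_source) -> list[GeneModel]:
    """Load gene models from GFF3 (gene/mRNA/CDS, phase column respected)."""
    db = gffutils.create_db(
        str(gff3_source),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene  # first transcript only
        cds = list(db.children(parent, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        first = cds[-1] if gene.strand == "-" else cds[0]
        phase = int(first.frame) if first.frame not in (".", None) else 0
        models.append(
            GeneModel(
                gene_id=gene.id,
                gene_name=gene.attributes.get("Name", [gene.id])[0],
                chrom=gene.seqid,
                strand=gene.strand,
                cds_exons=[
                    GenomicInterval(c.seqid, c.start - 1, c.end) for c in cds
                ],
                phase=phase,
            )
        )
    return models


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _read_base(chrom_seq: str, pos0: int, strand: str) -> str:
    b = chrom_seq[pos0].upper()
    return b.translate(_COMPLEMENT) if strand == "-" else b


def _classify(ref_aa: str, alt_aa: str) -> Impact:
    if ref_aa == alt_aa:
        return Impact.SYNONYMOUS
    if alt_aa == "*":
        return Impact.STOP_GAINED
    if ref_aa == "*":
        return Impact.STOP_LOST
    return Impact.MISSENSE


class ReferenceMismatchError(ValueError):
    pass


def annotate_consequence(
    call: VariantCall,
    models: list[GeneModel],
    chrom_seq: str,
) -> list[ConsequenceCall]:
    """Annotate one variant against every overlapping gene model.

    ``chrom_seq`` is the full sequence of the variant's chromosome. A
    variant hitting no model yields a single noncoding call with empty
    gene_id. The REF allele is checked against the sequence to guard
    against genome-build mismatches.
    """
    seq_ref = chrom_seq[call.pos0 : call.pos0 + len(call.ref)].upper()
    if seq_ref != call.ref.upper():
        raise ReferenceMismatchError(
            f"REF {call.ref!r} at {call.chrom}:{call.pos} disagrees with "
            f"sequence {seq_ref!r}"
        )
    hits = [
        m
        for m in models
        if m.chrom == call.chrom and m.span.start <= call.pos0 < m.span.end
    ]
    if not hits:
        return [ConsequenceCall(call, "", Impact.NONCODING)]
    out = []
    for m in hits:
        if call.vtype is VariantType.INDEL:
            touched = GenomicInterval(
                call.chrom, call.pos0, call.pos0 + max(len(call.ref), 1)
            )
            in_cds = any(e.overlaps(touched) for e in m.cds_exons)
            out.append(
                ConsequenceCall(
                    call, m.gene_id, Impact.CDS_INDEL if in_cds else Impact.NONCODING
                )
            )
            continue
        off = m.cds_offset(call.pos0)
        if off is None or off < 0:
            out.append(ConsequenceCall(call, m.gene_id, Impact.NONCODING))
            continue
        codon_i, within = divmod(off, 3)
        codon_pos = [m.genomic_pos(codon_i * 3 + k) for k in range(3)]
        ref_codon = "".join(_read_base(chrom_seq, p, m.strand) for p in codon_pos)
        alt_base = (
            call.alt.translate(_COMPLEMENT) if m.strand == "-" else call.alt
        ).upper()
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        impact = _classify(ref_aa, alt_aa)
        change = ""
        if impact in (Impact.MISSENSE, Impact.STOP_GAINED, Impact.STOP_LOST):
            change = f"{ref_aa}{codon_i + 1}{alt_aa}"
        out.append(ConsequenceCall(call, m.gene_id, impact, change))
    return out


def annotate_all(
    calls: list[VariantCall],
    models: list[GeneModel],
    chrom_seqs: dict[str, str],
) -> list[ConsequenceCall]:
    out = []
    for c in calls:
        seq = chrom_seqs.get(c.chrom)
        if seq is None:
            raise KeyError(f"no sequence for chromosome {c.chrom}")
        out.extend(annotate_consequence(c, models, seq))
    return out


def attach_scores(
    consequences: list[ConsequenceCall],
    score_table: dict[tuple[str, int, str, str], float],
) -> list[ConsequenceCall]:
    """Fill SIFT-style annotations from a (chrom, pos, ref, alt) -> score map.

    Matched consequences get score + deleterious/tolerated label (strict
    < 0.05 threshold); unmatched are left without a score.
    """
    for c in consequences:
        v = c.variant
        key = (normalize_chrom(v.chrom), v.pos, v.ref, v.alt)
        if key in score_table:
            c.sift = SiftAnnotation.from_score(score_table[key])
    return consequences


def read_score_table(tsv_source) -> dict[tuple[str, int, str, str], float]:
    """Score TSV with columns chrom, pos, ref, alt, sift_score."""
    from .io import xopen

    table: dict[tuple[str, int, str, str], float] = {}
    with xopen(tsv_source) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"score table line {i}: need 5 columns")
            table[(normalize_chrom(parts[0]), int(parts[1]), parts[2], parts[3])] = (
                float(parts[4])
            )
    return table
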