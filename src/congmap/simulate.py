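"""Synthetic congenic-cross genomes with recorded ground truth.

Emulates the breeding design behind congenic fine mapping: a recipient
parental strain (AKR-like) and a donor parental strain (CBA-like) that
differ at strain-specific homozygous variants; a congenic strain carrying
one donor-derived fragment with known boundaries on an otherwise recipient
background; and a selective-breeding mosaic strain sharing that fragment
plus a few extra donor segments elsewhere. Gene models are planted on the
main chromosome, with exactly one donor-specific causal missense variant
(plus a few synonymous CDS variants) inside the fragment, so downstream
expectations are exact by construction.

Derived-strain genomes are genotype-label mosaics: within each true donor
segment the derived strains copy the donor parent's genotype, elsewhere
the recipient's. No recombination process is simulated beyond the placed
breakpoints — the analysis consumes genotype mosaics, not pedigrees.

Randomness comes from one ``numpy`` Generator seeded once; sub-generators
draw in a fixed order (chromosome sequences, gene planting, causal and
synonymous CDS variants, marker positions per chromosome and class, mosaic
extra segments, structural variants, synteny permutation, peaks,
association table, genotype noise), so outputs are byte-identical for a
fixed seed. Genotype noise (state flips and missingness, applied after
truth recording) affects SNV/indel calls only; structural-variant
genotypes stay clean so the planted specificity set is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from . import io as cio
from .consequence import GeneModel
from .homology import SyntenyBlock, lift_sub, write_synteny
from .models import (
    GenomicInterval,
    Genotype,
    Phenotype,
    Role,
    StrainEntry,
    StrainPanel,
    StructuralVariant,
    SvType,
    VariantCall,
)

DONOR, RECIPIENT, CONGENIC, MOSAIC = "CBA", "AKR", "HT76", "ASC"
MAIN_CHROM = "13"
HUMAN_CHROM = "hs5"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GT_CODE = [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT, Genotype.MISSING]

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if str(Seq(a + b + c).translate()) != "*"
]
_STOP_CODONS = ["TAA", "TAG", "TGA"]


@dataclass
class CausalSpec:
    """The planted causal missense: gene index among in-segment genes,
    1-based protein position, and the amino-acid change."""

    gene_index: int = 0
    codon_position: int = 148
    ref_aa: str = "H"
    alt_aa: str = "R"


@dataclass
class SimConfig:
    chrom_length: int = 20_000_000
    n_chroms: int = 1
    donor_marker_rate: float = 1 / 2000
    recipient_marker_rate: float = 1 / 2000
    shared_variant_rate: float = 1 / 5000
    indel_fraction: float = 0.1
    introgressed_segment: tuple[int, int] = (10_000_000, 12_000_000)
    n_extra_mosaic_segments: int = 3
    extra_segment_length: int = 500_000
    genotype_error_rate: float = 1e-3
    missing_rate: float = 1e-3
    n_genes: int = 8
    n_cds_synonymous: int = 5
    causal: CausalSpec = field(default_factory=CausalSpec)
    n_sv_specific: int = 3
    n_sv_background: int = 10
    n_synteny_blocks: int = 5
    n_peaks_inside: int = 76
    n_peaks_outside: int = 40
    n_dys_inside: int = 5
    n_assoc_inside: int = 12
    n_assoc_outside: int = 30
    seed: int = 0

    def __post_init__(self):
        for r in (
            self.donor_marker_rate,
            self.recipient_marker_rate,
            self.shared_variant_rate,
            self.genotype_error_rate,
            self.missing_rate,
            self.indel_fraction,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        s, e = self.introgressed_segment
        if not (0 <= s < e <= self.chrom_length):
            raise ValueError("introgressed_segment outside chromosome")

    @property
    def segment(self) -> GenomicInterval:
        return GenomicInterval(MAIN_CHROM, *self.introgressed_segment)

    @property
    def chrom_names(self) -> list[str]:
        return [MAIN_CHROM] + [str(i + 1) for i in range(self.n_chroms - 1)]


@dataclass
class TruthSet:
    true_segments: dict[str, list[GenomicInterval]]
    causal_variant: VariantCall
    causal_gene_id: str
    causal_protein_change: str
    expected_candidates: list[str]
    expected_specific_sv_ids: list[str]
    expected_lifted_pieces: list[GenomicInterval]
    expected_lifted_hull: GenomicInterval
    expected_peak_counts: tuple[int, int]
    n_assoc_inside: int
    gene_models_path: str | None = None


@dataclass
class SimResult:
    config: SimConfig
    panel: StrainPanel
    calls: list[VariantCall]
    svs: list[StructuralVariant]
    genes: list[GeneModel]
    chrom_seqs: dict[str, str]
    synteny: list[SyntenyBlock]
    peaks: list[tuple[GenomicInterval, str]]
    assoc: list[dict]
    truth: TruthSet


def default_panel() -> StrainPanel:
    return StrainPanel(
        [
            StrainEntry(DONOR, Phenotype.PRONE, Role.DONOR_PARENT),
            StrainEntry(RECIPIENT, Phenotype.RESISTANT, Role.RECIPIENT_PARENT),
            StrainEntry(CONGENIC, Phenotype.PRONE, Role.DERIVED),
            StrainEntry(MOSAIC, Phenotype.PRONE, Role.DERIVED),
        ]
    )


def _design_causal_codon(ref_aa: str, alt_aa: str) -> tuple[str, int, str]:
    """Find (ref_codon, offset_in_codon, alt_base) turning ref_aa into
    alt_aa with a single substitution; error if impossible."""
    admissible = []
    for codon in _SENSE_CODONS:
        if str(Seq(codon).translate()) != ref_aa:
            continue
        for k in range(3):
            for b in "ACGT":
                if b == codon[k]:
                    continue
                mut = codon[:k] + b + codon[k + 1 :]
                if str(Seq(mut).translate()) == alt_aa:
                    return codon, k, b
                admissible.append(f"{codon}->{mut}:{Seq(mut).translate()}")
    raise ValueError(
        f"{ref_aa}->{alt_aa} not reachable by one substitution; "
        f"nearest substitutions: {sorted(set(admissible))[:8]}"
    )


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


@dataclass
class _PlantedGene:
    model: GeneModel
    codons: list[str]


def _plant_genes(rng, seq: np.ndarray, cfg: SimConfig) -> list[_PlantedGene]:
    """Place non-overlapping multi-exon genes inside and outside the true
    segment on the main chromosome and write their CDS into the sequence."""
    n_in = max(1, cfg.n_genes // 2)
    n_out = cfg.n_genes - n_in
    seg = cfg.segment
    slots: list[tuple[int, int, bool]] = []  # (lo, hi, in_segment)
    width_in = len(seg) // max(n_in, 1)
    for k in range(n_in):
        slots.append((seg.start + k * width_in, seg.start + (k + 1) * width_in, True))
    out_lo, out_hi = 500_000, max(seg.start - 500_000, 600_000)
    width_out = (out_hi - out_lo) // max(n_out, 1) if n_out else 0
    for k in range(n_out):
        slots.append((out_lo + k * width_out, out_lo + (k + 1) * width_out, False))

    genes: list[_PlantedGene] = []
    in_seg_idx = 0
    for gi, (lo, hi, in_seg) in enumerate(slots):
        n_codons = int(rng.integers(180, 260))
        if in_seg and in_seg_idx == cfg.causal.gene_index:
            n_codons = max(n_codons, cfg.causal.codon_position + 20)
        codons = [
            "ATG",
            *(_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)),
            _STOP_CODONS[int(rng.integers(0, 3))],
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 4))
        cds_len = 3 * n_codons
        cuts = sorted(rng.integers(30, cds_len - 30, n_exons - 1))
        chunk_lens = np.diff([0, *cuts, cds_len])
        introns = rng.integers(200, 2000, n_exons - 1)
        start = int(lo + rng.integers(0, max(hi - lo - (cds_len + int(introns.sum())) - 10, 1)))
        exons = []
        p = start
        for k, cl in enumerate(chunk_lens):
            exons.append(GenomicInterval(MAIN_CHROM, p, p + int(cl)))
            p += int(cl) + (int(introns[k]) if k < n_exons - 1 else 0)
        model = GeneModel(
            gene_id=f"gene{gi:03d}",
            gene_name=f"G{gi}",
            chrom=MAIN_CHROM,
            strand=strand,
            cds_exons=exons,
            phase=0,
        )
        genes.append(_PlantedGene(model, codons))
        if in_seg:
            in_seg_idx += 1
        _write_cds(seq, model, "".join(codons))
    return genes


def _write_cds(seq: np.ndarray, model: GeneModel, cds: str) -> None:
    """Write a spliced CDS into the chromosome sequence, strand-aware."""
    off = 0
    exons = model.cds_exons if model.strand == "+" else list(reversed(model.cds_exons))
    for e in exons:
        chunk = cds[off : off + len(e)]
        genomic = chunk if model.strand == "+" else _revcomp(chunk)
        seq[e.start : e.end] = np.frombuffer(genomic.encode(), dtype=np.uint8)
        off += len(e)


def _draw_positions(rng, lo: int, hi: int, n: int, blocked: np.ndarray, window: int = 6) -> np.ndarray:
    """n distinct positions in [lo, hi) whose ``window`` following bases are
    unblocked; chosen positions block their window."""
    chosen: list[int] = []
    guard = 0
    while len(chosen) < n:
        guard += 1
        if guard > 200:
            raise RuntimeError("position sampling failed; region too dense")
        # draw unsorted; the blocked mask also rejects within-round duplicates
        cand = rng.integers(lo, hi - window, size=(n - len(chosen)) + 16)
        for p in cand:
            if len(chosen) >= n:
                break
            p = int(p)
            if not blocked[p : p + window].any():
                blocked[p : p + window] = True
                chosen.append(p)
    return np.sort(np.array(chosen, dtype=np.int64))


def _alleles(rng, seq: np.ndarray, pos0: int, is_indel: bool) -> tuple[str, str]:
    ref_b = chr(seq[pos0])
    if not is_indel:
        alt = "ACGT"[int(rng.integers(0, 4))]
        while alt == ref_b:
            alt = "ACGT"[int(rng.integers(0, 4))]
        return ref_b, alt
    ilen = int(rng.integers(1, 4))
    if rng.random() < 0.5:  # insertion
        ins = "".join("ACGT"[i] for i in rng.integers(0, 4, ilen))
        return ref_b, ref_b + ins
    ref = "".join(chr(b) for b in seq[pos0 : pos0 + 1 + ilen])
    return ref, ref_b


def simulate_cross(config: SimConfig | None = None) -> SimResult:
    """Generate the four-strain synthetic cross with full ground truth."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    panel = default_panel()
    seg = cfg.segment

    # 1. chromosome sequences
    seqs: dict[str, np.ndarray] = {
        c: _BASES[rng.integers(0, 4, cfg.chrom_length, dtype=np.uint8)]
        for c in cfg.chrom_names
    }
    main = seqs[MAIN_CHROM]

    # 2. gene planting (main chromosome only)
    genes = _plant_genes(rng, main, cfg)
    in_seg_genes = [g for g in genes if seg.start <= g.model.span.start < seg.end]

    # 3. causal + synonymous CDS variants (donor-specific by construction)
    causal_gene = in_seg_genes[cfg.causal.gene_index]
    ref_codon, within, alt_base = _design_causal_codon(cfg.causal.ref_aa, cfg.causal.alt_aa)
    ci = cfg.causal.codon_position - 1
    if not 0 < ci < len(causal_gene.codons) - 1:
        raise ValueError("causal codon_position outside the planted ORF")
    causal_gene.codons[ci] = ref_codon
    _write_cds(main, causal_gene.model, "".join(causal_gene.codons))
    causal_pos0 = causal_gene.model.genomic_pos(ci * 3 + within)
    flip = causal_gene.model.strand == "-"
    causal_ref = chr(main[causal_pos0])
    causal_alt = _revcomp(alt_base) if flip else alt_base

    planted: list[tuple[int, str, str]] = [(causal_pos0, causal_ref, causal_alt)]
    syn_sites = []
    for g in in_seg_genes:
        for k, codon in enumerate(g.codons[1:-1], start=1):
            if g is causal_gene and k == ci:
                continue
            aa = str(Seq(codon).translate())
            for b in "ACGT":
                if b != codon[2] and str(Seq(codon[:2] + b).translate()) == aa:
                    syn_sites.append((g, k, b))
                    break
    order = rng.permutation(len(syn_sites))[: cfg.n_cds_synonymous]
    for idx in sorted(int(i) for i in order):
        g, k, b = syn_sites[idx]
        p0 = g.model.genomic_pos(k * 3 + 2)
        planted.append(
            (p0, chr(main[p0]), _revcomp(b) if g.model.strand == "-" else b)
        )

    # 4. marker positions and alleles per chromosome and class
    blocked: dict[str, np.ndarray] = {
        c: np.zeros(cfg.chrom_length, dtype=bool) for c in cfg.chrom_names
    }
    for g in genes:
        for e in g.model.cds_exons:
            blocked[MAIN_CHROM][e.start : e.end] = True
    for p0, _, _ in planted:
        blocked[MAIN_CHROM][p0 : p0 + 6] = True

    P, R = (Genotype.HOM_ALT, Genotype.HOM_REF)
    class_gts = {  # (donor parent, recipient parent)
        "donor": (P, R),
        "recipient": (R, P),
        "shared": (P, P),
    }
    rates = {
        "donor": cfg.donor_marker_rate,
        "recipient": cfg.recipient_marker_rate,
        "shared": cfg.shared_variant_rate,
    }
    raw: list[tuple[str, int, str, str, Genotype, Genotype]] = []
    for chrom in cfg.chrom_names:
        for klass in ("donor", "recipient", "shared"):
            n = int(rng.binomial(cfg.chrom_length, rates[klass]))
            pos = _draw_positions(rng, 0, cfg.chrom_length, n, blocked[chrom])
            indel_mask = rng.random(n) < cfg.indel_fraction
            d_gt, r_gt = class_gts[klass]
            for p0, is_indel in zip(pos, indel_mask):
                ref, alt = _alleles(rng, seqs[chrom], int(p0), bool(is_indel))
                raw.append((chrom, int(p0), ref, alt, d_gt, r_gt))
    for p0, ref, alt in planted:
        raw.append((MAIN_CHROM, p0, ref, alt, P, R))

    # 5. mosaic extra donor segments (outside the main segment)
    extra: list[GenomicInterval] = []
    guard = 0
    while len(extra) < cfg.n_extra_mosaic_segments:
        guard += 1
        if guard > 1000:
            raise RuntimeError("could not place extra mosaic segments")
        chrom = cfg.chrom_names[int(rng.integers(0, len(cfg.chrom_names)))]
        s = int(rng.integers(0, cfg.chrom_length - cfg.extra_segment_length))
        iv = GenomicInterval(chrom, s, s + cfg.extra_segment_length)
        clash = (chrom == MAIN_CHROM and iv.overlaps(seg)) or any(
            iv.overlaps(x) for x in extra
        )
        if not clash:
            extra.append(iv)
    extra.sort(key=lambda v: (v.chrom, v.start))
    true_segments = {CONGENIC: [seg], MOSAIC: sorted([seg, *extra], key=lambda v: (v.chrom, v.start))}

    def origin_is_donor(strain: str, chrom: str, p0: int) -> bool:
        return any(iv.contains_pos(chrom, p0) for iv in true_segments[strain])

    # assemble calls (truth genotypes)
    calls: list[VariantCall] = []
    for chrom, p0, ref, alt, d_gt, r_gt in raw:
        gts = {DONOR: d_gt, RECIPIENT: r_gt}
        for strain in (CONGENIC, MOSAIC):
            gts[strain] = d_gt if origin_is_donor(strain, chrom, p0) else r_gt
        calls.append(VariantCall(chrom, p0 + 1, ref, alt, dict(gts)))
    calls.sort(key=VariantCall.sort_key)
    for i, c in enumerate(calls):
        c.var_id = f"v{i:06d}"
    causal_call = next(c for c in calls if c.pos0 == causal_pos0 and c.chrom == MAIN_CHROM)

    expected_candidates = [
        c.var_id
        for c in calls
        if c.chrom == MAIN_CHROM
        and seg.start <= c.pos0 < seg.end
        and c.genotypes[DONOR] is P
        and c.genotypes[RECIPIENT] is R
    ]

    # 6. structural variants
    svs: list[StructuralVariant] = []
    spec_types = [SvType.DEL, SvType.INV, SvType.DUP]
    for k in range(cfg.n_sv_specific):
        ln = int(rng.integers(5_000, 30_000))
        s = int(rng.integers(seg.start, seg.end - ln))
        svs.append(
            StructuralVariant(
                MAIN_CHROM, s, s + ln, spec_types[k % 3],
                {DONOR: P, CONGENIC: P, MOSAIC: P, RECIPIENT: R},
            )
        )
    bg_types = [SvType.DEL, SvType.DUP, SvType.INV, SvType.INS]
    k = 0
    guard = 0
    while k < cfg.n_sv_background:
        guard += 1
        if guard > 2000:
            raise RuntimeError("could not place background SVs")
        chrom = cfg.chrom_names[int(rng.integers(0, len(cfg.chrom_names)))]
        ln = int(rng.integers(1_000, 50_000))
        s = int(rng.integers(0, cfg.chrom_length - ln))
        svt = bg_types[int(rng.integers(0, 4))]
        carriers = rng.random(4) < 0.5
        if chrom == MAIN_CHROM and GenomicInterval(chrom, s, s + ln).overlaps(seg):
            continue
        names = [DONOR, RECIPIENT, CONGENIC, MOSAIC]
        gts = {n: (P if carry else R) for n, carry in zip(names, carriers)}
        prone_specific = (
            gts[DONOR] is P and gts[CONGENIC] is P and gts[MOSAIC] is P and gts[RECIPIENT] is R
        )
        if prone_specific or not carriers.any():
            continue
        svs.append(StructuralVariant(chrom, s, s + (1 if svt is SvType.INS else ln), svt, gts))
        k += 1
    svs.sort(key=StructuralVariant.sort_key)
    for i, sv in enumerate(svs):
        sv.sv_id = f"sv{i:03d}"
    specific_ids = [
        sv.sv_id
        for sv in svs
        if sv.genotypes[DONOR] is P
        and sv.genotypes[CONGENIC] is P
        and sv.genotypes[MOSAIC] is P
        and sv.genotypes[RECIPIENT] is R
    ]

    # 7. synteny blocks main chromosome -> fictitious human chromosome
    nb = cfg.n_synteny_blocks
    edges = [cfg.chrom_length * i // nb for i in range(nb + 1)]
    src_blocks = [(edges[i], edges[i + 1]) for i in range(nb)]
    perm = rng.permutation(nb)
    inverted = int(rng.integers(0, nb))
    dst_base = 50_000_000
    blocks: list[SyntenyBlock] = []
    cursor = dst_base
    for bi in perm:
        s, e = src_blocks[int(bi)]
        strand = "-" if int(bi) == inverted else "+"
        blocks.append(
            SyntenyBlock(
                GenomicInterval(MAIN_CHROM, s, e),
                GenomicInterval(HUMAN_CHROM, cursor, cursor + (e - s)),
                strand,
            )
        )
        cursor += e - s
    blocks.sort(key=lambda b: b.src.start)

    # truth liftover of the main segment (inline arithmetic, not the
    # homology module, so the construction oracle stays independent)
    pieces: list[GenomicInterval] = []
    for b in blocks:
        s = max(seg.start, b.src.start)
        e = min(seg.end, b.src.end)
        if s >= e:
            continue
        ds, de = lift_sub(b, s, e)
        pieces.append(GenomicInterval(HUMAN_CHROM, ds, de))
    pieces.sort(key=lambda p: p.start)
    hull = GenomicInterval(
        HUMAN_CHROM, min(p.start for p in pieces), max(p.end for p in pieces)
    )

    # 8. peaks on the human chromosome; in-locus peaks are placed with an
    # interior margin so they sit well inside the lifted locus rather than
    # straddling its boundary (the marker-resolved detected boundary sits
    # within ~kb of truth, and boundary-straddling peaks are not a useful
    # truth condition)
    margin = min(25_000, min(len(p) for p in pieces) // 10)
    inner = [
        GenomicInterval(p.chrom, p.start + margin, p.end - margin) for p in pieces
    ]
    peaks: list[tuple[GenomicInterval, str]] = []
    piece_lens = np.array([len(p) for p in inner])
    piece_cum = np.concatenate([[0], np.cumsum(piece_lens)])
    dys_idx = set(int(i) for i in rng.permutation(cfg.n_peaks_inside)[: cfg.n_dys_inside])
    for i in range(cfg.n_peaks_inside):
        u = int(rng.integers(0, piece_cum[-1]))
        pi = int(np.searchsorted(piece_cum, u, side="right") - 1)
        p = inner[pi]
        w = int(rng.integers(300, 1500))
        s = p.start + min(u - int(piece_cum[pi]), len(p) - 1)
        e = min(s + w, p.end)
        e = max(e, s + 1)
        peaks.append((GenomicInterval(HUMAN_CHROM, s, e), "dys" if i in dys_idx else "stable"))
    placed = 0
    guard = 0
    while placed < cfg.n_peaks_outside:
        guard += 1
        if guard > 5000:
            raise RuntimeError("could not place outside peaks")
        s = int(rng.integers(dst_base, dst_base + cfg.chrom_length - 2000))
        w = int(rng.integers(300, 1500))
        iv = GenomicInterval(HUMAN_CHROM, s, s + w)
        if iv.overlaps(GenomicInterval(HUMAN_CHROM, hull.start - 2000, hull.end + 2000)):
            continue
        peaks.append((iv, "stable"))
        placed += 1
    peaks.sort(key=lambda t: (t[0].start, t[0].end))

    # 9. association table on the human chromosome
    traits = [
        "schizophrenia",
        "major_depressive_disorder",
        "educational_attainment",
        "cognitive_performance",
    ]
    assoc: list[dict] = []
    for i in range(cfg.n_assoc_inside):
        pos0 = int(rng.integers(hull.start + margin, hull.end - margin))
        assoc.append(
            {"chrom": HUMAN_CHROM, "pos": pos0 + 1, "trait": traits[i % 4],
             "p": float(10 ** rng.uniform(-8, -2))}
        )
    placed = 0
    guard = 0
    while placed < cfg.n_assoc_outside:
        guard += 1
        if guard > 5000:
            raise RuntimeError("could not place outside associations")
        pos0 = int(rng.integers(dst_base, dst_base + cfg.chrom_length))
        if hull.start <= pos0 < hull.end:
            continue
        assoc.append(
            {"chrom": HUMAN_CHROM, "pos": pos0 + 1, "trait": traits[placed % 4],
             "p": float(10 ** rng.uniform(-8, -2))}
        )
        placed += 1
    assoc.sort(key=lambda r: (r["pos"], r["trait"]))

    # 10. genotype noise on SNV/indel calls, after truth recording
    names = [DONOR, RECIPIENT, CONGENIC, MOSAIC]
    if cfg.missing_rate > 0 or cfg.genotype_error_rate > 0:
        n = len(calls)
        miss = rng.random((n, 4)) < cfg.missing_rate
        err = rng.random((n, 4)) < cfg.genotype_error_rate
        pick = rng.integers(0, 2, (n, 4))
        for i, c in enumerate(calls):
            for j, s in enumerate(names):
                if miss[i, j]:
                    c.genotypes[s] = Genotype.MISSING
                elif err[i, j]:
                    wrong = [g for g in (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)
                             if g is not c.genotypes[s]]
                    c.genotypes[s] = wrong[int(pick[i, j])]

    truth = TruthSet(
        true_segments=true_segments,
        causal_variant=causal_call,
        causal_gene_id=causal_gene.model.gene_id,
        causal_protein_change=(
            f"{cfg.causal.ref_aa}{cfg.causal.codon_position}{cfg.causal.alt_aa}"
        ),
        expected_candidates=expected_candidates,
        expected_specific_sv_ids=specific_ids,
        expected_lifted_pieces=pieces,
        expected_lifted_hull=hull,
        expected_peak_counts=(cfg.n_peaks_inside, cfg.n_dys_inside),
        n_assoc_inside=cfg.n_assoc_inside,
    )
    chrom_seqs = {c: a.tobytes().decode() for c, a in seqs.items()}
    return SimResult(
        config=cfg,
        panel=panel,
        calls=calls,
        svs=svs,
        genes=[g.model for g in genes],
        chrom_seqs=chrom_seqs,
        synteny=blocks,
        peaks=peaks,
        assoc=assoc,
        truth=truth,
    )


def patterned_peakset(
    locus: GenomicInterval,
    n_inside: int,
    n_labeled: int,
    label: str,
    n_outside: int = 20,
    other_label: str = "stable",
    seed: int = 0,
) -> list[tuple[GenomicInterval, str]]:
    """A peak set with a known in-locus counting pattern: ``n_inside``
    peaks overlap the locus, of which ``n_labeled`` carry ``label``; the
    rest (and all outside peaks) carry ``other_label``."""
    if not 0 <= n_labeled <= n_inside:
        raise ValueError("n_labeled must be <= n_inside")
    rng = np.random.default_rng(seed)
    peaks: list[tuple[GenomicInterval, str]] = []
    lab_idx = set(int(i) for i in rng.permutation(n_inside)[:n_labeled])
    for i in range(n_inside):
        s = int(rng.integers(locus.start, locus.end - 1))
        w = int(rng.integers(200, 1200))
        peaks.append(
            (
                GenomicInterval(locus.chrom, s, min(s + w, locus.end)),
                label if i in lab_idx else other_label,
            )
        )
    span = max(len(locus), 10_000)
    for _ in range(n_outside):
        left = rng.random() < 0.5
        if left and locus.start > 2000:
            s = int(rng.integers(max(locus.start - span, 0), max(locus.start - 1500, 1)))
        else:
            s = int(rng.integers(locus.end + 10, locus.end + span))
        peaks.append((GenomicInterval(locus.chrom, s, s + int(rng.integers(200, 1200))), other_label))
    peaks.sort(key=lambda t: (t[0].start, t[0].end))
    return peaks


# ---------------------------------------------------------------------------
# artifact emission


def _gff3_text(genes: list[GeneModel]) -> str:
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda m: (m.chrom, m.span.start)):
        span = g.span
        lines.append(
            f"{g.chrom}\tcongmap\tgene\t{span.start + 1}\t{span.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id};Name={g.gene_name}"
        )
        tid = f"{g.gene_id}.t1"
        lines.append(
            f"{g.chrom}\tcongmap\tmRNA\t{span.start + 1}\t{span.end}\t.\t{g.strand}\t.\t"
            f"ID={tid};Parent={g.gene_id}"
        )
        order = g.cds_exons if g.strand == "+" else list(reversed(g.cds_exons))
        running = 0
        phases = {}
        for e in order:
            phases[(e.start, e.end)] = (3 - running % 3) % 3
            running += len(e)
        for e in g.cds_exons:
            ph = phases[(e.start, e.end)]
            lines.append(
                f"{g.chrom}\tcongmap\tCDS\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t{ph}\t"
                f"ID={g.gene_id}.cds;Parent={tid}"
            )
    return "\n".join(lines) + "\n"


def _fasta_text(chrom_seqs: dict[str, str], width: int = 60) -> str:
    parts = []
    for chrom, s in chrom_seqs.items():
        parts.append(f">{chrom}")
        parts.extend(s[i : i + width] for i in range(0, len(s), width))
    return "\n".join(parts) + "\n"


def _truth_json(truth: TruthSet) -> dict:
    iv = lambda v: {"chrom": v.chrom, "start": v.start, "end": v.end}
    c = truth.causal_variant
    return {
        "true_segments": {
            s: [iv(v) for v in ivs] for s, ivs in truth.true_segments.items()
        },
        "causal_variant": {
            "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
            "var_id": c.var_id,
        },
        "causal_gene_id": truth.causal_gene_id,
        "causal_protein_change": truth.causal_protein_change,
        "expected_candidates": truth.expected_candidates,
        "expected_specific_sv_ids": truth.expected_specific_sv_ids,
        "expected_lifted_pieces": [iv(p) for p in truth.expected_lifted_pieces],
        "expected_lifted_hull": iv(truth.expected_lifted_hull),
        "expected_peak_counts": list(truth.expected_peak_counts),
        "n_assoc_inside": truth.n_assoc_inside,
        "gene_models_path": truth.gene_models_path,
    }


def write_artifacts(sim: SimResult, out_dir) -> dict[str, Path]:
    """Write every artifact of one simulation; byte-identical per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "calls.vcf",
        "sv_vcf": out / "sv.vcf",
        "gff3": out / "genes.gff3",
        "fasta": out / "genome.fa",
        "peaks": out / "peaks.bed",
        "synteny": out / "synteny.tsv",
        "panel": out / "panel.tsv",
        "assoc": out / "assoc.tsv",
        "truth": out / "truth.json",
    }
    cio.write_variants(sim.calls, paths["vcf"], sim.panel)
    cio.write_structural_variants(sim.svs, paths["sv_vcf"], sim.panel)
    paths["gff3"].write_text(_gff3_text(sim.genes))
    paths["fasta"].write_text(_fasta_text(sim.chrom_seqs))
    cio.write_intervals(sim.peaks, paths["peaks"])
    write_synteny(sim.synteny, paths["synteny"])
    cio.write_panel(sim.panel, paths["panel"])
    with open(paths["assoc"], "w") as fh:
        fh.write("chrom\tpos\ttrait\tp\n")
        for r in sim.assoc:
            fh.write(f"{r['chrom']}\t{r['pos']}\t{r['trait']}\t{r['p']:.6g}\n")
    sim.truth.gene_models_path = paths["gff3"].name  # relative: keeps truth.json seed-stable
    with open(paths["truth"], "w") as fh:
        json.dump(_truth_json(sim.truth), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
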