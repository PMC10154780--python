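"""Codon-level consequence calling against a full-translation oracle."""

import numpy as np
import pytest
from Bio.Seq import Seq

from _oracles import full_translation_consequence, spliced_cds
from congmap.consequence import (
    ConsequenceCall,
    GeneModel,
    Impact,
    ReferenceMismatchError,
    SiftAnnotation,
    annotate_consequence,
    attach_scores,
    read_gene_models,
)
from congmap.models import GenomicInterval, VariantCall

SENSE = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if str(Seq(a + b + c).translate()) != "*"
]


def _toy_gene(seq="ATGCATGGG", start=10, strand="+", chrom="13"):
    """Single-exon gene with the given CDS planted in a padded sequence."""
    pad = "A" * start
    cds = seq if strand == "+" else str(Seq(seq).reverse_complement())
    chrom_seq = pad + cds + "A" * 20
    model = GeneModel("g1", "G1", chrom, strand,
                      [GenomicInterval(chrom, start, start + len(seq))])
    return model, chrom_seq


def _snv(pos0, ref, alt):
    return VariantCall("13", pos0 + 1, ref, alt, {})


def test_missense_call_with_protein_change():
    # CDS ATG CAT GGG; codon 2 CAT(H) -> CGT(R)
    model, seq = _toy_gene()
    call = _snv(10 + 4, "A", "G")
    (c,) = annotate_consequence(call, [model], seq)
    assert c.impact is Impact.MISSENSE
    assert c.protein_change == "H2R"


def test_synonymous_third_position_change():
    model, seq = _toy_gene()
    call = _snv(10 + 8, "G", "A")  # GGG -> GGA, both Gly
    (c,) = annotate_consequence(call, [model], seq)
    assert c.impact is Impact.SYNONYMOUS
    assert c.protein_change == ""


def test_stop_gained_and_stop_lost():
    model, seq = _toy_gene("ATGTACTAA")  # M Y *
    # codon 2 TAC(Y) at pos0 13..15: C->A gives TAA -> stop gained
    (c,) = annotate_consequence(_snv(15, "C", "A"), [model], seq)
    assert c.impact is Impact.STOP_GAINED
    assert c.protein_change == "Y2*"
    # codon 3 TAA(*) at pos0 16..18: T->C gives CAA(Q) -> stop lost
    (c2,) = annotate_consequence(_snv(16, "T", "C"), [model], seq)
    assert c2.impact is Impact.STOP_LOST
    assert c2.protein_change == "*3Q"


def test_variant_outside_any_gene_is_noncoding_with_empty_gene():
    model, seq = _toy_gene()
    (c,) = annotate_consequence(_snv(2, "A", "C"), [model], seq)
    assert c.impact is Impact.NONCODING
    assert c.gene_id == ""


def test_intronic_variant_is_noncoding_with_gene_id():
    chrom_seq = "A" * 10 + "ATG" + "AAAA" + "CATGGGTAA" + "A" * 10
    model = GeneModel(
        "g2", "G2", "13", "+",
        [GenomicInterval("13", 10, 13), GenomicInterval("13", 17, 26)],
    )
    (c,) = annotate_consequence(_snv(14, "A", "G"), [model], chrom_seq)
    assert c.impact is Impact.NONCODING
    assert c.gene_id == "g2"


def test_cds_indel_umbrella():
    model, seq = _toy_gene()
    call = VariantCall("13", 15, seq[14], seq[14] + "TT", {})
    (c,) = annotate_consequence(call, [model], seq)
    assert c.impact is Impact.CDS_INDEL
    assert c.protein_change == ""


def test_reference_mismatch_is_detected():
    model, seq = _toy_gene()
    wrong = "C" if seq[14] != "C" else "G"
    with pytest.raises(ReferenceMismatchError, match="15"):
        annotate_consequence(_snv(14, wrong, "T"), [model], seq)


def _random_gene_case(rng, chrom="13"):
    """Random multi-exon gene on random strand + a random exonic SNV."""
    n_codons = int(rng.integers(5, 40))
    codons = ["ATG"] + [SENSE[int(i)] for i in rng.integers(0, len(SENSE), n_codons - 2)]
    codons.append(["TAA", "TAG", "TGA"][int(rng.integers(0, 3))])
    cds = "".join(codons)
    n_exons = int(rng.integers(1, 4))
    cuts = sorted(set(int(c) for c in rng.integers(1, len(cds), n_exons - 1)))
    chunks = [cds[a:b] for a, b in zip([0, *cuts], [*cuts, len(cds)])]
    strand = "+" if rng.random() < 0.5 else "-"
    start = int(rng.integers(5, 30))
    pos = start
    exons = []
    tx_chunks = chunks if strand == "+" else [
        str(Seq(c).reverse_complement()) for c in reversed(chunks)
    ]
    # genomic order: for '-' strand the first transcription chunk is rightmost
    genomic_chunks = tx_chunks
    seq_parts = ["T" * start]
    for k, ch in enumerate(genomic_chunks):
        exons.append(GenomicInterval(chrom, pos, pos + len(ch)))
        seq_parts.append(ch)
        pos += len(ch)
        if k < len(genomic_chunks) - 1:
            gap = int(rng.integers(3, 20))
            seq_parts.append("T" * gap)
            pos += gap
    seq_parts.append("T" * 25)
    chrom_seq = "".join(seq_parts)
    model = GeneModel("gr", "GR", chrom, strand, exons)
    # sanity: splice must reproduce the CDS
    assert spliced_cds(model, chrom_seq) == cds
    exon = exons[int(rng.integers(0, len(exons)))]
    p0 = int(rng.integers(exon.start, exon.end))
    ref = chrom_seq[p0]
    alt = "ACGT"[int(rng.integers(0, 4))]
    while alt == ref:
        alt = "ACGT"[int(rng.integers(0, 4))]
    return model, chrom_seq, _snv(p0, ref, alt)


def test_agrees_with_full_translation_oracle_on_random_genes():
    rng = np.random.default_rng(77)
    n_checked = 0
    for _ in range(400):
        model, chrom_seq, call = _random_gene_case(rng)
        (got,) = annotate_consequence(call, [model], chrom_seq)
        impact, change = full_translation_consequence(call, model, chrom_seq)
        assert got.impact.value == impact
        assert got.protein_change == change
        n_checked += 1
    assert n_checked == 400


def test_strand_mirror_symmetry():
    """A gene and its reverse-complement mirror image yield identical calls."""
    rng = np.random.default_rng(99)
    for _ in range(100):
        model, chrom_seq, call = _random_gene_case(rng)
        L = len(chrom_seq)
        mirror_seq = str(Seq(chrom_seq).reverse_complement())
        mirror_exons = [
            GenomicInterval(model.chrom, L - e.end, L - e.start)
            for e in reversed(model.cds_exons)
        ]
        mirror_model = GeneModel(
            "gm", "GM", model.chrom,
            "-" if model.strand == "+" else "+", mirror_exons,
        )
        mirror_call = VariantCall(
            call.chrom, L - call.pos0, str(Seq(call.ref).complement()),
            str(Seq(call.alt).complement()), {},
        )
        (a,) = annotate_consequence(call, [model], chrom_seq)
        (b,) = annotate_consequence(mirror_call, [mirror_model], mirror_seq)
        assert (a.impact, a.protein_change) == (b.impact, b.protein_change)


def test_protein_change_parses_back_consistently():
    rng = np.random.default_rng(13)
    import re

    for _ in range(200):
        model, chrom_seq, call = _random_gene_case(rng)
        (c,) = annotate_consequence(call, [model], chrom_seq)
        if c.impact is not Impact.MISSENSE:
            continue
        m = re.fullmatch(r"([A-Z*])(\d+)([A-Z*])", c.protein_change)
        assert m
        ref_aa, pos, alt_aa = m.group(1), int(m.group(2)), m.group(3)
        cds = spliced_cds(model, chrom_seq)
        prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
        assert prot[pos - 1] == ref_aa
        assert ref_aa != alt_aa


def test_gff3_round_trip_of_simulated_models(sim_noise_free, tmp_path):
    from congmap.simulate import _gff3_text

    (tmp_path / "g.gff3").write_text(_gff3_text(sim_noise_free.genes))
    back = read_gene_models(tmp_path / "g.gff3")
    orig = {g.gene_id: g for g in sim_noise_free.genes}
    assert len(back) == len(orig)
    for m in back:
        o = orig[m.gene_id]
        assert m.strand == o.strand
        assert m.cds_exons == o.cds_exons
        assert m.phase == o.phase == 0


def test_sift_threshold_is_strict():
    assert SiftAnnotation.from_score(0.01).label == "deleterious"
    assert SiftAnnotation.from_score(0.35).label == "tolerated"
    assert SiftAnnotation.from_score(0.05).label == "tolerated"  # boundary
    with pytest.raises(ValueError, match="outside"):
        SiftAnnotation.from_score(1.5)


def test_attach_scores_fills_matches_only():
    v1 = VariantCall("13", 104069202, "T", "C", {})
    v2 = VariantCall("13", 104111134, "G", "A", {})
    v3 = VariantCall("13", 999, "A", "G", {})
    cons = [
        ConsequenceCall(v1, "Nln-like", Impact.MISSENSE, "H148R"),
        ConsequenceCall(v2, "Sgtb-like", Impact.MISSENSE, "C7Y"),
        ConsequenceCall(v3, "x", Impact.MISSENSE, "A1V"),
    ]
    table = {("13", 104069202, "T", "C"): 0.35, ("13", 104111134, "G", "A"): 0.01}
    attach_scores(cons, table)
    assert cons[0].sift.label == "tolerated" and cons[0].sift.score == 0.35
    assert cons[1].sift.label == "deleterious"
    assert cons[2].sift is None
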