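"""Readers/writers for the external formats (VCF, BED, panel TSV).

VCF access is built on :mod:`pysam`; on top of it this module performs the
normalization every downstream filter assumes: multi-allelic records are
split into biallelic calls, alleles are trimmed to minimal representation,
and records are sorted by (chromosome natural order, position, alt).
Records carrying an ``SVTYPE`` INFO key are structural variants and are
read by :func:`read_structural_variants` instead.

Writers emit plain VCF 4.2 / BED text so that read(write(x)) == x for
normalized input. All text I/O is transparently gzip-aware by suffix.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence

import pysam

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
    chrom_sort_key,
    normalize_chrom,
)


class VcfFormatError(ValueError):
    pass


def xopen(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# allele normalization


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then prefix down to minimal representation.

    ``pos`` is 1-based; prefix trimming advances it. Idempotent.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _gt_from_tuple(gt: tuple, alt_index: int) -> Genotype:
    """Collapse a diploid GT tuple to a state for one alt allele.

    ``alt_index`` is the 1-based allele index of the alt under
    consideration; other alt alleles count as non-carrier so that a 1/2
    sample is het for each decomposed record.
    """
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        return Genotype.MISSING
    n = sum(1 for a in gt if a == alt_index)
    if len(gt) == 1:  # haploid call, treated as homozygous
        return Genotype.HOM_ALT if n == 1 else Genotype.HOM_REF
    if n >= 2:
        return Genotype.HOM_ALT
    if n == 1:
        return Genotype.HET
    return Genotype.HOM_REF


# ---------------------------------------------------------------------------
# VCF reading


def _open_vcf(vcf_source) -> pysam.VariantFile:
    path = str(vcf_source)
    try:
        return pysam.VariantFile(path)
    except NotImplementedError:
        # plain (non-BGZF) gzip: htslib cannot seek it; inflate to a temp file
        import tempfile

        with gzip.open(path, "rt") as fh:
            tmp = tempfile.NamedTemporaryFile(
                "w", suffix=".vcf", delete=False
            )
            tmp.write(fh.read())
            tmp.close()
        return pysam.VariantFile(tmp.name)
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"cannot read VCF {vcf_source}: {exc}") from exc


def _check_panel_samples(vcf: pysam.VariantFile, panel: StrainPanel) -> list[str]:
    samples = list(vcf.header.samples)
    wanted = [e.name for e in panel.sequenced]
    for name in wanted:
        if name not in samples:
            raise VcfFormatError(
                f"panel sample {name!r} absent from VCF header "
                f"(header has: {', '.join(samples) or 'no samples'})"
            )
    return wanted


def read_variants(vcf_source, panel: StrainPanel) -> list[VariantCall]:
    """Read SNV/indel records as normalized biallelic :class:`VariantCall`.

    Multi-allelic rows are decomposed; SV-typed rows are skipped (use
    :func:`read_structural_variants`); output is sorted.
    """
    vcf = _open_vcf(vcf_source)
    wanted = _check_panel_samples(vcf, panel)
    calls: list[VariantCall] = []
    lineno = 0
    try:
        for rec in vcf:
            lineno += 1
            if "SVTYPE" in rec.info:
                continue
            if rec.alts is None:
                continue
            for ai, alt in enumerate(rec.alts, start=1):
                if alt is None or alt.startswith("<") or alt in (".", "*"):
                    continue
                pos, ref, alt_t = trim_alleles(rec.pos, rec.ref, alt)
                gts = {
                    s: _gt_from_tuple(rec.samples[s].get("GT"), ai)
                    for s in wanted
                }
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt_t,
                        var_id=rec.id,
                        genotypes=gts,
                    )
                )
    except VcfFormatError:
        raise
    except Exception as exc:  # pragma: no cover - malformed input path
        raise VcfFormatError(
            f"malformed VCF record near data line {lineno + 1}: {exc}"
        ) from exc
    calls.sort(key=VariantCall.sort_key)
    return calls


def read_structural_variants(vcf_source, panel: StrainPanel) -> list[StructuralVariant]:
    """Read records with an SVTYPE INFO key as :class:`StructuralVariant`."""
    vcf = _open_vcf(vcf_source)
    wanted = _check_panel_samples(vcf, panel)
    svs: list[StructuralVariant] = []
    for rec in vcf:
        if "SVTYPE" not in rec.info:
            continue
        svtype = SvType(str(rec.info["SVTYPE"]))
        start = rec.start  # 0-based
        end = rec.stop  # honors INFO/END
        if svtype is SvType.INS:
            end = start + 1
        elif svtype is SvType.BND and end <= start:
            end = start + 1
        gts = {s: _gt_from_tuple(rec.samples[s].get("GT"), 1) for s in wanted}
        svs.append(
            StructuralVariant(
                chrom=rec.chrom,
                start=start,
                end=end,
                svtype=svtype,
                genotypes=gts,
                sv_id=rec.id,
            )
        )
    svs.sort(key=StructuralVariant.sort_key)
    return svs


# ---------------------------------------------------------------------------
# VCF writing

_GT_FIELD = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def _vcf_header(samples: Sequence[str], contigs: Iterable[str], sv: bool) -> list[str]:
    lines = ["##fileformat=VCFv4.2", "##source=congmap"]
    for c in sorted(set(contigs), key=chrom_sort_key):
        lines.append(f"##contig=<ID={c}>")
    if sv:
        lines.append(
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">'
        )
        lines.append(
            '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    return lines


def write_variants(calls: Sequence[VariantCall], sink, panel: StrainPanel) -> None:
    """Write normalized calls as VCF 4.2. Input must be sorted."""
    keys = [c.sort_key() for c in calls]
    if keys != sorted(keys):
        raise ValueError("write_variants requires position-sorted input")
    samples = [e.name for e in panel.sequenced]
    lines = _vcf_header(samples, (c.chrom for c in calls), sv=False)
    for c in calls:
        gts = "\t".join(_GT_FIELD[c.genotypes.get(s, Genotype.MISSING)] for s in samples)
        lines.append(
            f"{c.chrom}\t{c.pos}\t{c.var_id or '.'}\t{c.ref}\t{c.alt}"
            f"\t.\t.\t.\tGT\t{gts}"
        )
    _write_text(sink, "\n".join(lines) + "\n")


def write_structural_variants(
    svs: Sequence[StructuralVariant], sink, panel: StrainPanel
) -> None:
    keys = [s.sort_key() for s in svs]
    if keys != sorted(keys):
        raise ValueError("write_structural_variants requires sorted input")
    samples = [e.name for e in panel.sequenced]
    lines = _vcf_header(samples, (s.chrom for s in svs), sv=True)
    for s in svs:
        gts = "\t".join(_GT_FIELD[s.genotypes.get(n, Genotype.MISSING)] for n in samples)
        info = f"SVTYPE={s.svtype.value};END={s.end}"
        lines.append(
            f"{s.chrom}\t{s.start + 1}\t{s.sv_id or '.'}\tN\t<{s.svtype.value}>"
            f"\t.\t.\t{info}\tGT\t{gts}"
        )
    _write_text(sink, "\n".join(lines) + "\n")


def _write_text(sink, text: str) -> None:
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with xopen(sink, "wt") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# BED


def read_intervals(bed_source) -> list[tuple[GenomicInterval, str | None]]:
    """Read BED3/BED4 as (interval, label) pairs, coordinates kept native."""
    out: list[tuple[GenomicInterval, str | None]] = []
    with xopen(bed_source) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise VcfFormatError(f"BED line {i}: fewer than 3 columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise VcfFormatError(f"BED line {i}: non-integer coordinate") from exc
            if start > end:
                raise VcfFormatError(f"BED line {i}: start > end")
            label = parts[3] if len(parts) > 3 else None
            out.append((GenomicInterval(normalize_chrom(chrom), start, end), label))
    return out


def write_intervals(items: Sequence[tuple[GenomicInterval, str | None]], sink) -> None:
    lines = []
    for iv, label in items:
        cols = [iv.chrom, str(iv.start), str(iv.end)]
        if label is not None:
            cols.append(label)
        lines.append("\t".join(cols))
    _write_text(sink, "\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# strain panel TSV


def read_panel(tsv_source) -> StrainPanel:
    """Read a strain panel TSV with columns name, phenotype, role."""
    entries = []
    with xopen(tsv_source) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "name":  # header row
                continue
            if len(parts) < 3:
                raise VcfFormatError(f"panel line {i}: need name/phenotype/role")
            try:
                entries.append(
                    StrainEntry(parts[0], Phenotype(parts[1]), Role(parts[2]))
                )
            except ValueError as exc:
                raise VcfFormatError(f"panel line {i}: {exc}") from exc
    return StrainPanel(entries)


def write_panel(panel: StrainPanel, sink) -> None:
    lines = ["name\tphenotype\trole"]
    for e in panel.entries:
        lines.append(f"{e.name}\t{e.phenotype.value}\t{e.role.value}")
    _write_text(sink, "\n".join(lines) + "\n")
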