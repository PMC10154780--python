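"""Synteny-block interval liftover and interval screens.

The mapped mouse locus is carried into the homologous human region through
a table of colinear, equal-length synteny blocks (strand-aware, per-base
bijective within a block). On the lifted interval the module counts
regulatory-peak overlaps (e.g. H3K27ac peaks, with a dysregulated subset)
and screens an association table. Which homology resource produced the
blocks is deliberately an input, not a dependency.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

from intervaltree import IntervalTree

from .io import xopen
from .models import GenomicInterval, normalize_chrom


@dataclass(frozen=True)
class SyntenyBlock:
    """Colinear homologous segment; len(src) == len(dst) by construction."""

    src: GenomicInterval
    dst: GenomicInterval
    strand: str  # '+' | '-'

    def __post_init__(self):
        if len(self.src) != len(self.dst):
            raise ValueError("synteny block src/dst lengths differ")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


def read_synteny(tsv_source) -> list[SyntenyBlock]:
    """7-column TSV: src_chrom src_start src_end dst_chrom dst_start dst_end strand."""
    blocks = []
    with xopen(tsv_source) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("src_chrom\t"):
                continue
            p = line.split("\t")
            if len(p) < 7:
                raise ValueError(f"synteny line {i}: need 7 columns")
            blocks.append(
                SyntenyBlock(
                    GenomicInterval(normalize_chrom(p[0]), int(p[1]), int(p[2])),
                    GenomicInterval(normalize_chrom(p[3]), int(p[4]), int(p[5])),
                    p[6],
                )
            )
    return blocks


def write_synteny(blocks: list[SyntenyBlock], sink) -> None:
    lines = ["src_chrom\tsrc_start\tsrc_end\tdst_chrom\tdst_start\tdst_end\tstrand"]
    for b in blocks:
        lines.append(
            f"{b.src.chrom}\t{b.src.start}\t{b.src.end}\t"
            f"{b.dst.chrom}\t{b.dst.start}\t{b.dst.end}\t{b.strand}"
        )
    text = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with xopen(sink, "wt") as fh:
            fh.write(text)


def invert_blocks(blocks: list[SyntenyBlock]) -> list[SyntenyBlock]:
    """Swap src and dst so a mapped interval can be lifted back."""
    return [SyntenyBlock(b.dst, b.src, b.strand) for b in blocks]


def lift_sub(block: SyntenyBlock, s: int, e: int) -> tuple[int, int]:
    """Map src sub-interval [s, e) of one block onto dst coordinates,
    reflecting within the block for '-' strand."""
    off_s, off_e = s - block.src.start, e - block.src.start
    if block.strand == "+":
        return block.dst.start + off_s, block.dst.start + off_e
    return block.dst.end - off_e, block.dst.end - off_s


def liftover_interval(
    iv: GenomicInterval, blocks: list[SyntenyBlock]
) -> tuple[list[GenomicInterval], GenomicInterval | None, float]:
    """Map an interval through the block set.

    Returns (mapped pieces sorted by dst position, bounding hull on the
    majority dst chromosome, fraction of input bp that mapped). An interval
    overlapping no block maps to no pieces with a warning.
    """
    pieces: list[GenomicInterval] = []
    for b in blocks:
        x = iv.intersect(b.src)
        if x is None or len(x) == 0:
            continue
        ds, de = lift_sub(b, x.start, x.end)
        pieces.append(GenomicInterval(b.dst.chrom, ds, de))
    if not pieces:
        warnings.warn(f"interval {iv.chrom}:{iv.start}-{iv.end} overlaps no synteny block")
        return [], None, 0.0
    pieces.sort(key=lambda p: (p.chrom, p.start))
    mapped_bp: dict[str, int] = defaultdict(int)
    for p in pieces:
        mapped_bp[p.chrom] += len(p)
    major = max(mapped_bp, key=lambda c: (mapped_bp[c], c))
    on_major = [p for p in pieces if p.chrom == major]
    bounding = GenomicInterval(
        major, min(p.start for p in on_major), max(p.end for p in on_major)
    )
    coverage = sum(mapped_bp.values()) / len(iv) if len(iv) else 0.0
    return pieces, bounding, coverage


def count_peak_overlaps(
    iv: GenomicInterval,
    peaks: list[tuple[GenomicInterval, str | None]],
    label_filter: str,
) -> tuple[int, int]:
    """(peaks overlapping iv by >= 1 bp, of which carrying label_filter)."""
    tree = IntervalTree()
    for k, (p, _label) in enumerate(peaks):
        if normalize_chrom(p.chrom) == normalize_chrom(iv.chrom) and len(p) > 0:
            tree.addi(p.start, p.end, k)
    hits = tree.overlap(iv.start, iv.end)
    n_total = len(hits)
    n_labeled = sum(1 for h in hits if peaks[h.data][1] == label_filter)
    return n_total, n_labeled


def screen_associations(iv: GenomicInterval, assoc_rows: list[dict]) -> list[dict]:
    """Rows (chrom, pos 1-based, trait, p) falling inside iv, by p ascending."""
    out = [
        r
        for r in assoc_rows
        if iv.contains_pos(normalize_chrom(str(r["chrom"])), int(r["pos"]) - 1)
    ]
    return sorted(out, key=lambda r: (float(r["p"]), int(r["pos"])))


def read_associations(tsv_source) -> list[dict]:
    """Association TSV with columns chrom, pos, trait, p."""
    rows = []
    with xopen(tsv_source) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            p = line.split("\t")
            if len(p) < 4:
                raise ValueError(f"association table line {i}: need 4 columns")
            try:
                rows.append(
                    {"chrom": normalize_chrom(p[0]), "pos": int(p[1]),
                     "trait": p[2], "p": float(p[3])}
                )
            except ValueError as exc:
                raise ValueError(f"association table line {i}: {exc}") from exc
    return rows
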