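"""Independent brute-force oracles used by the test suite.

Each function here recomputes a result by the most transparent route
available (exhaustive enumeration, per-base mapping, full-sequence
translation) and is kept free of the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

from congmap.consequence import GeneModel
from congmap.models import GenomicInterval, Genotype, StrainPanel, VariantCall


def brute_recessive(calls, panel: StrainPanel, locus: GenomicInterval):
    """Per-strain predicate sets, then set intersection."""
    prone = [e.name for e in panel.prone()]
    resistant = [e.name for e in panel.resistant()]
    idx_sets = []
    for s in prone:
        idx_sets.append(
            {i for i, c in enumerate(calls) if c.genotypes.get(s) is Genotype.HOM_ALT}
        )
    for s in resistant:
        idx_sets.append(
            {i for i, c in enumerate(calls) if c.genotypes.get(s) is Genotype.HOM_REF}
        )
    in_locus = {i for i, c in enumerate(calls) if locus.contains_pos(c.chrom, c.pos0)}
    keep = set.intersection(in_locus, *idx_sets)
    return [calls[i] for i in sorted(keep)]


def enumerate_segments(pos, is_donor, min_markers, max_gap_bp, max_frac):
    """All inclusion-maximal (i, j) marker-index pairs with donor-state
    endpoints, gaps <= max_gap_bp, whole-run discordant fraction <=
    max_frac, support >= min_markers. O(n^2)."""
    pos = np.asarray(pos)
    is_donor = np.asarray(is_donor, dtype=bool)
    n = len(pos)
    valid = []
    for i in range(n):
        if not is_donor[i]:
            continue
        sup = 0
        disc = 0
        for j in range(i, n):
            if j > i and pos[j] - pos[j - 1] > max_gap_bp:
                break
            if is_donor[j]:
                sup += 1
            else:
                disc += 1
            if not is_donor[j]:
                continue
            if sup >= min_markers and disc <= max_frac * (sup + disc) + 1e-9:
                valid.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in valid
        if not any(a <= i and b >= j and (a, b) != (i, j) for a, b in valid)
    ]
    return sorted(maximal)


def sv_closure(svs, params):
    """All-pairs transitive closure under the pairwise sameness predicate."""
    from congmap.filters import _same_sv

    n = len(svs)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            adj[i][j] = i == j or _same_sv(svs[i], svs[j], params)
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in range(n):
                if not seen[v] and adj[u][v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(frozenset(comp))
    return set(comps)


def spliced_cds(model: GeneModel, chrom_seq: str) -> str:
    """Full CDS in transcription order (reverse-complemented for '-')."""
    parts = [chrom_seq[e.start : e.end] for e in model.cds_exons]
    s = "".join(parts)
    if model.strand == "-":
        s = str(Seq(s).reverse_complement())
    return s[model.phase :]


def full_translation_consequence(call: VariantCall, model: GeneModel, chrom_seq: str):
    """Classify an SNV by substituting into the chromosome, re-splicing the
    whole CDS and translating both proteins end to end."""
    alt_seq = chrom_seq[: call.pos0] + call.alt + chrom_seq[call.pos0 + 1 :]
    ref_cds = spliced_cds(model, chrom_seq)
    alt_cds = spliced_cds(model, alt_seq)
    usable = len(ref_cds) - len(ref_cds) % 3
    ref_prot = str(Seq(ref_cds[:usable]).translate())
    alt_prot = str(Seq(alt_cds[:usable]).translate())
    diffs = [k for k, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    if not diffs:
        return ("synonymous", "")
    assert len(diffs) == 1
    k = diffs[0]
    a, b = ref_prot[k], alt_prot[k]
    if b == "*":
        impact = "stop_gained"
    elif a == "*":
        impact = "stop_lost"
    else:
        impact = "missense"
    return (impact, f"{a}{k + 1}{b}")


def brute_lift_bases(iv: GenomicInterval, blocks) -> set[tuple[str, int]]:
    """Map every base of iv through the blocks one base at a time."""
    out = set()
    for p in range(iv.start, iv.end):
        for b in blocks:
            if b.src.chrom == iv.chrom and b.src.start <= p < b.src.end:
                off = p - b.src.start
                if b.strand == "+":
                    out.add((b.dst.chrom, b.dst.start + off))
                else:
                    out.add((b.dst.chrom, b.dst.end - 1 - off))
                break
    return out


def brute_peak_count(iv: GenomicInterval, peaks, label):
    n = n_lab = 0
    for p, lab in peaks:
        if p.chrom == iv.chrom and p.start < iv.end and iv.start < p.end:
            n += 1
            if lab == label:
                n_lab += 1
    return n, n_lab
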