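"""Parental-origin marker classification and introgressed-segment calling.

A congenic or selectively bred strain is a mosaic of two inbred parental
genomes. At an *informative* marker the two parents are homozygous for
different alleles, so the derived strain's homozygous genotype reveals
local parental origin. Donor-derived segments appear as runs of
donor-state markers; this module finds those runs with tolerance for
genotyping error and missingness, and intersects them across the
catalepsy-prone derived strains to produce the mapped locus.

Segment definition (made precise so a brute-force oracle can verify it):
an emitted segment is an inclusion-maximal pair (i, j) of informative
markers such that

* markers i and j are donor-state in the derived strain,
* every gap between consecutive informative markers inside [i, j] is
  <= ``max_gap_bp``,
* the discordant fraction over the whole run, recipient-state /
  (donor-state + recipient-state), is <= ``max_discordant_frac``,
* donor-state support is >= ``min_markers``.

Het or missing calls in the derived strain are ambiguous and skipped (not
discordant): the strains are inbred and residual hets are almost always
artifacts. The segment interval spans [first supporting marker,
last supporting marker] as a 0-based half-open interval.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import (
    GenomicInterval,
    Genotype,
    StrainPanel,
    VariantCall,
    chrom_sort_key,
)


class MarkerClass(enum.Enum):
    DONOR_SPECIFIC = "donor_specific"
    RECIPIENT_SPECIFIC = "recipient_specific"
    UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class Marker:
    """A classified variant; ``donor_state`` is the genotype a strain shows
    where its genome is donor-derived (HOM_ALT for donor-specific markers,
    HOM_REF for recipient-specific ones; None if uninformative)."""

    call: VariantCall
    mclass: MarkerClass
    donor_state: Genotype | None


@dataclass
class SegmentParams:
    min_markers: int = 25
    max_gap_bp: int = 500_000
    max_discordant_frac: float = 0.02


@dataclass
class IntrogressionSegment:
    strain: str
    interval: GenomicInterval
    n_support: int
    n_discordant: int
    marker_span: tuple[int, int]  # 1-based positions of first/last support


def classify_markers(
    calls: list[VariantCall], panel: StrainPanel
) -> list[Marker]:
    """Label every call by parental origin informativeness.

    donor_specific: donor parent hom_alt, recipient parent hom_ref;
    recipient_specific: the mirror; anything with het/missing in either
    parent, or identical parental states, is uninformative.
    """
    donor = panel.donor_parent.name
    recip = panel.recipient_parent.name
    out = []
    for c in calls:
        d = c.genotypes.get(donor, Genotype.MISSING)
        r = c.genotypes.get(recip, Genotype.MISSING)
        if d is Genotype.HOM_ALT and r is Genotype.HOM_REF:
            out.append(Marker(c, MarkerClass.DONOR_SPECIFIC, Genotype.HOM_ALT))
        elif d is Genotype.HOM_REF and r is Genotype.HOM_ALT:
            out.append(Marker(c, MarkerClass.RECIPIENT_SPECIFIC, Genotype.HOM_REF))
        else:
            out.append(Marker(c, MarkerClass.UNINFORMATIVE, None))
    return out


def derived_states(
    markers: list[Marker], derived_strain: str
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: (positions, is_donor) for non-ambiguous informative
    markers of one derived strain. Positions are 1-based, sorted."""
    per: dict[str, list[tuple[int, bool]]] = {}
    for m in markers:
        if m.mclass is MarkerClass.UNINFORMATIVE:
            continue
        g = m.call.genotypes.get(derived_strain, Genotype.MISSING)
        if g not in (Genotype.HOM_REF, Genotype.HOM_ALT):
            continue  # het/missing: ambiguous, skipped
        per.setdefault(m.call.chrom, []).append((m.call.pos, g is m.donor_state))
    out = {}
    for chrom, items in per.items():
        items.sort()
        pos = np.array([p for p, _ in items], dtype=np.int64)
        isd = np.array([d for _, d in items], dtype=bool)
        out[chrom] = (pos, isd)
    return out


def _segments_in_block(
    pos: np.ndarray, is_donor: np.ndarray, params: SegmentParams
) -> list[tuple[int, int]]:
    """Inclusion-maximal valid (i, j) index pairs within one gap-block.

    Validity of (i, j): endpoints donor-state, whole-run discordant
    fraction <= f, support >= min_markers (gaps already satisfied inside a
    block). Weights w = f for donor, f-1 for recipient turn the fraction
    constraint into prefix-sum nonnegativity: S[j+1] - S[i] >= 0.
    """
    f = params.max_discordant_frac
    n = len(pos)
    didx = np.flatnonzero(is_donor)
    if len(didx) == 0:
        return []
    w = np.where(is_donor, f, f - 1.0)
    S = np.concatenate([[0.0], np.cumsum(w)])
    D = np.concatenate([[0], np.cumsum(is_donor.astype(np.int64))])
    # S_donor[k] = S[didx[k]+1]; R[k] = max over k' >= k (non-increasing)
    S_donor = S[didx + 1]
    R = np.maximum.accumulate(S_donor[::-1])[::-1]
    out: list[tuple[int, int]] = []
    best_j = -1
    eps = 1e-9
    for k0, i in enumerate(didx):
        t = S[i] - eps
        # largest k >= k0 with R[k] >= t (R non-increasing)
        hi = np.searchsorted(-R, -t, side="right") - 1
        if hi < k0:
            continue
        j = int(didx[hi])
        if D[j + 1] - D[i] < params.min_markers:
            continue
        if j > best_j:
            out.append((int(i), j))
            best_j = j
    return out


def call_segments(
    markers: list[Marker],
    derived_strain: str,
    params: SegmentParams | None = None,
) -> list[IntrogressionSegment]:
    """Call donor-derived segments in one derived strain.

    Deterministic given the marker set; invariant to input order (markers
    are re-sorted per chromosome).
    """
    params = params or SegmentParams()
    segs: list[IntrogressionSegment] = []
    for chrom, (pos, isd) in sorted(
        derived_states(markers, derived_strain).items(),
        key=lambda kv: chrom_sort_key(kv[0]),
    ):
        if len(pos) == 0:
            continue
        # split into blocks where consecutive gaps <= max_gap_bp
        cut = np.flatnonzero(np.diff(pos) > params.max_gap_bp) + 1
        for blk_pos, blk_isd in zip(np.split(pos, cut), np.split(isd, cut)):
            for i, j in _segments_in_block(blk_pos, blk_isd, params):
                sup = int(blk_isd[i : j + 1].sum())
                disc = int(j - i + 1 - sup)
                segs.append(
                    IntrogressionSegment(
                        strain=derived_strain,
                        interval=GenomicInterval(
                            chrom, int(blk_pos[i]) - 1, int(blk_pos[j])
                        ),
                        n_support=sup,
                        n_discordant=disc,
                        marker_span=(int(blk_pos[i]), int(blk_pos[j])),
                    )
                )
    return segs


def _union(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda v: (chrom_sort_key(v.chrom), v.start)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged.pop()
            iv = GenomicInterval(iv.chrom, last.start, max(last.end, iv.end))
        merged.append(iv)
    return merged


def intersect_prone_segments(
    segments_by_strain: dict[str, list[IntrogressionSegment]],
    prone_strains: list[str],
) -> GenomicInterval:
    """Maximal interval contained in some segment of every prone derived
    strain (the mapped locus). Ties broken leftmost; empty intersection
    yields a zero-length interval with a warning."""
    if not prone_strains:
        raise ValueError("no prone derived strains given")
    for s in prone_strains:
        if s not in segments_by_strain:
            raise KeyError(f"strain {s!r} contributed no segments")
    common = _union([seg.interval for seg in segments_by_strain[prone_strains[0]]])
    for s in prone_strains[1:]:
        other = _union([seg.interval for seg in segments_by_strain[s]])
        new: list[GenomicInterval] = []
        for a in common:
            for b in other:
                x = a.intersect(b)
                if x is not None and len(x) > 0:
                    new.append(x)
        common = _union(new)
    if not common:
        warnings.warn("prone-strain segments have empty intersection")
        any_seg = next(iter(segments_by_strain.values()))
        chrom = any_seg[0].interval.chrom if any_seg else "NA"
        return GenomicInterval(chrom, 0, 0)
    return max(common, key=lambda iv: (len(iv), -iv.start))


# ---------------------------------------------------------------------------
# truth comparison helpers


def truth_boundary_error(
    detected: GenomicInterval, truth: GenomicInterval
) -> tuple[int, int]:
    """Signed bp errors (detected.start - truth.start, detected.end - truth.end)."""
    from .models import normalize_chrom

    if normalize_chrom(detected.chrom) != normalize_chrom(truth.chrom):
        raise ValueError(
            f"chromosome mismatch: {detected.chrom} vs {truth.chrom}"
        )
    return detected.start - truth.start, detected.end - truth.end


def boundary_marker_offset(
    detected: GenomicInterval,
    truth: GenomicInterval,
    informative_pos: np.ndarray,
) -> tuple[int, int]:
    """Boundary error in marker units: the number of informative markers
    strictly between each detected boundary and the corresponding truth
    boundary. A detected boundary is within k marker spacings of truth when
    this count is <= k; the bp distance is meaningless below the local
    marker resolution. ``informative_pos`` must be 0-based to match the
    interval coordinates."""
    pos = np.sort(np.asarray(informative_pos))

    def count_between(a: int, b: int) -> int:
        lo, hi = min(a, b), max(a, b)
        return int(np.searchsorted(pos, hi) - np.searchsorted(pos, lo, "right"))

    return (
        count_between(detected.start, truth.start),
        count_between(detected.end, truth.end),
    )
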