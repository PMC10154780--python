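"""End-to-end orchestration: simulate -> map-locus -> filter -> annotate -> homology.

Stages exchange plain files (VCF/TSV/JSON) so every intermediate is
inspectable; the machine-readable artifact of record is ``report.json``.
Reruns with the same config and inputs are byte-identical except for the
``timings_s`` block (wall-clock can never be stable; determinism is
defined over the report with timings excluded).
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__
from . import io as cio
from .consequence import (
    Impact,
    annotate_all,
    attach_scores,
    read_gene_models,
    read_score_table,
)
from .filters import (
    SvParams,
    match_sv_across_strains,
    recessive_filter,
    sv_specificity,
)
from .homology import (
    count_peak_overlaps,
    liftover_interval,
    read_associations,
    read_synteny,
    screen_associations,
)
from .introgression import (
    SegmentParams,
    call_segments,
    classify_markers,
    intersect_prone_segments,
)
from .models import GenomicInterval, normalize_chrom

log = logging.getLogger("congmap")


class _Forbid(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SegmentParamsCfg(_Forbid):
    min_markers: int = 25
    max_gap_bp: int = 500_000
    max_discordant_frac: float = 0.02

    def build(self) -> SegmentParams:
        return SegmentParams(self.min_markers, self.max_gap_bp, self.max_discordant_frac)


class SvParamsCfg(_Forbid):
    min_reciprocal_overlap: float = 0.8
    bnd_tolerance_bp: int = 50

    def build(self) -> SvParams:
        return SvParams(self.min_reciprocal_overlap, self.bnd_tolerance_bp)


class CausalCfg(_Forbid):
    gene_index: int = 0
    codon_position: int = 148
    ref_aa: str = "H"
    alt_aa: str = "R"


class SimulateCfg(_Forbid):
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
    causal: CausalCfg = CausalCfg()
    n_sv_specific: int = 3
    n_sv_background: int = 10
    n_synteny_blocks: int = 5
    n_peaks_inside: int = 76
    n_peaks_outside: int = 40
    n_dys_inside: int = 5
    n_assoc_inside: int = 12
    n_assoc_outside: int = 30


class InputPathsCfg(_Forbid):
    vcf: str
    sv_vcf: str | None = None
    panel: str
    gff3: str | None = None
    fasta: str | None = None
    synteny: str | None = None
    peaks: str | None = None
    assoc: str | None = None
    scores: str | None = None


class RunConfig(_Forbid):
    """Schema-validated configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    simulate: SimulateCfg | None = None
    inputs: InputPathsCfg | None = None
    segment_params: SegmentParamsCfg = SegmentParamsCfg()
    sv_params: SvParamsCfg = SvParamsCfg()
    peak_label: str = "dys"

    @model_validator(mode="after")
    def _one_source(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config needs exactly one of 'simulate' or 'inputs'")
        return self


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _iv_dict(iv: GenomicInterval) -> dict:
    return {"chrom": iv.chrom, "start": iv.start, "end": iv.end}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "congmap",
        "version": __version__,
        "seed": config.seed,
        "params": {
            "segment_params": config.segment_params.model_dump(),
            "sv_params": config.sv_params.model_dump(),
            "peak_label": config.peak_label,
        },
    }
    timings: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("[%s] start", name)
            try:
                result = fn()
            except Exception as exc:
                log.error("[%s] FAILED: %s", name, exc)
                raise StageError(name, exc) from exc
            timings[name] = round(time.perf_counter() - t0, 3)
            log.info("[%s] done in %.2fs", name, timings[name])
            return result

        return deco

    # --- inputs (optionally simulated) ------------------------------------
    if config.simulate is not None:

        @stage("simulate")
        def paths():
            from .simulate import CausalSpec, SimConfig, simulate_cross, write_artifacts

            sim_kwargs = config.simulate.model_dump()
            causal = sim_kwargs.pop("causal")
            sim = simulate_cross(
                SimConfig(**sim_kwargs, causal=CausalSpec(**causal), seed=config.seed)
            )
            return {k: str(v) for k, v in write_artifacts(sim, out / "sim").items()}

        inputs = InputPathsCfg(
            vcf=paths["vcf"],
            sv_vcf=paths["sv_vcf"],
            panel=paths["panel"],
            gff3=paths["gff3"],
            fasta=paths["fasta"],
            synteny=paths["synteny"],
            peaks=paths["peaks"],
            assoc=paths["assoc"],
        )
    else:
        inputs = config.inputs
        for name in ("vcf", "panel"):
            p = getattr(inputs, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"required input {name!r} missing: {p}")

    @stage("read")
    def loaded():
        panel = cio.read_panel(inputs.panel)
        calls = cio.read_variants(inputs.vcf, panel)
        svs = (
            cio.read_structural_variants(inputs.sv_vcf, panel)
            if inputs.sv_vcf
            else []
        )
        return panel, calls, svs

    panel, calls, svs = loaded
    report["n_variants"] = len(calls)
    report["n_svs"] = len(svs)

    @stage("map_locus")
    def locus_result():
        markers = classify_markers(calls, panel)
        n_inf = sum(1 for m in markers if m.donor_state is not None)
        params = config.segment_params.build()
        prone_derived = [
            e.name for e in panel.derived() if e in panel.prone()
        ]
        seg_by_strain = {
            s: call_segments(markers, s, params) for s in prone_derived
        }
        locus = intersect_prone_segments(seg_by_strain, prone_derived)
        return n_inf, seg_by_strain, locus

    n_informative, seg_by_strain, locus = locus_result
    report["n_informative_markers"] = n_informative
    report["segments"] = {
        s: [
            {
                "interval": _iv_dict(g.interval),
                "n_support": g.n_support,
                "n_discordant": g.n_discordant,
            }
            for g in segs
        ]
        for s, segs in seg_by_strain.items()
    }
    report["locus"] = _iv_dict(locus)
    locus_path = out / "locus.json"
    locus_path.write_text(
        json.dumps(
            {"locus": report["locus"], "segments": report["segments"]},
            indent=1,
            sort_keys=True,
        )
        + "\n"
    )

    @stage("filter")
    def filtered():
        in_locus = [c for c in calls if locus.contains_pos(c.chrom, c.pos0)]
        candidates = recessive_filter(calls, panel, locus)
        clusters = match_sv_across_strains(svs, config.sv_params.build()) if svs else []
        specific = sv_specificity(clusters, panel) if clusters else []
        return in_locus, candidates, clusters, specific

    in_locus, candidates, clusters, specific = filtered
    report["n_calls_in_locus"] = len(in_locus)
    report["n_candidates"] = len(candidates)
    report["n_sv_clusters"] = len(clusters)
    report["n_sv_specific"] = len(specific)
    report["specific_sv_ids"] = sorted(
        m.sv_id or "." for c in specific for m in c.members
    )

    missense = []
    if inputs.gff3 and inputs.fasta:

        @stage("annotate")
        def annotated():
            from Bio import SeqIO

            models = read_gene_models(inputs.gff3)
            seqs = {
                normalize_chrom(rec.id): str(rec.seq)
                for rec in SeqIO.parse(inputs.fasta, "fasta")
            }
            cons = annotate_all(candidates, models, seqs)
            if inputs.scores:
                attach_scores(cons, read_score_table(inputs.scores))
            return cons

        consequences = annotated
        by_impact: dict[str, int] = {}
        for c in consequences:
            by_impact[c.impact.value] = by_impact.get(c.impact.value, 0) + 1
        missense = [c for c in consequences if c.impact is Impact.MISSENSE]
        report["consequences_by_impact"] = dict(sorted(by_impact.items()))
        report["n_missense"] = len(missense)
        report["missense"] = [
            {
                "var_id": c.variant.var_id,
                "chrom": c.variant.chrom,
                "pos": c.variant.pos,
                "gene_id": c.gene_id,
                "protein_change": c.protein_change,
                "sift": None if c.sift is None else {"score": c.sift.score, "label": c.sift.label},
            }
            for c in missense
        ]
        with open(out / "candidates.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talt\tvar_id\tconsequence\tprotein_change\n")
            cons_by_var = {(id(c.variant)): c for c in consequences}
            for v in candidates:
                c = cons_by_var.get(id(v))
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.var_id or '.'}\t"
                    f"{c.impact.value if c else '.'}\t{c.protein_change if c else ''}\n"
                )

    if inputs.synteny:

        @stage("homology")
        def homology_result():
            blocks = read_synteny(inputs.synteny)
            pieces, hull, coverage = liftover_interval(locus, blocks)
            peaks_counts = None
            if inputs.peaks and hull is not None:
                peaks = cio.read_intervals(inputs.peaks)
                peaks_counts = count_peak_overlaps(hull, peaks, config.peak_label)
            assoc_hits = None
            if inputs.assoc and hull is not None:
                assoc_hits = screen_associations(hull, read_associations(inputs.assoc))
            return pieces, hull, coverage, peaks_counts, assoc_hits

        pieces, hull, coverage, peaks_counts, assoc_hits = homology_result
        report["lifted"] = {
            "pieces": [_iv_dict(p) for p in pieces],
            "hull": None if hull is None else _iv_dict(hull),
            "coverage_frac": round(coverage, 6),
        }
        if peaks_counts is not None:
            report["peaks_in_locus"] = peaks_counts[0]
            report["peaks_labeled_in_locus"] = peaks_counts[1]
        if assoc_hits is not None:
            report["n_assoc_hits"] = len(assoc_hits)
        (out / "homology.json").write_text(
            json.dumps(report["lifted"], indent=1, sort_keys=True) + "\n"
        )

    # --- consistency invariants -------------------------------------------
    assert report["n_candidates"] <= report["n_calls_in_locus"]
    if "n_missense" in report:
        assert report["n_missense"] <= report["n_candidates"]

    report["timings_s"] = timings
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report


def report_without_timings(report: dict) -> dict:
    return {k: v for k, v in report.items() if k != "timings_s"}


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if verbose else logging.WARNING)
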