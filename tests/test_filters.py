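"""Recessive filter, SV clustering/specificity, segregation scoring."""

import numpy as np
import pytest

from _oracles import brute_recessive, sv_closure
from conftest import random_calls
from congmap.filters import (
    SvParams,
    match_sv_across_strains,
    reciprocal_overlap,
    recessive_filter,
    segregation_scan,
    sv_specificity,
    read_presence_table,
)
from congmap.models import (
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

HR, HE, HA, MI = Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT, Genotype.MISSING


def _call(gts, pos=1_500_000):
    names = ["CBA", "AKR", "HT76", "ASC"]
    return VariantCall("13", pos, "T", "C", dict(zip(names, gts)))


def test_table2_pattern_is_retained(panel4, toy_locus):
    # all prone hom_alt, resistant hom_ref -> candidate
    kept = recessive_filter([_call([HA, HR, HA, HA])], panel4, toy_locus)
    assert len(kept) == 1


@pytest.mark.parametrize(
    "gts",
    [
        [HA, HR, HE, HA],  # prone het
        [HA, HA, HA, HA],  # resistant carries allele
        [HA, MI, HA, HA],  # resistant missing: absence unproven
        [MI, HR, HA, HA],  # prone missing
        [HA, HE, HA, HA],  # resistant het
    ],
)
def test_non_recessive_patterns_are_excluded(panel4, toy_locus, gts):
    assert recessive_filter([_call(gts)], panel4, toy_locus) == []


def test_variant_outside_locus_excluded(panel4, toy_locus):
    assert recessive_filter([_call([HA, HR, HA, HA], pos=5_000_000)], panel4, toy_locus) == []


def test_recessive_filter_equals_bruteforce_set_intersection(panel4, toy_locus):
    rng = np.random.default_rng(17)
    calls = random_calls(rng, 5000, panel4.names, span=3_000_000)
    got = recessive_filter(calls, panel4, toy_locus)
    exp = brute_recessive(calls, panel4, toy_locus)
    assert got == exp
    # idempotent and a subset of input
    assert recessive_filter(got, panel4, toy_locus) == got


def test_adding_a_strain_never_grows_the_candidate_set(toy_locus):
    rng = np.random.default_rng(23)
    base = StrainPanel(
        [
            StrainEntry("CBA", Phenotype.PRONE, Role.DONOR_PARENT),
            StrainEntry("AKR", Phenotype.RESISTANT, Role.RECIPIENT_PARENT),
            StrainEntry("HT76", Phenotype.PRONE, Role.DERIVED),
        ]
    )
    bigger = StrainPanel(base.entries + [StrainEntry("ASC", Phenotype.PRONE, Role.DERIVED)])
    calls = random_calls(rng, 3000, ["CBA", "AKR", "HT76", "ASC"], span=3_000_000)
    small = {c.var_id for c in recessive_filter(calls, base, toy_locus)}
    large = {c.var_id for c in recessive_filter(calls, bigger, toy_locus)}
    assert large <= small


def test_no_prone_or_resistant_strain_is_fatal(toy_locus):
    panel = StrainPanel(
        [
            StrainEntry("A", Phenotype.PRONE, Role.DONOR_PARENT),
            StrainEntry("B", Phenotype.PRONE, Role.DERIVED),
        ]
    )
    with pytest.raises(ValueError, match="prone and resistant"):
        recessive_filter([], panel, toy_locus)


# ---------------------------------------------------------------------------
# structural variants


def _sv(start, end, svtype=SvType.DEL, gts=None, chrom="13"):
    names = ["CBA", "AKR", "HT76", "ASC"]
    gts = gts or [HA, HR, HA, HA]
    return StructuralVariant(chrom, start, end, svtype, dict(zip(names, gts)))


def test_identical_deletions_cluster_together():
    clusters = match_sv_across_strains([_sv(100, 200), _sv(100, 200)])
    assert len(clusters) == 1


def test_low_reciprocal_overlap_stays_separate():
    a, b = _sv(100, 200), _sv(190, 300)
    # min(overlap/len_a, overlap/len_b) = min(10/100, 10/110)
    assert reciprocal_overlap(a, b) == pytest.approx(10 / 110)
    assert len(match_sv_across_strains([a, b])) == 2


def test_different_svtypes_never_cluster():
    assert len(match_sv_across_strains([_sv(100, 200, SvType.DEL), _sv(100, 200, SvType.DUP)])) == 2


def test_insertions_cluster_by_breakpoint_distance():
    a = _sv(1000, 1001, SvType.INS)
    b = _sv(1040, 1041, SvType.INS)
    c = _sv(1200, 1201, SvType.INS)
    clusters = match_sv_across_strains([a, b, c], SvParams(bnd_tolerance_bp=50))
    sizes = sorted(len(cl.members) for cl in clusters)
    assert sizes == [1, 2]


def test_clustering_equals_allpairs_transitive_closure():
    rng = np.random.default_rng(31)
    params = SvParams()
    for trial in range(20):
        svs = []
        for _ in range(int(rng.integers(10, 120))):
            s = int(rng.integers(0, 500_000))
            ln = int(rng.integers(50, 20_000))
            t = [SvType.DEL, SvType.DUP, SvType.INV, SvType.INS][int(rng.integers(0, 4))]
            gts = [[HR, HA][int(x)] for x in rng.integers(0, 2, 4)]
            svs.append(_sv(s, s + ln, t, gts))
        got = match_sv_across_strains(svs, params)
        got_sets = {frozenset(id(m) for m in c.members) for c in got}
        exp = sv_closure(svs, params)
        exp_sets = {frozenset(id(svs[i]) for i in comp) for comp in exp}
        assert got_sets == exp_sets, f"trial {trial}"


def test_clustering_invariant_to_input_order():
    rng = np.random.default_rng(8)
    svs = [
        _sv(int(s), int(s) + int(l), SvType.DEL)
        for s, l in zip(rng.integers(0, 100_000, 40), rng.integers(100, 5000, 40))
    ]
    a = match_sv_across_strains(svs)
    b = match_sv_across_strains(list(reversed(svs)))
    key = lambda cl: sorted((m.start, m.end) for m in cl.members)
    assert sorted(map(key, a)) == sorted(map(key, b))


def test_sv_specificity_requires_all_prone_and_no_resistant(panel4):
    spec = _sv(100, 5000, SvType.DEL, [HA, HR, HA, HA])
    in_resistant = _sv(50_000, 60_000, SvType.DEL, [HA, HA, HA, HA])
    partial = _sv(100_000, 110_000, SvType.DEL, [HA, HR, HR, HA])
    clusters = match_sv_across_strains([spec, in_resistant, partial])
    kept = sv_specificity(clusters, panel4)
    assert len(kept) == 1
    assert kept[0].members[0].start == 100


def test_planted_specific_svs_recovered_exactly(sim_noise_free, panel4):
    sim = sim_noise_free
    clusters = match_sv_across_strains(sim.svs)
    kept = sv_specificity(clusters, sim.panel)
    got = sorted(m.sv_id for c in kept for m in c.members)
    assert got == sorted(sim.truth.expected_specific_sv_ids)


# ---------------------------------------------------------------------------
# segregation


PHEN = {
    "CBA": Phenotype.PRONE, "D13Mit76C": Phenotype.PRONE, "ASC": Phenotype.PRONE,
    "C3H/HeJ": Phenotype.PRONE, "A/He": Phenotype.PRONE, "BALB/cJ": Phenotype.PRONE,
    "AKR/J": Phenotype.RESISTANT, "C57BL/6J": Phenotype.RESISTANT,
    "DBA/1J": Phenotype.RESISTANT,
}


def _cand(var_id, pos):
    return VariantCall("13", pos, "T", "C", {}, var_id=var_id)


def test_fully_concordant_candidate_has_no_violations():
    presence = {"rs1": {s: p is Phenotype.PRONE for s, p in PHEN.items()}}
    (res,) = segregation_scan([_cand("rs1", 104_069_202)], presence, PHEN)
    assert res.fully_concordant
    assert res.n_consistent == len(PHEN)


def test_allele_absent_in_two_prone_strains_yields_those_violations():
    row = {s: p is Phenotype.PRONE for s, p in PHEN.items()}
    row["A/He"] = False
    row["BALB/cJ"] = False
    presence = {"rs2": row}
    (res,) = segregation_scan([_cand("rs2", 104_111_134)], presence, PHEN)
    assert sorted(s for s, _, _ in res.violations) == ["A/He", "BALB/cJ"]
    assert not res.fully_concordant


def test_allele_present_everywhere_violates_all_resistant_strains():
    presence = {"rs3": {s: True for s in PHEN}}
    (res,) = segregation_scan([_cand("rs3", 1)], presence, PHEN)
    assert sorted(s for s, _, _ in res.violations) == sorted(
        s for s, p in PHEN.items() if p is Phenotype.RESISTANT
    )


def test_results_sorted_by_violations_then_position():
    concordant = {s: p is Phenotype.PRONE for s, p in PHEN.items()}
    bad = {s: True for s in PHEN}
    presence = {"a": bad, "b": concordant}
    res = segregation_scan([_cand("a", 10), _cand("b", 20)], presence, PHEN)
    assert [r.variant.var_id for r in res] == ["b", "a"]


def test_strain_without_phenotype_is_fatal():
    presence = {"x": {"UNKNOWN": True}}
    with pytest.raises(ValueError, match="UNKNOWN"):
        segregation_scan([_cand("x", 1)], presence, {})


def test_presence_table_parsing(tmp_path):
    p = tmp_path / "presence.tsv"
    p.write_text("var_id\tCBA\tAKR\nrs1\t1\t0\nrs2\t0\t1\n")
    table = read_presence_table(p)
    assert table == {
        "rs1": {"CBA": True, "AKR": False},
        "rs2": {"CBA": False, "AKR": True},
    }
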