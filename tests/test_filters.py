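"""Filter predicates: boundary behavior, trio inheritance truth table, composition."""

from __future__ import annotations

from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_case, make_record
from varprio.filters import (FilterConfig, apply_filters, baseline_filtration,
                             annotate_compound_het, call_zygosity,
                             classify_variant_type, infer_inheritance, maf_filter,
                             membership_filters, predictor_filter,
                             splice_region_filter)
from varprio.vcf_io import PREDICTOR_TOOLS

TRIO = {"proband": "proband", "mother": "mother", "father": "father"}
SINGLETON = {"proband": "proband"}


# ---------------------------------------------------------------------------
# defaults and classification

def test_default_config_values():
    cfg = FilterConfig()
    assert cfg.splice_distance == 10
    assert cfg.splice_z_min == 1.8
    assert cfg.predictor_tools == set(PREDICTOR_TOOLS)


def test_config_yaml_round_trip(tmp_path):
    path = tmp_path / "filters.yaml"
    path.write_text("maf_max: 0.01\npanel: [BRCA1, RAF1]\nsplice_distance: 5\n")
    cfg = FilterConfig.from_yaml(path)
    assert cfg.maf_max == 0.01
    assert cfg.panel == {"BRCA1", "RAF1"}
    assert cfg.splice_distance == 5


@pytest.mark.parametrize("func,expected", [
    ("stopgain", "stopgain"),
    ("nonsynonymous SNV", "missense"),
    ("synonymous SNV", "synonymous"),
    ("weird_new_class", "unknown"),
    ("", "unknown"),
])
def test_classify_variant_type(annotation_factory, func, expected):
    assert classify_variant_type(annotation_factory(functional_class=func)) == expected


# ---------------------------------------------------------------------------
# baseline filtration

def test_baseline_keeps_coding_drops_synonymous_and_deep_intronic(record_factory):
    missense = record_factory(pos=1, functional_class="nonsynonymous SNV")
    synonymous = record_factory(pos=2, functional_class="synonymous SNV")
    deep_intronic = record_factory(pos=3, functional_class="intronic",
                                   exon_boundary_distance=500)
    splice_ok = record_factory(pos=4, functional_class="splicing",
                               exon_boundary_distance=5, splice_z=-2.0)
    kept = baseline_filtration([missense, synonymous, deep_intronic, splice_ok])
    assert [r.key.pos for r in kept] == [1, 4]


@pytest.mark.parametrize("dist,z,expected", [
    (5, -2.0, True),    # within distance, |z| above threshold
    (11, 3.0, False),   # one base past the default distance 10
    (10, 3.0, True),    # inclusive on distance
    (5, 1.8, False),    # strict on |z|
    (5, None, False),   # missing z never kept
])
def test_splice_region_filter_boundaries(annotation_factory, dist, z, expected):
    ann = annotation_factory(functional_class="splicing",
                             exon_boundary_distance=dist, splice_z=z)
    assert splice_region_filter(ann, FilterConfig()) is expected


# ---------------------------------------------------------------------------
# zygosity

def test_zygosity_calls(record_factory):
    het = record_factory(gts={"proband": (0, 1)})
    hom = record_factory(gts={"proband": (1, 1)})
    missing = record_factory(gts={"proband": None})
    assert call_zygosity(het, SINGLETON, "female").value == "heterozygous"
    assert call_zygosity(hom, SINGLETON, "female").value == "homozygous"
    assert call_zygosity(missing, SINGLETON, "female").value == "missing"


def test_male_nonpar_x_single_alt_is_hemizygous(record_factory):
    x_var = record_factory(chrom="X", pos=50_000_000, gts={"proband": (0, 1)})
    assert call_zygosity(x_var, SINGLETON, "male").value == "hemizygous"
    assert call_zygosity(x_var, SINGLETON, "female").value == "heterozygous"
    # pseudo-autosomal X is treated as autosomal
    par_var = record_factory(chrom="X", pos=20_000, gts={"proband": (0, 1)})
    assert call_zygosity(par_var, SINGLETON, "male", build="hg38").value == "heterozygous"


def test_gene_compound_het_flag_requires_two_hets(record_factory):
    a = record_factory(pos=1, gene="G1", gts={"proband": (0, 1)})
    b = record_factory(pos=2, gene="G1", gts={"proband": (0, 1)})
    c = record_factory(pos=3, gene="G2", gts={"proband": (0, 1)})
    calls = annotate_compound_het([a, b, c], SINGLETON, "female")
    assert calls[id(a)].gene_compound_het and calls[id(b)].gene_compound_het
    assert not calls[id(c)].gene_compound_het


# ---------------------------------------------------------------------------
# trio inheritance vs exhaustive truth-table oracle

GT_STATES = ((0, 0), (0, 1), (1, 1))


def oracle_modes(pro, mom, dad):
    """Independent encoding of the written trio rules for an autosomal site."""
    modes = set()
    n = lambda gt: sum(gt)
    if n(pro) == 0:
        return modes
    if n(mom) == 0 and n(dad) == 0:
        modes.add("de_novo")
    if n(pro) == 1 and (n(mom) == 1) != (n(dad) == 1):
        modes.add("autosomal_dominant")
    if n(pro) == 2 and n(mom) == 1 and n(dad) == 1:
        modes.add("autosomal_recessive")
    return modes


def test_trio_inheritance_matches_27_combination_oracle(record_factory):
    for pro, mom, dad in product(GT_STATES, repeat=3):
        rec = record_factory(gts={"proband": pro, "mother": mom, "father": dad})
        got = infer_inheritance(rec, [rec], TRIO, "female")
        got.discard("compound_het_in_trans")  # gene-level mode, tested separately
        assert got == oracle_modes(pro, mom, dad), (pro, mom, dad)


def test_male_x_inheritance_matches_9_combination_oracle(record_factory):
    for mom, dad in product(GT_STATES, repeat=2):
        # male proband carrying one alt on non-PAR X
        rec = record_factory(chrom="X", pos=50_000_000,
                             gts={"proband": (0, 1), "mother": mom, "father": dad})
        got = infer_inheritance(rec, [rec], TRIO, "male")
        expected = set()
        if sum(mom) == 0 and sum(dad) == 0:
            expected.add("de_novo")
        if sum(mom) >= 1:
            expected.add("x_linked")
        assert got == expected, (mom, dad)


def test_singleton_inheritance_is_empty(record_factory):
    rec = record_factory(gts={"proband": (0, 1)})
    assert infer_inheritance(rec, [rec], SINGLETON, "female") == set()


def test_compound_het_in_trans_requires_one_variant_from_each_parent(record_factory):
    maternal = record_factory(pos=1, gene="G1",
                              gts={"proband": (0, 1), "mother": (0, 1), "father": (0, 0)})
    paternal = record_factory(pos=2, gene="G1",
                              gts={"proband": (0, 1), "mother": (0, 0), "father": (0, 1)})
    gene = [maternal, paternal]
    assert "compound_het_in_trans" in infer_inheritance(maternal, gene, TRIO, "female")
    # both from the same parent: in cis, not in trans
    cis = [maternal,
           record_factory(pos=3, gene="G1",
                          gts={"proband": (0, 1), "mother": (0, 1), "father": (0, 0)})]
    assert "compound_het_in_trans" not in infer_inheritance(cis[0], cis, TRIO, "female")


# ---------------------------------------------------------------------------
# predictor / MAF / membership predicates

@pytest.mark.parametrize("scores,threshold,expected", [
    ({"sift": 0.2, "cadd": 0.9}, 0.5, True),
    ({t: None for t in PREDICTOR_TOOLS}, 0.5, True),  # absent evidence never removes
    ({"sift": 0.5}, 0.5, False),  # strict inequality
])
def test_predictor_filter(annotation_factory, scores, threshold, expected):
    full = {t: None for t in PREDICTOR_TOOLS}
    full.update(scores)
    ann = annotation_factory(predictor_scores=full)
    cfg = FilterConfig(predictor_threshold=threshold)
    assert predictor_filter(ann, cfg) is expected


@pytest.mark.parametrize("afs,maf_max,expected", [
    ({"afr": 0.0001, "nfe": 0.02}, 0.01, False),
    ({}, 0.01, True),  # all missing kept
    ({"nfe": 0.01}, 0.01, True),  # ceiling is inclusive
])
def test_maf_filter(annotation_factory, afs, maf_max, expected):
    ann = annotation_factory(pop_afs=afs)
    assert maf_filter(ann, FilterConfig(maf_max=maf_max)) is expected


def test_membership_filters(record_factory):
    rec = record_factory(gene="RAF1", clinvar_class="pathogenic")
    assert membership_filters(rec, FilterConfig(clinvar_classes={"pathogenic"}))
    assert not membership_filters(rec, FilterConfig(clinvar_classes={"benign"}))
    assert not membership_filters(rec, FilterConfig(require_omim=True), omim_genes={"BRCA1"})
    assert membership_filters(rec, FilterConfig(require_omim=True), omim_genes={"RAF1"})
    assert not membership_filters(rec, FilterConfig(panel={"BRCA1"}))
    absent = record_factory(clinvar_class="absent")
    assert not membership_filters(absent, FilterConfig(clinvar_classes={"pathogenic"}))


# ---------------------------------------------------------------------------
# composition

def _all_missense_case(case_factory, record_factory, n=6):
    records = [record_factory(pos=100 + i, gene=f"G{i % 3}",
                              pop_afs={"nfe": 0.001 * i},
                              predictor_scores={t: 0.1 * (i + 1) for t in PREDICTOR_TOOLS})
               for i in range(n)]
    return case_factory(records)


def test_apply_filters_identity_when_nothing_enabled(case_factory, record_factory):
    case = _all_missense_case(case_factory, record_factory)
    kept, counts = apply_filters(case, FilterConfig())
    assert kept == case.variants
    assert counts["baseline"] == 0


def test_apply_filters_counts_are_consistent(case_factory, record_factory):
    case = _all_missense_case(case_factory, record_factory)
    cfg = FilterConfig(maf_max=0.002, predictor_threshold=0.35)
    kept, counts = apply_filters(case, cfg)
    assert len(kept) <= len(case.variants)
    # every removal is logged under at least one filter
    assert sum(counts.values()) >= len(case.variants) - len(kept)
    # conjunction semantics: each kept record passes each individual predicate
    for v in kept:
        assert maf_filter(v.annotation, cfg)
        assert predictor_filter(v.annotation, cfg)


def test_apply_filters_is_idempotent_and_monotone(case_factory, record_factory):
    case = _all_missense_case(case_factory, record_factory)
    cfg = FilterConfig(maf_max=0.003)
    kept, _ = apply_filters(case, cfg)
    again, _ = apply_filters(case_factory(kept), cfg)
    assert again == kept
    stricter, _ = apply_filters(case, FilterConfig(maf_max=0.001))
    assert set(id(v) for v in stricter) <= set(id(v) for v in kept)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(maf_max=st.floats(min_value=0.0, max_value=0.05),
       threshold=st.one_of(st.none(), st.floats(min_value=0.0, max_value=1.0)))
def test_enabling_extra_filter_never_grows_kept_set(maf_max, threshold):
    """Adding a knob to a config is monotone: the kept set can only shrink."""
    case = _all_missense_case(make_case, make_record, n=8)
    base_kept, _ = apply_filters(case, FilterConfig(maf_max=maf_max))
    extra_kept, _ = apply_filters(case, FilterConfig(maf_max=maf_max,
                                                     predictor_threshold=threshold))
    assert set(id(v) for v in extra_kept) <= set(id(v) for v in base_kept)
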