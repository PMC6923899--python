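"""Shared fixtures: toy ontology, record factories, and a small synthetic cohort."""

from __future__ import annotations

import networkx as nx
import pytest

from varprio.phenotype import InteractomeGraph, PhenotypeResources
from varprio.synthetic import CohortSpec, generate_cohort, generate_external_ranks
from varprio.vcf_io import (PREDICTOR_TOOLS, AnnotationRecord, CaseInput,
                            GenotypeCall, VariantKey, VariantRecord)


def make_annotation(**overrides) -> AnnotationRecord:
    base = dict(
        gene="GENE1", functional_class="nonsynonymous SNV",
        exon_boundary_distance=0, splice_z=None,
        pop_afs={"nfe": 0.0001}, predictor_scores={t: 0.7 for t in PREDICTOR_TOOLS},
        conservation=1.2, clinvar_class="absent",
    )
    base.update(overrides)
    return AnnotationRecord(**base)


def make_record(chrom="1", pos=1000, ref="A", alt="G", gts=None, **ann_overrides) -> VariantRecord:
    gts = gts or {"proband": (0, 1)}
    return VariantRecord(
        key=VariantKey(chrom, pos, ref, alt),
        annotation=make_annotation(**ann_overrides),
        genotypes=[GenotypeCall(sid, alleles) for sid, alleles in gts.items()],
        annotated=True,
    )


def make_case(records, hpo={"HP:0000010"}, trio=False, sex="female", case_id="case") -> CaseInput:
    pedigree = ({"proband": "proband", "mother": "mother", "father": "father"}
                if trio else {"proband": "proband"})
    return CaseInput(variants=list(records), hpo_terms=set(hpo), pedigree=pedigree,
                     proband_sex=sex, case_id=case_id)


@pytest.fixture
def annotation_factory():
    return make_annotation


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def case_factory():
    return make_case


@pytest.fixture
def toy_resources() -> PhenotypeResources:
    """Five-term chain-plus-branch ontology with hand-assigned information content.

        HP:0000001 (root, IC 0)
         ├── HP:0000002 (IC 1)
         │    ├── HP:0000003 (IC 2)
         │    └── HP:0000004 (IC 2.5)
         └── HP:0000005 (IC 1.5)

    GENE_A: disease DA with terms {3, 4}; GENE_B: disease DB with term {5}.
    GENE_NONE has no disease annotation.
    """
    dag = nx.DiGraph()
    edges = [("HP:0000002", "HP:0000001"), ("HP:0000003", "HP:0000002"),
             ("HP:0000004", "HP:0000002"), ("HP:0000005", "HP:0000001")]
    dag.add_edges_from(edges)
    ic = {"HP:0000001": 0.0, "HP:0000002": 1.0, "HP:0000003": 2.0,
          "HP:0000004": 2.5, "HP:0000005": 1.5}
    return PhenotypeResources(
        ontology=dag,
        gene_to_diseases={"GENE_A": {"DA"}, "GENE_B": {"DB"}},
        disease_to_terms={"DA": {"HP:0000003", "HP:0000004"}, "DB": {"HP:0000005"}},
        term_ic=ic,
    )


@pytest.fixture
def toy_interactome() -> InteractomeGraph:
    return InteractomeGraph.from_edges([("GENE_A", "GENE_B", 1.0),
                                        ("GENE_B", "GENE_C", 0.4)])


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort shared across tests (6 cases, 40 genes, ~60 variants/case)."""
    spec = CohortSpec(n_cases=6, n_genes=40, variants_per_case=60,
                      causal_effect=1.5, phenotype_noise=0.2, trio_fraction=0.5, seed=2)
    cohort = generate_cohort(spec)
    ranks = generate_external_ranks(cohort, noise=0.5, seed=2)
    return cohort, ranks
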