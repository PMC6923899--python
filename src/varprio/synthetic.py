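"""Self-contained synthetic cohorts: ontology, disease annotations, interactome,
annotated variant tables with one planted causal gene per case, noisy patient
phenotypes, reference-ranker files and a fixture knowledge base.

The generator emulates a rare-disease exome cohort: each case carries a large
background of mostly benign coding variants plus one causal SNV whose feature
distribution is shifted toward pathogenicity by ``causal_effect`` standard
deviations, and whose gene's disease terms (noised by ``phenotype_noise``)
supply the patient's phenotype. At ``causal_effect = 0`` the causal variant's
continuous features are drawn from exactly the background distributions, which
makes the planted signal a clean experimental dial.

Everything is deterministic under the spec seed, including the emitted files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .knowledge_base import EvidenceRelation
from .phenotype import InteractomeGraph, PhenotypeResources
from .ranker import ExternalRankRecord
from .vcf_io import (PREDICTOR_TOOLS, AnnotationRecord, CaseInput, GenotypeCall,
                     VariantKey, VariantRecord)

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "Cohort",
    "generate_resources",
    "generate_case",
    "generate_cohort",
    "generate_external_ranks",
    "generate_fixture_kb",
    "write_cohort",
]

POPULATIONS = ("afr", "eas", "nfe")
_BG_BETA = (2.0, 5.0)  # background predictor-score shape
_BG_SCORE_SD = math.sqrt(_BG_BETA[0] * _BG_BETA[1]
                         / ((sum(_BG_BETA)) ** 2 * (sum(_BG_BETA) + 1.0)))
_FUNC_CLASSES = ("nonsynonymous SNV", "synonymous SNV", "stopgain",
                 "frameshift insertion", "splicing", "ncRNA_exonic", "intronic")
_FUNC_WEIGHTS = (0.55, 0.18, 0.04, 0.04, 0.07, 0.06, 0.06)
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a synthetic cohort (all defaults are the study defaults)."""

    n_cases: int = 50
    n_genes: int = 300
    variants_per_case: int = 1200  # Poisson mean
    causal_effect: float = 1.5  # feature shift in background-SD units
    phenotype_noise: float = 0.2  # fraction of patient terms drawn off-disease
    trio_fraction: float = 0.5
    seed: int = 0
    n_terms: int = 200
    n_patient_terms: int = 6

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_genes < 1 or self.variants_per_case < 1:
            raise ValueError("cohort sizes must be positive")
        if self.causal_effect < 0:
            raise ValueError("causal_effect must be >= 0")
        if not 0.0 <= self.phenotype_noise <= 1.0:
            raise ValueError("phenotype_noise must lie in [0,1]")
        if not 0.0 <= self.trio_fraction <= 1.0:
            raise ValueError("trio_fraction must lie in [0,1]")


@dataclass(frozen=True)
class GroundTruth:
    case_id: str
    causal_gene: str
    causal_key: VariantKey
    inheritance_mode: Optional[str]  # None for singleton cases


@dataclass
class SyntheticResources:
    phenotype: PhenotypeResources
    interactome: InteractomeGraph
    omim_genes: set[str]
    panels: dict[str, set[str]]
    gene_locations: dict[str, tuple[str, int]]  # gene -> (chrom, start)
    disease_category: dict[str, str]


@dataclass
class Cohort:
    spec: CohortSpec
    resources: SyntheticResources
    cases: list[CaseInput]
    truth: dict[str, GroundTruth]

    @property
    def causal_truth(self) -> dict[str, tuple[str, VariantKey]]:
        return {cid: (t.causal_gene, t.causal_key) for cid, t in self.truth.items()}


# ---------------------------------------------------------------------------
# Resources

def _term_id(i: int) -> str:
    return f"HP:{i:07d}"


def generate_resources(spec: CohortSpec) -> SyntheticResources:
    """Random DAG ontology, disease annotations, scale-free interactome, gene lists.

    The ontology has ``n_terms`` terms and depth >= 4 (the first five terms form
    a chain under the root; later terms attach to 1-2 earlier terms). Each gene
    is annotated to 1-3 diseases of 3-8 terms each.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_terms
    dag = nx.DiGraph()
    dag.add_node(_term_id(1))
    for i in range(2, n + 1):
        term = _term_id(i)
        if i <= 6:
            parents = [_term_id(i - 1)]  # guarantees depth >= 5
        else:
            k = 1 + int(rng.random() < 0.3)
            parents = [_term_id(int(j)) for j in
                       rng.choice(np.arange(1, i), size=min(k, i - 1), replace=False)]
        for p in parents:
            dag.add_edge(term, p)

    genes = [f"GENE{i:04d}" for i in range(1, spec.n_genes + 1)]
    usable_terms = [_term_id(i) for i in range(7, n + 1)]  # skip the root chain
    gene_to_diseases: dict[str, set[str]] = {}
    disease_to_terms: dict[str, set[str]] = {}
    disease_category: dict[str, str] = {}
    d_idx = 0
    for gene in genes:
        n_dis = int(rng.integers(1, 4))
        gene_to_diseases[gene] = set()
        for _ in range(n_dis):
            d_idx += 1
            disease = f"D{d_idx:05d}"
            n_t = int(rng.integers(3, 9))
            terms = rng.choice(usable_terms, size=n_t, replace=False)
            disease_to_terms[disease] = set(str(t) for t in terms)
            gene_to_diseases[gene].add(disease)
            disease_category[disease] = f"category_{1 + d_idx % 5}"

    phen = PhenotypeResources(ontology=dag, gene_to_diseases=gene_to_diseases,
                              disease_to_terms=disease_to_terms)

    m = max(1, min(2, spec.n_genes - 1))
    ba = nx.barabasi_albert_graph(spec.n_genes, m, seed=int(rng.integers(0, 2**31)))
    ppi = nx.Graph()
    for u, v in sorted(ba.edges()):
        ppi.add_edge(genes[u], genes[v], weight=float(np.round(rng.uniform(0.3, 1.0), 4)))
    interactome = InteractomeGraph(ppi)

    omim = {g for g in genes if rng.random() < 0.7}
    panels = {f"panel_{i}": set(str(g) for g in rng.choice(genes, size=min(20, spec.n_genes),
                                                           replace=False))
              for i in range(1, 3)}

    chroms = [str(c) for c in range(1, 23)] + ["X"]
    gene_locations = {}
    for i, gene in enumerate(genes):
        chrom = chroms[i % len(chroms)]
        start = 100_000 + (i // len(chroms)) * 1_000_000
        gene_locations[gene] = (chrom, start)

    return SyntheticResources(phenotype=phen, interactome=interactome,
                              omim_genes=omim, panels=panels,
                              gene_locations=gene_locations,
                              disease_category=disease_category)


# ---------------------------------------------------------------------------
# Cases

def _draw_background_annotation(rng: np.random.Generator, gene: str) -> AnnotationRecord:
    func = str(rng.choice(_FUNC_CLASSES, p=_FUNC_WEIGHTS))
    splicing = func == "splicing"
    exon_dist = int(rng.integers(1, 30)) if splicing or func == "intronic" else 0
    scores = {}
    for tool in PREDICTOR_TOOLS:
        scores[tool] = float(np.round(rng.beta(*_BG_BETA), 6)) if rng.random() < 0.8 else None
    if rng.random() < 0.7:
        base_af = float(rng.uniform(0.01, 0.2))
    else:
        base_af = float(rng.uniform(0.0, 0.001))
    afs = {p: float(np.round(min(1.0, base_af * rng.uniform(0.5, 1.5)), 6))
           for p in POPULATIONS}
    r = rng.random()
    clinvar = "absent" if r < 0.90 else "unknown" if r < 0.95 else \
        "benign" if r < 0.98 else "pathogenic"
    return AnnotationRecord(
        gene=gene, functional_class=func, exon_boundary_distance=exon_dist,
        splice_z=float(np.round(rng.normal(0.0, 2.0), 4)) if splicing else None,
        pop_afs=afs, predictor_scores=scores,
        conservation=float(np.round(rng.normal(0.0, 1.0), 4)),
        clinvar_class=clinvar)


def _draw_causal_annotation(rng: np.random.Generator, gene: str,
                            effect: float) -> AnnotationRecord:
    # background distributions shifted by `effect` background-SDs; at effect 0
    # this coincides exactly with the background draw
    scores = {}
    for tool in PREDICTOR_TOOLS:
        if rng.random() < 0.8:
            scores[tool] = float(np.round(min(1.0, rng.beta(*_BG_BETA)
                                              + effect * _BG_SCORE_SD), 6))
        else:
            scores[tool] = None
    if rng.random() < 0.7:
        base_af = float(rng.uniform(0.01, 0.2))
    else:
        base_af = float(rng.uniform(0.0, 0.001))
    base_af *= math.exp(-2.0 * effect)  # causal alleles are rare
    afs = {p: float(np.round(min(1.0, base_af * rng.uniform(0.5, 1.5)), 6))
           for p in POPULATIONS}
    if effect > 0 and rng.random() < 0.3:
        clinvar = "pathogenic"
    else:
        r = rng.random()
        clinvar = "absent" if r < 0.90 else "unknown" if r < 0.95 else \
            "benign" if r < 0.98 else "pathogenic"
    return AnnotationRecord(
        gene=gene, functional_class="nonsynonymous SNV", exon_boundary_distance=0,
        splice_z=None, pop_afs=afs, predictor_scores=scores,
        conservation=float(np.round(rng.normal(effect, 1.0), 4)),
        clinvar_class=clinvar)


def _simulate_genotypes(rng: np.random.Generator, af: float, trio: bool,
                        samples: Sequence[str]) -> list[GenotypeCall]:
    af = min(max(af, 1e-4), 0.5)

    def draw() -> tuple[int, int]:
        return (int(rng.random() < af), int(rng.random() < af))

    if not trio:
        gt = draw()
        if sum(gt) == 0:
            gt = (0, 1)  # a singleton VCF only contains sites the proband carries
        return [GenotypeCall(samples[0], gt)]
    # family VCF: parents from Hardy-Weinberg, child inherits one allele per parent;
    # sites carried by a parent only are legitimate trio rows
    mom, dad = draw(), draw()
    if sum(mom) + sum(dad) == 0:
        mom = (0, 1)
    child = (mom[int(rng.integers(0, 2))], dad[int(rng.integers(0, 2))])
    return [GenotypeCall(samples[0], child), GenotypeCall(samples[1], mom),
            GenotypeCall(samples[2], dad)]


def _causal_genotypes(rng: np.random.Generator, trio: bool,
                      samples: Sequence[str]) -> tuple[list[GenotypeCall], Optional[str]]:
    if not trio:
        return [GenotypeCall(samples[0], (0, 1))], None
    if rng.random() < 0.6:
        mode = "de_novo"
        calls = [(0, 1), (0, 0), (0, 0)]
    else:
        mode = "autosomal_recessive"
        calls = [(1, 1), (0, 1), (0, 1)]
    return [GenotypeCall(s, c) for s, c in zip(samples, calls)], mode


def generate_case(spec: CohortSpec, resources: SyntheticResources,
                  rng: np.random.Generator, case_id: str) -> tuple[CaseInput, GroundTruth]:
    """One synthetic case: background variants + the planted causal SNV + phenotypes."""
    genes = sorted(resources.gene_locations)
    trio = bool(rng.random() < spec.trio_fraction)
    samples = ["proband", "mother", "father"] if trio else ["proband"]
    pedigree = dict(zip(samples, ["proband", "mother", "father"][: len(samples)]))
    sex = "male" if rng.random() < 0.5 else "female"

    # causal gene: autosomal, with disease annotations (all synthetic genes have them)
    autosomal = [g for g in genes if resources.gene_locations[g][0] not in ("X", "Y")]
    causal_gene = str(rng.choice(autosomal))

    n_background = max(1, int(rng.poisson(spec.variants_per_case)))
    used_pos: set[tuple[str, int]] = set()
    variants: list[VariantRecord] = []

    def place(gene: str) -> tuple[str, int]:
        chrom, start = resources.gene_locations[gene]
        while True:
            pos = start + int(rng.integers(0, 50_000))
            if (chrom, pos) not in used_pos:
                used_pos.add((chrom, pos))
                return chrom, pos

    for _ in range(n_background):
        gene = str(rng.choice(genes))
        ann = _draw_background_annotation(rng, gene)
        chrom, pos = place(gene)
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        key = VariantKey(chrom, pos, str(ref), str(alt))
        af = ann.max_maf or 1e-4
        gts = _simulate_genotypes(rng, af, trio, samples)
        variants.append(VariantRecord(key=key, annotation=ann, genotypes=gts, annotated=True))

    ann = _draw_causal_annotation(rng, causal_gene, spec.causal_effect)
    chrom, pos = place(causal_gene)
    ref, alt = rng.choice(_BASES, size=2, replace=False)
    causal_key = VariantKey(chrom, pos, str(ref), str(alt))
    gts, mode = _causal_genotypes(rng, trio, samples)
    variants.append(VariantRecord(key=causal_key, annotation=ann, genotypes=gts,
                                  annotated=True))
    variants.sort(key=lambda v: v.key.sort_key)

    # phenotypes: the causal disease's terms, noised
    phen = resources.phenotype
    disease = str(rng.choice(sorted(phen.gene_to_diseases[causal_gene])))
    disease_terms = sorted(phen.disease_to_terms[disease])
    all_terms = sorted(phen.ontology.nodes)
    k = min(spec.n_patient_terms, len(disease_terms))
    chosen = [str(t) for t in rng.choice(disease_terms, size=k, replace=False)]
    hpo = set()
    for t in chosen:
        if rng.random() < spec.phenotype_noise:
            hpo.add(str(rng.choice(all_terms)))
        else:
            hpo.add(t)

    case = CaseInput(variants=variants, hpo_terms=hpo, pedigree=pedigree,
                     proband_sex=sex, case_id=case_id)
    return case, GroundTruth(case_id, causal_gene, causal_key, mode)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Resources plus ``n_cases`` cases, fully determined by ``spec.seed``."""
    resources = generate_resources(spec)
    rng = np.random.default_rng(spec.seed + 1)
    cases, truth = [], {}
    for i in range(1, spec.n_cases + 1):
        case_id = f"case{i:04d}"
        case, gt = generate_case(spec, resources, rng, case_id)
        cases.append(case)
        truth[case_id] = gt
    return Cohort(spec=spec, resources=resources, cases=cases, truth=truth)


# ---------------------------------------------------------------------------
# Reference-ranker files and fixture knowledge base

def generate_external_ranks(cohort: Cohort, noise: float = 0.5, seed: int = 0,
                            rankers: Sequence[str] = ("ranker_a", "ranker_b"),
                            ) -> list[ExternalRankRecord]:
    """Per ranker and case, a permutation rank over the case's genes.

    Each ranker orders genes by a noisy copy of the causal evidence: the causal
    gene's latent score is 2, background genes draw Uniform(0,1), and Gaussian
    noise with SD ``noise`` perturbs all of them; at noise 0 the causal gene is
    ranked 1 by every ranker.
    """
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[ExternalRankRecord] = []
    for case in cohort.cases:
        case_genes = sorted({v.annotation.gene for v in case.variants if v.annotation.gene})
        causal = cohort.truth[case.case_id].causal_gene
        for ranker in rankers:
            latent = {}
            for g in case_genes:
                base = 2.0 if g == causal else float(rng.uniform(0.0, 1.0))
                jitter = float(rng.normal(0.0, noise)) if noise > 0 else 0.0
                latent[g] = base + jitter
            ordered = sorted(case_genes, key=lambda g: (-latent[g], g))
            for rank, gene in enumerate(ordered, start=1):
                records.append(ExternalRankRecord(case.case_id, ranker, gene, rank))
    return records


_SENTENCE_TEMPLATE = ("Analysis of {variant} showed that it {trigger} "
                      "{disease} in the studied pedigree.")
_TRIGGERS = ("causes", "underlies", "is associated with", "modifies")


def generate_fixture_kb(cohort: Cohort, seed: int = 0) -> list[EvidenceRelation]:
    """Fixture relations: 1-10 per causal variant, 1-2 for ~5% of background variants."""
    rng = np.random.default_rng(seed)
    resources = cohort.resources
    diseases = sorted(resources.disease_category)
    relations: list[EvidenceRelation] = []

    def add(variant_id: str, gene: str, n: int) -> None:
        for _ in range(n):
            disease = str(rng.choice(diseases))
            trigger = str(rng.choice(_TRIGGERS))
            relations.append(EvidenceRelation(
                variant_id=variant_id, disease_id=disease,
                disease_category=resources.disease_category[disease],
                pmid=int(rng.integers(1_000_000, 40_000_000)),
                sentence=_SENTENCE_TEMPLATE.format(variant=variant_id, trigger=trigger,
                                                   disease=disease),
                trigger=trigger, gene=gene))

    for case in cohort.cases:
        gt = cohort.truth[case.case_id]
        add(str(gt.causal_key), gt.causal_gene, int(rng.integers(1, 11)))
        for v in case.variants:
            if v.key != gt.causal_key and rng.random() < 0.05:
                add(str(v.key), v.annotation.gene, int(rng.integers(1, 3)))
    return relations


# ---------------------------------------------------------------------------
# File emission (all plain text, consumed unmodified by the other modules)

_CHROM_LENGTH = 260_000_000  # synthetic contig length, covers every placed variant


def _write_vcf(case: CaseInput, path: Path) -> None:
    chroms = sorted({v.key.chrom for v in case.variants},
                    key=lambda c: ([str(i) for i in range(1, 23)] + ["X", "Y", "M"]).index(c))
    samples = list(case.pedigree)
    lines = ["##fileformat=VCFv4.2", "##source=varprio-synthetic",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    lines += [f"##contig=<ID={c},length={_CHROM_LENGTH}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for v in case.variants:
        gts = []
        for s in samples:
            g = v.genotype(s)
            gts.append("./." if g.is_missing else "/".join(str(a) for a in g.allele_indices))
        lines.append(f"{v.key.chrom}\t{v.key.pos}\t.\t{v.key.ref}\t{v.key.alt}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(gts))
    path.write_text("\n".join(lines) + "\n")


def _write_annotations(case: CaseInput, path: Path) -> None:
    cols = (["chrom", "pos", "ref", "alt", "gene", "func", "exon_dist", "splice_z"]
            + [f"af_{p}" for p in POPULATIONS]
            + [f"score_{t}" for t in PREDICTOR_TOOLS] + ["gerp", "clinvar"])
    rows = ["\t".join(cols)]
    for v in case.variants:
        a = v.annotation
        row = [v.key.chrom, str(v.key.pos), v.key.ref, v.key.alt, a.gene,
               a.functional_class, str(a.exon_boundary_distance),
               "" if a.splice_z is None else repr(a.splice_z)]
        row += ["" if p not in a.pop_afs else repr(a.pop_afs[p]) for p in POPULATIONS]
        row += ["" if a.predictor_scores.get(t) is None else repr(a.predictor_scores[t])
                for t in PREDICTOR_TOOLS]
        row += ["" if a.conservation is None else repr(a.conservation), a.clinvar_class]
        rows.append("\t".join(row))
    path.write_text("\n".join(rows) + "\n")


def _write_obo(resources: SyntheticResources, path: Path) -> None:
    dag = resources.phenotype.ontology
    blocks = ["format-version: 1.2", "ontology: synthetic-hpo-subset"]
    for term in sorted(dag.nodes):
        block = [f"[Term]", f"id: {term}", f"name: synthetic term {term}"]
        for parent in sorted(dag.successors(term)):
            block.append(f"is_a: {parent} ! synthetic term {parent}")
        blocks.append("\n".join(block))
    path.write_text("\n\n".join(blocks) + "\n")


def write_cohort(cohort: Cohort, outdir: str | Path,
                 external_ranks: Optional[Sequence[ExternalRankRecord]] = None,
                 kb_relations: Optional[Sequence[EvidenceRelation]] = None) -> Path:
    """Emit the whole cohort as plain-text files under ``outdir``."""
    out = Path(outdir)
    res_dir = out / "resources"
    res_dir.mkdir(parents=True, exist_ok=True)
    resources = cohort.resources

    _write_obo(resources, res_dir / "ontology.obo")
    phen = resources.phenotype
    (res_dir / "gene_diseases.tsv").write_text("".join(
        f"{g}\t{d}\n" for g in sorted(phen.gene_to_diseases)
        for d in sorted(phen.gene_to_diseases[g])))
    (res_dir / "disease_terms.tsv").write_text("".join(
        f"{d}\t{t}\n" for d in sorted(phen.disease_to_terms)
        for t in sorted(phen.disease_to_terms[d])))
    (res_dir / "ppi.tsv").write_text("".join(
        f"{u}\t{v}\t{data['weight']}\n"
        for u, v, data in sorted(resources.interactome.graph.edges(data=True))))
    (res_dir / "omim_genes.txt").write_text(
        "".join(f"{g}\n" for g in sorted(resources.omim_genes)))
    for name, genes in sorted(resources.panels.items()):
        (res_dir / f"{name}.txt").write_text("".join(f"{g}\n" for g in sorted(genes)))
    (res_dir / "disease_categories.tsv").write_text("".join(
        f"{d}\t{c}\n" for d, c in sorted(resources.disease_category.items())))

    for case in cohort.cases:
        case_dir = out / case.case_id
        case_dir.mkdir(exist_ok=True)
        _write_vcf(case, case_dir / f"{case.case_id}.vcf")
        _write_annotations(case, case_dir / "annotations.tsv")
        (case_dir / "hpo.txt").write_text("".join(f"{t}\n" for t in sorted(case.hpo_terms)))
        (case_dir / "pedigree.tsv").write_text(
            "".join(f"{sid}\t{role}\n" for sid, role in case.pedigree.items())
            + f"#sex\t{case.proband_sex}\n")

    (out / "truth.tsv").write_text(
        "case_id\tgene\tchrom\tpos\tref\talt\n" + "".join(
            f"{t.case_id}\t{t.causal_gene}\t{t.causal_key.chrom}\t{t.causal_key.pos}"
            f"\t{t.causal_key.ref}\t{t.causal_key.alt}\n"
            for t in (cohort.truth[c.case_id] for c in cohort.cases)))

    if external_ranks is not None:
        (out / "external_ranks.tsv").write_text(
            "case_id\tranker_name\tgene\trank\n" + "".join(
                f"{r.case_id}\t{r.ranker_name}\t{r.gene}\t{r.rank}\n"
                for r in external_ranks))
    if kb_relations is not None:
        header = "variant_id\tdisease_id\tdisease_category\tpmid\tsentence\ttrigger\tdependency_path\tgene\n"
        (out / "kb.tsv").write_text(header + "".join(
            f"{r.variant_id}\t{r.disease_id}\t{r.disease_category}\t{r.pmid}\t{r.sentence}"
            f"\t{r.trigger or ''}\t{r.dependency_path or ''}\t{r.gene or ''}\n"
            for r in kb_relations))
    return out
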