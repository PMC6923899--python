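"""Phenotype-similarity features and assembly of the per-mutation feature vector.

Two phenotype features drive the ranking: the semantic similarity between the
patient's HPO terms and the diseases annotated to a gene (Resnik similarity of
most-informative common ancestors, combined by a symmetric best-match average
and normalized to [0,1]), and the same similarity propagated one hop through
the protein-protein interactome with a damping factor.

Information content (IC) is computed from the supplied disease-annotation
corpus as -log(annotation frequency); for toy ontologies without annotations a
uniform depth-based IC is used instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import obonet

from .vcf_io import PREDICTOR_TOOLS, CaseInput, VariantRecord

__all__ = [
    "PhenotypeResources",
    "InteractomeGraph",
    "FeatureVector",
    "FEATURE_NAMES",
    "term_similarity",
    "phenotype_similarity",
    "interactome_similarity",
    "build_feature_vector",
    "featurize_case",
    "load_resources",
]

CLINVAR_CODE = {"pathogenic": 1.0, "unknown": 0.5, "absent": 0.5, "benign": 0.0}

#: Order of the numeric fields fed to the scoring network.
FEATURE_NAMES = (
    ("pheno_sim_direct", "pheno_sim_ppi", "conservation", "clinvar_code", "max_maf")
    + tuple(f"score_{t}" for t in PREDICTOR_TOOLS)
    + ("lit_count",)
)


class UnknownTermError(KeyError):
    pass


@dataclass
class PhenotypeResources:
    """HPO ontology (child→parent DAG) with disease annotations and term IC."""

    ontology: nx.DiGraph  # edges point child -> parent (is_a)
    gene_to_diseases: dict[str, set[str]]
    disease_to_terms: dict[str, set[str]]
    term_ic: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.ontology):
            raise ValueError("ontology must be acyclic")
        for dis, terms in self.disease_to_terms.items():
            missing = terms - set(self.ontology.nodes)
            if missing:
                raise ValueError(f"disease {dis} uses terms absent from ontology: {sorted(missing)}")
        if not self.term_ic:
            self.term_ic = compute_information_content(self.ontology, self.disease_to_terms)
        self._ancestors: dict[str, frozenset[str]] = {}
        self._simcache: dict[tuple, float] = {}
        self._paircache: dict[frozenset[str], float] = {}

    def ancestors(self, term: str) -> frozenset[str]:
        """The term plus all of its is-a ancestors."""
        cached = self._ancestors.get(term)
        if cached is None:
            if term not in self.ontology:
                raise UnknownTermError(term)
            cached = frozenset(nx.descendants(self.ontology, term)) | {term}
            self._ancestors[term] = cached
        return cached


def compute_information_content(ontology: nx.DiGraph,
                                disease_to_terms: Mapping[str, set[str]]) -> dict[str, float]:
    """IC(t) = -log p(t) where p(t) is the fraction of diseases annotated to t or a descendant.

    With no annotation corpus, falls back to a depth-proportional IC so that
    ancestors are never more informative than their children.
    """
    terms = list(ontology.nodes)
    n_dis = len(disease_to_terms)
    if n_dis == 0:
        depth = {}
        for t in terms:
            # longest path to a root along is_a edges
            depth[t] = max((len(p) - 1 for p in _root_paths(ontology, t)), default=0)
        dmax = max(depth.values()) or 1
        return {t: depth[t] / dmax * math.log(len(terms) + 1) for t in terms}
    counts = {t: 0 for t in terms}
    for annotated in disease_to_terms.values():
        implied: set[str] = set()
        for t in annotated:
            implied |= nx.descendants(ontology, t) | {t}
        for t in implied:
            counts[t] += 1
    ic = {}
    for t in terms:
        p = counts[t] / n_dis
        ic[t] = -math.log(p) if p > 0 else -math.log(0.5 / n_dis)
    return ic


def _root_paths(ontology: nx.DiGraph, term: str):
    roots = [n for n in ontology.nodes if ontology.out_degree(n) == 0]
    for r in roots:
        if nx.has_path(ontology, term, r):
            yield from nx.all_simple_paths(ontology, term, r)
    if ontology.out_degree(term) == 0:
        yield [term]


@dataclass
class InteractomeGraph:
    """Undirected protein-protein interaction graph with edge confidences in [0,1]."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on {u}")
            w = data.get("weight", 1.0)
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"edge weight out of [0,1]: {u}-{v} {w}")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "InteractomeGraph":
        g = nx.Graph()
        for a, b, w in edges:
            g.add_edge(a, b, weight=float(w))
        return cls(g)

    def neighbors(self, gene: str) -> list[tuple[str, float]]:
        if gene not in self.graph:
            return []
        return [(n, self.graph[gene][n].get("weight", 1.0))
                for n in self.graph.neighbors(gene)]


@dataclass
class FeatureVector:
    """Numeric inputs to the scoring network for one mutation, with missingness mask."""

    pheno_sim_direct: float
    pheno_sim_ppi: float
    conservation: float
    clinvar_code: float
    max_maf: float
    predictor_scores: tuple[float, ...]  # in PREDICTOR_TOOLS order
    lit_count: float
    missing_mask: dict[str, bool]

    def as_array(self) -> np.ndarray:
        values = [self.pheno_sim_direct, self.pheno_sim_ppi, self.conservation,
                  self.clinvar_code, self.max_maf, *self.predictor_scores, self.lit_count]
        arr = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("feature vector contains non-finite values")
        return arr


# ---------------------------------------------------------------------------
# Similarity

def term_similarity(t1: str, t2: str, resources: PhenotypeResources) -> float:
    """Resnik similarity: IC of the most-informative common ancestor of t1 and t2."""
    pair = frozenset((t1, t2))
    cached = resources._paircache.get(pair)
    if cached is not None:
        return cached
    common = resources.ancestors(t1) & resources.ancestors(t2)
    value = max((resources.term_ic.get(t, 0.0) for t in common), default=0.0)
    resources._paircache[pair] = value
    return value


def _best_match_average(patient: Sequence[str], disease: Sequence[str],
                        resources: PhenotypeResources) -> float:
    """Symmetric best-match average of Resnik similarities, normalized by the
    mean of the two sets' self-similarities; lies in [0,1]."""
    sim = np.array([[term_similarity(p, d, resources) for d in disease] for p in patient])
    fwd = sim.max(axis=1).mean()
    rev = sim.max(axis=0).mean()
    self_p = np.mean([resources.term_ic.get(t, 0.0) for t in patient])
    self_d = np.mean([resources.term_ic.get(t, 0.0) for t in disease])
    denom = (self_p + self_d) / 2.0
    if denom <= 0:
        return 0.0
    return float(np.clip((fwd + rev) / 2.0 / denom, 0.0, 1.0))


def phenotype_similarity(patient_terms: Iterable[str], gene: str,
                         resources: PhenotypeResources) -> float:
    """Similarity between the patient's terms and the gene's best-matching disease.

    Score per disease is the normalized symmetric best-match average; the gene
    score is the max over its diseases. Genes with no disease annotation score 0.
    """
    patient = sorted(set(patient_terms))
    if not patient:
        raise ValueError("patient phenotype term set must be non-empty")
    for t in patient:
        if t not in resources.ontology:
            raise UnknownTermError(t)
    cache_key = (frozenset(patient), gene)
    cached = resources._simcache.get(cache_key)
    if cached is not None:
        return cached
    best = 0.0
    for disease in sorted(resources.gene_to_diseases.get(gene, ())):
        terms = sorted(resources.disease_to_terms.get(disease, ()))
        if terms:
            best = max(best, _best_match_average(patient, terms, resources))
    resources._simcache[cache_key] = best
    return best


def interactome_similarity(gene: str, patient_terms: Iterable[str],
                           resources: PhenotypeResources, graph: InteractomeGraph,
                           damping: float = 0.5) -> float:
    """One-hop phenotype similarity through the interactome.

    damping * max over neighbors n of edge_weight(gene, n) *
    phenotype_similarity(patient_terms, n). Isolated genes score 0.
    """
    if not 0.0 < damping <= 1.0:
        raise ValueError("damping must lie in (0,1]")
    patient = sorted(set(patient_terms))
    best = 0.0
    for neighbor, weight in graph.neighbors(gene):
        if neighbor == gene:
            continue
        best = max(best, weight * phenotype_similarity(patient, neighbor, resources))
    return float(np.clip(damping * best, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Feature assembly

def build_feature_vector(record: VariantRecord, case: CaseInput,
                         resources: PhenotypeResources, graph: InteractomeGraph,
                         kb=None, damping: float = 0.5) -> FeatureVector:
    """Assemble the network inputs for one mutation.

    Imputation (recorded in the mask): conservation → 0 (neutral), predictor
    scores → 0.5, max MAF → 0. The two phenotype similarities are computed,
    never imputed. lit_count is log1p of the number of knowledge-base
    relations for the variant's positional key.
    """
    ann = record.annotation
    gene = ann.gene
    mask: dict[str, bool] = {}

    direct = phenotype_similarity(case.hpo_terms, gene, resources) if gene else 0.0
    ppi = interactome_similarity(gene, case.hpo_terms, resources, graph, damping) if gene else 0.0

    cons = ann.conservation
    mask["conservation"] = cons is None
    maf = ann.max_maf
    mask["max_maf"] = maf is None
    scores = []
    for tool in PREDICTOR_TOOLS:
        s = ann.predictor_scores.get(tool)
        mask[f"score_{tool}"] = s is None
        scores.append(0.5 if s is None else float(s))
    mask["clinvar_code"] = ann.clinvar_class == "absent"

    n_rel = len(kb.query_variant(str(record.key))) if kb is not None else 0
    return FeatureVector(
        pheno_sim_direct=direct,
        pheno_sim_ppi=ppi,
        conservation=0.0 if cons is None else float(cons),
        clinvar_code=CLINVAR_CODE[ann.clinvar_class],
        max_maf=0.0 if maf is None else float(maf),
        predictor_scores=tuple(scores),
        lit_count=math.log1p(n_rel),
        missing_mask=mask,
    )


def featurize_case(case: CaseInput, resources: PhenotypeResources,
                   graph: InteractomeGraph, kb=None, damping: float = 0.5,
                   ) -> tuple[np.ndarray, list[VariantRecord]]:
    """Feature matrix (n_variants x n_features) for every variant of a case."""
    vectors = [build_feature_vector(v, case, resources, graph, kb, damping)
               for v in case.variants]
    if not vectors:
        return np.empty((0, len(FEATURE_NAMES))), []
    return np.vstack([fv.as_array() for fv in vectors]), list(case.variants)


# ---------------------------------------------------------------------------
# Resource loading

def load_resources(obo_path: str | Path, gene_to_diseases_path: str | Path,
                   disease_to_terms_path: str | Path) -> PhenotypeResources:
    """Load the ontology (OBO subset) and the two annotation TSVs."""
    graph = obonet.read_obo(str(obo_path))
    dag = nx.DiGraph()
    dag.add_nodes_from(graph.nodes)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    g2d: dict[str, set[str]] = {}
    for line in Path(gene_to_diseases_path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        gene, disease = line.rstrip("\n").split("\t")
        g2d.setdefault(gene, set()).add(disease)
    d2t: dict[str, set[str]] = {}
    for line in Path(disease_to_terms_path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        disease, term = line.rstrip("\n").split("\t")
        d2t.setdefault(disease, set()).add(term)
    return PhenotypeResources(ontology=dag, gene_to_diseases=g2d, disease_to_terms=d2t)


def load_interactome(path: str | Path) -> InteractomeGraph:
    """Three-column TSV: gene_a, gene_b, weight."""
    edges = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        a, b, w = line.rstrip("\n").split("\t")
        edges.append((a, b, float(w)))
    return InteractomeGraph.from_edges(edges)
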