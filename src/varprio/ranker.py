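"""Rank-decay training labels, the scoring network, and gene/mutation ranking.

Training labels come from reference gene prioritizers: for each case the known
causal mutation gets label 1, and the ``n_decoys`` genes with the smallest
average reference rank x get label gamma**(x - 1) (gamma defaults to 0.99).
A small multilayer network regresses these labels from the per-mutation
feature vector; at interpretation time every mutation's prediction is clipped
to [0,1], a gene scores the max over its mutations, and genes are ranked by
descending score with a deterministic tie-break (gene symbol ascending, then
variant key order).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .phenotype import (FEATURE_NAMES, FeatureVector, InteractomeGraph,
                        PhenotypeResources, build_feature_vector, featurize_case)
from .vcf_io import CaseInput, VariantKey, VariantRecord

__all__ = [
    "ExternalRankRecord",
    "LabelSpec",
    "TrainingExample",
    "NetConfig",
    "ScoreModel",
    "RankedResult",
    "make_label",
    "average_rank",
    "build_training_set",
    "train",
    "score_case",
    "rank_by_popularity",
    "leave_one_out_evaluate",
    "load_external_ranks",
    "load_causal_truth",
]


@dataclass(frozen=True)
class ExternalRankRecord:
    """One (case, reference ranker, gene) rank, 1 = most likely causal."""

    case_id: str
    ranker_name: str
    gene: str
    rank: int

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


@dataclass(frozen=True)
class LabelSpec:
    """Parameters of the rank-decay label: label = gamma**(x-1), x = average rank."""

    gamma: float = 0.99
    n_decoys: int = 40
    rankers: tuple[str, ...] = ("ranker_a", "ranker_b")

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie strictly in (0,1)")
        if self.n_decoys < 1:
            raise ValueError("n_decoys must be positive")


@dataclass
class TrainingExample:
    case_id: str
    variant_key: VariantKey
    gene: str
    features: FeatureVector
    label: float
    is_causal: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.label <= 1.0:
            raise ValueError("label must lie in (0,1]")


def make_label(x: float, spec: LabelSpec = LabelSpec()) -> float:
    """Rank-decay label gamma**(x-1); equals 1 at x = 1 and decays strictly with x."""
    if x < 1:
        raise ValueError(f"average rank x must be >= 1, got {x}")
    return spec.gamma ** (x - 1.0)


def average_rank(records: Iterable[ExternalRankRecord],
                 rankers: Sequence[str]) -> float:
    """Arithmetic mean of the configured rankers' ranks for one case+gene.

    Rankers missing the gene are excluded from the denominator; if none of the
    configured rankers covers the gene the gene is not labelable.
    """
    ranks = [r.rank for r in records if r.ranker_name in rankers]
    if not ranks:
        raise ValueError("no configured ranker covers this gene")
    return float(np.mean(ranks))


def _rank_index(external_ranks: Iterable[ExternalRankRecord]
                ) -> dict[str, dict[str, list[ExternalRankRecord]]]:
    index: dict[str, dict[str, list[ExternalRankRecord]]] = {}
    for r in external_ranks:
        index.setdefault(r.case_id, {}).setdefault(r.gene, []).append(r)
    return index


def _mean_predictor_score(record: VariantRecord) -> float:
    present = [s for s in record.annotation.predictor_scores.values() if s is not None]
    return float(np.mean(present)) if present else 0.0


def _representative_mutation(records: Sequence[VariantRecord]) -> VariantRecord:
    # most deleterious by mean available predictor score; ties by variant key order
    return min(records, key=lambda r: (-_mean_predictor_score(r), r.key.sort_key))


Featurizer = Callable[[CaseInput, VariantRecord], FeatureVector]


def build_training_set(cases: Sequence[CaseInput],
                       external_ranks: Iterable[ExternalRankRecord],
                       causal_truth: Mapping[str, tuple[str, VariantKey]],
                       spec: LabelSpec,
                       featurizer: Featurizer) -> list[TrainingExample]:
    """One causal example (label 1) plus up to n_decoys decoy examples per case.

    Decoy genes are the case's genes with the smallest average reference rank,
    excluding the causal gene (ties by gene symbol); the representative
    mutation of a multi-mutation gene is the most deleterious one by mean
    available predictor score. Cases with fewer rankable genes use all of them
    (with a warning).
    """
    index = _rank_index(external_ranks)
    examples: list[TrainingExample] = []
    for case in cases:
        causal_gene, causal_key = causal_truth[case.case_id]
        by_gene: dict[str, list[VariantRecord]] = {}
        causal_record = None
        for v in case.variants:
            if v.annotation.gene:
                by_gene.setdefault(v.annotation.gene, []).append(v)
            if v.key == causal_key:
                causal_record = v
        if causal_record is None:
            raise ValueError(f"case {case.case_id}: causal variant {causal_key} not in table")
        examples.append(TrainingExample(
            case_id=case.case_id, variant_key=causal_record.key, gene=causal_gene,
            features=featurizer(case, causal_record), label=1.0, is_causal=True))

        case_ranks = index.get(case.case_id, {})
        rankable = []
        for gene in by_gene:
            if gene == causal_gene or gene not in case_ranks:
                continue
            x = average_rank(case_ranks[gene], spec.rankers)
            rankable.append((x, gene))
        rankable.sort()
        if len(rankable) < spec.n_decoys:
            warnings.warn(f"case {case.case_id}: only {len(rankable)} rankable decoy genes "
                          f"(requested {spec.n_decoys})")
        for x, gene in rankable[: spec.n_decoys]:
            rep = _representative_mutation(by_gene[gene])
            examples.append(TrainingExample(
                case_id=case.case_id, variant_key=rep.key, gene=gene,
                features=featurizer(case, rep), label=make_label(x, spec)))
    return examples


# ---------------------------------------------------------------------------
# The scoring network

@dataclass(frozen=True)
class NetConfig:
    """Architecture and optimisation knobs for the scoring network."""

    hidden_layers: tuple[int, ...] = (32, 16)
    activation: str = "relu"
    max_iter: int = 400
    early_stopping: bool = True
    validation_fraction: float = 0.1
    learning_rate_init: float = 1e-3


@dataclass
class ScoreModel:
    """Trained network with embedded standardization constants.

    Prediction is a plain feed-forward pass (hidden activations per config,
    identity output) on standardized features, clipped to [0,1].
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_mean: np.ndarray
    feature_std: np.ndarray
    config: NetConfig = field(default_factory=NetConfig)
    gamma: float = 0.99
    seed: int = 0
    feature_names: tuple[str, ...] = FEATURE_NAMES
    version: str = "1"

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Scores in [0,1] for a (n, n_features) matrix."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        h = (X - self.feature_mean) / self.feature_std
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = h @ W + b
            if self.config.activation == "relu":
                np.maximum(h, 0.0, out=h)
            elif self.config.activation == "tanh":
                np.tanh(h, out=h)
            else:
                raise ValueError(f"unsupported activation {self.config.activation!r}")
        out = h @ self.weights[-1] + self.biases[-1]
        return np.clip(out.ravel(), 0.0, 1.0)

    def save(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "gamma": self.gamma,
            "seed": self.seed,
            "feature_names": list(self.feature_names),
            "config": {"hidden_layers": list(self.config.hidden_layers),
                       "activation": self.config.activation,
                       "max_iter": self.config.max_iter,
                       "early_stopping": self.config.early_stopping,
                       "validation_fraction": self.config.validation_fraction,
                       "learning_rate_init": self.config.learning_rate_init},
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ScoreModel":
        raw = json.loads(Path(path).read_text())
        cfg = raw["config"]
        return cls(
            weights=[np.asarray(w, dtype=float) for w in raw["weights"]],
            biases=[np.asarray(b, dtype=float) for b in raw["biases"]],
            feature_mean=np.asarray(raw["feature_mean"], dtype=float),
            feature_std=np.asarray(raw["feature_std"], dtype=float),
            config=NetConfig(hidden_layers=tuple(cfg["hidden_layers"]),
                             activation=cfg["activation"], max_iter=cfg["max_iter"],
                             early_stopping=cfg["early_stopping"],
                             validation_fraction=cfg["validation_fraction"],
                             learning_rate_init=cfg["learning_rate_init"]),
            gamma=raw["gamma"], seed=raw["seed"],
            feature_names=tuple(raw["feature_names"]), version=raw["version"],
        )


def train(examples: Sequence[TrainingExample], config: NetConfig = NetConfig(),
          seed: int = 0, gamma: float = 0.99) -> ScoreModel:
    """Fit the scoring network on rank-decay labels (squared-error regression).

    Examples are canonically sorted before fitting, so the model is invariant
    to input order; the optimiser is seeded, so the same data and seed yield
    identical weights. Degenerate inputs (all-identical features) emit a
    convergence warning but still return a model.
    """
    if len({round(e.label, 12) for e in examples}) < 2:
        raise ValueError("training requires >= 2 distinct labels")
    ordered = sorted(examples, key=lambda e: (e.case_id, e.gene, e.variant_key.sort_key))
    X = np.vstack([e.features.as_array() for e in ordered])
    y = np.array([e.label for e in ordered], dtype=float)

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0.0] = 1.0
    Xs = (X - mean) / std

    net = MLPRegressor(hidden_layer_sizes=config.hidden_layers,
                       activation=config.activation, solver="adam",
                       learning_rate_init=config.learning_rate_init,
                       max_iter=config.max_iter,
                       early_stopping=config.early_stopping and len(ordered) >= 20,
                       validation_fraction=config.validation_fraction,
                       n_iter_no_change=10, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("always", ConvergenceWarning)
        net.fit(Xs, y)
    return ScoreModel(weights=[np.asarray(w) for w in net.coefs_],
                      biases=[np.asarray(b) for b in net.intercepts_],
                      feature_mean=mean, feature_std=std,
                      config=config, gamma=gamma, seed=seed)


# ---------------------------------------------------------------------------
# Ranking

@dataclass
class RankedResult:
    """Genes in rank order with per-mutation scores.

    ``genes`` is a list of (gene, gene_score, mutations) where mutations is a
    list of (variant_key, mutation_score) sorted by descending score. The gene
    score is always the max of its mutations' scores.
    """

    genes: list[tuple[str, float, list[tuple[VariantKey, float]]]]
    ordering_mode: str = "score"  # "score" | "popularity"

    def __post_init__(self) -> None:
        for gene, gscore, muts in self.genes:
            if muts and abs(gscore - max(s for _, s in muts)) > 1e-12:
                raise ValueError(f"gene score for {gene} is not the max of its mutations")

    def gene_rank(self, gene: str) -> Optional[int]:
        for i, (g, _, _) in enumerate(self.genes, start=1):
            if g == gene:
                return i
        return None

    @property
    def gene_order(self) -> list[str]:
        return [g for g, _, _ in self.genes]


def _group_and_rank(scored: Iterable[tuple[VariantRecord, float]]) -> RankedResult:
    per_gene: dict[str, list[tuple[VariantKey, float]]] = {}
    for record, score in scored:
        gene = record.annotation.gene
        if not gene:
            continue  # unannotated mutations cannot be attributed to a gene
        per_gene.setdefault(gene, []).append((record.key, float(score)))
    genes = []
    for gene, muts in per_gene.items():
        muts.sort(key=lambda ks: (-ks[1], ks[0].sort_key))
        genes.append((gene, max(s for _, s in muts), muts))
    genes.sort(key=lambda item: (-item[1], item[0]))
    return RankedResult(genes=genes, ordering_mode="score")


def score_case(model: ScoreModel, case: CaseInput, resources: PhenotypeResources,
               graph: InteractomeGraph, kb=None) -> RankedResult:
    """Score every mutation of a (filtered, featurized) case and rank its genes.

    Genes are sorted by descending score (max over their mutations), ties by
    gene symbol ascending; an empty case yields an empty result.
    """
    if not case.variants:
        return RankedResult(genes=[])
    X, records = featurize_case(case, resources, graph, kb)
    scores = model.predict(X)
    return _group_and_rank(zip(records, scores))


def rank_by_popularity(result: RankedResult, kb) -> RankedResult:
    """Reorder genes by research popularity: total knowledge-base evidence count.

    A gene's count is the number of relations over its mutations plus its
    gene-level mentions; ties (including the no-evidence case) fall back to
    gene symbol ascending. The member set is preserved exactly.
    """
    def popularity(entry) -> int:
        gene, _, muts = entry
        n = sum(len(kb.query_variant(str(key))) for key, _ in muts)
        n += len(kb.query_gene(gene))
        return n

    reordered = sorted(result.genes, key=lambda e: (-popularity(e), e[0]))
    return RankedResult(genes=reordered, ordering_mode="popularity")


def leave_one_out_evaluate(cases: Sequence[CaseInput],
                           external_ranks: Iterable[ExternalRankRecord],
                           causal_truth: Mapping[str, tuple[str, VariantKey]],
                           spec: LabelSpec,
                           resources: PhenotypeResources,
                           graph: InteractomeGraph,
                           kb=None,
                           config: NetConfig = NetConfig(),
                           seed: int = 0) -> list[Optional[int]]:
    """Leave-one-out protocol: train on all other cases, rank the held-out case.

    The held-out case is scored unfiltered (no mutation or gene removed).
    Returns the causal gene's 1-based rank per case (None when the causal gene
    received no rank). Features are computed once per case and shared across
    folds; the training seed is fixed, so the evaluation is deterministic.
    """
    if len(cases) < 2:
        raise ValueError("leave-one-out needs >= 2 cases")
    external_ranks = list(external_ranks)
    feature_cache: dict[tuple[str, VariantKey], FeatureVector] = {}
    matrix_cache: dict[str, tuple[np.ndarray, list[VariantRecord]]] = {}
    for case in cases:
        X, records = featurize_case(case, resources, graph, kb)
        matrix_cache[case.case_id] = (X, records)
        for rec, row in zip(records, X):
            fv = build_cached_vector(row)
            feature_cache[(case.case_id, rec.key)] = fv

    def featurizer(case: CaseInput, record: VariantRecord) -> FeatureVector:
        return feature_cache[(case.case_id, record.key)]

    ranks: list[Optional[int]] = []
    for held_out in cases:
        training_cases = [c for c in cases if c.case_id != held_out.case_id]
        examples = build_training_set(training_cases, external_ranks, causal_truth,
                                      spec, featurizer)
        model = train(examples, config, seed=seed, gamma=spec.gamma)
        X, records = matrix_cache[held_out.case_id]
        scores = model.predict(X) if len(records) else np.empty(0)
        result = _group_and_rank(zip(records, scores))
        causal_gene, _ = causal_truth[held_out.case_id]
        ranks.append(result.gene_rank(causal_gene))
    return ranks


def build_cached_vector(row: np.ndarray) -> FeatureVector:
    """Wrap an already-computed feature row back into a FeatureVector."""
    return FeatureVector(
        pheno_sim_direct=float(row[0]), pheno_sim_ppi=float(row[1]),
        conservation=float(row[2]), clinvar_code=float(row[3]),
        max_maf=float(row[4]),
        predictor_scores=tuple(float(v) for v in row[5:11]),
        lit_count=float(row[11]), missing_mask={},
    )


# ---------------------------------------------------------------------------
# File interfaces

def load_external_ranks(path: str | Path) -> list[ExternalRankRecord]:
    """TSV: case_id, ranker_name, gene, rank (header optional)."""
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "case_id":
            continue
        case_id, ranker, gene, rank = parts[:4]
        records.append(ExternalRankRecord(case_id, ranker, gene, int(rank)))
    seen = set()
    for r in records:
        k = (r.case_id, r.ranker_name, r.gene)
        if k in seen:
            raise ValueError(f"duplicate external rank record for {k}")
        seen.add(k)
    return records


def load_causal_truth(path: str | Path) -> dict[str, tuple[str, VariantKey]]:
    """TSV: case_id, gene, chrom, pos, ref, alt."""
    truth = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "case_id":
            continue
        case_id, gene, chrom, pos, ref, alt = parts[:6]
        truth[case_id] = (gene, VariantKey(chrom, int(pos), ref, alt))
    return truth
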