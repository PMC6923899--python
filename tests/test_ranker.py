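"""Rank-decay labels, training-set construction, network contracts, ranking."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from scipy.stats import spearmanr

from conftest import make_case, make_record
from varprio.knowledge_base import EvidenceRelation, KnowledgeBase
from varprio.phenotype import FEATURE_NAMES
from varprio.ranker import (ExternalRankRecord, LabelSpec, NetConfig, RankedResult,
                            ScoreModel, average_rank, build_cached_vector,
                            build_training_set, leave_one_out_evaluate, make_label,
                            rank_by_popularity, score_case, train)
from varprio.vcf_io import VariantKey


# ---------------------------------------------------------------------------
# label formula

def test_label_is_exactly_one_at_rank_one():
    for gamma in (0.5, 0.9, 0.99, 0.999):
        assert make_label(1.0, LabelSpec(gamma=gamma)) == 1.0


def test_label_matches_iterative_multiplication_oracle():
    spec = LabelSpec(gamma=0.99)
    product = 1.0
    for x in range(1, 101):
        assert make_label(float(x), spec) == pytest.approx(product, rel=1e-12)
        product *= spec.gamma
    # strict monotone decrease
    labels = [make_label(float(x), spec) for x in range(1, 101)]
    assert all(a > b for a, b in zip(labels, labels[1:]))


def test_label_domain_error_below_one():
    with pytest.raises(ValueError):
        make_label(0.5)


def test_gamma_must_be_in_open_unit_interval():
    for gamma in (0.0, 1.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            LabelSpec(gamma=gamma)


# ---------------------------------------------------------------------------
# average rank

def records_for(case, gene, ranks: dict) -> list[ExternalRankRecord]:
    return [ExternalRankRecord(case, name, gene, r) for name, r in ranks.items()]


def test_average_rank_rules():
    rankers = ("ranker_a", "ranker_b")
    assert average_rank(records_for("c", "G", {"ranker_a": 3, "ranker_b": 5}), rankers) == 4.0
    assert average_rank(records_for("c", "G", {"ranker_a": 7}), rankers) == 7.0
    three = ("ranker_a", "ranker_b", "ranker_c")
    assert average_rank(records_for("c", "G", dict.fromkeys(three, 1)), three) == 1.0
    # unconfigured rankers are ignored; none available -> error
    assert average_rank(records_for("c", "G", {"ranker_a": 2, "other": 100}), rankers) == 2.0
    with pytest.raises(ValueError):
        average_rank(records_for("c", "G", {"other": 1}), rankers)


# ---------------------------------------------------------------------------
# training set construction

def _toy_featurizer(case, record):
    rng = np.random.default_rng(abs(hash((case.case_id, str(record.key)))) % 2**31)
    return build_cached_vector(rng.uniform(0.0, 1.0, size=len(FEATURE_NAMES)))


def _case_with_genes(n_genes: int, case_id="c1"):
    records = [make_record(pos=100 + i, gene=f"G{i:03d}") for i in range(n_genes)]
    return make_case(records, case_id=case_id)


def test_training_set_has_one_causal_plus_n_decoys():
    case = _case_with_genes(60)
    causal_gene = "G000"
    truth = {"c1": (causal_gene, case.variants[0].key)}
    ranks = [ExternalRankRecord("c1", rk, f"G{i:03d}", i + 1)
             for i in range(60) for rk in ("ranker_a", "ranker_b")]
    spec = LabelSpec(n_decoys=40)
    examples = build_training_set([case], ranks, truth, spec, _toy_featurizer)
    assert len(examples) == 41
    causal = [e for e in examples if e.is_causal]
    assert len(causal) == 1 and causal[0].label == 1.0 and causal[0].gene == causal_gene
    # decoys are the smallest-average-rank genes, excluding the causal gene
    decoy_genes = {e.gene for e in examples if not e.is_causal}
    assert decoy_genes == {f"G{i:03d}" for i in range(1, 41)}


def test_decoy_label_uses_rank_decay():
    case = _case_with_genes(3)
    truth = {"c1": ("G000", case.variants[0].key)}
    ranks = (records_for("c1", "G001", {"ranker_a": 2, "ranker_b": 2})
             + records_for("c1", "G002", {"ranker_a": 9, "ranker_b": 13}))
    spec = LabelSpec(gamma=0.99, n_decoys=2)
    examples = build_training_set([case], ranks, truth, spec, _toy_featurizer)
    by_gene = {e.gene: e for e in examples}
    assert by_gene["G001"].label == pytest.approx(0.99)          # x = 2
    assert by_gene["G002"].label == pytest.approx(0.99 ** 10.0)  # x = 11


def test_representative_mutation_is_most_deleterious():
    weak = make_record(pos=1, gene="G1", predictor_scores={"sift": 0.1, "cadd": 0.2})
    strong = make_record(pos=2, gene="G1", predictor_scores={"sift": 0.9, "cadd": 0.8})
    causal = make_record(pos=3, gene="G0")
    case = make_case([weak, strong, causal])
    truth = {"case": ("G0", causal.key)}
    ranks = records_for("case", "G1", {"ranker_a": 1})
    examples = build_training_set([case], ranks, truth, LabelSpec(n_decoys=1),
                                  _toy_featurizer)
    decoy = [e for e in examples if not e.is_causal][0]
    assert decoy.variant_key.pos == 2


def test_too_few_rankable_genes_warns_but_builds():
    case = _case_with_genes(3)
    truth = {"c1": ("G000", case.variants[0].key)}
    ranks = records_for("c1", "G001", {"ranker_a": 1})
    with pytest.warns(UserWarning, match="rankable"):
        examples = build_training_set([case], ranks, truth, LabelSpec(n_decoys=40),
                                      _toy_featurizer)
    assert len(examples) == 2


# ---------------------------------------------------------------------------
# training contracts

def _monotone_examples(n=200, seed=0):
    """Labels are a noiseless monotone function of feature 0."""
    rng = np.random.default_rng(seed)
    examples = []
    for i in range(n):
        row = rng.uniform(0.0, 1.0, size=len(FEATURE_NAMES))
        fv = build_cached_vector(row)
        label = 0.05 + 0.9 * row[0]
        from varprio.ranker import TrainingExample
        examples.append(TrainingExample(case_id=f"c{i:04d}",
                                        variant_key=VariantKey("1", i + 1, "A", "G"),
                                        gene=f"G{i:04d}", features=fv, label=label))
    return examples


def test_train_recovers_monotone_signal():
    examples = _monotone_examples()
    model = train(examples, NetConfig(), seed=0)
    X = np.vstack([e.features.as_array() for e in examples])
    rho, _ = spearmanr(model.predict(X), [e.label for e in examples])
    assert rho >= 0.95


def test_train_is_deterministic_and_order_invariant():
    examples = _monotone_examples(n=80)
    m1 = train(examples, seed=3)
    m2 = train(examples, seed=3)
    m3 = train(list(reversed(examples)), seed=3)
    for a, b in ((m1, m2), (m1, m3)):
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)


def test_train_requires_two_distinct_labels():
    examples = _monotone_examples(n=10)
    for e in examples:
        e.label = 0.5
    with pytest.raises(ValueError):
        train(examples)


def test_model_json_round_trip(tmp_path):
    examples = _monotone_examples(n=80)
    model = train(examples, seed=1)
    path = tmp_path / "model.json"
    model.save(path)
    loaded = ScoreModel.load(path)
    X = np.vstack([e.features.as_array() for e in examples])
    np.testing.assert_allclose(loaded.predict(X), model.predict(X), atol=1e-12)
    assert loaded.gamma == model.gamma and loaded.config == model.config


# ---------------------------------------------------------------------------
# scoring and ranking

def test_score_case_contracts(small_cohort):
    cohort, ranks = small_cohort
    truth = cohort.causal_truth
    spec = LabelSpec(n_decoys=10)
    from varprio.phenotype import build_feature_vector

    def featurizer(case, record):
        return build_feature_vector(record, case, cohort.resources.phenotype,
                                    cohort.resources.interactome)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        examples = build_training_set(cohort.cases, ranks, truth, spec, featurizer)
        model = train(examples, seed=0)
    case = cohort.cases[0]
    result = score_case(model, case, cohort.resources.phenotype,
                        cohort.resources.interactome)
    genes = result.gene_order
    assert len(genes) == len(set(genes))  # total order, no duplicates
    scores = [s for _, s, _ in result.genes]
    assert scores == sorted(scores, reverse=True)
    for gene, gscore, muts in result.genes:
        assert 0.0 <= gscore <= 1.0
        assert gscore == max(s for _, s in muts)
        for _, s in muts:
            assert 0.0 <= s <= 1.0


def test_gene_score_is_max_of_mutations():
    k1, k2 = VariantKey("1", 1, "A", "G"), VariantKey("1", 2, "C", "T")
    result = RankedResult(genes=[("G1", 0.9, [(k1, 0.9), (k2, 0.2)])])
    assert result.genes[0][1] == 0.9
    with pytest.raises(ValueError):
        RankedResult(genes=[("G1", 0.2, [(k1, 0.9), (k2, 0.2)])])


def test_empty_case_gives_empty_result(small_cohort):
    cohort, _ = small_cohort
    model = train(_monotone_examples(n=60), seed=0)
    empty = make_case([], hpo={"HP:0000010"})
    empty.variants = []
    result = score_case(model, empty, cohort.resources.phenotype,
                        cohort.resources.interactome)
    assert result.genes == []


def test_rank_by_popularity_counts_and_fallback():
    k1, k2, k3 = (VariantKey("1", p, "A", "G") for p in (1, 2, 3))
    result = RankedResult(genes=[("GA", 0.9, [(k1, 0.9)]),
                                 ("GB", 0.5, [(k2, 0.5)]),
                                 ("GC", 0.1, [(k3, 0.1)])])
    rels = [EvidenceRelation(str(k3), f"D{i}", "cat", 100 + i, "x causes y", "causes")
            for i in range(10)]
    rels += [EvidenceRelation(str(k2), "D0", "cat", 999, "x causes y", "causes")]
    kb = KnowledgeBase(relations=rels)
    popular = rank_by_popularity(result, kb)
    assert popular.gene_order == ["GC", "GB", "GA"]
    assert popular.ordering_mode == "popularity"
    assert {g for g, _, _ in popular.genes} == {"GA", "GB", "GC"}  # permutation
    # no evidence at all: alphabetical fallback
    empty_kb = KnowledgeBase(relations=[])
    assert rank_by_popularity(result, empty_kb).gene_order == ["GA", "GB", "GC"]


# ---------------------------------------------------------------------------
# leave-one-out protocol

def test_leave_one_out_structure_and_determinism(small_cohort):
    cohort, ranks = small_cohort
    spec = LabelSpec(n_decoys=10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r1 = leave_one_out_evaluate(cohort.cases[:3], ranks, cohort.causal_truth, spec,
                                    cohort.resources.phenotype,
                                    cohort.resources.interactome, seed=5)
        r2 = leave_one_out_evaluate(cohort.cases[:3], ranks, cohort.causal_truth, spec,
                                    cohort.resources.phenotype,
                                    cohort.resources.interactome, seed=5)
    assert len(r1) == 3
    assert r1 == r2
    assert all(r is None or r >= 1 for r in r1)
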