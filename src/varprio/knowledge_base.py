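"""Mutation-disease literature evidence: storage, variant queries, summaries.

The knowledge base consumes relation records produced upstream by named-entity
recognition and relation extraction over the literature; this module only
stores, indexes and serves them. Variant identifiers are either dbSNP RSIDs
(``rs#``) or normalized positional keys (``chrom:pos:ref:alt``); an optional
alias table maps one onto the other.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "EvidenceRelation",
    "KnowledgeBase",
    "load_relations",
    "load_aliases",
    "query_variant",
    "summarize_two_level",
    "highlight_sentence",
]

_RSID_RE = re.compile(r"^rs\d+$")
_POSITIONAL_RE = re.compile(r"^(chr)?([0-9]{1,2}|[XYM]|MT):\d+:[ACGTN]+:[ACGTN]+$", re.I)

RELATION_COLUMNS = ("variant_id", "disease_id", "disease_category", "pmid", "sentence")
OPTIONAL_COLUMNS = ("trigger", "dependency_path", "gene")


class KeyFormatError(ValueError):
    """Variant key is neither an RSID nor chrom:pos:ref:alt."""


class SchemaError(ValueError):
    """Relations file is missing a required column."""


def _valid_key(key: str) -> bool:
    return bool(_RSID_RE.match(key) or _POSITIONAL_RE.match(key))


@dataclass(frozen=True)
class EvidenceRelation:
    """One mined mutation-disease association with its literature provenance."""

    variant_id: str
    disease_id: str
    disease_category: str
    pmid: int
    sentence: str
    trigger: Optional[str] = None
    dependency_path: Optional[str] = None
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pmid <= 0:
            raise ValueError(f"pmid must be positive, got {self.pmid}")
        if not self.sentence:
            raise ValueError("sentence must be non-empty")
        if not _valid_key(self.variant_id):
            raise KeyFormatError(
                f"variant_id {self.variant_id!r} is neither an RSID nor chrom:pos:ref:alt")


@dataclass
class KnowledgeBase:
    """Relations indexed by variant key and by gene symbol."""

    relations: list[EvidenceRelation] = field(default_factory=list)
    aliases: dict[str, str] = field(default_factory=dict)  # rsid -> positional key
    _by_variant: dict[str, list[EvidenceRelation]] = field(default_factory=dict, repr=False)
    _by_gene: dict[str, list[EvidenceRelation]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for rel in self.relations:
            self._index(rel)

    def _index(self, rel: EvidenceRelation) -> None:
        self._by_variant.setdefault(self._canonical(rel.variant_id), []).append(rel)
        if rel.gene:
            self._by_gene.setdefault(rel.gene, []).append(rel)

    def _canonical(self, key: str) -> str:
        return self.aliases.get(key, key)

    def __len__(self) -> int:
        return len(self.relations)

    def query_variant(self, key: str) -> list[EvidenceRelation]:
        """All relations for an RSID or positional key, ordered by
        (disease_category, disease_id, pmid); unknown variants yield []."""
        if not _valid_key(key):
            raise KeyFormatError(f"malformed variant key {key!r}")
        hits = list(self._by_variant.get(self._canonical(key), []))
        hits.sort(key=lambda r: (r.disease_category, r.disease_id, r.pmid))
        return hits

    def query_gene(self, gene: str) -> list[EvidenceRelation]:
        return list(self._by_gene.get(gene, []))


def load_aliases(path: str | Path) -> dict[str, str]:
    """Two-column TSV: rsid, chrom:pos:ref:alt."""
    aliases = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rsid, positional = line.rstrip("\n").split("\t")[:2]
        aliases[rsid] = positional
    return aliases


def load_relations(path: str | Path, aliases: Optional[Mapping[str, str]] = None,
                   ) -> tuple["KnowledgeBase", list[tuple[int, str]]]:
    """Load the relations TSV; returns (knowledge base, rejected line report).

    Invalid rows are rejected with their line numbers; exact duplicates on
    (variant_id, disease_id, pmid, sentence) are de-duplicated. A missing
    required column raises :class:`SchemaError`.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise SchemaError("empty relations file")
    header = lines[0].rstrip("\n").split("\t")
    missing = set(RELATION_COLUMNS) - set(header)
    if missing:
        raise SchemaError(f"relations file missing required columns: {sorted(missing)}")
    col = {name: header.index(name) for name in header}

    relations: list[EvidenceRelation] = []
    rejected: list[tuple[int, str]] = []
    seen: set[tuple] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")

        def get(name: str) -> Optional[str]:
            i = col.get(name)
            if i is None or i >= len(parts):
                return None
            return parts[i] or None

        try:
            rel = EvidenceRelation(
                variant_id=get("variant_id") or "",
                disease_id=get("disease_id") or "",
                disease_category=get("disease_category") or "",
                pmid=int(get("pmid") or 0),
                sentence=get("sentence") or "",
                trigger=get("trigger"),
                dependency_path=get("dependency_path"),
                gene=get("gene"),
            )
        except (ValueError, KeyFormatError) as exc:
            rejected.append((lineno, str(exc)))
            continue
        dedup_key = (rel.variant_id, rel.disease_id, rel.pmid, rel.sentence)
        if dedup_key in seen:
            continue
        seen.add(dedup_key)
        relations.append(rel)
    kb = KnowledgeBase(relations=relations, aliases=dict(aliases or {}))
    return kb, rejected


def query_variant(kb: KnowledgeBase, key: str) -> list[EvidenceRelation]:
    return kb.query_variant(key)


def summarize_two_level(relations: Iterable[EvidenceRelation]) -> dict[str, dict[str, int]]:
    """category → disease → evidence count; counts conserve totals at both levels."""
    summary: dict[str, dict[str, int]] = {}
    for rel in relations:
        inner = summary.setdefault(rel.disease_category, {})
        inner[rel.disease_id] = inner.get(rel.disease_id, 0) + 1
    return summary


def summary_to_json(summary: Mapping[str, Mapping[str, int]]) -> str:
    return json.dumps(summary, sort_keys=True, indent=2)


def highlight_sentence(relation: EvidenceRelation, marker: str = "**") -> str:
    """Wrap the first case-insensitive occurrence of the trigger word in markup.

    Sentences without a trigger, or whose trigger does not occur, are returned
    unchanged.
    """
    if not relation.trigger:
        return relation.sentence
    sentence = relation.sentence
    low = sentence.lower()
    i = low.find(relation.trigger.lower())
    if i < 0:
        return sentence
    j = i + len(relation.trigger)
    return f"{sentence[:i]}{marker}{sentence[i:j]}{marker}{sentence[j:]}"
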