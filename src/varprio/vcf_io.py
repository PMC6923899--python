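"""Reading VCF + annotation inputs into the joined variant table; writing ranked results.

A case is represented as a list of :class:`VariantRecord`, one per
(site, alt allele) pair: multi-allelic VCF rows are split and each sample
genotype is recoded against the carried alt. Coordinates are 1-based
inclusive. Chromosome labels are normalized by stripping a leading "chr"
and mapping "MT" to "M".
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

__all__ = [
    "VariantKey",
    "GenotypeCall",
    "AnnotationRecord",
    "VariantRecord",
    "CaseInput",
    "PREDICTOR_TOOLS",
    "read_vcf",
    "merge_trio_vcfs",
    "detect_reference_build",
    "join_annotations",
    "write_results_csv",
    "read_results_csv",
    "normalize_chrom",
]

#: The six protein-impact predictors whose scores are carried per variant.
PREDICTOR_TOOLS = ("sift", "polyphen2", "mutationtaster", "primateai", "dann", "cadd")

ALLOWED_CHROMS = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "M")
_CHROM_ORDER = {c: i for i, c in enumerate(ALLOWED_CHROMS)}

CLINVAR_CLASSES = ("pathogenic", "unknown", "benign", "absent")


class VcfParseError(ValueError):
    """Malformed VCF content; carries the offending line number when known."""


class PedigreeBindingError(ValueError):
    """A pedigree sample is absent from the VCF sample columns."""


class DuplicateAnnotationError(ValueError):
    """The annotation table contains duplicate chrom:pos:ref:alt keys."""


def normalize_chrom(label: str) -> str:
    """Strip a leading 'chr' prefix and map 'MT' to 'M'."""
    c = label[3:] if label.lower().startswith("chr") else label
    if c.upper() == "MT":
        return "M"
    return c.upper() if c.upper() in ("X", "Y", "M") else c


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of one alternate allele at one site (1-based, normalized chrom)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.chrom not in ALLOWED_CHROMS:
            raise ValueError(f"chromosome label {self.chrom!r} not in allowed set")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or set(allele) - set("ACGTN"):
                raise ValueError(f"{name} allele {allele!r} must be a non-empty A/C/G/T/N string")

    @property
    def sort_key(self) -> tuple:
        return (_CHROM_ORDER[self.chrom], self.pos, self.ref, self.alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        parts = text.split(":")
        if len(parts) != 4:
            raise ValueError(f"variant key {text!r} is not chrom:pos:ref:alt")
        chrom, pos, ref, alt = parts
        return cls(normalize_chrom(chrom), int(pos), ref.upper(), alt.upper())


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's diploid (or haploid) call, recoded against a single alt."""

    sample_id: str
    allele_indices: Optional[tuple[int, ...]]  # None == missing (./.)
    phased: bool = False

    @property
    def is_missing(self) -> bool:
        return self.allele_indices is None

    @property
    def n_alt(self) -> int:
        return 0 if self.allele_indices is None else sum(1 for a in self.allele_indices if a == 1)

    @property
    def carries_alt(self) -> bool:
        return self.n_alt > 0


def _missing_annotation() -> "AnnotationRecord":
    return AnnotationRecord(
        gene="", functional_class="", exon_boundary_distance=0,
        splice_z=None, pop_afs={}, predictor_scores={},
        conservation=None, clinvar_class="absent",
    )


@dataclass
class AnnotationRecord:
    """Per-variant functional annotation (the pre-computed annotation-table row)."""

    gene: str
    functional_class: str
    exon_boundary_distance: int
    splice_z: Optional[float]
    pop_afs: dict[str, float]
    predictor_scores: dict[str, Optional[float]]
    conservation: Optional[float]
    clinvar_class: str

    def __post_init__(self) -> None:
        if self.exon_boundary_distance < 0:
            raise ValueError("exon_boundary_distance must be >= 0")
        if self.clinvar_class not in CLINVAR_CLASSES:
            raise ValueError(f"clinvar_class {self.clinvar_class!r} not in {CLINVAR_CLASSES}")
        for pop, af in self.pop_afs.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency for {pop} out of [0,1]: {af}")
        for tool, s in self.predictor_scores.items():
            if s is not None and not 0.0 <= s <= 1.0:
                raise ValueError(f"predictor score for {tool} out of [0,1]: {s}")

    @property
    def max_maf(self) -> Optional[float]:
        present = [v for v in self.pop_afs.values() if v is not None]
        return max(present) if present else None


@dataclass
class VariantRecord:
    """One VCF alt allele joined with its annotation and per-sample genotypes."""

    key: VariantKey
    annotation: AnnotationRecord = field(default_factory=_missing_annotation)
    genotypes: list[GenotypeCall] = field(default_factory=list)
    annotated: bool = False
    n_alts_at_site: int = 1

    def genotype(self, sample_id: str) -> GenotypeCall:
        for g in self.genotypes:
            if g.sample_id == sample_id:
                return g
        raise KeyError(sample_id)


@dataclass
class CaseInput:
    """One patient: variant table + phenotype terms + pedigree binding."""

    variants: list[VariantRecord]
    hpo_terms: set[str]
    pedigree: dict[str, str]  # sample_id -> role in {proband, mother, father}
    proband_sex: str  # "male" | "female"
    case_id: str = "case"

    def __post_init__(self) -> None:
        for term in self.hpo_terms:
            if not (term.startswith("HP:") and len(term) == 10 and term[3:].isdigit()):
                raise ValueError(f"{term!r} is not an HP:####### identifier")
        roles = list(self.pedigree.values())
        if len(set(roles)) != len(roles):
            raise ValueError("pedigree roles must be unique")
        if self.proband_sex not in ("male", "female"):
            raise ValueError("proband_sex must be 'male' or 'female'")

    @property
    def proband_id(self) -> str:
        for sid, role in self.pedigree.items():
            if role == "proband":
                return sid
        raise ValueError("pedigree has no proband")

    @property
    def is_trio(self) -> bool:
        return set(self.pedigree.values()) == {"proband", "mother", "father"}


# ---------------------------------------------------------------------------
# VCF reading

def _strip_padding(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    # remove shared leading padding bases while both alleles stay non-empty
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return pos, ref, alt


def read_vcf(path: str | Path, pedigree: Mapping[str, str]) -> list[VariantRecord]:
    """Read a VCF into split, genotype-recoded variant records.

    Multi-allelic rows are split into one record per alt; each sample's
    genotype is recoded against that alt (the alt's index becomes 1, any
    other allele becomes 0, missing stays missing). Records are returned
    sorted by (chrom, pos, ref, alt).
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    missing = set(pedigree) - set(samples)
    if missing:
        raise PedigreeBindingError(
            f"pedigree samples {sorted(missing)} absent from VCF samples {samples}")

    records: list[VariantRecord] = []
    for lineno, rec in enumerate(vf, start=1):
        if rec.alts is None:
            continue
        try:
            chrom = normalize_chrom(rec.chrom)
            alts = [a.upper() for a in rec.alts]
            ref = rec.ref.upper()
        except Exception as exc:  # pragma: no cover - defensive
            raise VcfParseError(f"malformed VCF body record #{lineno}: {exc}") from exc
        for alt_idx, alt in enumerate(alts, start=1):
            if set(alt) - set("ACGTN"):
                continue  # symbolic / breakend alts are out of scope
            pos, r, a = _strip_padding(rec.pos, ref, alt)
            try:
                key = VariantKey(chrom, pos, r, a)
            except ValueError as exc:
                raise VcfParseError(f"VCF body record #{lineno}: {exc}") from exc
            calls = []
            for sid in pedigree:
                sample = rec.samples[sid]
                gt = sample.get("GT")
                if gt is None or all(g is None for g in gt):
                    calls.append(GenotypeCall(sid, None))
                else:
                    recoded = tuple(1 if g == alt_idx else 0 for g in gt if g is not None)
                    calls.append(GenotypeCall(sid, recoded, phased=bool(sample.phased)))
            records.append(VariantRecord(key=key, genotypes=calls,
                                         n_alts_at_site=len(alts)))
    records.sort(key=lambda r: r.key.sort_key)
    return records


def merge_trio_vcfs(paths: Mapping[str, str | Path], pedigree: Mapping[str, str]) -> list[VariantRecord]:
    """Merge per-sample VCFs by variant key (absent sites → missing genotype).

    ``paths`` maps sample_id → VCF path; each file is read as a singleton and
    the union of keys is carried, with a missing call for samples whose file
    lacks a site. Reference-block semantics are not modelled.
    """
    per_sample: dict[str, dict[VariantKey, GenotypeCall]] = {}
    for sid, p in paths.items():
        recs = read_vcf(p, {sid: "proband"})
        per_sample[sid] = {r.key: r.genotypes[0] for r in recs}
    all_keys = sorted({k for table in per_sample.values() for k in table},
                      key=lambda k: k.sort_key)
    merged = []
    for key in all_keys:
        calls = [per_sample[sid].get(key, GenotypeCall(sid, None)) for sid in pedigree]
        merged.append(VariantRecord(key=key, genotypes=calls))
    return merged


# contig-length signatures of the two human reference builds (chrom -> length)
_BUILD_CONTIG_LENGTHS = {
    "hg19": {"1": 249250621, "2": 243199373, "X": 155270560, "Y": 59373566},
    "hg38": {"1": 248956422, "2": 242193529, "X": 156040895, "Y": 57227415},
}


def detect_reference_build(header_text: str) -> str:
    """Detect hg19/hg38 from ##reference lines or contig-length signatures.

    Returns ``"unknown"`` when neither signal matches; the caller must then
    supply the build explicitly.
    """
    for line in header_text.splitlines():
        if line.startswith("##reference"):
            low = line.lower()
            if "hg19" in low or "grch37" in low or "b37" in low:
                return "hg19"
            if "hg38" in low or "grch38" in low:
                return "hg38"
        if line.startswith("##contig"):
            body = line[line.find("<") + 1 : line.rfind(">")]
            fields = dict(kv.split("=", 1) for kv in body.split(",") if "=" in kv)
            if "ID" in fields and "length" in fields:
                chrom = normalize_chrom(fields["ID"])
                try:
                    length = int(fields["length"])
                except ValueError:
                    continue
                for build, sig in _BUILD_CONTIG_LENGTHS.items():
                    if sig.get(chrom) == length:
                        return build
    return "unknown"


# ---------------------------------------------------------------------------
# Annotation join

_ANNOTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "func", "exon_dist", "splice_z",
                       "gerp", "clinvar"]


def _parse_optional_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", ".", "NA", "nan"):
        return None
    return float(s)


def read_annotation_table(table_path: str | Path) -> dict[VariantKey, AnnotationRecord]:
    """Read the annotation TSV into a key→record map (duplicate keys → error)."""
    df = pd.read_csv(table_path, sep="\t", dtype=str)
    required = set(_ANNOTATION_COLUMNS)
    if not required <= set(df.columns):
        raise ValueError(f"annotation table missing columns: {sorted(required - set(df.columns))}")
    af_cols = [c for c in df.columns if c.startswith("af_")]
    score_cols = {t: f"score_{t}" for t in PREDICTOR_TOOLS if f"score_{t}" in df.columns}

    table: dict[VariantKey, AnnotationRecord] = {}
    dupes = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        key = VariantKey(normalize_chrom(d["chrom"]), int(d["pos"]),
                         d["ref"].upper(), d["alt"].upper())
        if key in table:
            dupes.append(str(key))
            continue
        clinvar = str(d["clinvar"]).strip().lower() if d["clinvar"] is not None else "absent"
        if clinvar in ("", ".", "nan", "na"):
            clinvar = "absent"
        table[key] = AnnotationRecord(
            gene=str(d["gene"]),
            functional_class=str(d["func"]) if d["func"] is not None else "",
            exon_boundary_distance=int(d["exon_dist"]),
            splice_z=_parse_optional_float(d["splice_z"]),
            pop_afs={c[3:]: v for c in af_cols
                     if (v := _parse_optional_float(d[c])) is not None},
            predictor_scores={t: _parse_optional_float(d[c]) for t, c in score_cols.items()},
            conservation=_parse_optional_float(d["gerp"]),
            clinvar_class=clinvar,
        )
    if dupes:
        raise DuplicateAnnotationError(f"duplicate annotation keys: {dupes}")
    return table


def join_annotations(variants: Sequence[VariantRecord],
                     table_path: str | Path) -> list[VariantRecord]:
    """Attach annotation rows to variants by chrom:pos:ref:alt.

    Variants with no matching row keep an all-missing annotation and stay
    flagged unannotated (``annotated=False``).
    """
    table = read_annotation_table(table_path)
    joined = []
    for v in variants:
        ann = table.get(v.key)
        if ann is None:
            joined.append(replace(v, annotation=_missing_annotation(), annotated=False))
        else:
            joined.append(replace(v, annotation=ann, annotated=True))
    return joined


# ---------------------------------------------------------------------------
# Results CSV

RESULT_COLUMNS = (
    ["rank", "gene", "gene_score", "chrom", "pos", "ref", "alt", "mutation_score",
     "zygosity", "functional_class", "max_maf"]
    + [f"score_{t}" for t in PREDICTOR_TOOLS]
    + ["clinvar", "evidence_count"]
)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.6f}"
    return str(value)


def write_results_csv(result, path: str | Path, *, zygosity: Mapping[VariantKey, str] = {},
                      evidence_counts: Mapping[VariantKey, int] = {},
                      annotations: Mapping[VariantKey, AnnotationRecord] = {}) -> None:
    """Write a ranked result as RFC 4180 CSV, one row per mutation.

    Rows are grouped by gene in rank order; within a gene the
    higher-scoring mutation comes first. Scores round-trip at 1e-6.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for rank, (gene, gene_score, mutations) in enumerate(result.genes, start=1):
            for key, mscore in mutations:
                ann = annotations.get(key)
                row = [rank, gene, _fmt(float(gene_score)),
                       key.chrom, key.pos, key.ref, key.alt, _fmt(float(mscore)),
                       zygosity.get(key, ""),
                       ann.functional_class if ann else "",
                       _fmt(ann.max_maf) if ann else ""]
                row += [_fmt(ann.predictor_scores.get(t)) if ann else "" for t in PREDICTOR_TOOLS]
                row += [ann.clinvar_class if ann else "", evidence_counts.get(key, 0)]
                writer.writerow(row)


def read_results_csv(path: str | Path) -> pd.DataFrame:
    """Re-read a results CSV (used for round-trip checks and downstream tooling)."""
    return pd.read_csv(path)
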