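"""Baseline filtration and the nine user-facing filter settings, plus gene panels.

Every filter is a pure predicate over a :class:`~varprio.vcf_io.VariantRecord`
(and, where needed, its gene context). ``apply_filters`` composes the enabled
predicates as a conjunction and reports per-filter removal counts.

Strictness conventions (pinned by tests): predictor and splice-|z| comparisons
are strict (">"), the MAF ceiling is inclusive ("<="). Absence of a score never
removes a variant, except under the ClinVar-class and literature-membership
filters where the user explicitly asked for known records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .vcf_io import PREDICTOR_TOOLS, CaseInput, GenotypeCall, VariantRecord

__all__ = [
    "FilterConfig",
    "ZygosityCall",
    "VARIANT_TYPES",
    "DEFAULT_TYPE_MAP",
    "baseline_filtration",
    "classify_variant_type",
    "call_zygosity",
    "infer_inheritance",
    "splice_region_filter",
    "predictor_filter",
    "maf_filter",
    "membership_filters",
    "apply_filters",
    "load_gene_list",
    "load_type_map",
]

#: The 11-type variant vocabulary; anything else maps to "unknown".
VARIANT_TYPES = (
    "missense", "stopgain", "stoploss", "startloss",
    "frameshift_insertion", "frameshift_deletion",
    "nonframeshift_insertion", "nonframeshift_deletion",
    "splicing", "synonymous", "ncRNA",
)

# functional_class -> type label, following the ANNOVAR exonic-function
# vocabulary; editable via load_type_map().
DEFAULT_TYPE_MAP: dict[str, str] = {
    "nonsynonymous SNV": "missense",
    "missense": "missense",
    "stopgain": "stopgain",
    "stoploss": "stoploss",
    "startloss": "startloss",
    "frameshift insertion": "frameshift_insertion",
    "frameshift_insertion": "frameshift_insertion",
    "frameshift deletion": "frameshift_deletion",
    "frameshift_deletion": "frameshift_deletion",
    "nonframeshift insertion": "nonframeshift_insertion",
    "nonframeshift_insertion": "nonframeshift_insertion",
    "nonframeshift deletion": "nonframeshift_deletion",
    "nonframeshift_deletion": "nonframeshift_deletion",
    "splicing": "splicing",
    "synonymous SNV": "synonymous",
    "synonymous": "synonymous",
    "ncRNA_exonic": "ncRNA",
    "ncRNA_splicing": "ncRNA",
    "ncRNA": "ncRNA",
}

#: Coding (exonic non-synonymous) type labels retained by baseline filtration.
CODING_NONSYNONYMOUS = frozenset({
    "missense", "stopgain", "stoploss", "startloss",
    "frameshift_insertion", "frameshift_deletion",
    "nonframeshift_insertion", "nonframeshift_deletion",
})

ZYGOSITY_VALUES = ("heterozygous", "homozygous", "hemizygous", "missing")
INHERITANCE_MODES = ("de_novo", "autosomal_dominant", "autosomal_recessive",
                     "compound_het_in_trans", "x_linked")

# X pseudo-autosomal regions (treated as autosomal), 1-based inclusive.
DEFAULT_PAR_REGIONS = {
    "hg19": (("X", 60001, 2699520), ("X", 154931044, 155260560)),
    "hg38": (("X", 10001, 2781479), ("X", 155701383, 156030895)),
}


@dataclass
class FilterConfig:
    """All filter knobs with their documented defaults.

    ``None`` (or ``False``) disables a knob; the default configuration keeps
    everything except the always-on splice-region rule for splicing variants
    (exon/intron boundary distance <= 10 and |z| > 1.8).
    """

    chromosomes: Optional[set[str]] = None
    variant_types: Optional[set[str]] = None
    zygosity: Optional[set[str]] = None
    inheritance: Optional[set[str]] = None
    predictor_threshold: Optional[float] = None
    predictor_tools: set[str] = field(default_factory=lambda: set(PREDICTOR_TOOLS))
    maf_max: Optional[float] = None
    populations: Optional[set[str]] = None
    require_dmvar: bool = False
    clinvar_classes: Optional[set[str]] = None
    require_omim: bool = False
    panel: Optional[set[str]] = None
    splice_distance: int = 10
    splice_z_min: float = 1.8
    reference_build: str = "hg38"

    def __post_init__(self) -> None:
        if self.splice_distance < 1:
            raise ValueError("splice_distance must be a positive integer")
        if self.splice_z_min <= 0:
            raise ValueError("splice_z_min must be positive")
        for name in ("predictor_threshold", "maf_max"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        bad = self.predictor_tools - set(PREDICTOR_TOOLS)
        if bad:
            raise ValueError(f"unknown predictor tools: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("chromosomes", "variant_types", "zygosity", "inheritance",
                    "predictor_tools", "clinvar_classes", "panel", "populations"):
            if key in raw and raw[key] is not None:
                raw[key] = set(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class ZygosityCall:
    value: str  # heterozygous | homozygous | hemizygous | missing
    gene_compound_het: bool = False

    def __post_init__(self) -> None:
        if self.value not in ZYGOSITY_VALUES:
            raise ValueError(f"zygosity {self.value!r} not in {ZYGOSITY_VALUES}")


def load_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; '#' starts a comment."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.add(line)
    return genes


def load_type_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV functional_class → type label."""
    mapping = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        func, label = line.rstrip("\n").split("\t")
        mapping[func] = label
    return mapping


def classify_variant_type(annotation, type_map: Mapping[str, str] = DEFAULT_TYPE_MAP) -> str:
    """Map the annotation's functional class into the 11-type vocabulary or 'unknown'."""
    label = type_map.get(annotation.functional_class, "unknown")
    return label if label in VARIANT_TYPES else "unknown"


def _in_par(chrom: str, pos: int, build: str) -> bool:
    for c, start, end in DEFAULT_PAR_REGIONS.get(build, ()):
        if chrom == c and start <= pos <= end:
            return True
    return False


def call_zygosity(record: VariantRecord, pedigree: Mapping[str, str], proband_sex: str,
                  build: str = "hg38") -> ZygosityCall:
    """Zygosity of the proband call; hemizygous for male non-PAR X / Y single-alt calls."""
    proband = next(sid for sid, role in pedigree.items() if role == "proband")
    gt = record.genotype(proband)
    if gt.is_missing:
        return ZygosityCall("missing")
    chrom = record.key.chrom
    sex_chrom = chrom == "Y" or (chrom == "X" and not _in_par(chrom, record.key.pos, build))
    if proband_sex == "male" and sex_chrom and gt.n_alt >= 1:
        return ZygosityCall("hemizygous")
    if gt.n_alt >= 2:
        return ZygosityCall("homozygous")
    if gt.n_alt == 1:
        return ZygosityCall("heterozygous")
    return ZygosityCall("missing")  # homozygous reference: no alt zygosity to report


def annotate_compound_het(records: Sequence[VariantRecord], pedigree: Mapping[str, str],
                          proband_sex: str, build: str = "hg38") -> dict[int, ZygosityCall]:
    """Per-record zygosity with the gene-level compound-het flag filled in.

    Returns id(record) → ZygosityCall; the flag is true for every heterozygous
    proband variant in a gene carrying >= 2 such variants.
    """
    calls = {id(r): call_zygosity(r, pedigree, proband_sex, build) for r in records}
    het_per_gene: dict[str, int] = {}
    for r in records:
        if calls[id(r)].value == "heterozygous" and r.annotation.gene:
            het_per_gene[r.annotation.gene] = het_per_gene.get(r.annotation.gene, 0) + 1
    for r in records:
        c = calls[id(r)]
        if c.value == "heterozygous" and het_per_gene.get(r.annotation.gene, 0) >= 2:
            calls[id(r)] = ZygosityCall("heterozygous", gene_compound_het=True)
    return calls


def _role_gt(record: VariantRecord, pedigree: Mapping[str, str], role: str) -> Optional[GenotypeCall]:
    for sid, r in pedigree.items():
        if r == role:
            try:
                return record.genotype(sid)
            except KeyError:
                return None
    return None


def infer_inheritance(record: VariantRecord, gene_records: Sequence[VariantRecord],
                      pedigree: Mapping[str, str], proband_sex: str,
                      build: str = "hg38") -> set[str]:
    """Inheritance modes compatible with the trio genotypes at this site.

    Singleton cases return the empty set (no inheritance output). Modes:
    de_novo, autosomal_dominant, autosomal_recessive, compound_het_in_trans,
    x_linked.
    """
    roles = set(pedigree.values())
    if roles != {"proband", "mother", "father"}:
        return set()
    pro = _role_gt(record, pedigree, "proband")
    mom = _role_gt(record, pedigree, "mother")
    dad = _role_gt(record, pedigree, "father")
    if pro is None or pro.is_missing or not pro.carries_alt:
        return set()

    modes: set[str] = set()
    parents_known = mom is not None and not mom.is_missing and dad is not None and not dad.is_missing
    chrom = record.key.chrom
    on_x = chrom == "X" and not _in_par(chrom, record.key.pos, build)

    if parents_known:
        if mom.n_alt == 0 and dad.n_alt == 0:
            modes.add("de_novo")
        if not on_x:
            if pro.n_alt == 1 and (mom.n_alt == 1) != (dad.n_alt == 1):
                modes.add("autosomal_dominant")
            if pro.n_alt >= 2 and mom.n_alt == 1 and dad.n_alt == 1:
                modes.add("autosomal_recessive")
        if on_x:
            if proband_sex == "male" and pro.n_alt >= 1 and mom.n_alt >= 1:
                modes.add("x_linked")
            if proband_sex == "female" and pro.n_alt >= 2:
                modes.add("x_linked")

    # compound het in trans: >=2 proband hets in the gene, at least one
    # transmitted from each parent
    if pro.n_alt == 1 and not on_x:
        from_mom = from_dad = False
        for other in gene_records:
            og = _role_gt(other, pedigree, "proband")
            if og is None or og.is_missing or og.n_alt != 1:
                continue
            om = _role_gt(other, pedigree, "mother")
            od = _role_gt(other, pedigree, "father")
            if om is None or od is None or om.is_missing or od.is_missing:
                continue
            if om.n_alt >= 1 and od.n_alt == 0:
                from_mom = True
            if od.n_alt >= 1 and om.n_alt == 0:
                from_dad = True
        if from_mom and from_dad:
            modes.add("compound_het_in_trans")
    return modes


def splice_region_filter(annotation, config: FilterConfig) -> bool:
    """Keep a splicing variant iff it is close enough to the boundary and |z| is large.

    keep iff exon_boundary_distance <= splice_distance AND |splice_z| > splice_z_min;
    a missing z-score is not kept.
    """
    if annotation.splice_z is None:
        return False
    return (annotation.exon_boundary_distance <= config.splice_distance
            and abs(annotation.splice_z) > config.splice_z_min)


def baseline_filtration(variants: Sequence[VariantRecord],
                        config: Optional[FilterConfig] = None,
                        type_map: Mapping[str, str] = DEFAULT_TYPE_MAP) -> list[VariantRecord]:
    """Keep coding-region and splice-site variants; drop synonymous ones.

    Splicing variants are additionally subject to :func:`splice_region_filter`.
    """
    config = config or FilterConfig()
    kept = []
    for v in variants:
        vtype = classify_variant_type(v.annotation, type_map)
        if vtype in CODING_NONSYNONYMOUS:
            kept.append(v)
        elif vtype == "splicing" and splice_region_filter(v.annotation, config):
            kept.append(v)
    return kept


def predictor_filter(annotation, config: FilterConfig) -> bool:
    """Keep iff the max present score over selected tools exceeds the threshold.

    With no threshold set, or all selected scores missing, the variant is kept.
    """
    if config.predictor_threshold is None:
        return True
    present = [s for t, s in annotation.predictor_scores.items()
               if t in config.predictor_tools and s is not None]
    if not present:
        return True
    return max(present) > config.predictor_threshold


def maf_filter(annotation, config: FilterConfig) -> bool:
    """Keep iff the max frequency over selected populations is <= the ceiling."""
    if config.maf_max is None:
        return True
    pops = config.populations
    if pops is not None:
        # a configured population never seen in any annotation is a config error,
        # checked by apply_filters up front; here absent == missing
        present = [af for p, af in annotation.pop_afs.items() if p in pops]
    else:
        present = list(annotation.pop_afs.values())
    if not present:
        return True
    return max(present) <= config.maf_max


def membership_filters(record: VariantRecord, config: FilterConfig, *,
                       kb=None, omim_genes: Optional[set[str]] = None) -> bool:
    """Conjunction of the literature, ClinVar-class, OMIM and panel filters."""
    gene = record.annotation.gene
    if config.require_dmvar:
        if kb is None or not kb.query_variant(str(record.key)):
            return False
    if config.clinvar_classes is not None:
        if record.annotation.clinvar_class not in config.clinvar_classes:
            return False  # 'absent' fails any explicit class selection
    if config.require_omim:
        if omim_genes is None or gene not in omim_genes:
            return False
    if config.panel is not None and gene not in config.panel:
        return False
    return True


def apply_filters(case: CaseInput, config: FilterConfig, *, kb=None,
                  omim_genes: Optional[set[str]] = None,
                  type_map: Mapping[str, str] = DEFAULT_TYPE_MAP,
                  ) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply baseline filtration then every enabled filter as a pure conjunction.

    Returns (kept variants, per-filter removal counts). Zygosity and
    compound-het are evaluated on the post-baseline set; all other predicates
    are record-local, so filtering is order-independent and idempotent.
    """
    if config.populations is not None:
        seen = {p for v in case.variants for p in v.annotation.pop_afs}
        unknown = config.populations - seen
        if unknown and seen:
            raise ValueError(f"unknown population labels in config: {sorted(unknown)}")

    counts: dict[str, int] = {}
    pool = baseline_filtration(case.variants, config, type_map)
    counts["baseline"] = len(case.variants) - len(pool)

    zyg = annotate_compound_het(pool, case.pedigree, case.proband_sex, config.reference_build)
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in pool:
        by_gene.setdefault(v.annotation.gene, []).append(v)

    def checks(v: VariantRecord) -> Iterable[tuple[str, bool]]:
        ann = v.annotation
        if config.chromosomes is not None:
            yield "chromosome", v.key.chrom in config.chromosomes
        if config.variant_types is not None:
            yield "variant_type", classify_variant_type(ann, type_map) in config.variant_types
        if config.zygosity is not None:
            z = zyg[id(v)]
            ok = (z.value in config.zygosity
                  or ("compound_heterozygous" in config.zygosity and z.gene_compound_het))
            yield "zygosity", ok
        if config.inheritance is not None:
            modes = infer_inheritance(v, by_gene.get(ann.gene, []), case.pedigree,
                                      case.proband_sex, config.reference_build)
            yield "inheritance", bool(modes & config.inheritance)
        if config.predictor_threshold is not None:
            yield "predictor", predictor_filter(ann, config)
        if config.maf_max is not None:
            yield "maf", maf_filter(ann, config)
        if config.require_dmvar or config.clinvar_classes is not None \
                or config.require_omim or config.panel is not None:
            yield "membership", membership_filters(v, config, kb=kb, omim_genes=omim_genes)

    kept = []
    for v in pool:
        ok = True
        for name, passed in checks(v):
            if not passed:
                counts[name] = counts.get(name, 0) + 1
                ok = False
        if ok:
            kept.append(v)
    return kept, counts
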