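# Methods

## Problem setting

Given an annotated exome VCF (singleton or trio) and a patient's HPO terms,
rank the mutated genes so that the causal gene appears as early as possible.
The package treats upstream annotation as given: a TSV keyed by
chrom:pos:ref:alt supplies gene symbol, functional class, exon/intron boundary
distance, splice |z|, per-population allele frequencies, six predictor scores,
conservation and ClinVar class. Multi-allelic VCF rows are split per alt
allele, genotypes recoded against that alt, coordinates kept 1-based, and
chromosome labels normalized (`chr` stripped, `MT`→`M`).

## Scoring model

Each mutation is represented by 12 features: direct phenotype similarity,
interactome-propagated phenotype similarity, conservation, ClinVar code
(pathogenic 1.0, unknown/absent 0.5, benign 0.0), max population MAF, six
predictor scores, and log1p of the literature-evidence count. Missing values
are imputed (conservation → 0, predictor score → 0.5, MAF → 0) and recorded in
a per-field mask; the two phenotype features are always computed, never
imputed. Treating "unknown" and "absent" ClinVar identically is a deliberate
prior: neither carries evidence either way.

### Phenotype similarity

Term-to-term similarity is Resnik's measure: the information content (IC) of
the most informative common ancestor in the HPO is-a DAG. IC is estimated from
the supplied disease-annotation corpus as −log of the fraction of diseases
annotated to the term or a descendant (unannotated terms get a small-sample
floor); toy ontologies without a corpus fall back to depth-proportional IC.
Both estimators keep IC non-increasing toward the root.

A patient term set P is compared with a disease term set D by the symmetric
best-match average, normalized by the mean of the two sets' self-similarities
and clipped to [0, 1]; a gene scores the max over its diseases. Identical sets
score exactly 1; genes without disease annotations score 0. One caveat is
documented rather than hidden: because the normalizer shrinks when a patient
term is generalized to an ancestor, the *normalized* score is not guaranteed
monotone under that replacement — the unnormalized best-match score is, and
that is the property the tests pin.

Interactome propagation is deliberately one hop: damping × max over direct
neighbors of (edge confidence × neighbor's phenotype similarity), damping 0.5.
A full random walk is a documented extension point; the one-hop form is
deterministic, cheap, and captures the "guilt by association" signal the
feature exists for.

### Labels and training

Reference prioritizers (two by default; the set is configuration) provide
per-case gene ranks. The label of a mutation whose gene has average available
rank x is γ^(x−1), γ = 0.99 — the causal mutation is pinned to exactly 1. Per
case, the 40 lowest-average-rank non-causal genes become decoys (ties by gene
symbol); a multi-mutation decoy gene is represented by its most deleterious
mutation (mean of available predictor scores, ties by variant key). Cases
with fewer rankable genes use all of them and warn.

The regressor is a feed-forward network (input → 32 → 16 → 1, ReLU, squared
error, Adam, early stopping on a 10% validation split), fitted via
scikit-learn with a fixed seed; examples are canonically sorted before
fitting, so training is invariant to input order. The stored model embeds the
feature standardization constants and γ, is serialized as a single JSON file,
and predicts with its own vectorized forward pass whose output is clipped to
[0, 1] — the clip, rather than a saturating output unit, enforces the score
range; in practice predictions already concentrate inside it.

Gene score = max over the gene's mutation scores; genes sort by descending
score, then gene symbol, then variant key — fixed so CSV output is
byte-stable. An alternative "research popularity" ordering sorts genes by
their total knowledge-base evidence count instead.

### Evaluation

Leave-one-out: for each case, train on all others and rank the held-out case
*unfiltered* (no mutation or gene removed before ranking); report the causal
gene's rank and top-k fractions (k = 1, 5, 20, 50 by default; unranked cases
count toward the denominator at every k). Per-case features are computed once
and shared across folds, which changes nothing statistically (features do not
depend on the model) and keeps 50 folds around two minutes on one CPU.

## Filtration semantics

Baseline filtration keeps exonic non-synonymous and splice-region variants
and removes synonymous ones; splice-region variants must lie within
`splice_distance` (default 10) bases of an exon/intron boundary with
|z| > `splice_z_min` (default 1.8), and a missing z is never kept. Strictness
conventions are pinned by tests: predictor and splice-|z| comparisons strict,
the MAF ceiling inclusive. Absent evidence never removes a variant, except
under the ClinVar-class and literature-membership filters, where the user
explicitly asked for known records. All other filters are record-local pure
predicates composed as a conjunction, hence order-independent and idempotent;
zygosity/compound-het is gene-contextual and computed on the post-baseline
set. Trio inheritance calls follow an explicit genotype truth table (de novo,
autosomal dominant with exactly one heterozygous parent, autosomal recessive,
compound het in trans requiring one transmitted variant per parent, X-linked
with sex-aware hemizygosity outside the pseudo-autosomal regions); singletons
produce no inheritance output, and compound-het candidates in singletons are
flagged without trans confirmation.

## Synthetic cohorts

The generator emulates a rare-disease exome study: ~200-term random DAG
ontology (depth ≥ 4), each gene annotated to 1–3 diseases of 3–8 terms, a
scale-free interactome, and per case a Poisson number of background variants
(default mean 1200 across 300 genes, matching the order of magnitude of real
exome gene counts at desk scale) plus one causal SNV. Background predictor
scores draw Beta(2,5), MAF a mixture with mass at 0.01–0.2, conservation
N(0,1), ClinVar mostly absent. The causal variant draws the *same*
distributions shifted by `causal_effect` background standard deviations
(scores, conservation), MAF damped by exp(−2·effect), and ClinVar pathogenic
with probability 0.3 when the effect is positive — so `causal_effect = 0`
degenerates exactly to the background draw, making the planted signal a clean
null/alternative dial. Patient terms are sampled from the causal gene's
disease terms with a `phenotype_noise` fraction replaced by random ontology
terms; trio genotypes follow Hardy–Weinberg parents with Mendelian
transmission, and the causal variant is planted as de novo or recessive.
Reference-ranker files order genes by a noisy copy of the causal evidence.

What the generator does **not** emulate: linkage structure, sequence context,
annotation errors, phenotype-term correlation within the ontology beyond the
disease annotations, and multi-gene or incompletely penetrant architectures.
Passing tests therefore demonstrate that the machinery recovers a planted
signal under the stated conditions, not clinical performance on real cohorts.

## Task queue

Batch workloads (originally large-scale literature mining) run through a FIFO
queue protocol: workers request the queue head, upload a result before the
next request, and receive NO-TASK when the queue drains; a dead worker's
in-flight tasks are reloaded at the queue tail (fair to fresh tasks — the
alternative, head reinsertion, is equivalent for correctness). Dispatch is
at-least-once and collection idempotent, which yields exactly-once results
under any failure schedule; a task that keeps raising (3 consecutive
attempts) is marked failed without stalling the run. The pool is an
in-process deterministic simulation driven by a seeded RNG (worker choice,
crash injection, mid-run joins); the protocol contract is what a distributed
deployment would implement over a wire.

## Numerical and degenerate-input choices

Tie-breaks are total everywhere (score desc, gene symbol asc, variant key
order). Feature standardization guards zero-variance columns (std → 1).
Training on fewer than 20 examples disables the validation split; all-equal
labels are rejected. Empty filtered cases yield empty (valid) results.
Duplicate annotation keys, malformed variant keys, and missing KB columns are
hard errors with the offending keys/lines named; invalid KB rows are rejected
per line, valid ones kept. Knowledge-base variant identifiers accept RSIDs or
normalized positional keys, bridged by an optional alias table.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| γ | 0.99 | rank-decay base of the training label |
| decoys per case | 40 | lowest-average-rank non-causal genes |
| splice distance | 10 bp | max boundary distance for splice-region variants |
| splice \|z\| | 1.8 | min splice-impact z-score (strict) |
| damping | 0.5 | one-hop interactome attenuation |
| hidden layers | 32, 16 | network architecture |
| cohort | 50 cases, 300 genes, ~1200 variants/case | synthetic study conditions |
| causal effect | 1.5 SD | planted feature shift |
| phenotype noise | 0.2 | off-disease patient-term fraction |

## Known limitations

The phenotype metric and interactome propagation are principled
reconstructions of standard practice, not reproductions of any production
system's undisclosed formulas. GVCF reference blocks, structural variants,
liftover, pedigrees beyond trios, mitochondrial heteroplasmy and mosaicism
are out of scope. The popularity ordering depends entirely on the supplied
knowledge base's coverage.
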