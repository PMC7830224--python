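# Methods

This note records the models, parameter choices and numerical decisions
behind `painpanel`, and what the synthetic benchmarks do and do not
demonstrate.

## Ontology model and annotation propagation

An ontology is a directed acyclic graph of terms connected by typed
edges (`is_a`, `part_of`, `regulates`; the GO sub-relations
`positively/negatively_regulates` are folded into `regulates`, all other
relations are ignored with a warning). Edges are stored child → parent;
acyclicity is validated at construction by topological sort, and a
dangling parent reference is a hard error. Obsolete OBO stanzas are
never loaded. The namespace filter defaults to `biological_process`
(the GO category conventionally used for process-level functional
characterization); synthetic ontologies use the namespace `synthetic`.

Annotation follows the true-path rule: a gene directly annotated to a
term is implicitly annotated to every ancestor. By default all three
relation types count as ancestry — the convention that makes
parent-term gene counts monotone — and a restriction to `is_a` alone is
available. Propagation is computed once per relation set via a
topological traversal and memoized; it is idempotent by construction.
Gene identity is the uppercased symbol; duplicates collapse with a
warning.

## Over-representation analysis

For a term with `K` of `N` background genes annotated and `k` of the
`nG` study genes annotated, the p-value is the hypergeometric upper tail
`P(X ≥ k)`, `X ~ Hypergeom(N, K, nG)` — the one-sided Fisher exact test
for over-representation. Bonferroni control is implemented as threshold
division (`p < t_p/m`) rather than p-value inflation; `m` counts the
terms actually tested (at least one background gene and at least
`min_annotated` study genes, default 1). The default threshold
`t_p = 5·10⁻¹⁵` is deliberately conservative: it was chosen in the
original workflow so that the number of significant terms does not
exceed the gene-set size. Results sort by (p-value, term id) so ties
order deterministically. A cutoff ≥ 1 is treated as vacuous (every
tested term flagged), since `p < 1` would silently exclude terms with
p exactly 1 (e.g. root terms).

## Remarkableness

`Cert(Tᵢ) = |{Tₖ : p(Tₖ) < p(Tᵢ)}|/nT` is computed over the significant
set only, exactly as printed in the source method: the most significant
term receives certainty 0 and therefore remarkableness 0. Because the
accompanying prose ("how safe it is to assume that the term describes
the gene set") suggests the opposite orientation, the complement
`1 − Cert` is available behind `cert_complement` / `--cert-complement`;
the as-printed form is the default everywhere. `Info = −e·p·ln(p)` uses
the continuity conventions `Info(0) = Info(1) = 0` and peaks at exactly
1 for `p = 1/e`.

## Computed ABC analysis

Items are sorted by descending value; the ABC curve plots cumulative
item fraction against cumulative value fraction. The A|B boundary is the
curve point of minimal Euclidean distance to the ideal point (0, 1); the
B|C boundary is the first point at or after it whose following segment
has slope ≤ 1 (break-even: added effort no longer buys
proportionally more yield). Value ties across a boundary move as one
block into the more important set. An all-equal input is degenerate (the
curve is the diagonal, every point is "a" boundary): it is split purely
by index — the diagonal's closest point to (0, 1) is at the midpoint,
so set A is exactly the first half — and a warning is logged.

## Details, headlines, subsumption

A *detail* is a significant term with no significant descendant. For
every distinct upward path from each detail to a root, the on-path
significant term of maximal remarkableness becomes a *headline*; when
several on-path terms tie, the one nearest the detail wins (specificity
is preserved). Headlines are filtered to ABC set A (all kept, with a
warning, when fewer than three exist).

Subsumption abstracts the retained headlines: while more than 9 remain,
the ontology terms at the deepest level (longest distance to a root)
that cover — are ancestors of or equal to — at least two current members
replace the members they cover. All covering terms of that deepest
level merge in the same iteration, so sibling branches abstract
together: twelve headlines under three disjoint parents collapse to the
three parents in one pass rather than stalling at nine after a single
merge. Within a level, candidates covering more members merge first,
ties broken lexicographically. The 5–9 range is a soft target on both
sides: a batch may land below 5 when no smaller abstraction exists, and
if no term covers two members the irreducible set is reported with a
warning. Node classes for rendering follow the precedence
functional area > headline > detail > significant > structural.

## Variant QC

**Coordinates.** VCF positions (1-based) convert to 0-based half-open
internally; gene models read as 0-based half-open BED-like intervals.
Strand is ignored for location classification — UTR identity comes from
the model's interval labels. Multi-allelic records decompose into one
record per alternate allele, with genotype counts relative to that
allele.

**Location classes.** Priority within a gene model: CDS exon → exonic,
then 5′/3′-UTR, then span interior → intronic, then the 25 bp padding
fringe → intergenic. With overlapping genes the model whose CDS contains
the position wins, else the first in genomic order (logged). The five
classes partition every classified variant, so class counts always sum
to the total.

**Coverage.** A padded exon region is accepted only if *every* base has
depth strictly greater than 20 (a single base at exactly 20 rejects the
region).

**HWE filter.** From observed counts `(n_AA, n_Aa, n_aa)` the allele
frequency is `p = (2n_AA + n_Aa)/2n` and the expected trio
`(np², 2npq, nq²)`. Three tests are available:

* `fisher_expected` (default — the literal described procedure): the
  Freeman–Halton exact conditional test on the 2×3 table of observed
  versus expected counts, the expected trio rounded by largest
  remainder so it still sums to `n`. Implemented by full enumeration
  over tables with fixed margins (no library in the stack provides an
  r×c exact test); validated against R's `fisher.test` to 9+ digits.
* `exact_hwe`: the standard exact HWE test conditioning on the allele
  counts (summing probabilities of heterozygote counts no more probable
  than the observed one).
* `exact_hwe_midp`: the mid-p variant counting only half the
  probability of the observed outcome class.

Exact conditional tests on a discrete support are conservative: full
enumeration over the trinomial support at n = 61, MAF = 0.2 gives a true
retention probability of 1.000 for `fisher_expected` and 0.975 for
`exact_hwe` at α = 0.05, versus 0.957 for the mid-p variant. The mid-p
test is therefore the calibrated choice when the filter is meant to
operate at its nominal level; the conservative defaults err on the side
of retaining variants, which is the safer direction for a QC filter.
Monomorphic variants are trivially in equilibrium (p = 1, retained).
Default α = 0.05.

**Percentage-bend correlation** (Wilcox 1994, β = 0.2): per vector the
bend scale ω is the m-th smallest absolute deviation from the median
with `m = floor((1−β)n + 0.5)`; observations are standardized about the
bend-adjusted location and clipped to [−1, 1]; r is the normalized inner
product of the clipped scores, and significance uses
`T = r·√((n−2)/(1−r²))` against a t distribution with n−2 degrees of
freedom. A constant vector (ω = 0) is a hard error. The implementation
agrees with an independent reference implementation to ~1e−15 at sample
sizes where the two m conventions coincide, and stays within 0.05 of
Pearson's r on clean bivariate normal data.

**Cohort composition.** The expected number of case subjects in a
planned sample that preserves a reference cohort's case:control ratio is
`planned_n · cases/controls` (60 · 74/779 = 5.70 for the packaged
scenario).

## Synthetic data

The generators replace two inputs that cannot ship: cohort genotypes
and a GO snapshot. Each generator draws from its own stream derived from
the master seed, so outputs are fully deterministic per seed and adding
a generator never perturbs existing ones.

* **Ontology**: a layered random DAG, single root, geometric layer
  widths (×3 per level), each non-root term drawing 1–3 parents from the
  layer above with relation probabilities 0.8/0.15/0.05 for
  is_a/part_of/regulates. Default 500 terms — the scale of a process
  subgraph relevant to one gene panel.
* **Annotations**: 2000 background genes annotated to leaves with
  power-law term-size weights (exponent 1.3) and 1 + Poisson(0.6)
  annotations per gene. The planted "theme" is the depth ≥ 2 term
  covering about 6.5% of the background whose gene content is balanced
  across at least two children (no child holding > 60%) — an unbalanced
  theme would be indistinguishable from its dominant child and the
  planted truth ambiguous. The 72-gene study set is drawn stratified:
  the number of theme genes is binomial at `enrichment_factor` times the
  theme's background share (capped at 90%), so `enrichment_factor` is
  the theme's expected fold-enrichment and factor 1 reduces exactly to
  uniform sampling.
* **Genotypes**: trios multinomial in
  `(p² + Fpq, 2pq(1−F), q² + Fpq)` with `p = 1 − MAF`; `F = 0` is exact
  HWE, `F = 1` removes heterozygotes, infeasible `(MAF, F)` pairs are
  rejected. Defaults n = 61 subjects, MAF 0.2.
* **Variant tables**: gene lengths uniform on [500, 20000] bp; counts
  Poisson with rate affine in length,
  `λ = μ·(1 − α + α·L/mean(L))`, with μ = 9.6 (≈ 691 variants over 72
  genes) and α solved in closed form so the population correlation
  equals the target ρ (clipped where the rate would go negative). Short
  genes naturally draw zero counts, mirroring the empty-gene behavior of
  real panels.

**What the benchmarks show — and do not.** Planted-theme recovery
(≥ 90% over 50 seeds at 8-fold enrichment, with zero functional areas in
≥ 95% of null runs) demonstrates that the ORA → remarkableness → ABC →
subsumption chain can re-identify a known enriched ancestor under
GO-like topology and power-law annotation sizes. The recovery benchmark
scores remarkableness with the complement certainty: under the
as-printed formula the planted theme is typically the minimum-p term and
receives remarkableness 0 by definition, so headline selection
structurally avoids it (recovery plateaus near 70–80%); the complement
orientation is the one under which "most remarkable" aligns with "most
confidently enriched". The synthetic DAG lacks several features of real
GO — multiple namespaces, term depths beyond ~6, annotation evidence
codes, inter-ontology links — so passing these tests supports the
algorithmic chain, not fidelity to any particular GO release. Likewise
the genotype and variant-count generators emulate marginal distributions
only (no linkage between variants, no per-amplicon coverage structure).

## Problem sizes

Defaults mirror the motivating study's dimensions: 72-gene study set,
2000-gene background (a desk-scale stand-in for the genome-wide
background), 500-term ontology, 61 subjects, 69–72 panel genes in
correlation checks. Simulation-based checks use 50 seeds (recovery,
null calibration), 1000 variants (HWE calibration) and 10 replicates
(correlation recovery).

## Known limitations

* The pipeline report omits wall-clock timestamps so reruns are
  byte-identical; provenance is carried by the config hash instead.
* Subsumption searches ancestors over all three relation types,
  consistent with propagation; there is no per-relation control there.
* The Freeman–Halton enumeration is O(n²) in the sample size per table —
  fine for cohort-scale genotype counts, slow for n in the tens of
  thousands.
* Real-GO workflows (GAF evidence filtering, release pinning) are out of
  scope; annotations enter as a plain two-column table.
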