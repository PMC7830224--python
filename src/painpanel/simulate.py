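"""Synthetic inputs with known ground truth.

The cohort DNA behind the original panel cannot be shared and the GO
snapshot it used is release-dependent, so every input of the pipeline is
emulated here with planted, recoverable truth:

* a layered random ontology DAG with a single root and a designated
  planted "theme" subtree;
* gene annotations with power-law leaf-term sizes and a study set whose
  genes are oversampled from the planted subtree by a configurable
  enrichment factor;
* diploid genotype count trios under (or violating) Hardy-Weinberg
  equilibrium, parameterized by minor-allele frequency and the inbreeding
  coefficient F;
* per-gene (length, variant count) tables whose population correlation is
  calibrated to a target rho.

Each generator draws from its own stream split off the master seed, so
adding a generator never perturbs existing fixtures, and identical seeds
reproduce identical objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ontology import AnnotationMap, OntologyDAG, OntologyTerm, propagate

# fixed stream indices per generator
_STREAMS = {"ontology": 1, "annotations": 2, "genotypes": 3, "variant_table": 4}


@dataclass
class SimConfig:
    """Study conditions of the synthetic experiments.

    Defaults mirror the dimensions of the original study: a ~500-term
    process ontology slice, 2000 background genes, a 72-gene study set and
    61 genotyped subjects.
    """

    seed: int = 0
    # ontology + annotations
    n_terms: int = 500
    n_genes: int = 2000
    max_parents: int = 3
    annotation_exponent: float = 1.3
    planted_terms: list[str] = field(default_factory=list)
    #: background-gene share of the planted theme subtree
    theme_fraction: float = 0.065
    enrichment_factor: float = 8.0
    n_study: int = 72
    # genotypes
    n_subjects: int = 61
    maf: float = 0.2
    inbreeding_f: float = 0.0
    # variant table
    n_panel_genes: int = 72
    length_range: tuple[int, int] = (500, 20000)
    target_rho: float = 0.6
    mean_count: float = 9.6

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])


# --------------------------------------------------------------------------
# ontology


def _term_id(i: int) -> str:
    return f"SYN:{i:07d}"


def gen_ontology(config: SimConfig) -> OntologyDAG:
    """Layered random DAG with a single root.

    Terms are assigned to layers of geometrically growing width; every
    non-root term draws 1..max_parents distinct parents from the layer
    above, so the graph is acyclic by construction and each term's depth
    equals its layer.  The planted "theme" used by the annotation
    generator is chosen from this DAG by :func:`theme_term`.
    """
    if config.n_terms < 3:
        raise ValueError("need at least 3 terms")
    rng = config.rng("ontology")
    n = config.n_terms

    # geometric layer widths 1, 3, 9, ... capped to n terms
    widths = [1]
    while sum(widths) < n:
        widths.append(min(3 * widths[-1], n - sum(widths)))
    layers: list[list[int]] = []
    idx = 0
    for w in widths:
        layers.append(list(range(idx, idx + w)))
        idx += w

    parents_of: dict[int, list[tuple[int, str]]] = {0: []}
    relations = np.array(["is_a", "part_of", "regulates"])
    rel_probs = np.array([0.8, 0.15, 0.05])
    for li in range(1, len(layers)):
        above = layers[li - 1]
        for term in layers[li]:
            k = int(rng.integers(1, min(config.max_parents, len(above)) + 1))
            chosen = rng.choice(above, size=k, replace=False)
            rels = rng.choice(relations, size=k, p=rel_probs)
            parents_of[term] = [(int(p), str(r)) for p, r in zip(chosen, rels)]

    terms = [
        OntologyTerm(
            term_id=_term_id(i),
            name=f"synthetic process {i}",
            namespace="synthetic",
            parents=tuple(sorted((_term_id(p), rel)
                                 for p, rel in parents_of[i])),
        )
        for i in range(n)
    ]
    return OntologyDAG(terms)


def theme_term(dag: OntologyDAG, config: SimConfig,
               ann: AnnotationMap | None = None) -> str:
    """Deterministic planted-theme choice.

    The theme is an internal term at depth >= 2 whose subtree covers a
    share of the background close to ``config.theme_fraction`` — large
    enough to carry signal, small enough that oversampling its genes is
    meaningful.  Among such candidates the most *balanced* one is chosen:
    no single child subtree may dominate the theme's gene content,
    otherwise the theme is indistinguishable from that child and "the"
    planted truth would be ambiguous.  Coverage is measured in propagated
    background genes when *ann* is given, in leaf descendants otherwise.
    """
    if config.planted_terms:
        return config.planted_terms[0]
    depths = dag.depths()
    leaves = dag.leaves
    if ann is not None:
        from .ontology import term_to_genes
        cover_sets = term_to_genes(ann, ann.background_genes)
        coverage = {t: len(gs) for t, gs in cover_sets.items()}
        total = len(ann.background_genes)
    else:
        cover_sets = {t: (dag.descendants(t) | {t}) & leaves for t in dag.terms}
        coverage = {t: len(s) for t, s in cover_sets.items()}
        total = len(leaves)
    target = config.theme_fraction * total

    def balance(term: str) -> float:
        # share of the theme's genes concentrated in its largest child
        own = cover_sets.get(term, set())
        if not own:
            return 1.0
        biggest = max((len(cover_sets.get(c, set()) & own)
                       for c in dag.children(term)), default=len(own))
        return biggest / len(own)

    candidates = [
        t for t in sorted(dag.terms)
        if depths[t] >= 2 and t not in leaves
        and 0.6 * target <= coverage.get(t, 0) <= 1.4 * target
        and len(dag.children(t)) >= 2
    ]
    balanced = [t for t in candidates if balance(t) <= 0.6]
    pool = balanced or candidates
    if pool:
        return min(pool, key=lambda t: (abs(coverage.get(t, 0) - target), t))
    # fallback: nearest coverage regardless of branching
    fallback = [t for t in sorted(dag.terms)
                if depths[t] >= 2 and t not in leaves]
    if not fallback:
        raise ValueError("DAG has no internal term at depth >= 2")
    return min(fallback, key=lambda t: (abs(coverage.get(t, 0) - target), t))


# --------------------------------------------------------------------------
# annotations with planted enrichment


def gen_annotations_with_planting(
    dag: OntologyDAG, config: SimConfig
) -> tuple[AnnotationMap, list[str], dict]:
    """Annotate background genes to leaves and draw an enriched study set.

    Leaf terms receive power-law annotation weights (a few big terms, many
    small ones).  Every background gene is annotated to one or more leaves.
    The study set of ``n_study`` genes oversamples genes annotated (after
    propagation) to the planted theme subtree so that the theme's expected
    fold-enrichment (study share over background share) equals
    ``enrichment_factor``; factor 1 reduces to uniform sampling.  Returns
    the annotation map, the study set and a truth record with the planted
    term and its realized fold-enrichment.
    """
    rng = config.rng("annotations")
    leaves = sorted(dag.leaves)
    ranks = rng.permutation(len(leaves)) + 1
    weights = ranks.astype(float) ** (-config.annotation_exponent)
    weights /= weights.sum()

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    direct: dict[str, set[str]] = {}
    n_ann = 1 + rng.poisson(0.6, size=config.n_genes)
    for gene, k in zip(genes, n_ann):
        chosen = rng.choice(len(leaves), size=min(k, len(leaves)),
                            replace=False, p=weights)
        direct[gene] = {leaves[i] for i in chosen}
    ann = propagate(dag, direct, background_genes=genes)

    planted = theme_term(dag, config, ann)
    if planted not in dag:
        raise ValueError(f"planted term {planted} not in DAG")

    theme_genes = [g for g in genes if planted in ann.propagated[g]]
    other_genes = [g for g in genes if planted not in ann.propagated[g]]
    # stratified draw: the study set's theme-gene count is binomial at
    # enrichment_factor times the background share (capped), so the
    # realized fold-enrichment is centered on enrichment_factor
    bg_share = len(theme_genes) / config.n_genes
    target_share = min(config.enrichment_factor * bg_share, 0.9)
    k_theme = int(rng.binomial(config.n_study, target_share))
    k_theme = min(k_theme, len(theme_genes))
    k_other = min(config.n_study - k_theme, len(other_genes))
    study = sorted(
        [theme_genes[i] for i in rng.choice(len(theme_genes), size=k_theme,
                                            replace=False)]
        + [other_genes[i] for i in rng.choice(len(other_genes), size=k_other,
                                              replace=False)]
    )

    k_planted = sum(1 for g in study if planted in ann.propagated[g])
    bg_planted = len(theme_genes)
    fold = ((k_planted / config.n_study) / (bg_planted / config.n_genes)
            if bg_planted else float("nan"))
    truth = {
        "planted_term": planted,
        "k_study": k_planted,
        "K_background": bg_planted,
        "realized_fold": fold,
    }
    return ann, study, truth


# --------------------------------------------------------------------------
# genotypes


def genotype_probs(maf: float, inbreeding_f: float) -> tuple[float, float, float]:
    """(P_ref_hom, P_het, P_alt_hom) with inbreeding coefficient F.

    F = 0 gives exact Hardy-Weinberg proportions; F = 1 removes all
    heterozygotes; F = -1 (at maf 0.5) removes all homozygotes.
    """
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    q = maf
    p = 1.0 - q
    probs = (p * p + inbreeding_f * p * q,
             2 * p * q * (1 - inbreeding_f),
             q * q + inbreeding_f * p * q)
    if any(pr < -1e-12 for pr in probs):
        raise ValueError(
            f"F={inbreeding_f} is too negative for maf={maf}: "
            f"genotype probabilities {probs}")
    return tuple(max(0.0, pr) for pr in probs)


def gen_genotypes(config: SimConfig, n_variants: int = 1) -> list[tuple[int, int, int]]:
    """Multinomial genotype count trios for *n_variants* variants."""
    if config.n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = config.rng("genotypes")
    probs = genotype_probs(config.maf, config.inbreeding_f)
    draws = rng.multinomial(config.n_subjects, probs, size=n_variants)
    return [tuple(int(c) for c in row) for row in draws]


# --------------------------------------------------------------------------
# variant-count vs gene-length tables


def _length_slope(config: SimConfig) -> float:
    """Mixing weight alpha of the affine Poisson rate
    lam = mu*(1 - alpha + alpha*L/mean(L)) such that the population
    correlation corr(L, Y) equals target_rho (clipped where unattainable)."""
    lo, hi = config.length_range
    mean_l = (lo + hi) / 2.0
    var_l = (hi - lo) ** 2 / 12.0
    rho, mu = config.target_rho, config.mean_count
    if rho == 0:
        return 0.0
    alpha = abs(rho) * mean_l / math.sqrt((1 - rho * rho) * var_l * mu)
    # keep the rate nonnegative at the shortest gene
    alpha_max = 1.0 / (1.0 - lo / mean_l)
    return math.copysign(min(alpha, alpha_max), rho)


def gen_variant_table(config: SimConfig) -> list[tuple[str, int, int]]:
    """(gene, length, variant count) rows with corr(length, count) near
    target_rho: lengths uniform on length_range, counts Poisson with a
    rate affine in length; short genes naturally draw zero counts."""
    if config.n_panel_genes < 4:
        raise ValueError("need at least 4 panel genes")
    rng = config.rng("variant_table")
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_panel_genes)
    mean_l = (lo + hi) / 2.0
    alpha = _length_slope(config)
    lam = config.mean_count * (1.0 - alpha + alpha * lengths / mean_l)
    lam = np.maximum(lam, 0.0)
    counts = rng.poisson(lam)
    return [(f"PG{i:03d}", int(l), int(c))
            for i, (l, c) in enumerate(zip(lengths, counts))]


# --------------------------------------------------------------------------
# file emission (OBO, TSV, VCF, truth JSON)


def write_bundle(config: SimConfig, outdir) -> dict:
    """Generate and write every synthetic input the pipeline consumes:
    ontology.obo, annotations.tsv, study_genes.txt, background_genes.txt,
    genotypes.vcf, variant_table.tsv and truth.json.  Returns the truth
    record."""
    import json
    from pathlib import Path

    from .ontology import write_obo

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    dag = gen_ontology(config)
    write_obo(dag, outdir / "ontology.obo")
    ann, study, truth = gen_annotations_with_planting(dag, config)
    with open(outdir / "annotations.tsv", "w") as fh:
        for gene in sorted(ann.direct):
            for term in sorted(ann.direct[gene]):
                fh.write(f"{gene}\t{term}\n")
    (outdir / "study_genes.txt").write_text("\n".join(study) + "\n")
    (outdir / "background_genes.txt").write_text(
        "\n".join(sorted(ann.background_genes)) + "\n")

    trios = gen_genotypes(config, n_variants=20)
    _write_vcf(trios, config.n_subjects, outdir / "genotypes.vcf")

    table = gen_variant_table(config)
    with open(outdir / "variant_table.tsv", "w") as fh:
        fh.write("gene\tlength\tn_variants\n")
        for gene, length, count in table:
            fh.write(f"{gene}\t{length}\t{count}\n")

    truth = dict(truth, seed=config.seed)
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return truth


def _write_vcf(trios, n_subjects: int, path) -> None:
    """Minimal single-chromosome VCF realizing the given genotype trios."""
    samples = [f"S{i:03d}" for i in range(n_subjects)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=chrS>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i, (n_rr, n_ra, n_aa) in enumerate(trios):
            gts = ["0/0"] * n_rr + ["0/1"] * n_ra + ["1/1"] * n_aa
            gts += ["./."] * (n_subjects - len(gts))
            fh.write(f"chrS\t{1000 + 10 * i}\t.\tA\tG\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
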