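"""Gene-panel assembly and descriptive variant QC.

Covers the amplicon-panel bookkeeping around the sequencing output: panel
assembly with per-subset provenance, variant-location classification
against BED-like gene models (CDS exons, UTRs, gene span, 25 bp padding),
Hardy-Weinberg equilibrium filtering, per-base coverage acceptance, and
the robust (percentage-bend) correlation of per-gene variant counts with
gene length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import t as t_dist

logger = logging.getLogger(__name__)

LOCATION_CLASSES = ("exonic", "utr5", "utr3", "intronic", "intergenic")


# --------------------------------------------------------------------------
# panel assembly


@dataclass
class GenePanel:
    """Gene panel with per-gene subset provenance."""

    entries: list[tuple[str, frozenset[str]]]

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    def subset(self, label: str) -> set[str]:
        return {g for g, labels in self.entries if label in labels}

    def summary(self) -> dict[str, int]:
        s1, s2 = self.subset("subset1"), self.subset("subset2")
        return {
            "subset1": len(s1),
            "subset2": len(s2),
            "intersection": len(s1 & s2),
            "union": len(self.entries),
        }


def intersect_gene_sets(a, b) -> set[str]:
    """Order-insensitive intersection of uppercased gene symbols."""
    return {g.upper() for g in a} & {g.upper() for g in b}


def assemble_panel(subset1, subset2) -> GenePanel:
    """Union of two subsets with per-gene labels recording provenance."""
    if not subset1 or not subset2:
        raise ValueError("both subsets must be nonempty")
    s1 = {g.upper() for g in subset1}
    s2 = {g.upper() for g in subset2}
    entries = []
    for gene in sorted(s1 | s2):
        labels = frozenset(
            lab for lab, s in (("subset1", s1), ("subset2", s2)) if gene in s
        )
        entries.append((gene, labels))
    return GenePanel(entries=entries)


def expected_outcome_count(planned_n: int, cohort_cases: int,
                           cohort_controls: int) -> float:
    """Expected number of case subjects when a planned sample keeps the
    case:control ratio of a reference cohort (planned_n * cases/controls)."""
    if min(planned_n, cohort_cases, cohort_controls) <= 0:
        raise ValueError("all counts must be positive")
    return planned_n * cohort_cases / cohort_controls


# --------------------------------------------------------------------------
# gene models and location classification


@dataclass
class GeneModel:
    """Intervals of one gene, 0-based half-open.

    ``span`` is the genomic extent; ``cds_exons`` / ``utr5`` / ``utr3``
    are labeled sub-intervals; ``padding`` extends the targeted region by
    25 bases on each side (the amplicon design convention).
    """

    gene_symbol: str
    chrom: str
    span: tuple[int, int]
    cds_exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    strand: str = "+"
    padding: int = 25

    def __post_init__(self):
        for name in ("cds_exons", "utr5", "utr3"):
            ivs = sorted(getattr(self, name))
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"{self.gene_symbol}: {name} self-overlap")
            for s, e in ivs:
                if not (self.span[0] <= s < e <= self.span[1]):
                    raise ValueError(
                        f"{self.gene_symbol}: {name} interval outside span")
            setattr(self, name, ivs)

    def contains_padded(self, pos0: int) -> bool:
        return self.span[0] - self.padding <= pos0 < self.span[1] + self.padding

    def locate(self, pos0: int) -> str | None:
        """Location class of a 0-based position, or None if outside the
        padded span."""
        if not self.contains_padded(pos0):
            return None
        for ivs, cls in ((self.cds_exons, "exonic"), (self.utr5, "utr5"),
                         (self.utr3, "utr3")):
            if any(s <= pos0 < e for s, e in ivs):
                return cls
        if self.span[0] <= pos0 < self.span[1]:
            return "intronic"
        return "intergenic"


def read_gene_models(path, padding: int = 25) -> list[GeneModel]:
    """BED-like TSV: chrom, start, end, gene, feature in {span,cds,utr5,utr3},
    strand; 0-based half-open coordinates."""
    raw: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, gene, feature, *rest = line.split("\t")
            gene = gene.upper()
            rec = raw.setdefault(gene, {
                "chrom": chrom, "span": None, "cds": [], "utr5": [], "utr3": [],
                "strand": rest[0] if rest else "+",
            })
            iv = (int(start), int(end))
            if feature == "span":
                rec["span"] = iv
            elif feature in ("cds", "utr5", "utr3"):
                rec[feature].append(iv)
            else:
                raise ValueError(f"unknown feature {feature!r} for {gene}")
    models = []
    for gene, rec in raw.items():
        if rec["span"] is None:
            raise ValueError(f"gene {gene} has no span interval")
        models.append(GeneModel(
            gene_symbol=gene, chrom=rec["chrom"], span=rec["span"],
            cds_exons=rec["cds"], utr5=rec["utr5"], utr3=rec["utr3"],
            strand=rec["strand"], padding=padding,
        ))
    models.sort(key=lambda m: (m.chrom, m.span[0], m.gene_symbol))
    return models


@dataclass
class VariantRecord:
    """One called variant (one per alternate allele) with genotype counts
    (n_ref_hom, n_het, n_alt_hom) relative to that allele."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    genotype_counts: tuple[int, int, int] = (0, 0, 0)
    gene_symbol: str | None = None
    location: str | None = None


def classify_location(variant: VariantRecord, gene_models: list[GeneModel],
                      padding: int | None = None) -> str:
    """Assign a location class and gene to *variant* (mutates and returns).

    Priority within a model: CDS exon -> exonic, then UTRs, then the span
    interior -> intronic, then the padding fringe -> intergenic.  With
    overlapping genes the model whose CDS contains the position wins, else
    the first by genomic order (logged).  Positions outside every padded
    span are intergenic with no gene.
    """
    pos0 = variant.pos - 1
    hits = []
    for model in gene_models:
        if model.chrom != variant.chrom:
            continue
        if padding is not None and padding != model.padding:
            model = GeneModel(model.gene_symbol, model.chrom, model.span,
                              model.cds_exons, model.utr5, model.utr3,
                              model.strand, padding)
        cls = model.locate(pos0)
        if cls is not None:
            hits.append((model, cls))
    if not hits:
        variant.location = "intergenic"
        variant.gene_symbol = None
        return "intergenic"
    if len(hits) > 1:
        exonic = [h for h in hits if h[1] == "exonic"]
        if exonic:
            hits = exonic
        else:
            logger.info("position %s:%d overlaps %d genes; keeping first",
                        variant.chrom, variant.pos, len(hits))
    model, cls = hits[0]
    variant.gene_symbol = model.gene_symbol
    variant.location = cls
    return cls


def read_vcf(path) -> list[VariantRecord]:
    """Read GT genotypes from a VCF; multi-allelic records are decomposed
    into one VariantRecord per alternate allele."""
    from cyvcf2 import VCF

    records = []
    for v in VCF(path):
        for ai, alt in enumerate(v.ALT, start=1):
            counts = [0, 0, 0]
            for g in v.genotypes:
                alleles = [a for a in g[:-1] if a >= 0]
                if len(alleles) != 2:
                    continue
                dose = sum(1 for a in alleles if a == ai)
                counts[dose] += 1
            records.append(VariantRecord(
                chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                genotype_counts=tuple(counts),
            ))
    return records


def variant_location_table(variants: list[VariantRecord]) -> dict:
    """Per-class counts (summing to the total), per-gene totals and the
    genes left without any variant are reported together."""
    by_class = {cls: 0 for cls in LOCATION_CLASSES}
    per_gene: dict[str, int] = {}
    for v in variants:
        if v.location is None:
            raise ValueError(f"unclassified variant at {v.chrom}:{v.pos}")
        by_class[v.location] += 1
        if v.gene_symbol:
            per_gene[v.gene_symbol] = per_gene.get(v.gene_symbol, 0) + 1
    return {
        "by_class": by_class,
        "total": sum(by_class.values()),
        "per_gene": per_gene,
    }


def zero_variant_genes(per_gene: dict[str, int], panel_genes) -> list[str]:
    return sorted(set(g.upper() for g in panel_genes) - set(per_gene))


# --------------------------------------------------------------------------
# Hardy-Weinberg filtering


@dataclass
class HWEResult:
    observed: tuple[int, int, int]
    expected: tuple[float, float, float]
    p_value: float
    retained: bool


def _round_preserving_sum(values, total: int) -> list[int]:
    """Largest-remainder rounding so the rounded trio sums to *total*."""
    floors = [math.floor(v) for v in values]
    remainder = total - sum(floors)
    order = sorted(range(len(values)), key=lambda i: values[i] - floors[i],
                   reverse=True)
    for i in order[:remainder]:
        floors[i] += 1
    return floors


def _log_table_prob(table: list[list[int]]) -> float:
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    n = sum(rows)
    lp = sum(gammaln(r + 1) for r in rows) + sum(gammaln(c + 1) for c in cols)
    lp -= gammaln(n + 1)
    lp -= sum(gammaln(x + 1) for row in table for x in row)
    return lp


def freeman_halton_2x3(table: list[list[int]]) -> float:
    """Exact conditional test (Freeman-Halton extension of Fisher's exact
    test) for a 2x3 contingency table, by full enumeration over tables with
    the observed margins."""
    r1 = sum(table[0])
    cols = [sum(c) for c in zip(*table)]
    lp_obs = _log_table_prob(table)
    p = 0.0
    for a in range(min(r1, cols[0]) + 1):
        for b in range(min(r1 - a, cols[1]) + 1):
            c = r1 - a - b
            if c > cols[2]:
                continue
            cand = [[a, b, c], [cols[0] - a, cols[1] - b, cols[2] - c]]
            lp = _log_table_prob(cand)
            if lp <= lp_obs + 1e-9:
                p += math.exp(lp)
    return min(p, 1.0)


def exact_hwe_test(counts: tuple[int, int, int], midp: bool = False) -> float:
    """Standard exact Hardy-Weinberg test conditioning on allele counts:
    the p-value sums the probabilities of all heterozygote counts no more
    probable than the observed one.

    Exact conditional tests are conservative on a discrete support; with
    ``midp=True`` only half the probability of the observed outcome class
    is counted (the mid-p correction), which brings the realized type-I
    error close to the nominal level.
    """
    n_aa, n_ab, n_bb = counts
    n = n_aa + n_ab + n_bb
    n_b = n_ab + 2 * n_bb  # minor-ish allele count (orientation irrelevant)
    n_b = min(n_b, 2 * n - n_b)

    def log_prob(het: int) -> float:
        hom_b = (n_b - het) // 2
        hom_a = n - het - hom_b
        return (gammaln(n + 1) - gammaln(hom_a + 1) - gammaln(het + 1)
                - gammaln(hom_b + 1) + het * math.log(2)
                + gammaln(n_b + 1) + gammaln(2 * n - n_b + 1) - gammaln(2 * n + 1))

    # het count shares the parity of the minor-allele count, so the
    # observed value always lies on the enumeration grid
    hets = range(n_b % 2, n_b + 1, 2)
    lps = {h: log_prob(h) for h in hets}
    lp_obs = lps[n_ab]
    lower = sum(math.exp(lp) for lp in lps.values() if lp < lp_obs - 1e-9)
    equal = sum(math.exp(lp) for lp in lps.values()
                if abs(lp - lp_obs) <= 1e-9)
    return min(1.0, lower + (0.5 * equal if midp else equal))


def hwe_filter(counts: tuple[int, int, int], alpha: float = 0.05,
               method: str = "fisher_expected") -> HWEResult:
    """Test observed genotype counts against Hardy-Weinberg expectations.

    ``fisher_expected`` (the literal described procedure) runs the exact
    conditional test on the 2x3 table of observed versus rounded expected
    counts (n*p^2, 2n*p*q, n*q^2); ``exact_hwe`` runs the standard exact
    HWE test conditioning on the allele counts, and ``exact_hwe_midp`` its
    mid-p variant (the calibrated choice: the plain exact tests are
    conservative, so they retain more than the nominal 1-alpha under
    equilibrium).  Monomorphic variants are trivially in equilibrium
    (p = 1).  A variant is retained iff p_value >= alpha.
    """
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotyped subject")
    n_aa, n_ab, n_bb = counts
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    if p == 0.0 or q == 0.0:
        return HWEResult(counts, expected, 1.0, True)
    if method == "fisher_expected":
        exp_rounded = _round_preserving_sum(expected, n)
        p_value = freeman_halton_2x3([list(counts), exp_rounded])
    elif method == "exact_hwe":
        p_value = exact_hwe_test(counts)
    elif method == "exact_hwe_midp":
        p_value = exact_hwe_test(counts, midp=True)
    else:
        raise ValueError(f"unknown HWE method {method!r}")
    return HWEResult(counts, expected, p_value, p_value >= alpha)


# --------------------------------------------------------------------------
# coverage acceptance


def coverage_accept(depths, min_depth: int = 20) -> bool:
    """A padded exon region is successfully analyzed iff every per-base
    read depth strictly exceeds *min_depth*."""
    depths = list(depths)
    if not depths:
        raise ValueError("empty region")
    return all(d > min_depth for d in depths)


# --------------------------------------------------------------------------
# percentage-bend correlation


def _bend_vector(x: np.ndarray, beta: float) -> np.ndarray:
    n = len(x)
    med = np.median(x)
    w = np.sort(np.abs(x - med))
    m = int(math.floor((1.0 - beta) * n + 0.5))
    omega = w[m - 1]
    if omega <= 0:
        raise ValueError("constant (or near-constant) vector after bending")
    z = (x - med) / omega
    i1 = int(np.sum(z < -1))
    i2 = int(np.sum(z > 1))
    inner_sum = float(np.sum(x[(z >= -1) & (z <= 1)]))
    phi = (omega * (i2 - i1) + inner_sum) / (n - i1 - i2)
    u = (x - phi) / omega
    return np.clip(u, -1.0, 1.0)


def percentage_bend_correlation(x, y, beta: float = 0.2) -> tuple[float, float]:
    """Percentage-bend correlation coefficient (Wilcox 1994) and two-sided
    p-value.

    For each vector the bend scale is the m-th smallest absolute deviation
    from the median with ``m = floor((1-beta)n + 0.5)``; observations are
    standardized about the bend-adjusted location and clipped to [-1, 1]
    by psi; r is the inner product of the clipped scores normalized by
    their norms.  Significance uses ``T = r*sqrt((n-2)/(1-r^2))`` against
    a t distribution with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if not 0 <= beta < 0.5:
        raise ValueError("beta must be in [0, 0.5)")
    a = _bend_vector(x, beta)
    b = _bend_vector(y, beta)
    r = float(np.sum(a * b) / math.sqrt(np.sum(a * a) * np.sum(b * b)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t_stat = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(t_dist.sf(abs(t_stat), n - 2))
    return r, p
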