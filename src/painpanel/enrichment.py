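"""Over-representation analysis (ORA) of a gene set against a background.

For each ontology term the study-set annotation count is compared with the
background expectation via the upper tail of the hypergeometric
distribution (one-sided Fisher's exact test).  Multiple testing is
controlled with Bonferroni at a conservative threshold, chosen in the
source workflow so that the number of significant terms stays below the
size of the gene set (default t_p = 5e-15).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import hypergeom

from .ontology import AnnotationMap, OntologyDAG, term_to_genes

logger = logging.getLogger(__name__)


@dataclass
class ORAConfig:
    """Configuration of the over-representation analysis.

    p_threshold is the uncorrected significance threshold t_p; with
    ``correction="bonferroni"`` a term is significant iff
    p < p_threshold / m where m is the number of tested terms.
    Terms with fewer than ``min_annotated`` study-set genes are skipped.
    """

    p_threshold: float = 5e-15
    correction: str = "bonferroni"  # or "none"
    min_annotated: int = 1

    def __post_init__(self):
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.min_annotated < 1:
            raise ValueError("min_annotated must be >= 1")


@dataclass
class TermResult:
    """ORA outcome for one term.

    k study-set genes out of n_set are annotated to the term, against K of
    N background genes.
    """

    term_id: str
    k: int
    n_set: int
    K: int
    N: int
    p_value: float
    significant: bool = False
    name: str = ""


def fisher_over(k: int, n_set: int, K: int, N: int) -> float:
    """One-sided over-representation tail P(X >= k), X ~ Hypergeom(N, K, n_set).

    This is the p-value of Fisher's exact test on the 2x2 table
    [[k, n_set-k], [K-k, N-K-n_set+k]] against the over-representation
    alternative.
    """
    if not (0 <= k <= n_set <= N and k <= K <= N):
        raise ValueError(
            f"invalid counts k={k}, n_set={n_set}, K={K}, N={N}"
        )
    if k > n_set or K - k > N - n_set:
        # table impossible under the margins
        raise ValueError(f"impossible table k={k}, n_set={n_set}, K={K}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n_set))


def run_ora(
    dag: OntologyDAG,
    ann: AnnotationMap,
    gene_set,
    config: ORAConfig | None = None,
) -> list[TermResult]:
    """Test every annotated term for over-representation of *gene_set*.

    Symbols absent from the background are dropped with a warning.  Results
    are sorted by ascending p-value with term_id as deterministic tiebreak.
    Only terms with at least one background gene are testable; Bonferroni's
    m counts terms that reach ``config.min_annotated`` study-set genes.
    """
    config = config or ORAConfig()
    study = {g.upper() for g in gene_set}
    dropped = study - ann.background_genes
    if dropped:
        logger.warning("dropping %d symbols absent from background: %s",
                       len(dropped), sorted(dropped))
    study &= ann.background_genes
    if not study:
        raise ValueError("study set is empty after intersecting with background")

    N = len(ann.background_genes)
    n_set = len(study)
    bg_counts = term_to_genes(ann, ann.background_genes)
    study_counts = term_to_genes(ann, study)

    results: list[TermResult] = []
    for term_id, bg_genes in bg_counts.items():
        if term_id not in dag:
            continue
        k = len(study_counts.get(term_id, ()))
        if k < config.min_annotated:
            continue
        p = fisher_over(k, n_set, len(bg_genes), N)
        results.append(TermResult(
            term_id=term_id, k=k, n_set=n_set, K=len(bg_genes), N=N,
            p_value=p, name=dag.terms[term_id].name,
        ))

    m = len(results)
    cutoff = config.p_threshold / m if (config.correction == "bonferroni" and m) \
        else config.p_threshold
    for res in results:
        # cutoff >= 1 is a vacuous threshold: every tested term passes,
        # including p == 1 terms that a strict < would exclude.
        res.significant = res.p_value < cutoff if cutoff < 1 else True
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def significant_terms(results: list[TermResult]) -> list[TermResult]:
    return [r for r in results if r.significant]
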