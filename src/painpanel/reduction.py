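"""Knowledge reduction of significant ontology terms.

The significant terms of an over-representation analysis are condensed in
four steps:

1. **Remarkableness** — each significant term Ti gets
   ``Rem(Ti) = Cert(Ti) * Info(Ti)`` where ``Cert`` is the fraction of
   significant terms with strictly smaller p-value and ``Info`` is the
   partial Shannon information ``-e * p_i * ln(p_i)`` of the annotation
   fraction ``p_i = nG(Ti)/nG`` (normalized to [0, 1], maximal at
   ``p_i = 1/e``).
2. **Details and headlines** — a *detail* is a significant term with no
   significant descendant (the tip of a significant branch); on every path
   from a detail up to a root, the significant term of maximal
   remarkableness is a *headline*.
3. **Computed ABC analysis** — headlines are partitioned into the
   "important few" (set A), the proportional middle (B) and the "trivial
   many" (C) from the cumulative remarkableness curve; set A is retained.
4. **Subsumption** — remaining headlines are repeatedly replaced by a
   common ancestor term until at most 9 *functional areas* remain, aiming
   for Miller's 5-9 range of human-graspable set sizes.

Node classes (structural / significant / detail / headline /
functional_area) drive the DOT rendering of the reduced DAG.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass

import numpy as np

from .enrichment import TermResult
from .ontology import OntologyDAG

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# remarkableness


@dataclass
class TermScore:
    term_id: str
    cert: float
    info: float

    @property
    def rem(self) -> float:
        return self.cert * self.info


def certainty(results: list[TermResult], complement: bool = False) -> dict[str, float]:
    """Rank-based certainty over the significant term set.

    ``Cert(Ti) = |{Tk : p(Tk) < p(Ti)}| / nT`` as printed in the source
    method; with ``complement=True`` the value ``1 - Cert`` is returned
    instead, which rewards rather than penalizes the lowest-p term (the
    printed formula assigns the most significant term certainty 0).
    """
    if not results:
        raise ValueError("certainty requires a nonempty significant term set")
    n_t = len(results)
    pvals = sorted(r.p_value for r in results)
    out = {}
    for r in results:
        # number of strictly smaller p-values == left bisection index
        smaller = bisect.bisect_left(pvals, r.p_value)
        cert = smaller / n_t
        out[r.term_id] = 1.0 - cert if complement else cert
    return out


def information(k: int, n_set: int) -> float:
    """Partial Shannon information of the annotation fraction p = k/n_set.

    ``-e * p * ln(p)``, with the continuity conventions info(0) = 0 and
    info(1) = 0; the maximum 1 is attained at p = 1/e.
    """
    if n_set < 1 or not 0 <= k <= n_set:
        raise ValueError(f"invalid counts k={k}, n_set={n_set}")
    p = k / n_set
    if p == 0.0 or p == 1.0:
        return 0.0
    return -math.e * p * math.log(p)


def score_terms(results: list[TermResult], cert_complement: bool = False
                ) -> dict[str, TermScore]:
    """Remarkableness scores for every significant term in *results*."""
    sig = [r for r in results if r.significant]
    certs = certainty(sig, complement=cert_complement)
    return {
        r.term_id: TermScore(r.term_id, certs[r.term_id],
                             information(r.k, r.n_set))
        for r in sig
    }


# --------------------------------------------------------------------------
# computed ABC analysis


@dataclass
class ABCPartition:
    """Descending-sorted item partition into important few (A), middle (B)
    and trivial many (C)."""

    set_a: list[str]
    set_b: list[str]
    set_c: list[str]
    boundary_ab: int
    boundary_bc: int


def abc_analysis(values: dict[str, float]) -> ABCPartition:
    """Computed ABC analysis of nonnegative item values.

    Items are sorted by descending value; the ABC curve plots cumulative
    item fraction x against cumulative value fraction y.  The A|B boundary
    is the curve point closest (Euclidean) to the ideal point (0, 1); the
    B|C boundary is the first point at or after it where the segment slope
    dy/dx drops to <= 1 (break-even between added effort and added yield).
    Ties in value across a boundary move as one block into the more
    important set; an all-equal input is degenerate (diagonal curve) and is
    split purely by index, with a logged warning.
    """
    if len(values) < 3:
        raise ValueError("ABC analysis requires at least 3 items")
    if any(v < 0 for v in values.values()):
        raise ValueError("ABC analysis requires nonnegative values")
    total = float(sum(values.values()))
    if total == 0:
        raise ValueError("ABC analysis requires a nonzero total")

    items = sorted(values, key=lambda k: (-values[k], k))
    vals = np.array([values[k] for k in items], dtype=float)
    n = len(items)
    x = np.arange(1, n + 1) / n
    y = np.cumsum(vals) / total

    dist2 = x**2 + (1.0 - y) ** 2
    ab = int(np.argmin(dist2)) + 1  # first `ab` items form A

    # slope of segment following point i (x step is 1/n)
    bc = n
    for i in range(ab, n):
        slope = (y[i] - y[i - 1]) * n
        if slope <= 1.0 + 1e-12:
            bc = i
            break

    degenerate = np.allclose(vals, vals[0])
    if degenerate:
        logger.warning("ABC analysis on all-equal values: index-only split")
    else:
        ab = _absorb_ties(vals, ab)
        bc = max(_absorb_ties(vals, bc), ab)

    return ABCPartition(
        set_a=items[:ab], set_b=items[ab:bc], set_c=items[bc:],
        boundary_ab=ab, boundary_bc=bc,
    )


def _absorb_ties(vals: np.ndarray, boundary: int) -> int:
    """Extend *boundary* so a value-tie block stays in the earlier set."""
    while 0 < boundary < len(vals) and vals[boundary] == vals[boundary - 1]:
        boundary += 1
    return boundary


# --------------------------------------------------------------------------
# details, headlines, subsumption


def find_details(dag: OntologyDAG, significant: set[str]) -> set[str]:
    """Significant terms with no significant descendant (branch tips)."""
    if not significant:
        raise ValueError("empty significant set")
    return {
        t for t in significant
        if not (dag.descendants(t) & significant)
    }


def _paths_to_roots(dag: OntologyDAG, start: str) -> list[list[str]]:
    """All distinct upward paths from *start* to any root."""
    paths: list[list[str]] = []
    stack = [[start]]
    while stack:
        path = stack.pop()
        parents = dag.parents(path[-1])
        if not parents:
            paths.append(path)
        else:
            for p in sorted(parents):
                stack.append(path + [p])
    return paths


def find_headlines(
    dag: OntologyDAG, details: set[str], scores: dict[str, TermScore]
) -> set[str]:
    """Per detail->root path maxima of remarkableness among significant terms.

    A headline summarizes its branch: on each distinct upward path from a
    detail to a root, the on-path significant term of maximal rem is
    selected (ties resolved toward the detail, preserving specificity); the
    headline set is the union over all details and paths.
    """
    headlines: set[str] = set()
    for detail in sorted(details):
        paths = _paths_to_roots(dag, detail)
        if not paths:
            raise ValueError(f"detail {detail} has no path to a root")
        for path in paths:
            on_path = [t for t in path if t in scores]
            if not on_path:
                continue
            # path runs detail -> root; max() keeps the first (most
            # specific) term on rem ties
            best = max(on_path, key=lambda t: scores[t].rem)
            headlines.add(best)
    return headlines


def select_important_headlines(
    headlines: set[str], scores: dict[str, TermScore]
) -> list[str]:
    """ABC set A of the headlines by remarkableness (all if fewer than 3)."""
    if len(headlines) < 3:
        logger.warning("fewer than 3 headlines; keeping all")
        return sorted(headlines)
    part = abc_analysis({h: scores[h].rem for h in headlines})
    return part.set_a


def subsume(
    dag: OntologyDAG,
    headlines,
    target_range: tuple[int, int] = (5, 9),
) -> list[str]:
    """Abstract headlines to at most ``target_range[1]`` functional areas.

    While the set exceeds the upper bound, the deepest ontology terms that
    are ancestors of (or equal to) at least two current members replace
    the members they cover — all covering terms of that deepest level
    merge in the same iteration, so sibling branches abstract together
    (twelve headlines under three disjoint parents collapse to the three
    parents in one pass).  Depth is the longest distance to a root; within
    a level, terms covering more members merge first, ties broken
    lexicographically.  Miller's lower bound is a soft target: a batch
    that lands below it is accepted when no smaller abstraction exists.
    If no term covers two members the irreducible set is returned with a
    warning.
    """
    _lower, upper = target_range
    current = set(headlines)
    depths = dag.depths()
    while len(current) > upper:
        candidates = []
        for term in dag.terms:
            covered = frozenset(h for h in current
                                if h == term or term in dag.ancestors(h))
            if len(covered) >= 2:
                candidates.append((term, covered))
        if not candidates:
            logger.warning(
                "no common ancestor merges %d headlines below %d",
                len(current), upper,
            )
            break
        deepest = max(depths[t] for t, _ in candidates)
        batch = sorted(
            (c for c in candidates if depths[c[0]] == deepest),
            key=lambda c: (-len(c[1]), c[0]),
        )
        consumed: set[str] = set()
        for term, covered in batch:
            fresh = covered - consumed
            if len(fresh & current) >= 2:
                current = (current - fresh) | {term}
                consumed |= fresh | {term}
    return sorted(current)


# --------------------------------------------------------------------------
# node classification and rendering


NODE_CLASSES = ("structural", "significant", "detail", "headline", "functional_area")

_DOT_STYLE = {
    "structural": ("white", "black"),
    "significant": ("red", "black"),
    "detail": ("green", "blue"),
    "headline": ("yellow", "black"),
    "functional_area": ("violet", "black"),
}


def classify_nodes(
    dag: OntologyDAG,
    results: list[TermResult],
    details: set[str],
    headlines: set[str],
    areas,
) -> dict[str, str]:
    """Most specific applicable class per term.

    Precedence: functional_area > headline > detail > significant >
    structural (a term that is both detail and headline renders as a
    headline).
    """
    significant = {r.term_id for r in results if r.significant}
    areas = set(areas)
    classes = {}
    for term_id in dag.terms:
        if term_id in areas:
            cls = "functional_area"
        elif term_id in headlines:
            cls = "headline"
        elif term_id in details:
            cls = "detail"
        elif term_id in significant:
            cls = "significant"
        else:
            cls = "structural"
        classes[term_id] = cls
    return classes


def to_dot(dag: OntologyDAG, classes: dict[str, str] | None = None,
           restrict: set[str] | None = None) -> str:
    """Graphviz DOT rendering of the (classified) DAG, edges child <- parent.

    Colors follow the reduced-DAG convention: uncolored structural nodes,
    red significant, green details (blue label), yellow headlines, violet
    functional areas.
    """
    classes = classes or {}
    lines = ["digraph ontology {", "  rankdir=BT;",
             '  node [shape=ellipse, style=filled];']
    nodes = sorted(restrict) if restrict is not None else sorted(dag.terms)
    node_set = set(nodes)
    for term_id in nodes:
        cls = classes.get(term_id, "structural")
        fill, font = _DOT_STYLE[cls]
        name = dag.terms[term_id].name or term_id
        label = f"{term_id}\\n{name}" if name != term_id else term_id
        lines.append(
            f'  "{term_id}" [label="{label}", fillcolor="{fill}", '
            f'fontcolor="{font}"];'
        )
    for child, parent, relation in dag.edges():
        if child in node_set and parent in node_set:
            style = "solid" if relation == "is_a" else "dashed"
            lines.append(
                f'  "{child}" -> "{parent}" [label="{relation}", style={style}];'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"


def reduce_terms(
    dag: OntologyDAG,
    results: list[TermResult],
    cert_complement: bool = False,
    target_range: tuple[int, int] = (5, 9),
):
    """Full reduction: scores -> details -> headlines -> ABC set A -> areas.

    Returns a dict with scores, details, headlines, important headlines
    (ABC set A), functional areas and per-term node classes.  With no
    significant terms everything is empty.
    """
    sig = {r.term_id for r in results if r.significant}
    if not sig:
        return {
            "scores": {}, "details": set(), "headlines": set(),
            "important_headlines": [], "areas": [],
            "classes": classify_nodes(dag, results, set(), set(), []),
        }
    scores = score_terms(results, cert_complement=cert_complement)
    details = find_details(dag, sig)
    headlines = find_headlines(dag, details, scores)
    important = select_important_headlines(headlines, scores)
    areas = subsume(dag, important, target_range)
    classes = classify_nodes(dag, results, details, headlines, areas)
    return {
        "scores": scores, "details": details, "headlines": headlines,
        "important_headlines": important, "areas": areas, "classes": classes,
    }
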