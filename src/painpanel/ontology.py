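"""Ontology DAG handling and gene-annotation propagation.

The Gene Ontology (and the synthetic ontologies produced by
:mod:`painpanel.simulate`) is a polyhierarchy of terms linked by ``is_a``,
``part_of`` and ``regulates`` edges, forming a directed acyclic graph with
general roots and specific leaves.  Genes carry *direct* annotations to
terms; under the true-path rule a gene annotated to a term is implicitly
annotated to every ancestor of that term.  This module parses OBO flat
files into a validated :class:`OntologyDAG`, propagates annotations up the
graph, and counts study-set genes per term (the ``nG(Ti)`` numerators of the
over-representation analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Edge relations treated as ancestry under the true-path rule.
ANCESTRY_RELATIONS = ("is_a", "part_of", "regulates")

# GO uses positively/negatively_regulates as sub-relations of regulates.
_RELATION_ALIASES = {
    "positively_regulates": "regulates",
    "negatively_regulates": "regulates",
}


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies (cycles, dangling ids)."""


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology term with its typed parent links."""

    term_id: str
    name: str = ""
    namespace: str = "biological_process"
    #: list of (parent term_id, relation) pairs
    parents: tuple[tuple[str, str], ...] = ()


class OntologyDAG:
    """A validated term polyhierarchy.

    Edges are stored child -> parent in a :class:`networkx.MultiDiGraph`
    keyed by relation, so graph "descendants" of a term in the underlying
    graph are its ontological ancestors.
    """

    def __init__(self, terms: Iterable[OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = {}
        graph = nx.MultiDiGraph()
        for term in terms:
            if term.term_id in self.terms:
                raise OntologyError(f"duplicate term id {term.term_id}")
            self.terms[term.term_id] = term
            graph.add_node(term.term_id)
        for term in self.terms.values():
            for parent_id, relation in term.parents:
                if parent_id not in self.terms:
                    raise OntologyError(
                        f"term {term.term_id} references unknown parent {parent_id}"
                    )
                graph.add_edge(term.term_id, parent_id, key=relation)
        if not nx.is_directed_acyclic_graph(graph):
            edge = nx.find_cycle(graph)[0]
            raise OntologyError(
                f"ontology contains a cycle, e.g. edge {edge[0]} -> {edge[1]}"
            )
        self._graph = graph
        self._ancestor_cache: dict[tuple[str, ...], dict[str, frozenset[str]]] = {}

    # -- basic structure ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    @property
    def roots(self) -> set[str]:
        """Terms with no parents."""
        return {t for t in self._graph if self._graph.out_degree(t) == 0}

    @property
    def leaves(self) -> set[str]:
        """Terms with no children."""
        return {t for t in self._graph if self._graph.in_degree(t) == 0}

    def edges(self) -> list[tuple[str, str, str]]:
        """(child, parent, relation) triples."""
        return sorted(self._graph.edges(keys=True))

    def parents(self, term_id: str, relations: tuple[str, ...] = ANCESTRY_RELATIONS) -> set[str]:
        return {
            p
            for _, p, rel in self._graph.out_edges(term_id, keys=True)
            if rel in relations
        }

    def children(self, term_id: str, relations: tuple[str, ...] = ANCESTRY_RELATIONS) -> set[str]:
        return {
            c
            for c, _, rel in self._graph.in_edges(term_id, keys=True)
            if rel in relations
        }

    # -- traversal ---------------------------------------------------------

    def ancestors(
        self, term_id: str, relations: tuple[str, ...] = ANCESTRY_RELATIONS
    ) -> frozenset[str]:
        """All proper ancestors of *term_id* over the given relations."""
        return self._closure(relations)[term_id]

    def descendants(
        self, term_id: str, relations: tuple[str, ...] = ANCESTRY_RELATIONS
    ) -> frozenset[str]:
        """All proper descendants of *term_id* over the given relations."""
        closure = self._closure(relations)
        return frozenset(t for t, anc in closure.items() if term_id in anc)

    def _closure(self, relations: tuple[str, ...]) -> dict[str, frozenset[str]]:
        key = tuple(sorted(relations))
        if key not in self._ancestor_cache:
            closure: dict[str, frozenset[str]] = {}
            # edges run child -> parent, so reverse the topological order
            # to visit parents before children
            order = reversed(list(nx.topological_sort(self._restricted(relations))))
            for term_id in order:
                acc: set[str] = set()
                for parent in self.parents(term_id, relations):
                    acc.add(parent)
                    acc |= closure[parent]
                closure[term_id] = frozenset(acc)
            self._ancestor_cache[key] = closure
        return self._ancestor_cache[key]

    def _restricted(self, relations: tuple[str, ...]) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._graph)
        g.add_edges_from(
            (c, p) for c, p, rel in self._graph.edges(keys=True) if rel in relations
        )
        return g

    def depths(self, relations: tuple[str, ...] = ANCESTRY_RELATIONS) -> dict[str, int]:
        """Longest distance from any root, per term (roots have depth 0)."""
        depths: dict[str, int] = {}
        order = reversed(list(nx.topological_sort(self._restricted(relations))))
        for term_id in order:
            parent_ids = self.parents(term_id, relations)
            depths[term_id] = 1 + max((depths[p] for p in parent_ids), default=-1)
        return depths


@dataclass
class AnnotationMap:
    """Gene -> term incidence before and after true-path propagation."""

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]
    background_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.background_genes:
            self.background_genes = frozenset(self.propagated)


def parse_obo(path, namespace: str | None = "biological_process") -> OntologyDAG:
    """Parse an OBO 1.2/1.4 flat file into a validated :class:`OntologyDAG`.

    Obsolete stanzas are dropped (never loaded).  Edge relations other than
    is_a / part_of / regulates are ignored with a logged warning; the GO
    sub-relations positively/negatively_regulates are folded into regulates.

    Parameters
    ----------
    path : str or file-like
        OBO source.
    namespace : str or None
        Keep only terms of this namespace (GO convention: the analysis runs
        on ``biological_process``).  ``None`` keeps every namespace.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    keep = {
        node
        for node, data in graph.nodes(data=True)
        if namespace is None or data.get("namespace", namespace) == namespace
    }
    dangling = [n for n in graph if "name" not in graph.nodes[n]]
    if dangling:
        raise OntologyError(f"dangling parent ids referenced: {sorted(dangling)[:5]}")

    terms = []
    dropped_relations: set[str] = set()
    for node in sorted(keep):
        data = graph.nodes[node]
        parents = []
        for _, parent, relation in graph.out_edges(node, keys=True):
            relation = _RELATION_ALIASES.get(relation, relation)
            if relation not in ANCESTRY_RELATIONS:
                dropped_relations.add(relation)
                continue
            if parent in keep:
                parents.append((parent, relation))
        terms.append(
            OntologyTerm(
                term_id=node,
                name=data.get("name", ""),
                namespace=data.get("namespace", namespace or "biological_process"),
                parents=tuple(sorted(parents)),
            )
        )
    if dropped_relations:
        logger.warning("ignored edge relations: %s", sorted(dropped_relations))
    return OntologyDAG(terms)


def write_obo(dag: OntologyDAG, path) -> None:
    """Write a minimal OBO 1.2 flat file (round-trips through parse_obo)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term_id in sorted(dag.terms):
            term = dag.terms[term_id]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term.term_id}\n")
            fh.write(f"name: {term.name or term.term_id}\n")
            fh.write(f"namespace: {term.namespace}\n")
            for parent_id, relation in term.parents:
                if relation == "is_a":
                    fh.write(f"is_a: {parent_id}\n")
                else:
                    fh.write(f"relationship: {relation} {parent_id}\n")


def read_gene_list(path) -> list[str]:
    """Newline-delimited gene symbols, uppercased, de-duplicated in order."""
    seen: dict[str, None] = {}
    with open(path) as fh:
        for line in fh:
            symbol = line.strip().upper()
            if symbol and not symbol.startswith("#"):
                if symbol in seen:
                    logger.warning("duplicate gene symbol %s collapsed", symbol)
                seen[symbol] = None
    return list(seen)


def read_annotations(path) -> dict[str, frozenset[str]]:
    """Two-column TSV gene<TAB>term_id -> direct annotation mapping."""
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term_id = line.split("\t")[:2]
            direct.setdefault(gene.upper(), set()).add(term_id)
    return {g: frozenset(ts) for g, ts in direct.items()}


def propagate(
    dag: OntologyDAG,
    direct: Mapping[str, Iterable[str]],
    relations: tuple[str, ...] = ANCESTRY_RELATIONS,
    background_genes: Iterable[str] | None = None,
) -> AnnotationMap:
    """Apply the true-path rule: annotate every gene to all ancestors.

    Raises
    ------
    OntologyError
        If any annotated term is absent from *dag* (all offenders listed).
    """
    unknown = sorted(
        {t for terms in direct.values() for t in terms if t not in dag}
    )
    if unknown:
        raise OntologyError(f"annotations reference unknown terms: {unknown}")
    direct_frozen = {g.upper(): frozenset(ts) for g, ts in direct.items()}
    propagated = {}
    for gene, terms in direct_frozen.items():
        closed = set(terms)
        for t in terms:
            closed |= dag.ancestors(t, relations)
        propagated[gene] = frozenset(closed)
    background = frozenset(
        g.upper() for g in background_genes
    ) if background_genes is not None else frozenset(propagated)
    return AnnotationMap(direct=direct_frozen, propagated=propagated,
                         background_genes=background)


def term_gene_count(ann: AnnotationMap, term_id: str, gene_set: Iterable[str]) -> int:
    """Number of genes in *gene_set* annotated (after propagation) to *term_id*."""
    return sum(1 for g in set(gene_set) if term_id in ann.propagated.get(g, ()))


def term_to_genes(ann: AnnotationMap, gene_set: Iterable[str]) -> dict[str, set[str]]:
    """Invert the propagated map restricted to *gene_set* (term -> genes)."""
    inverted: dict[str, set[str]] = {}
    for gene in set(gene_set):
        for term in ann.propagated.get(gene, ()):
            inverted.setdefault(term, set()).add(gene)
    return inverted
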