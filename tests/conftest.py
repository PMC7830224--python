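import pytest

from painpanel.ontology import OntologyDAG, OntologyTerm
from painpanel.simulate import SimConfig, gen_ontology


def make_dag(edges, extra_terms=()):
    """Build a DAG from (child, parent, relation) triples."""
    parents = {}
    nodes = set(extra_terms)
    for child, parent, rel in edges:
        parents.setdefault(child, []).append((parent, rel))
        nodes.update((child, parent))
    return OntologyDAG(
        OntologyTerm(term_id=n, name=n, namespace="synthetic",
                     parents=tuple(sorted(parents.get(n, ()))))
        for n in sorted(nodes)
    )


@pytest.fixture
def chain_dag():
    """root <- a <- b (is_a)."""
    return make_dag([("b", "a", "is_a"), ("a", "root", "is_a")])


@pytest.fixture
def diamond_dag():
    """Two paths from d to root: d <- {l, r} <- root."""
    return make_dag([
        ("d", "l", "is_a"), ("d", "r", "part_of"),
        ("l", "root", "is_a"), ("r", "root", "is_a"),
    ])


@pytest.fixture(scope="session")
def random_dag():
    """200-term synthetic DAG shared across structural tests."""
    return gen_ontology(SimConfig(seed=11, n_terms=200))


def brute_force_ancestors(dag, term_id):
    """Independent reachability oracle: BFS over the raw parent lists."""
    seen = set()
    frontier = [term_id]
    while frontier:
        node = frontier.pop()
        for parent, _rel in dag.terms[node].parents:
            if parent not in seen:
                seen.add(parent)
                frontier.append(parent)
    return seen
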