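import math

import pytest

from simpheny.ontology import (
    AnnotationCorpus,
    OntologyGraph,
    OntologyTerm,
    compute_information_content,
)


def build_graph(edges: dict[str, set[str]], root: str = "R") -> OntologyGraph:
    """Graph from {term: parent set}; names equal ids."""
    terms = {
        t: OntologyTerm(term_id=t, name=t, parents=frozenset(parents))
        for t, parents in edges.items()
    }
    return OntologyGraph(terms=terms, root_id=root)


@pytest.fixture
def toy_graph():
    """R -> {A, B}; A -> {A1, A2}; 4 diseases giving freq(A)=1/2, freq(A1)=freq(A2)=1/4."""
    g = build_graph(
        {"R": set(), "A": {"R"}, "B": {"R"}, "A1": {"A"}, "A2": {"A"}}
    )
    corpus = AnnotationCorpus(
        {"d1": {"A1"}, "d2": {"A2"}, "d3": {"B"}, "d4": {"B"}}
    )
    compute_information_content(g, corpus)
    return g


@pytest.fixture
def toy_corpus():
    return AnnotationCorpus({"d1": {"A1"}, "d2": {"A2"}, "d3": {"B"}, "d4": {"B"}})


CHAIN_OBO = """format-version: 1.2

[Term]
id: T:0000001
name: root

[Term]
id: T:0000002
name: child
is_a: T:0000001 ! root

[Term]
id: T:0000003
name: grandchild
is_a: T:0000002 ! child
"""

# Two branches under a root; parent sets are hand-enumerated in tests.
TWO_BRANCH_OBO = """format-version: 1.2

[Term]
id: T:0000001
name: root

[Term]
id: T:0000002
name: left
is_a: T:0000001

[Term]
id: T:0000003
name: right
is_a: T:0000001

[Term]
id: T:0000004
name: left-1
is_a: T:0000002

[Term]
id: T:0000005
name: left-2
is_a: T:0000002

[Term]
id: T:0000006
name: right-1
is_a: T:0000003

[Term]
id: T:0000007
name: both-parents
is_a: T:0000004
is_a: T:0000006
"""


@pytest.fixture
def chain_obo(tmp_path):
    p = tmp_path / "chain.obo"
    p.write_text(CHAIN_OBO)
    return p


@pytest.fixture
def two_branch_obo(tmp_path):
    p = tmp_path / "two_branch.obo"
    p.write_text(TWO_BRANCH_OBO)
    return p
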