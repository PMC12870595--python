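"""Phenotype ontology handling.

Loads an OBO-format ontology into a lightweight DAG, computes per-term
annotation frequencies and information content (IC) from a disease
annotation corpus, curates phenotype term sets against an exclusion list,
and assigns term sets to top-level disease categories.

The ontology is a rooted DAG of phenotype terms (HPO or a synthetic
stand-in).  A term's *frequency* is the fraction of annotated diseases
carrying the term or any of its descendants (true-path rule), and its
information content is ``IC = -log(frequency)``: rarer, more specific
terms carry more information.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

__all__ = [
    "OntologyTerm",
    "OntologyGraph",
    "AnnotationCorpus",
    "OboStructureError",
    "load_obo",
    "ancestors",
    "compute_information_content",
    "read_annotations",
    "read_exclusion_list",
    "curate_phenotypes",
    "assign_disease_category",
]

#: Conventional label of the node whose first-level children define the
#: top-level disease categories (23 of them in the real HPO).
CATEGORY_ROOT_NAME = "phenotypic abnormality"


class OboStructureError(ValueError):
    """The OBO file is readable but structurally invalid (cycle, dangling parent)."""


@dataclass
class OntologyTerm:
    """A single phenotype term.

    ``frequency`` is the descendant-inclusive annotation frequency in
    ``(0, 1]`` once a corpus has been loaded; ``information_content`` is
    ``-log(frequency)`` in the configured base (natural log by default).
    """

    term_id: str
    name: str
    parents: frozenset[str]
    frequency: float | None = None
    information_content: float | None = None


@dataclass
class OntologyGraph:
    """A rooted DAG of phenotype terms with memoized ancestor closures."""

    terms: dict[str, OntologyTerm]
    root_id: str
    top_level_ids: list[str] = field(default_factory=list)
    _closures: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Reflexive-transitive closure over ``is_a`` links (includes the term)."""
        if term_id not in self.terms:
            raise KeyError(f"unknown term: {term_id!r}")
        cached = self._closures.get(term_id)
        if cached is not None:
            return cached
        # Iterative DFS; memoizes every closure it completes along the way.
        out: set[str] = {term_id}
        stack = list(self.terms[term_id].parents)
        while stack:
            t = stack.pop()
            hit = self._closures.get(t)
            if hit is not None:
                out |= hit
                continue
            if t in out:
                continue
            out.add(t)
            stack.extend(self.terms[t].parents)
        closure = frozenset(out)
        self._closures[term_id] = closure
        return closure

    def ic(self, term_id: str) -> float:
        term = self.terms[term_id]
        if term.information_content is None:
            raise ValueError(
                "information content not computed; call compute_information_content first"
            )
        return term.information_content

    def _invalidate_caches(self) -> None:
        # Similarity code attaches a precomputed cache under this attribute.
        self.__dict__.pop("_semsim", None)


@dataclass
class AnnotationCorpus:
    """Disease-to-term annotations used to derive term frequencies."""

    disease_to_terms: dict[str, set[str]]

    @property
    def n_diseases(self) -> int:
        return len(self.disease_to_terms)


def load_obo(path) -> OntologyGraph:
    """Load an OBO 1.2 flat file into an :class:`OntologyGraph`.

    Obsolete terms are dropped.  Raises :class:`OboStructureError` for
    cyclic ``is_a`` structure or ``is_a`` lines pointing at undeclared
    terms, and the underlying I/O error for unreadable files.
    """
    g = obonet.read_obo(path, ignore_obsolete=True)
    # obonet creates a bare attribute-less node for an is_a target that has
    # no [Term] stanza of its own.
    dangling = [n for n, data in g.nodes(data=True) if not data]
    if dangling:
        raise OboStructureError(
            f"is_a references unknown term(s): {sorted(dangling)[:5]}"
        )
    isa = nx.DiGraph()
    isa.add_nodes_from(g.nodes)
    isa.add_edges_from((u, v) for u, v, k in g.edges(keys=True) if k == "is_a")
    if not nx.is_directed_acyclic_graph(isa):
        cycle_member = next(iter(nx.find_cycle(isa)))[0]
        raise OboStructureError(f"is_a cycle detected involving {cycle_member!r}")

    terms: dict[str, OntologyTerm] = {}
    for node, data in g.nodes(data=True):
        parents = frozenset(isa.successors(node))
        terms[node] = OntologyTerm(term_id=node, name=data.get("name", node), parents=parents)

    roots = sorted(t for t, term in terms.items() if not term.parents)
    if not roots:
        raise OboStructureError("ontology has no root term")
    if len(roots) > 1:
        raise OboStructureError(f"ontology has multiple roots: {roots}")
    graph = OntologyGraph(terms=terms, root_id=roots[0])
    graph.top_level_ids = _find_top_level(graph)
    return graph


def _find_top_level(graph: OntologyGraph) -> list[str]:
    """First-level children of the phenotypic-abnormality node.

    If no term carries that label (synthetic ontologies may root the
    phenotype subtree directly), the children of the root are used.
    """
    category_root = graph.root_id
    for tid, term in graph.terms.items():
        if term.name.strip().lower() == CATEGORY_ROOT_NAME:
            category_root = tid
            break
    children = [
        tid for tid, term in graph.terms.items() if category_root in term.parents
    ]
    return sorted(children)


def ancestors(graph: OntologyGraph, term_id: str) -> frozenset[str]:
    """Self-inclusive ancestor closure of ``term_id``."""
    return graph.ancestors(term_id)


def read_annotations(path) -> AnnotationCorpus:
    """Read a disease-annotation TSV with header ``disease_id<TAB>term_id``.

    One (disease, term) pair per row; ``#`` comment lines ignored.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"disease_id", "term_id"} <= set(df.columns):
        raise ValueError("annotation table needs 'disease_id' and 'term_id' columns")
    mapping: dict[str, set[str]] = {}
    for disease, term in zip(df["disease_id"], df["term_id"]):
        mapping.setdefault(disease, set()).add(term)
    return AnnotationCorpus(disease_to_terms=mapping)


def read_exclusion_list(path) -> set[str]:
    """Exclusion list: one term id per line; blank and ``#`` lines skipped."""
    with open(path) as fh:
        return {
            line.strip()
            for line in fh
            if line.strip() and not line.startswith("#")
        }


def compute_information_content(
    graph: OntologyGraph,
    corpus: AnnotationCorpus,
    *,
    log_base: float | None = None,
) -> OntologyGraph:
    """Compute descendant-inclusive term frequencies and IC in place.

    For every term, ``frequency`` is the number of diseases annotated to
    the term or any descendant, divided by the number of diseases; a term
    with no annotations anywhere below it is smoothed to
    ``1 / (n_diseases + 1)`` so its IC stays finite.  ``IC = -log(freq)``
    (natural log unless ``log_base`` is given).  Mutates and returns
    ``graph``.
    """
    if corpus.n_diseases == 0:
        raise ValueError("empty annotation corpus")
    unknown = {
        t for ts in corpus.disease_to_terms.values() for t in ts if t not in graph
    }
    if unknown:
        raise KeyError(f"annotated term(s) absent from ontology: {sorted(unknown)[:5]}")

    covered: dict[str, set[str]] = {tid: set() for tid in graph.terms}
    for disease, term_set in corpus.disease_to_terms.items():
        hit: set[str] = set()
        for t in term_set:
            hit |= graph.ancestors(t)
        for a in hit:
            covered[a].add(disease)

    n = corpus.n_diseases
    log = math.log if log_base is None else (lambda x: math.log(x, log_base))
    for tid, term in graph.terms.items():
        k = len(covered[tid])
        freq = k / n if k else 1.0 / (n + 1)
        term.frequency = freq
        term.information_content = -log(freq) or 0.0  # normalize -0.0
    graph._invalidate_caches()
    return graph


def curate_phenotypes(
    terms: Iterable[str],
    exclusion_list: Iterable[str],
    *,
    graph: OntologyGraph | None = None,
    remove_descendants: bool = False,
) -> set[str]:
    """Remove excluded terms (e.g. prenatal/perinatal history) from a term set.

    Matching is exact by term id; with ``remove_descendants`` (requires
    ``graph``) every term whose ancestor closure touches the exclusion
    list is removed too.  A warning is emitted when curation empties the
    set.
    """
    terms = set(terms)
    excluded = set(exclusion_list)
    if remove_descendants:
        if graph is None:
            raise ValueError("remove_descendants requires the ontology graph")
        kept = {t for t in terms if not (graph.ancestors(t) & excluded)}
    else:
        kept = terms - excluded
    if terms and not kept:
        warnings.warn("phenotype curation removed every term", stacklevel=2)
    return kept


def assign_disease_category(
    graph: OntologyGraph, terms: Iterable[str]
) -> tuple[str, dict[str, float]]:
    """Assign a term set to the top-level category with highest cumulative IC.

    Each input term adds its IC once to the score of every top-level
    ancestor it reaches; the winning category is the argmax, ties broken
    by lexicographically smaller term id.  Terms that reach no top-level
    category are skipped with a warning.
    """
    terms = set(terms)
    if not terms:
        raise ValueError("cannot categorize an empty term set")
    top = set(graph.top_level_ids)
    scores: dict[str, float] = {t: 0.0 for t in graph.top_level_ids}
    for t in terms:
        hit = graph.ancestors(t) & top
        if not hit:
            warnings.warn(
                f"term {t!r} is not under any top-level category; skipped",
                stacklevel=2,
            )
            continue
        ic = graph.ic(t)
        for cat in hit:
            scores[cat] += ic
    best = min(scores, key=lambda c: (-scores[c], c))
    return best, scores
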