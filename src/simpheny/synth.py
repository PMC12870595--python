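"""Synthetic ontologies and cohorts with controllable phenotypic signal.

Emulates the structure the matching framework sees in practice: a rooted
phenotype DAG with a fixed number of top-level disease categories and
right-skewed term frequencies; diagnosed reference patients whose terms
are drawn from a gene-specific term pool (a subtree neighborhood, so the
phenotypic signal respects ontology structure) plus uniform noise; and
query patients built the same way whose candidate gene lists contain the
causal gene among frequency-weighted decoys.

``signal_frac`` is the dial between a pure null (0: patient terms carry
no information about the causal gene) and perfectly penetrant phenotypes
(1: every term comes from the gene's pool).  All randomness flows from
the single ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matching import PatientProfile, ReferencePatient
from .nulls import GeneCorpus
from .ontology import AnnotationCorpus, OntologyGraph, OntologyTerm, compute_information_content

__all__ = [
    "SynthConfig",
    "SynthCohort",
    "generate_ontology",
    "generate_cohort",
    "generate",
    "write_obo",
    "write_annotations",
    "write_patients_tsv",
    "write_gene_corpus",
    "write_truth",
]


@dataclass
class SynthConfig:
    """Knobs of the synthetic study.

    Defaults mirror a small but structurally faithful rare-disease
    setting: 23 top-level categories (as in the real phenotype
    ontology), three-level subtrees, 20 genes each diagnosed in 3
    reference patients, 12 terms per patient of which 70% come from the
    causal gene's pool, and candidate lists of the causal gene plus 5
    popularity-weighted decoys.
    """

    seed: int = 0
    n_top_level: int = 23
    depth: int = 3
    branching: int = 3
    n_diseases: int = 150
    terms_per_disease: int = 6
    n_genes: int = 20
    refs_per_gene: int = 3
    n_queries: int = 40
    terms_per_patient: int = 12
    signal_frac: float = 0.7
    decoy_genes_per_query: int = 5
    extra_edge_frac: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.signal_frac <= 1.0:
            raise ValueError("signal_frac must lie in [0, 1]")
        if self.refs_per_gene < 1:
            raise ValueError("refs_per_gene must be >= 1")
        for name in (
            "n_top_level", "depth", "branching", "n_diseases",
            "terms_per_disease", "n_genes", "n_queries", "terms_per_patient",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class SynthCohort:
    graph: OntologyGraph
    corpus: AnnotationCorpus
    references: list[ReferencePatient]
    queries: list[PatientProfile]
    truth: dict[str, frozenset[str]]
    gene_corpus: GeneCorpus
    gene_pools: dict[str, list[str]] = field(default_factory=dict)


def _tid(i: int) -> str:
    return f"SP:{i:07d}"


def generate_ontology(cfg: SynthConfig) -> tuple[OntologyGraph, AnnotationCorpus]:
    """Build a rooted phenotype DAG and a skewed disease-annotation corpus.

    The root has ``n_top_level`` first-level children; each carries a
    complete ``branching``-ary tree of ``depth`` further levels, plus a
    few extra is_a edges (toward shallower non-ancestors in the same
    branch) to make the graph a genuine DAG.  Disease annotations are
    drawn with Zipf-skewed term popularity, so a few terms are common
    and most are rare.  Deterministic under a fixed seed.
    """
    n_terms_per_branch = sum(cfg.branching**d for d in range(1, cfg.depth + 1))
    total = 1 + cfg.n_top_level * (1 + n_terms_per_branch)
    if cfg.branching**cfg.depth < 1 or total < cfg.n_top_level + 2:
        raise ValueError("infeasible ontology shape")
    rng = np.random.default_rng(cfg.seed)

    counter = 1
    root = _tid(counter)
    terms: dict[str, OntologyTerm] = {
        root: OntologyTerm(root, "Phenotypic abnormality", frozenset())
    }
    level_of: dict[str, int] = {root: 0}
    branch_of: dict[str, int] = {}

    for b in range(cfg.n_top_level):
        counter += 1
        top = _tid(counter)
        terms[top] = OntologyTerm(top, f"Abnormality of system {b + 1}", frozenset([root]))
        level_of[top] = 1
        branch_of[top] = b
        frontier = [top]
        for lvl in range(2, cfg.depth + 2):
            nxt = []
            for parent in frontier:
                for _ in range(cfg.branching):
                    counter += 1
                    t = _tid(counter)
                    terms[t] = OntologyTerm(t, f"Phenotype {counter}", frozenset([parent]))
                    level_of[t] = lvl
                    branch_of[t] = b
                    nxt.append(t)
            frontier = nxt

    # Extra is_a edges: deep node gains a second, strictly shallower parent
    # in the same top-level branch — acyclic by construction.
    deep = sorted(t for t, lvl in level_of.items() if lvl >= 3)
    n_extra = int(cfg.extra_edge_frac * len(deep))
    if n_extra and deep:
        graph_tmp = OntologyGraph(terms=dict(terms), root_id=root)
        chosen = rng.choice(len(deep), size=min(n_extra, len(deep)), replace=False)
        for i in sorted(chosen):
            child = deep[i]
            candidates = sorted(
                t
                for t, lvl in level_of.items()
                if branch_of.get(t) == branch_of[child]
                and 1 <= lvl < level_of[child]
                and t not in graph_tmp.ancestors(child)
            )
            if candidates:
                extra = candidates[int(rng.integers(len(candidates)))]
                terms[child] = OntologyTerm(
                    child, terms[child].name, terms[child].parents | {extra}
                )
                graph_tmp = OntologyGraph(terms=dict(terms), root_id=root)

    graph = OntologyGraph(terms=terms, root_id=root)
    graph.top_level_ids = sorted(t for t, lvl in level_of.items() if lvl == 1)

    # Right-skewed popularity: Zipf weight over a random term permutation.
    annotatable = sorted(t for t in terms if t != root)
    perm = rng.permutation(len(annotatable))
    weights = 1.0 / (perm + 1.0)
    weights /= weights.sum()
    disease_to_terms: dict[str, set[str]] = {}
    for d in range(cfg.n_diseases):
        k = min(1 + rng.poisson(max(cfg.terms_per_disease - 1, 0)), len(annotatable))
        idx = rng.choice(len(annotatable), size=k, replace=False, p=weights)
        disease_to_terms[f"DIS:{d + 1:05d}"] = {annotatable[i] for i in idx}
    corpus = AnnotationCorpus(disease_to_terms=disease_to_terms)
    compute_information_content(graph, corpus)
    return graph, corpus


def _descendants(graph: OntologyGraph, root: str) -> list[str]:
    children: dict[str, list[str]] = {}
    for tid, term in graph.terms.items():
        for p in term.parents:
            children.setdefault(p, []).append(tid)
    out, stack = [], [root]
    seen = set()
    while stack:
        t = stack.pop()
        if t in seen:
            continue
        seen.add(t)
        out.append(t)
        stack.extend(children.get(t, ()))
    return sorted(out)


def _draw_patient_terms(
    cfg: SynthConfig, pool: Sequence[str], all_terms: Sequence[str], rng
) -> frozenset[str]:
    n_signal = min(math.ceil(cfg.signal_frac * cfg.terms_per_patient), len(pool),
                   cfg.terms_per_patient)
    chosen: set[str] = set()
    if n_signal:
        idx = rng.choice(len(pool), size=n_signal, replace=False)
        chosen.update(pool[i] for i in idx)
    remaining = [t for t in all_terms if t not in chosen]
    n_noise = min(cfg.terms_per_patient - len(chosen), len(remaining))
    if n_noise > 0:
        idx = rng.choice(len(remaining), size=n_noise, replace=False)
        chosen.update(remaining[i] for i in idx)
    return frozenset(chosen)


def generate_cohort(
    cfg: SynthConfig, graph: OntologyGraph, corpus: AnnotationCorpus
) -> SynthCohort:
    """Build reference and query patients around gene-specific term pools.

    Each gene's pool is the subtree under one second-level term, so
    patients sharing a causal gene share a coherent region of the
    ontology.  Every query's candidate list contains its truth gene plus
    popularity-weighted decoy genes; the gene-frequency corpus is the
    multiset of all candidate entries.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    top = set(graph.top_level_ids)
    subtree_roots = sorted(
        t for t, term in graph.terms.items() if term.parents & top
    )
    if cfg.n_genes > len(subtree_roots):
        raise ValueError(
            f"{cfg.n_genes} genes requested but only {len(subtree_roots)} "
            "subtree neighborhoods available"
        )
    pick = rng.choice(len(subtree_roots), size=cfg.n_genes, replace=False)
    genes = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)]
    pools = {g: _descendants(graph, subtree_roots[p]) for g, p in zip(genes, sorted(pick))}
    all_terms = sorted(t for t in graph.terms if t != graph.root_id and t not in top)

    references: list[ReferencePatient] = []
    for gi, gene in enumerate(genes):
        for r in range(cfg.refs_per_gene):
            references.append(
                ReferencePatient(
                    patient_id=f"REF{gi * cfg.refs_per_gene + r + 1:04d}",
                    terms=_draw_patient_terms(cfg, pools[gene], all_terms, rng),
                    diagnostic_genes=frozenset([gene]),
                )
            )

    # Popularity-weighted decoys: Zipf over gene index, mimicking genes that
    # are recurrently prioritized by upstream variant tools.
    popularity = 1.0 / (np.arange(cfg.n_genes) + 1.0)
    queries: list[PatientProfile] = []
    truth: dict[str, frozenset[str]] = {}
    for qi in range(cfg.n_queries):
        gene = genes[qi % cfg.n_genes]
        others = [g for g in genes if g != gene]
        w = np.array([popularity[genes.index(g)] for g in others])
        w /= w.sum()
        n_decoy = min(cfg.decoy_genes_per_query, len(others))
        decoys = (
            [others[i] for i in rng.choice(len(others), size=n_decoy, replace=False, p=w)]
            if n_decoy
            else []
        )
        qid = f"QRY{qi + 1:04d}"
        queries.append(
            PatientProfile(
                patient_id=qid,
                terms=_draw_patient_terms(cfg, pools[gene], all_terms, rng),
                candidate_genes=frozenset([gene, *decoys]),
            )
        )
        truth[qid] = frozenset([gene])

    gene_corpus = GeneCorpus.from_candidate_lists(queries)
    return SynthCohort(
        graph=graph,
        corpus=corpus,
        references=references,
        queries=queries,
        truth=truth,
        gene_corpus=gene_corpus,
        gene_pools=pools,
    )


def generate(cfg: SynthConfig) -> SynthCohort:
    """Ontology + cohort in one call."""
    graph, corpus = generate_ontology(cfg)
    return generate_cohort(cfg, graph, corpus)


def write_obo(graph: OntologyGraph, path) -> None:
    """Serialize the ontology as a minimal OBO 1.2 flat file (deterministic)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-phenotype\n")
        for tid in sorted(graph.terms):
            term = graph.terms[tid]
            fh.write(f"\n[Term]\nid: {tid}\nname: {term.name}\n")
            for p in sorted(term.parents):
                fh.write(f"is_a: {p} ! {graph.terms[p].name}\n")


def write_annotations(corpus: AnnotationCorpus, path) -> None:
    with open(path, "w") as fh:
        fh.write("disease_id\tterm_id\n")
        for disease in sorted(corpus.disease_to_terms):
            for term in sorted(corpus.disease_to_terms[disease]):
                fh.write(f"{disease}\t{term}\n")


def write_patients_tsv(patients, path, *, kind: str = "query") -> None:
    gene_col = "candidate_genes" if kind == "query" else "diagnostic_genes"
    with open(path, "w") as fh:
        fh.write(f"patient_id\thpo_terms\t{gene_col}\n")
        for p in patients:
            genes = p.candidate_genes if kind == "query" else p.diagnostic_genes
            fh.write(
                f"{p.patient_id}\t{';'.join(sorted(p.terms))}\t{';'.join(sorted(genes))}\n"
            )


def write_gene_corpus(gene_corpus: GeneCorpus, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(gene_corpus.counts):
            for _ in range(gene_corpus.counts[gene]):
                fh.write(gene + "\n")


def write_truth(truth: dict[str, frozenset[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\tdiagnostic_genes\n")
        for qid in sorted(truth):
            fh.write(f"{qid}\t{';'.join(sorted(truth[qid]))}\n")
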