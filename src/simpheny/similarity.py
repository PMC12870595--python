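"""IC-weighted semantic similarity between phenotype terms and term sets.

PhenoSimJaccard for two terms is the sum of information content over the
shared (self-inclusive) ancestors divided by the IC sum over the union of
their ancestors — a Jaccard index on ancestor sets weighted by term
specificity.  Term-pair scores are aggregated into set-level scores with
the best-match-average (funSimAvg) rule, averaging each term's best match
in the other set over both directions of comparison.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ontology import OntologyGraph

__all__ = [
    "SemanticSimilarity",
    "pheno_sim_jaccard",
    "fun_sim_avg",
    "pairwise_matrix",
    "write_matrix",
]


class SemanticSimilarity:
    """Precomputed ancestor/IC tables for fast similarity evaluation.

    Materializes a boolean term-by-term ancestor matrix and an IC vector,
    so a block of term-pair scores reduces to two matrix products.  Purely
    a cache: results are identical to walking the graph per pair.
    """

    def __init__(self, graph: OntologyGraph):
        self.graph = graph
        self.index = {tid: i for i, tid in enumerate(sorted(graph.terms))}
        n = len(self.index)
        ic = np.empty(n)
        anc = np.zeros((n, n), dtype=bool)
        for tid, i in self.index.items():
            ic[i] = graph.ic(tid)
            for a in graph.ancestors(tid):
                anc[i, self.index[a]] = True
        self.ic = ic
        self.anc = anc
        self._anc_ic = anc * ic  # row i: IC of each ancestor of term i
        self._self_ic = self._anc_ic.sum(axis=1)  # IC sum of own closure

    def rows(self, terms: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self.index[t] for t in terms], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown term: {exc.args[0]!r}") from None

    def block(self, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
        """Pairwise PhenoSimJaccard for all (a, b) index pairs."""
        inter = self._anc_ic[idx_a] @ self.anc[idx_b].T
        union = self._self_ic[idx_a][:, None] + self._self_ic[idx_b][None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
        return sim

    def term_similarity(self, t1: str, t2: str) -> float:
        return float(self.block(self.rows([t1]), self.rows([t2]))[0, 0])

    def set_similarity(self, set_a: Iterable[str], set_b: Iterable[str]) -> float:
        a = sorted(set(set_a))
        b = sorted(set(set_b))
        if not a or not b:
            raise ValueError("funSimAvg requires two non-empty term sets")
        s = self.block(self.rows(a), self.rows(b))
        return 0.5 * (s.max(axis=1).mean() + s.max(axis=0).mean())


def _cache(graph: OntologyGraph) -> SemanticSimilarity:
    cache = graph.__dict__.get("_semsim")
    if cache is None:
        cache = SemanticSimilarity(graph)
        graph.__dict__["_semsim"] = cache
    return cache


def pheno_sim_jaccard(graph: OntologyGraph, t1: str, t2: str) -> float:
    """IC-weighted Jaccard similarity of two terms' ancestor closures.

    Returns a value in [0, 1]; 1 means identical ancestor-IC content.  A
    degenerate all-zero-IC union scores 0 by convention.
    """
    return _cache(graph).term_similarity(t1, t2)


def fun_sim_avg(graph: OntologyGraph, set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Best-match-average similarity between two term sets (symmetric).

    ``½·[mean_a max_b s(a,b) + mean_b max_a s(a,b)]`` with
    ``s = pheno_sim_jaccard``.  Duplicate term ids are collapsed before
    scoring.
    """
    return _cache(graph).set_similarity(set_a, set_b)


def pairwise_matrix(
    graph: OntologyGraph, profiles: Sequence[tuple[str, Iterable[str]]]
) -> pd.DataFrame:
    """Symmetric funSimAvg matrix over (id, term set) profiles.

    Diagonal is exactly 1; duplicate profile ids are rejected.
    """
    ids = [pid for pid, _ in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate profile ids in pairwise_matrix")
    sem = _cache(graph)
    n = len(profiles)
    out = np.ones((n, n))
    sets = [sorted(set(ts)) for _, ts in profiles]
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = sem.set_similarity(sets[i], sets[j])
    return pd.DataFrame(out, index=ids, columns=ids)


def write_matrix(matrix: pd.DataFrame, path, *, long_format: bool = False) -> None:
    """Write a similarity matrix as TSV (wide by default, or long triples)."""
    if long_format:
        long = matrix.stack().rename("score").rename_axis(["id_a", "id_b"]).reset_index()
        long.to_csv(path, sep="\t", index=False)
    else:
        matrix.to_csv(path, sep="\t", index_label="id")
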