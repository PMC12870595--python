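"""Monte-Carlo empirical null distributions for match significance.

Two empirical p-values are attached to every match:

* *pheno p* — probability that the observed set-level phenotypic
  similarity between query and reference would be reached by a random
  phenotype list.  Random lists are drawn without replacement from the
  multiset of all reference-cohort term annotations (frequency-weighted,
  preserving population-level biases), capped at ``max_sim_terms`` terms,
  and scored against the *observed* reference list.
* *gene p* — probability that the matched gene would appear in a random
  candidate list of the query's length, drawn with replacement from the
  cohort-wide gene-frequency corpus (duplicates preserved, so frequently
  prioritized genes are penalized).

Both use the +1-corrected estimator ``(1 + exceedances) / (1 + N)``, so
the smallest attainable p-value is exactly ``1/(N+1)`` and zero p-values
are impossible.
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .matching import PatientProfile, ReferencePatient
from .ontology import OntologyGraph
from .similarity import _cache

__all__ = [
    "SimulationConfig",
    "TermCorpus",
    "GeneCorpus",
    "match_rng",
    "simulate_term_list",
    "pheno_p",
    "gene_p",
]

# Exceedance comparisons use a tiny slack so that a simulated list that is
# set-equal to the observed query cannot miss the >= test to float noise.
_EPS = 1e-9


@dataclass
class SimulationConfig:
    """Monte-Carlo settings: replicate count, simulated-list cap, master seed."""

    n_simulations: int = 10_000
    max_sim_terms: int = 10
    seed: int | None = None

    def __post_init__(self):
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")
        if self.max_sim_terms < 1:
            raise ValueError("max_sim_terms must be >= 1")


def match_rng(seed: int | None, *key_parts: str) -> np.random.Generator:
    """Independent, order-invariant RNG stream for one match.

    Child streams are keyed by a stable CRC32 hash of the identifying
    strings (query id, reference id, gene), so per-match results do not
    depend on the order matches are processed in.
    """
    digest = zlib.crc32("|".join(key_parts).encode())
    entropy = [digest] if seed is None else [int(seed), digest]
    return np.random.default_rng(np.random.SeedSequence(entropy))


class TermCorpus:
    """Frequency-weighted multiset of phenotype term annotations."""

    def __init__(self, counts: Counter | dict[str, int]):
        items = sorted((t, int(c)) for t, c in dict(counts).items() if c > 0)
        if not items:
            raise ValueError("empty term corpus")
        self.terms = np.array([t for t, _ in items], dtype=object)
        self.counts = np.array([c for _, c in items], dtype=float)
        self.weights = self.counts / self.counts.sum()

    @classmethod
    def from_references(cls, references: Iterable[ReferencePatient]) -> "TermCorpus":
        counts: Counter = Counter()
        for ref in references:
            counts.update(ref.terms)
        return cls(counts)

    def __len__(self) -> int:
        return len(self.terms)

    def sample_indices(self, k: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``k`` distinct term indices, probability ∝ multiset counts.

        Successive draws over distinct terms without replacement (numpy's
        weighted ``replace=False`` scheme).
        """
        if k > len(self.terms):
            raise ValueError(
                f"corpus has only {len(self.terms)} distinct terms; need {k}"
            )
        return rng.choice(len(self.terms), size=k, replace=False, p=self.weights)


class GeneCorpus:
    """Multiset of gene symbols across all candidate lists (duplicates meaningful)."""

    def __init__(self, counts: Counter | dict[str, int]):
        self.counts = Counter(
            {g.strip().upper(): int(c) for g, c in dict(counts).items() if c > 0}
        )
        if not self.counts:
            raise ValueError("empty gene corpus")
        self.total = sum(self.counts.values())

    @classmethod
    def from_candidate_lists(cls, queries: Iterable[PatientProfile]) -> "GeneCorpus":
        counts: Counter = Counter()
        for q in queries:
            counts.update(q.candidate_genes)
        return cls(counts)

    @classmethod
    def from_file(cls, path) -> "GeneCorpus":
        """Plain text, one gene symbol per line; duplicate lines preserved."""
        counts: Counter = Counter()
        with open(path) as fh:
            for line in fh:
                g = line.strip()
                if g and not g.startswith("#"):
                    counts[g.upper()] += 1
        return cls(counts)

    def frequency(self, gene: str) -> float:
        return self.counts.get(gene.strip().upper(), 0) / self.total


def simulate_term_list(
    corpus: TermCorpus,
    target_len: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> set[str]:
    """One randomized phenotype list: ``min(target_len, cap)`` distinct terms.

    Draw probabilities at each step are proportional to remaining
    multiset counts.
    """
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    k = min(target_len, cfg.max_sim_terms)
    idx = corpus.sample_indices(k, rng)
    return set(corpus.terms[idx])


def pheno_p(
    graph: OntologyGraph,
    query_terms: Iterable[str],
    reference_terms: Iterable[str],
    corpus: TermCorpus,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Empirical p-value of the observed query↔reference set similarity.

    Returns ``(pheno_p, observed_sim)``.  Each of the N replicates draws
    a randomized query list from the corpus and scores it against the
    observed reference list with funSimAvg; the p-value is
    ``(1 + #{sim >= observed}) / (1 + N)``.
    """
    query = sorted(set(query_terms))
    reference = sorted(set(reference_terms))
    if not query or not reference:
        raise ValueError("pheno_p requires non-empty query and reference term sets")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    sem = _cache(graph)
    observed = sem.set_similarity(query, reference)

    # Similarity of every distinct corpus term against the reference list,
    # computed once: replicate scoring is then pure indexing.
    ref_idx = sem.rows(reference)
    corpus_idx = sem.rows(corpus.terms)
    S = sem.block(corpus_idx, ref_idx)       # (n_corpus_terms, n_ref)
    row_best = S.max(axis=1)                 # best match of each corpus term

    k = min(len(query), cfg.max_sim_terms)
    n_exceed = 0
    threshold = observed - _EPS
    for _ in range(cfg.n_simulations):
        idx = corpus.sample_indices(k, rng)
        forward = row_best[idx].mean()
        reverse = S[idx].max(axis=0).mean()
        if 0.5 * (forward + reverse) >= threshold:
            n_exceed += 1
    p = (1 + n_exceed) / (1 + cfg.n_simulations)
    return p, observed


def gene_p(
    gene: str,
    list_len: int,
    corpus: GeneCorpus,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Empirical p-value for the matched gene's presence in a random list.

    Each replicate draws ``list_len`` genes with replacement, weighted by
    corpus counts, and records binary presence of ``gene``; presence in a
    replicate is distributed Binomial(list_len, q) > 0 with q the gene's
    corpus fraction, which is how it is simulated.
    """
    if list_len < 1:
        raise ValueError("candidate list length must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    q = corpus.frequency(gene)
    if q == 0.0:
        n_present = 0
    elif q == 1.0:
        n_present = cfg.n_simulations
    else:
        n_present = int(np.count_nonzero(rng.binomial(list_len, q, size=cfg.n_simulations)))
    return (1 + n_present) / (1 + cfg.n_simulations)
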