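"""Combining match evidence: Empirical Brown's Method, scores, tiers, ranking.

The phenotype and gene p-values of a match are dependent (similar
phenotypes make the diagnostic gene likelier to be on the candidate
list), so they are combined with Empirical Brown's Method: Fisher's
statistic ``X = -2 ln p1 - 2 ln p2`` referred to a scaled chi-square
``c · χ²_f`` whose scale ``c`` and degrees of freedom ``f`` are
moment-matched to the empirically estimated dependence.  Under
independence (c, f) = (1, 4) recovers Fisher's method; under perfect
positive dependence (c, f) = (2, 2) collapses to the single test.  The
match score is ``-log10(combined p)``, banded into confidence tiers, and
genes are ranked by the mean of their two best match scores.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matching import SimPhenyMatch

__all__ = [
    "EBMParameters",
    "GeneCandidateRanking",
    "calibrate_ebm",
    "combine_pvalues",
    "simpheny_score",
    "assign_tier",
    "gene_score",
    "bh_adjust",
    "rank_genes",
]

#: Confidence-tier boundaries on the match score (inclusive lower bounds):
#: high >= 4.5, medium in [2.5, 4.5), low < 2.5.
DEFAULT_TIER_THRESHOLDS = (2.5, 4.5)

_P_FLOOR = float(np.finfo(float).tiny)


@dataclass
class EBMParameters:
    """Calibrated null parameters for one reference dataset.

    ``scale_factor * dof = 4`` always (mean preservation of the scaled
    chi-square against E[X] = 4).
    """

    rho: float
    scale_factor: float
    dof: float
    source_label: str = ""
    n_pairs: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "EBMParameters":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class GeneCandidateRanking:
    """Per-query gene ranking: (gene, gene score, supporting match count)."""

    query_id: str
    entries: list[tuple[str, float, int]]

    def rank_of(self, gene: str) -> int | None:
        gene = gene.strip().upper()
        for i, (g, _, _) in enumerate(self.entries, start=1):
            if g == gene:
                return i
        return None


def _validate_p(p: float, name: str = "p") -> None:
    if not (0.0 < p <= 1.0):
        raise ValueError(f"{name} must lie in (0, 1], got {p}")


def calibrate_ebm(
    pairs: Sequence[tuple[float, float]],
    *,
    source_label: str = "",
    estimator: str = "correlation",
) -> EBMParameters:
    """Estimate the scaled-chi-square null from observed (pheno p, gene p) pairs.

    With ``w_i = -2 ln p_i`` and ``X = w1 + w2``: E[X] = 4 and
    ``Var(X) = 8 + 2 cov(w1, w2)``, giving ``f = 32 / Var`` and
    ``c = Var / 8`` (so that c·f = 4).  The default estimator sets
    ``cov = 4 · corr(w1, w2)``, moment-matching the exact uniform-marginal
    variance Var(-2 ln p) = 4 with the empirical correlation — this hits
    (1, 4) at independence and exactly (2, 2) when the two columns are
    identical.  ``estimator="covariance"`` uses the raw sample covariance
    of (w1, w2) instead.  The correlation of the inverse-normal z-scores
    is reported as ``rho`` either way.
    """
    pairs = list(pairs)
    if len(pairs) < 10:
        raise ValueError("EBM calibration needs at least 10 (pheno_p, gene_p) pairs")
    p1 = np.array([a for a, _ in pairs], dtype=float)
    p2 = np.array([b for _, b in pairs], dtype=float)
    for arr, name in ((p1, "pheno_p"), (p2, "gene_p")):
        if np.any((arr <= 0) | (arr > 1)):
            raise ValueError(f"{name} values must lie in (0, 1]")
        if np.ptp(arr) == 0:
            raise ValueError(f"{name} column is constant; cannot calibrate")

    w1 = -2.0 * np.log(p1)
    w2 = -2.0 * np.log(p2)
    if estimator == "correlation":
        cov = 4.0 * float(np.corrcoef(w1, w2)[0, 1])
    elif estimator == "covariance":
        cov = float(np.cov(w1, w2, ddof=1)[0, 1])
    else:
        raise ValueError("estimator must be 'correlation' or 'covariance'")

    var = 8.0 + 2.0 * cov
    var = max(var, 1e-6)  # guard against pathological negative dependence
    scale = var / 8.0
    dof = 32.0 / var

    z1 = stats.norm.ppf(np.clip(p1, 1e-300, 1 - 1e-16))
    z2 = stats.norm.ppf(np.clip(p2, 1e-300, 1 - 1e-16))
    rho = float(np.corrcoef(z1, z2)[0, 1])
    return EBMParameters(
        rho=rho,
        scale_factor=scale,
        dof=dof,
        source_label=source_label,
        n_pairs=len(pairs),
    )


def combine_pvalues(pheno_p: float, gene_p: float, params: EBMParameters) -> float:
    """Combined p-value of a match under the calibrated scaled-chi-square null.

    ``X = -2 ln pheno_p - 2 ln gene_p``; the combined p is the upper-tail
    probability of χ²_f at ``X / c``, floored at the smallest positive
    normal float so -log10 stays finite.
    """
    _validate_p(pheno_p, "pheno_p")
    _validate_p(gene_p, "gene_p")
    x = -2.0 * (math.log(pheno_p) + math.log(gene_p))
    p = float(stats.chi2.sf(x / params.scale_factor, params.dof))
    return min(1.0, max(p, _P_FLOOR))


def simpheny_score(combined_p: float) -> float:
    """Match score: ``-log10(combined p)`` (0 for p = 1, larger is stronger)."""
    _validate_p(combined_p, "combined_p")
    return -math.log10(combined_p)


def assign_tier(
    score: float, thresholds: tuple[float, float] = DEFAULT_TIER_THRESHOLDS
) -> str:
    """Confidence tier for a match score: 'high', 'medium' or 'low'.

    Boundaries are inclusive lower bounds: score >= thresholds[1] is
    high, thresholds[0] <= score < thresholds[1] is medium, below is low.
    """
    if score < 0:
        raise ValueError("match score cannot be negative")
    low_hi, med_hi = thresholds
    if not 0 < low_hi < med_hi:
        raise ValueError("tier thresholds must satisfy 0 < low_hi < med_hi")
    if score >= med_hi:
        return "high"
    if score >= low_hi:
        return "medium"
    return "low"


def gene_score(match_scores: Sequence[float]) -> float:
    """Gene-level score: mean of the two highest match scores.

    A single supporting match contributes its score unchanged; further
    low-scoring matches beyond the best two never dilute the score.
    """
    if not match_scores:
        raise ValueError("gene_score requires at least one match score")
    top = sorted(match_scores, reverse=True)[:2]
    return float(sum(top) / len(top))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Run-scoped: adjusted values depend on the number of matches in this
    run and are not portable across cohorts.
    """
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def rank_genes(matches: Sequence[SimPhenyMatch]) -> GeneCandidateRanking:
    """Rank one query's candidate genes by gene score (desc, ties by symbol).

    All matches must carry a score and share a query id.
    """
    if not matches:
        raise ValueError("rank_genes requires at least one match")
    query_ids = {m.query_id for m in matches}
    if len(query_ids) != 1:
        raise ValueError(f"rank_genes got matches from multiple queries: {sorted(query_ids)}")
    by_gene: dict[str, list[float]] = {}
    for m in matches:
        if m.score is None:
            raise ValueError("all matches must be scored before ranking")
        by_gene.setdefault(m.gene, []).append(m.score)
    entries = [
        (gene, gene_score(scores), len(scores)) for gene, scores in by_gene.items()
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return GeneCandidateRanking(query_id=query_ids.pop(), entries=entries)
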