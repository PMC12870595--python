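"""Benchmarking against known diagnoses: TPR/FPR/FDR, ROC, FDR–TPR, top-k.

Matches are labeled true positive when the matched gene is among the
query's known diagnostic genes.  Because matched cohorts are heavily
imbalanced (most matches are false positives), the false discovery rate
at a score threshold is the primary operating metric, swept on a grid of
thresholds alongside the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .combine import GeneCandidateRanking
from .matching import SimPhenyMatch

__all__ = [
    "LabeledMatch",
    "ThresholdMetrics",
    "label_matches",
    "threshold_metrics",
    "roc_curve",
    "fdr_tpr_curve",
    "topk_summary",
    "read_truth",
    "metrics_table",
]

#: Default threshold sweep for FDR–TPR curves: 1.0 to 6.0 in 0.5 steps.
DEFAULT_THRESHOLDS = tuple(np.arange(1.0, 6.0 + 1e-9, 0.5))


@dataclass(frozen=True)
class LabeledMatch:
    match: SimPhenyMatch
    is_true_positive: bool


@dataclass(frozen=True)
class ThresholdMetrics:
    """Confusion counts and rates at one inclusive score threshold."""

    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    tpr: float
    fpr: float
    fdr: float


def read_truth(path) -> dict[str, frozenset[str]]:
    """Truth TSV: ``patient_id<TAB>diagnostic_genes`` (semicolon-separated)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return {
        str(row["patient_id"]): frozenset(
            g.strip().upper() for g in str(row["diagnostic_genes"]).split(";") if g.strip()
        )
        for _, row in df.iterrows()
    }


def label_matches(
    matches: Sequence[SimPhenyMatch], truth: Mapping[str, Iterable[str]]
) -> list[LabeledMatch]:
    """Label each match TP/FP by membership in the query's diagnostic gene set."""
    out = []
    for m in matches:
        if m.query_id not in truth:
            raise KeyError(f"query {m.query_id!r} missing from truth set")
        genes = {g.strip().upper() for g in truth[m.query_id]}
        out.append(LabeledMatch(match=m, is_true_positive=m.gene in genes))
    return out


def threshold_metrics(
    labeled: Sequence[LabeledMatch], threshold: float
) -> ThresholdMetrics:
    """Confusion counts at an inclusive score threshold.

    A match is called positive when ``score >= threshold``.  FDR is 0 by
    convention when nothing is called.
    """
    if not labeled:
        raise ValueError("no labeled matches")
    tp = fp = fn = tn = 0
    for lm in labeled:
        called = lm.match.score >= threshold
        if lm.is_true_positive:
            tp += called
            fn += not called
        else:
            fp += called
            tn += not called
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    fpr = fp / (fp + tn) if (fp + tn) else 0.0
    fdr = fp / (fp + tp) if (fp + tp) else 0.0
    return ThresholdMetrics(
        threshold=float(threshold), tp=tp, fp=fp, fn=fn, tn=tn, tpr=tpr, fpr=fpr, fdr=fdr
    )


def roc_curve(
    labeled: Sequence[LabeledMatch],
) -> tuple[list[tuple[float, float]], float]:
    """(FPR, TPR) points over all distinct score thresholds, plus auROC.

    The area is the trapezoid-rule integral, equal to the Mann–Whitney
    probability that a random TP outscores a random FP (ties ½).
    """
    y = np.array([lm.is_true_positive for lm in labeled], dtype=int)
    s = np.array([lm.match.score for lm in labeled], dtype=float)
    if y.all() or not y.any():
        raise ValueError("ROC requires at least one TP and one FP match")
    fpr, tpr, _ = _skm.roc_curve(y, s)
    auroc = float(_skm.auc(fpr, tpr))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points, auroc


def fdr_tpr_curve(
    labeled: Sequence[LabeledMatch],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[ThresholdMetrics]:
    """One :class:`ThresholdMetrics` per threshold (ascending grid)."""
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    return [threshold_metrics(labeled, t) for t in thresholds]


def metrics_table(points: Sequence[ThresholdMetrics]) -> pd.DataFrame:
    """Tabular view of a threshold sweep (one row per threshold)."""
    return pd.DataFrame(
        [
            {
                "threshold": p.threshold,
                "tp": p.tp,
                "fp": p.fp,
                "fn": p.fn,
                "tn": p.tn,
                "tpr": p.tpr,
                "fpr": p.fpr,
                "fdr": p.fdr,
            }
            for p in points
        ]
    )


def topk_summary(
    rankings: Sequence[GeneCandidateRanking],
    truth: Mapping[str, Iterable[str]],
    ks: Sequence[int] = (1, 5, 10),
) -> dict[int, float]:
    """Fraction of ranked queries whose diagnostic gene ranks within top k.

    Denominator is the queries with at least one ranked gene; a
    diagnostic gene absent from a query's ranking is a miss at every k.
    A multigenic query counts as a hit at k if any of its diagnostic
    genes ranks <= k.
    """
    rankings = [r for r in rankings if r.entries]
    if not rankings:
        raise ValueError("no rankings to summarize")
    best_rank: list[int | None] = []
    for r in rankings:
        if r.query_id not in truth:
            raise KeyError(f"query {r.query_id!r} missing from truth set")
        ranks = [
            r.rank_of(g) for g in truth[r.query_id] if r.rank_of(g) is not None
        ]
        best_rank.append(min(ranks) if ranks else None)
    n = len(rankings)
    return {
        int(k): sum(1 for b in best_rank if b is not None and b <= k) / n for k in ks
    }
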