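"""End-to-end orchestration: match pipeline, calibration, benchmarking.

The in-memory entry points (:func:`match_pipeline`,
:func:`benchmark_pipeline`) are the core; :func:`run_match` and
:func:`run_benchmark` wrap them with file I/O for the command line.
Per-match Monte-Carlo streams are keyed by (seed, query, reference,
gene), so results are independent of processing order and of which other
matches exist in the run.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import benchmark as _bench
from .combine import (
    DEFAULT_TIER_THRESHOLDS,
    EBMParameters,
    GeneCandidateRanking,
    assign_tier,
    bh_adjust,
    calibrate_ebm,
    combine_pvalues,
    rank_genes,
    simpheny_score,
)
from .matching import PatientProfile, ReferencePatient, SimPhenyMatch, find_matches
from .nulls import GeneCorpus, SimulationConfig, TermCorpus, gene_p, match_rng, pheno_p
from .ontology import OntologyGraph, curate_phenotypes
from .similarity import fun_sim_avg

__all__ = [
    "RunConfig",
    "MatchRunResult",
    "match_pipeline",
    "benchmark_pipeline",
    "phenotype_only_ranking",
    "matches_to_frame",
    "rankings_to_frame",
    "run_match",
    "run_benchmark",
]


@dataclass
class RunConfig:
    """File-based run configuration for the CLI entry points."""

    ontology: Path
    annotations: Path
    reference: Path
    queries: Path
    out_dir: Path
    exclude_terms: Path | None = None
    gene_corpus: Path | None = None
    ebm_params: Path | None = None
    truth: Path | None = None
    calibrate: bool = False
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    tier_thresholds: tuple[float, float] = DEFAULT_TIER_THRESHOLDS

    def __post_init__(self):
        low, high = self.tier_thresholds
        if not 0 < low < high:
            raise ValueError("tier thresholds must satisfy 0 < low_hi < med_hi")
        for name in ("ontology", "annotations", "reference", "queries"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


@dataclass
class MatchRunResult:
    matches: list[SimPhenyMatch]
    rankings: list[GeneCandidateRanking]
    manifest: dict
    ebm: EBMParameters


def match_pipeline(
    graph: OntologyGraph,
    references: Sequence[ReferencePatient],
    queries: Sequence[PatientProfile],
    *,
    sim_cfg: SimulationConfig | None = None,
    gene_corpus: GeneCorpus | None = None,
    ebm: EBMParameters | None = None,
    exclusion: Iterable[str] = (),
    tier_thresholds: tuple[float, float] = DEFAULT_TIER_THRESHOLDS,
    exclude_self: bool = True,
    source_label: str = "run",
) -> MatchRunResult:
    """Full scoring pipeline over a query set.

    For every query: curate terms, enumerate gene overlaps with the
    reference cohort, compute the phenotype and gene empirical p-values
    per match, combine them under the (given or freshly calibrated)
    scaled-chi-square null, convert to scores and tiers, apply a
    run-scoped BH correction, and rank candidate genes per query.
    Queries without matches are listed as "No Match" in the manifest.
    """
    sim_cfg = sim_cfg or SimulationConfig()
    exclusion = set(exclusion)

    refs = []
    for r in references:
        terms = curate_phenotypes(r.terms, exclusion) if exclusion else set(r.terms)
        if terms:
            refs.append(ReferencePatient(r.patient_id, frozenset(terms), r.diagnostic_genes))
    if not refs:
        raise ValueError("reference cohort empty after curation")
    term_corpus = TermCorpus.from_references(refs)
    if gene_corpus is None:
        gene_corpus = GeneCorpus.from_candidate_lists(queries)
    ref_by_id = {r.patient_id: r for r in refs}

    matches: list[SimPhenyMatch] = []
    no_match: list[str] = []
    skipped: list[str] = []
    for q in queries:
        terms = curate_phenotypes(q.terms, exclusion) if exclusion else set(q.terms)
        if not terms:
            warnings.warn(
                f"query {q.patient_id!r} has no terms left after curation; skipped",
                stacklevel=2,
            )
            skipped.append(q.patient_id)
            continue
        q = PatientProfile(q.patient_id, frozenset(terms), q.candidate_genes)
        triples = find_matches(q, refs, exclude_self=exclude_self)
        if not triples:
            no_match.append(q.patient_id)
            continue
        for qid, rid, gene in triples:
            # separate keyed streams so neither statistic's draws depend
            # on the other's entropy consumption
            pp, obs = pheno_p(
                graph, q.terms, ref_by_id[rid].terms, term_corpus, sim_cfg,
                match_rng(sim_cfg.seed, qid, rid, gene, "pheno"),
            )
            gp = gene_p(
                gene, len(q.candidate_genes), gene_corpus, sim_cfg,
                match_rng(sim_cfg.seed, qid, rid, gene, "gene"),
            )
            matches.append(
                SimPhenyMatch(
                    query_id=qid, reference_id=rid, gene=gene,
                    pheno_sim=obs, pheno_p=pp, gene_p=gp,
                )
            )

    if ebm is None:
        if matches:
            pairs = [(m.pheno_p, m.gene_p) for m in matches]
            ebm = calibrate_ebm(pairs, source_label=source_label)
        else:
            # Nothing to calibrate on; record the independence null.
            ebm = EBMParameters(rho=0.0, scale_factor=1.0, dof=4.0,
                                source_label=source_label, n_pairs=0)
    for m in matches:
        m.combined_p = combine_pvalues(m.pheno_p, m.gene_p, ebm)
        m.score = simpheny_score(m.combined_p)
        m.tier = assign_tier(m.score, tier_thresholds)
    if matches:
        adjusted = bh_adjust([m.combined_p for m in matches])
        for m, adj in zip(matches, adjusted):
            m.adjusted_p = adj

    by_query: dict[str, list[SimPhenyMatch]] = {}
    for m in matches:
        by_query.setdefault(m.query_id, []).append(m)
    rankings = [rank_genes(ms) for _, ms in sorted(by_query.items())]

    table = matches_to_frame(matches)
    manifest = {
        "seed": sim_cfg.seed,
        "n_simulations": sim_cfg.n_simulations,
        "max_sim_terms": sim_cfg.max_sim_terms,
        "tier_thresholds": list(tier_thresholds),
        "n_queries": len(queries),
        "n_references": len(refs),
        "n_matches": len(matches),
        "no_match_queries": sorted(no_match),
        "skipped_queries": sorted(skipped),
        "ebm": {
            "rho": ebm.rho,
            "scale_factor": ebm.scale_factor,
            "dof": ebm.dof,
            "source_label": ebm.source_label,
            "n_pairs": ebm.n_pairs,
        },
        "match_table_sha256": hashlib.sha256(
            table.to_csv(sep="\t", index=False).encode()
        ).hexdigest(),
    }
    return MatchRunResult(matches=matches, rankings=rankings, manifest=manifest, ebm=ebm)


def phenotype_only_ranking(
    graph: OntologyGraph,
    query: PatientProfile,
    references: Sequence[ReferencePatient],
) -> pd.DataFrame:
    """Similarity-ranked reference patients for a query without gene input.

    No match scores are computed in this mode — they require gene-level
    evidence; only set-level phenotypic similarity is reported.
    """
    rows = [
        {
            "reference_id": r.patient_id,
            "pheno_sim": fun_sim_avg(graph, query.terms, r.terms),
            "diagnostic_genes": ";".join(sorted(r.diagnostic_genes)),
        }
        for r in references
        if r.patient_id != query.patient_id
    ]
    df = pd.DataFrame(rows).sort_values(
        ["pheno_sim", "reference_id"], ascending=[False, True]
    )
    return df.reset_index(drop=True)


def matches_to_frame(matches: Sequence[SimPhenyMatch]) -> pd.DataFrame:
    cols = [
        "query_id", "reference_id", "gene", "pheno_sim", "pheno_p", "gene_p",
        "combined_p", "simpheny_score", "bh_adjusted_p", "tier",
    ]
    rows = [
        {
            "query_id": m.query_id, "reference_id": m.reference_id, "gene": m.gene,
            "pheno_sim": m.pheno_sim, "pheno_p": m.pheno_p, "gene_p": m.gene_p,
            "combined_p": m.combined_p, "simpheny_score": m.score,
            "bh_adjusted_p": m.adjusted_p, "tier": m.tier,
        }
        for m in matches
    ]
    return pd.DataFrame(rows, columns=cols)


def rankings_to_frame(rankings: Sequence[GeneCandidateRanking]) -> pd.DataFrame:
    rows = []
    for r in rankings:
        for rank, (gene, score, n) in enumerate(r.entries, start=1):
            rows.append(
                {
                    "query_id": r.query_id, "rank": rank, "gene": gene,
                    "gene_score": score, "n_matches": n,
                }
            )
    return pd.DataFrame(rows, columns=["query_id", "rank", "gene", "gene_score", "n_matches"])


def _load_inputs(cfg: RunConfig):
    from .matching import read_patients_tsv
    from .ontology import load_obo, read_annotations, read_exclusion_list
    from .ontology import compute_information_content

    graph = load_obo(str(cfg.ontology))
    corpus = read_annotations(cfg.annotations)
    compute_information_content(graph, corpus)
    references = read_patients_tsv(cfg.reference, kind="reference")
    queries = read_patients_tsv(cfg.queries, kind="query")
    exclusion = read_exclusion_list(cfg.exclude_terms) if cfg.exclude_terms else set()
    gene_corpus = GeneCorpus.from_file(cfg.gene_corpus) if cfg.gene_corpus else None
    return graph, references, queries, exclusion, gene_corpus


def run_match(cfg: RunConfig) -> MatchRunResult:
    """File-based match run: writes match/ranking tables and a manifest."""
    graph, references, queries, exclusion, gene_corpus = _load_inputs(cfg)
    ebm = None
    if cfg.ebm_params and Path(cfg.ebm_params).exists():
        ebm = EBMParameters.from_json(cfg.ebm_params)
    elif not cfg.calibrate:
        raise ValueError(
            "no EBM parameter file given; pass calibrate=True (--calibrate) "
            "to fit parameters from this run"
        )
    result = match_pipeline(
        graph, references, queries,
        sim_cfg=cfg.sim, gene_corpus=gene_corpus, ebm=ebm,
        exclusion=exclusion, tier_thresholds=cfg.tier_thresholds,
    )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matches_to_frame(result.matches).to_csv(out / "matches.tsv", sep="\t", index=False)
    rankings_to_frame(result.rankings).to_csv(out / "rankings.tsv", sep="\t", index=False)
    result.ebm.to_json(out / "ebm_params.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
        fh.write("\n")
    return result


def benchmark_pipeline(
    result: MatchRunResult,
    truth: Mapping[str, Iterable[str]],
    thresholds: Sequence[float] = _bench.DEFAULT_THRESHOLDS,
):
    """Label a finished run against known diagnoses and sweep metrics.

    Returns (labeled matches, threshold metrics table, ROC points,
    auROC, top-k summary).
    """
    missing = sorted(
        {m.query_id for m in result.matches} - set(truth)
    )
    if missing:
        raise KeyError(f"queries missing from truth set: {missing}")
    labeled = _bench.label_matches(result.matches, truth)
    sweep = _bench.fdr_tpr_curve(labeled, thresholds)
    n_tp = sum(lm.is_true_positive for lm in labeled)
    if 0 < n_tp < len(labeled):
        points, auroc = _bench.roc_curve(labeled)
    else:
        # single-class run: the ROC is undefined, the sweep still stands
        points, auroc = [], float("nan")
    topk = _bench.topk_summary(result.rankings, truth)
    return labeled, sweep, points, auroc, topk


def run_benchmark(cfg: RunConfig) -> dict:
    """File-based benchmark run; requires a truth file covering all queries."""
    if cfg.truth is None:
        raise ValueError("benchmark requires a truth file")
    truth = _bench.read_truth(cfg.truth)
    result = run_match(cfg)
    labeled, sweep, points, auroc, topk = benchmark_pipeline(result, truth)
    out = Path(cfg.out_dir)
    lab = matches_to_frame([lm.match for lm in labeled])
    lab["is_tp"] = [lm.is_true_positive for lm in labeled]
    lab.to_csv(out / "labeled_matches.tsv", sep="\t", index=False)
    _bench.metrics_table(sweep).to_csv(out / "threshold_metrics.tsv", sep="\t", index=False)
    pd.DataFrame(points, columns=["fpr", "tpr"]).to_csv(
        out / "roc_points.tsv", sep="\t", index=False
    )
    summary = {"auroc": auroc, "topk": {str(k): v for k, v in topk.items()}}
    with open(out / "benchmark_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    return summary
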