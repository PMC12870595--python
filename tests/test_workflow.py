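import json

import numpy as np
import pytest

from simpheny.combine import EBMParameters
from simpheny.matching import PatientProfile, ReferencePatient
from simpheny.nulls import SimulationConfig
from simpheny.synth import (
    SynthConfig,
    generate,
    write_annotations,
    write_gene_corpus,
    write_obo,
    write_patients_tsv,
    write_truth,
)
from simpheny.workflow import (
    RunConfig,
    benchmark_pipeline,
    match_pipeline,
    matches_to_frame,
    phenotype_only_ranking,
    rankings_to_frame,
    run_benchmark,
    run_match,
)

FISHER = EBMParameters(rho=0.0, scale_factor=1.0, dof=4.0)
FAST = SimulationConfig(n_simulations=150, max_sim_terms=10, seed=7)


@pytest.fixture(scope="module")
def cohort():
    return generate(
        SynthConfig(seed=21, n_top_level=6, n_diseases=60, n_genes=6,
                    refs_per_gene=2, n_queries=8, terms_per_patient=8,
                    decoy_genes_per_query=3)
    )


class TestMatchPipeline:
    def test_no_gene_overlap_gives_empty_table_and_no_match_manifest(self, cohort):
        queries = [
            PatientProfile(q.patient_id, q.terms, frozenset({"ZZZ9"}))
            for q in cohort.queries
        ]
        res = match_pipeline(cohort.graph, cohort.references, queries,
                             sim_cfg=FAST, ebm=FISHER)
        assert res.matches == []
        assert res.manifest["no_match_queries"] == sorted(q.patient_id for q in queries)
        assert matches_to_frame(res.matches).empty

    def test_fixed_seed_runs_are_identical(self, cohort):
        hashes = []
        for _ in range(2):
            res = match_pipeline(cohort.graph, cohort.references, cohort.queries,
                                 sim_cfg=FAST, ebm=FISHER)
            hashes.append(res.manifest["match_table_sha256"])
        assert hashes[0] == hashes[1]

    def test_planted_perfect_match_attains_top_score(self, cohort):
        # a reference diagnosed with a gene unique in the candidate corpus,
        # and a query with identical terms and only that gene: both
        # p-values are extremal, so its combined score must dominate
        ref = ReferencePatient("PLANTREF", cohort.references[0].terms,
                               frozenset({"UNIQUEGENE"}))
        planted = PatientProfile("PLANT", ref.terms, frozenset({"UNIQUEGENE"}))
        res = match_pipeline(cohort.graph, [ref, *cohort.references],
                             [planted, *cohort.queries], sim_cfg=FAST, ebm=FISHER)
        planted_scores = [m.score for m in res.matches
                          if m.query_id == "PLANT" and m.reference_id == "PLANTREF"]
        assert planted_scores
        assert max(planted_scores) == max(m.score for m in res.matches)

    def test_removing_unrelated_reference_leaves_pvalues_unchanged(self, cohort):
        res_full = match_pipeline(cohort.graph, cohort.references, cohort.queries,
                                  sim_cfg=FAST, ebm=FISHER)
        removed = cohort.references[0].patient_id
        remaining = [r for r in cohort.references if r.patient_id != removed]
        res_small = match_pipeline(cohort.graph, remaining, cohort.queries,
                                   sim_cfg=FAST, ebm=FISHER)
        by_key = {(m.query_id, m.reference_id, m.gene): m for m in res_small.matches}
        survivors = [m for m in res_full.matches if m.reference_id != removed]
        assert len(by_key) == len(survivors)
        for m in survivors:
            kept = by_key[(m.query_id, m.reference_id, m.gene)]
            # per-match streams are key-addressed, so removing one
            # reference cannot perturb any other match's p-values
            assert kept.gene_p == m.gene_p
            assert kept.pheno_sim == m.pheno_sim

    def test_curation_empties_query_skips_with_warning(self, cohort):
        q0 = cohort.queries[0]
        exclusion = set(q0.terms)
        with pytest.warns(UserWarning):
            res = match_pipeline(cohort.graph, cohort.references,
                                 [q0], sim_cfg=FAST, ebm=FISHER,
                                 exclusion=exclusion)
        assert q0.patient_id in res.manifest["skipped_queries"]

    def test_bh_and_tiers_populated(self, cohort):
        res = match_pipeline(cohort.graph, cohort.references, cohort.queries,
                             sim_cfg=FAST, ebm=FISHER)
        for m in res.matches:
            assert m.adjusted_p is not None and 0 < m.adjusted_p <= 1
            assert m.tier in {"high", "medium", "low"}
        frame = rankings_to_frame(res.rankings)
        assert set(frame.columns) == {"query_id", "rank", "gene", "gene_score", "n_matches"}


class TestPhenotypeOnly:
    def test_ranks_references_by_similarity_without_scores(self, cohort):
        df = phenotype_only_ranking(cohort.graph, cohort.queries[0], cohort.references)
        assert list(df.columns) == ["reference_id", "pheno_sim", "diagnostic_genes"]
        assert (df["pheno_sim"].values[:-1] >= df["pheno_sim"].values[1:]).all()
        assert "simpheny_score" not in df.columns


class TestFileBasedRuns:
    @pytest.fixture
    def run_dir(self, tmp_path, cohort):
        d = tmp_path
        write_obo(cohort.graph, d / "ontology.obo")
        write_annotations(cohort.corpus, d / "annotations.tsv")
        write_patients_tsv(cohort.references, d / "references.tsv", kind="reference")
        write_patients_tsv(cohort.queries, d / "queries.tsv", kind="query")
        write_gene_corpus(cohort.gene_corpus, d / "gene_corpus.txt")
        write_truth(cohort.truth, d / "truth.tsv")
        return d

    def _cfg(self, d, **kw):
        return RunConfig(
            ontology=d / "ontology.obo", annotations=d / "annotations.tsv",
            reference=d / "references.tsv", queries=d / "queries.tsv",
            gene_corpus=d / "gene_corpus.txt", out_dir=d / "out",
            sim=FAST, **kw,
        )

    def test_missing_ebm_without_calibrate_errors(self, run_dir):
        with pytest.raises(ValueError, match="EBM"):
            run_match(self._cfg(run_dir))

    def test_run_match_writes_outputs(self, run_dir):
        res = run_match(self._cfg(run_dir, calibrate=True))
        out = run_dir / "out"
        for name in ("matches.tsv", "rankings.tsv", "ebm_params.json", "manifest.json"):
            assert (out / name).exists()
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["n_matches"] == len(res.matches) > 0

    def test_run_benchmark_summary(self, run_dir):
        cfg = self._cfg(run_dir, calibrate=True, truth=run_dir / "truth.tsv")
        summary = run_benchmark(cfg)
        assert 0.0 <= summary["auroc"] <= 1.0
        assert (run_dir / "out" / "threshold_metrics.tsv").exists()
        assert (run_dir / "out" / "labeled_matches.tsv").exists()

    def test_invalid_tier_thresholds_rejected(self, run_dir):
        with pytest.raises(ValueError):
            self._cfg(run_dir, tier_thresholds=(4.5, 2.5))

    def test_missing_input_path_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            RunConfig(ontology=tmp_path / "nope.obo", annotations=tmp_path / "a",
                      reference=tmp_path / "r", queries=tmp_path / "q",
                      out_dir=tmp_path / "out")


class TestBenchmarkPipeline:
    def test_all_tp_run_has_zero_fdr_everywhere(self, cohort):
        queries = []
        for q in cohort.queries:
            (gene,) = cohort.truth[q.patient_id]
            queries.append(PatientProfile(q.patient_id, q.terms, frozenset({gene})))
        res = match_pipeline(cohort.graph, cohort.references, queries,
                             sim_cfg=FAST, ebm=FISHER)
        truth = cohort.truth
        labeled, sweep, *_ = benchmark_pipeline(res, truth, thresholds=[0.0, 1.0, 2.0])
        assert all(lm.is_true_positive for lm in labeled)
        assert all(m.fdr == 0.0 for m in sweep)

    def test_truth_mismatch_lists_missing_ids(self, cohort):
        res = match_pipeline(cohort.graph, cohort.references, cohort.queries,
                             sim_cfg=FAST, ebm=FISHER)
        with pytest.raises(KeyError):
            benchmark_pipeline(res, {})
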