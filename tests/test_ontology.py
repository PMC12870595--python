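import math
import warnings

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from simpheny.ontology import (
    AnnotationCorpus,
    OboStructureError,
    ancestors,
    assign_disease_category,
    compute_information_content,
    curate_phenotypes,
    load_obo,
    read_annotations,
    read_exclusion_list,
)
from conftest import build_graph


class TestLoadObo:
    def test_chain_ontology(self, chain_obo):
        g = load_obo(str(chain_obo))
        assert len(g) == 3
        assert g.ancestors("T:0000003") == {"T:0000001", "T:0000002", "T:0000003"}
        assert g.root_id == "T:0000001"

    def test_obsolete_terms_dropped(self, tmp_path):
        obo = tmp_path / "obs.obo"
        obo.write_text(
            "format-version: 1.2\n\n[Term]\nid: T:1\nname: root\n\n"
            "[Term]\nid: T:2\nname: gone\nis_a: T:1\nis_obsolete: true\n\n"
            "[Term]\nid: T:3\nname: kept\nis_a: T:1\n"
        )
        g = load_obo(str(obo))
        assert "T:2" not in g
        assert "T:3" in g

    def test_two_branch_parent_sets_match_hand_parse(self, two_branch_obo):
        g = load_obo(str(two_branch_obo))
        expected = {
            "T:0000001": set(),
            "T:0000002": {"T:0000001"},
            "T:0000003": {"T:0000001"},
            "T:0000004": {"T:0000002"},
            "T:0000005": {"T:0000002"},
            "T:0000006": {"T:0000003"},
            "T:0000007": {"T:0000004", "T:0000006"},
        }
        assert {t: set(term.parents) for t, term in g.terms.items()} == expected

    def test_cycle_raises_structural_error(self, tmp_path):
        obo = tmp_path / "cycle.obo"
        obo.write_text(
            "format-version: 1.2\n\n[Term]\nid: T:1\nname: a\nis_a: T:2\n\n"
            "[Term]\nid: T:2\nname: b\nis_a: T:1\n"
        )
        with pytest.raises(OboStructureError, match="cycle"):
            load_obo(str(obo))

    def test_unknown_is_a_target_raises(self, tmp_path):
        obo = tmp_path / "dangling.obo"
        obo.write_text(
            "format-version: 1.2\n\n[Term]\nid: T:1\nname: root\n\n"
            "[Term]\nid: T:2\nname: c\nis_a: T:99\n"
        )
        with pytest.raises(OboStructureError, match="unknown"):
            load_obo(str(obo))

    def test_unreadable_file_raises_io_error(self, tmp_path):
        with pytest.raises(OSError):
            load_obo(str(tmp_path / "missing.obo"))


class TestAncestors:
    def test_root_closure_is_itself(self, toy_graph):
        assert ancestors(toy_graph, "R") == {"R"}

    def test_diamond_closure(self):
        g = build_graph({"R": set(), "B": {"R"}, "C": {"R"}, "D": {"B", "C"}})
        assert ancestors(g, "D") == {"D", "B", "C", "R"}

    def test_unknown_term_raises(self, toy_graph):
        with pytest.raises(KeyError):
            ancestors(toy_graph, "nope")

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_matches_reachability_oracle_on_random_dags(self, data):
        n = data.draw(st.integers(2, 50))
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        # Random DAG: node i may take parents among 0..i-1; node 0 is the root.
        edges = {"N0": set()}
        for i in range(1, n):
            k = int(rng.integers(1, min(i, 3) + 1))
            parents = rng.choice(i, size=k, replace=False)
            edges[f"N{i}"] = {f"N{p}" for p in parents}
        g = build_graph(edges, root="N0")
        nxg = nx.DiGraph(
            (child, parent) for child, ps in edges.items() for parent in ps
        )
        nxg.add_nodes_from(edges)
        probe = f"N{int(rng.integers(n))}"
        oracle = nx.descendants(nxg, probe) | {probe}  # reachable via parent links
        assert set(g.ancestors(probe)) == oracle


class TestInformationContent:
    def test_fully_annotated_term_has_zero_ic(self, toy_graph):
        assert toy_graph.ic("R") == 0.0
        assert toy_graph.terms["R"].frequency == 1.0

    def test_quarter_frequency_gives_ln4(self, toy_graph):
        assert toy_graph.ic("A1") == pytest.approx(math.log(4))

    def test_unannotated_term_smoothed(self, toy_corpus):
        g = build_graph({"R": set(), "A": {"R"}, "B": {"R"}, "A1": {"A"},
                         "A2": {"A"}, "Z": {"R"}})
        compute_information_content(g, toy_corpus)
        assert g.terms["Z"].frequency == pytest.approx(1 / 5)
        assert g.ic("Z") == pytest.approx(math.log(5))

    def test_descendant_inclusive_counting(self, toy_graph):
        # A is never annotated directly, but A1/A2 cover half the diseases.
        assert toy_graph.terms["A"].frequency == pytest.approx(0.5)

    def test_empty_corpus_rejected(self, toy_graph):
        with pytest.raises(ValueError):
            compute_information_content(toy_graph, AnnotationCorpus({}))

    def test_log_base_config(self, toy_corpus):
        g = build_graph({"R": set(), "A": {"R"}, "B": {"R"}, "A1": {"A"}, "A2": {"A"}})
        compute_information_content(g, toy_corpus, log_base=2)
        assert g.ic("A1") == pytest.approx(2.0)  # -log2(1/4)

    def test_ic_antitone_in_frequency_and_child_freq_bounded(self, toy_graph):
        terms = list(toy_graph.terms.values())
        for a in terms:
            for b in terms:
                if a.frequency < b.frequency:
                    assert a.information_content > b.information_content
            for p in a.parents:
                assert a.frequency <= toy_graph.terms[p].frequency

    def test_annotation_reader(self, tmp_path):
        f = tmp_path / "ann.tsv"
        f.write_text("# comment\ndisease_id\tterm_id\nd1\tA1\nd1\tA2\nd2\tB\n")
        corpus = read_annotations(f)
        assert corpus.n_diseases == 2
        assert corpus.disease_to_terms["d1"] == {"A1", "A2"}


class TestCuration:
    def test_exclusion_removes_listed_terms(self):
        assert curate_phenotypes({"seizure", "premature-birth"}, {"premature-birth"}) == {
            "seizure"
        }

    def test_empty_exclusion_is_identity(self):
        s = {"a", "b"}
        assert curate_phenotypes(s, set()) == s

    def test_full_exclusion_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="every term"):
            out = curate_phenotypes({"a"}, {"a"})
        assert out == set()

    def test_descendant_removal_flag(self, toy_graph):
        out = curate_phenotypes({"A1", "B"}, {"A"}, graph=toy_graph, remove_descendants=True)
        assert out == {"B"}

    def test_exclusion_list_reader(self, tmp_path):
        f = tmp_path / "excl.txt"
        f.write_text("# prenatal\nHP:1\n\nHP:2\n")
        assert read_exclusion_list(f) == {"HP:1", "HP:2"}


class TestDiseaseCategory:
    @pytest.fixture
    def category_graph(self):
        # Top-level branches N and E under root; X (IC 2.0) under N, Y/Z (0.5) under E.
        g = build_graph({"R": set(), "E": {"R"}, "N": {"R"},
                         "X": {"N"}, "Y": {"E"}, "Z": {"E"}})
        g.top_level_ids = ["E", "N"]
        ics = {"R": 0.0, "N": 0.1, "E": 0.1, "X": 2.0, "Y": 0.5, "Z": 0.5}
        for t, ic in ics.items():
            g.terms[t].information_content = ic
            g.terms[t].frequency = math.exp(-ic)
        return g

    def test_single_branch_term(self, category_graph):
        cat, _ = assign_disease_category(category_graph, {"X"})
        assert cat == "N"

    def test_hand_summed_scores(self, category_graph):
        cat, scores = assign_disease_category(category_graph, {"X", "Y", "Z"})
        assert cat == "N"
        assert scores == {"N": pytest.approx(2.0), "E": pytest.approx(1.0)}

    def test_tie_broken_lexicographically(self, category_graph):
        category_graph.terms["X"].information_content = 1.0
        cat, scores = assign_disease_category(category_graph, {"X", "Y", "Z"})
        assert scores["E"] == scores["N"]
        assert cat == "E"

    def test_empty_terms_rejected(self, category_graph):
        with pytest.raises(ValueError):
            assign_disease_category(category_graph, set())

    def test_off_category_term_skipped_with_warning(self, category_graph):
        with pytest.warns(UserWarning, match="top-level"):
            cat, _ = assign_disease_category(category_graph, {"R", "X"})
        assert cat == "N"

    def test_order_invariance(self, category_graph):
        a = assign_disease_category(category_graph, ["X", "Y", "Z"])
        b = assign_disease_category(category_graph, ["Z", "Y", "X"])
        assert a == b
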