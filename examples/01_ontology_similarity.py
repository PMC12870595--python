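"""Information content and IC-weighted similarity on a toy ontology.

Builds a five-term ontology (root R; branch A with leaves A1, A2; leaf
B), derives term frequencies from four annotated diseases, and prints
term-pair and set-level similarities.  Scores are in [0, 1]: 1 means the
two sides carry identical ancestor-IC content, 0 means they share only
uninformative (IC 0) ancestry.
"""

from simpheny.ontology import (
    AnnotationCorpus,
    OntologyGraph,
    OntologyTerm,
    assign_disease_category,
    compute_information_content,
)
from simpheny.similarity import fun_sim_avg, pheno_sim_jaccard

terms = {
    "R": OntologyTerm("R", "Phenotypic abnormality", frozenset()),
    "A": OntologyTerm("A", "Abnormality of system A", frozenset({"R"})),
    "B": OntologyTerm("B", "Abnormality of system B", frozenset({"R"})),
    "A1": OntologyTerm("A1", "Specific finding A1", frozenset({"A"})),
    "A2": OntologyTerm("A2", "Specific finding A2", frozenset({"A"})),
}
graph = OntologyGraph(terms=terms, root_id="R")
graph.top_level_ids = ["A", "B"]

# two diseases under branch A, two under B -> freq(A)=1/2, freq(A1)=1/4
corpus = AnnotationCorpus({"d1": {"A1"}, "d2": {"A2"}, "d3": {"B"}, "d4": {"B"}})
compute_information_content(graph, corpus)

for t in ("R", "A", "A1"):
    print(f"IC({t}) = {graph.ic(t):.4f}  (frequency {graph.terms[t].frequency:.2f})")

print(f"sim(A1, A2) = {pheno_sim_jaccard(graph, 'A1', 'A2'):.4f}   # siblings share R and A")
print(f"sim(A1, A)  = {pheno_sim_jaccard(graph, 'A1', 'A'):.4f}   # child vs parent")
print(f"funSimAvg({{A1}}, {{A1,A2}}) = {fun_sim_avg(graph, {'A1'}, {'A1', 'A2'}):.4f}")

category, scores = assign_disease_category(graph, {"A1", "A2", "B"})
print(f"disease category: {category}  (cumulative IC scores {scores})")
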