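"""Patient profiles and enumeration of query↔reference gene matches.

A *match* is a (query, reference, gene) triple in which one of the
query's candidate genes is a diagnostic gene of a reference patient; a
gene diagnosed in k reference patients yields k matches.  Matches carry
the downstream statistical annotations (phenotypic similarity, empirical
p-values, combined p, score, tier).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PatientProfile",
    "ReferencePatient",
    "SimPhenyMatch",
    "find_matches",
    "read_patients_tsv",
    "read_patients_jsonl",
]


def _norm_genes(genes: Iterable[str] | None) -> frozenset[str]:
    if genes is None:
        return frozenset()
    out = frozenset(g.strip().upper() for g in genes if g and g.strip())
    return out


@dataclass(frozen=True)
class PatientProfile:
    """A query patient: id, curated phenotype terms, optional candidate genes."""

    patient_id: str
    terms: frozenset[str]
    candidate_genes: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "terms", frozenset(self.terms))
        object.__setattr__(self, "candidate_genes", _norm_genes(self.candidate_genes))


@dataclass(frozen=True)
class ReferencePatient:
    """A diagnosed reference patient; multigenic diagnoses are allowed."""

    patient_id: str
    terms: frozenset[str]
    diagnostic_genes: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "terms", frozenset(self.terms))
        genes = _norm_genes(self.diagnostic_genes)
        if not genes:
            raise ValueError(
                f"reference patient {self.patient_id!r} has no diagnostic gene"
            )
        object.__setattr__(self, "diagnostic_genes", genes)


@dataclass
class SimPhenyMatch:
    """One query↔reference gene overlap with its statistical annotations."""

    query_id: str
    reference_id: str
    gene: str
    pheno_sim: float | None = None
    pheno_p: float | None = None
    gene_p: float | None = None
    combined_p: float | None = None
    score: float | None = None
    adjusted_p: float | None = None
    tier: str | None = None


def find_matches(
    query: PatientProfile,
    cohort: Sequence[ReferencePatient],
    *,
    exclude_self: bool = True,
) -> list[tuple[str, str, str]]:
    """Enumerate (query_id, reference_id, gene) overlaps against a cohort.

    One tuple per reference patient per shared gene, sorted by
    (reference_id, gene).  With ``exclude_self`` the query cannot match
    itself (by patient_id) — avoids trivial rediscovery.
    """
    if not query.candidate_genes:
        raise ValueError(
            f"query {query.patient_id!r} has no candidate gene list; "
            "use phenotype-only mode for similarity without gene scoring"
        )
    out: list[tuple[str, str, str]] = []
    for ref in cohort:
        if exclude_self and ref.patient_id == query.patient_id:
            continue
        for gene in query.candidate_genes & ref.diagnostic_genes:
            out.append((query.patient_id, ref.patient_id, gene))
    out.sort(key=lambda t: (t[1], t[2]))
    return out


def _split(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return []
    return [x for x in str(cell).split(";") if x.strip()]


def read_patients_tsv(path, *, kind: str = "query"):
    """Read patients from TSV.

    Columns: ``patient_id``, ``hpo_terms`` (semicolon-separated), and
    ``candidate_genes`` (kind="query") or ``diagnostic_genes``
    (kind="reference").
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return _patients_from_records(df.to_dict("records"), kind=kind)


def read_patients_jsonl(path, *, kind: str = "query"):
    """JSON-lines equivalent of :func:`read_patients_tsv` (same field names)."""
    records = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                records.append(json.loads(line))
    return _patients_from_records(records, kind=kind)


def _patients_from_records(records, *, kind: str):
    if kind not in ("query", "reference"):
        raise ValueError("kind must be 'query' or 'reference'")
    out = []
    for rec in records:
        terms = rec.get("hpo_terms", [])
        if not isinstance(terms, (list, tuple, set)):
            terms = _split(terms)
        if kind == "query":
            genes = rec.get("candidate_genes", [])
            if not isinstance(genes, (list, tuple, set)):
                genes = _split(genes)
            out.append(
                PatientProfile(
                    patient_id=str(rec["patient_id"]),
                    terms=frozenset(terms),
                    candidate_genes=frozenset(genes),
                )
            )
        else:
            genes = rec.get("diagnostic_genes", [])
            if not isinstance(genes, (list, tuple, set)):
                genes = _split(genes)
            out.append(
                ReferencePatient(
                    patient_id=str(rec["patient_id"]),
                    terms=frozenset(terms),
                    diagnostic_genes=frozenset(genes),
                )
            )
    return out
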