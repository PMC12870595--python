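# Methods

## Model overview

`simpheny` scores candidate genes for an undiagnosed patient by matching
the patient against diagnosed reference patients. The model has four
layers: (1) an ontology-derived phenotypic similarity, (2) Monte-Carlo
empirical nulls for phenotype and gene evidence, (3) a dependence-aware
p-value combination, and (4) gene-level aggregation and ranking. Each is
described below together with the numerical choices made where the design
was genuinely open.

## Information content and similarity

Term frequency is counted **descendant-inclusively**: a disease annotated
to a child counts for every ancestor (true-path rule), so frequency is
monotone along the hierarchy and `IC = −log(frequency)` is antitone.
Terms with no annotations anywhere below them are smoothed to
`frequency = 1/(n_diseases + 1)`, keeping IC finite while staying below
the smallest observable frequency `1/n_diseases`.

IC uses the **natural logarithm** by default. All similarity values are
ratios of IC sums and therefore base-invariant; absolute IC values are
not, so the base is exposed as `log_base` on
`compute_information_content` for anyone comparing raw ICs against
bit-scaled conventions.

PhenoSimJaccard divides the IC sum of the shared self-inclusive ancestor
closure by the IC sum of the union. Degenerate 0/0 cases (e.g. the root
compared with itself under full annotation) are defined as similarity 0:
a comparison supported by zero information carries no evidence of
similarity. Duplicate terms in a patient's list are collapsed before
scoring (set semantics). The set-level funSimAvg score is the symmetric
best-match average; no cap or weighting is applied to large term sets.

Internally, similarity is evaluated from a precomputed boolean
term-by-ancestor matrix and IC vector, so blocks of term pairs reduce to
two matrix products. This is purely a cache; the unit tests check it
against an explicit ancestor-set oracle at 1e-12.

## Phenotype curation and disease categories

Curation removes uninformative terms (typically prenatal/perinatal
history, which is often pre-populated in collection interfaces rather
than clinically meaningful) by exact ID match against a user-supplied
exclusion file; an optional `remove_descendants` flag additionally drops
every term below a listed term. Patients emptied by curation are skipped
with a warning rather than silently dropped.

A term set's disease category is the top-level branch (first-level child
of the phenotypic-abnormality node; 23 in the real ontology) with the
highest cumulative IC over the set, each term contributing its IC once to
every top-level ancestor it reaches. Ties are broken by lexicographically
smaller term id — arbitrary, but deterministic and documented.

## Monte-Carlo nulls

Both p-values use the +1-corrected estimator `(1 + k)/(1 + N)`, so the
attainable range is exactly `[1/(N+1), 1]` and zero p-values are
impossible. Default `N = 10,000` per match.

*pheno p*: each replicate draws a randomized query list from the multiset
of all reference-cohort annotations, weighted by multiset count, without
replacement (successive draws over distinct terms with probability
proportional to remaining counts), capped at `max_sim_terms = 10` terms
(the observed list length if shorter), and scores it against the
*observed reference list*. Only the query side is randomized. The cap
keeps replicate cost bounded for deeply phenotyped patients; note that
when a query exceeds the cap, simulated lists are shorter than the
observed one, which makes the null slightly conservative. The ontology's
hierarchy correlates terms, so simulated lists can partially recreate
real presentations; no correction is applied for this.

*gene p*: each replicate draws a candidate list of the query's length
with replacement from the cohort-wide gene multiset and records binary
presence of the matched gene. Presence per replicate is
`Binomial(L, q) > 0` with `q` the gene's corpus fraction — exactly the
distribution of materializing the `L` draws — and is simulated that way,
which vectorizes cleanly at `N = 10⁴`.

Per-match RNG streams are derived from the master seed plus a CRC32 hash
of (query id, reference id, gene), with separate child streams for the
phenotype and gene nulls. Consequences: fixed seed ⇒ bit-identical
results; matches can be computed in any order; adding or removing other
patients never perturbs a surviving match's gene p or similarity (pheno p
shifts only insofar as the annotation corpus itself changes).

## Combining p-values

The two p-values are positively dependent (phenotypic similarity makes
the shared gene likelier to appear on the candidate list), so Fisher's
method would be anti-conservative. Empirical Brown's Method refers
`X = −2 ln p₁ − 2 ln p₂` to a scaled chi-square `c·χ²_f` with
`E[X] = 4`, `Var(X) = 8 + 2·cov(w₁, w₂)`, `f = 32/Var`, `c = Var/8`
(hence `c·f = 4` identically).

The covariance is estimated as `4·corr(−2 ln p₁, −2 ln p₂)`: the exact
uniform-marginal variance (`Var(−2 ln p) = 4`) moment-matched with the
empirical correlation. This makes the two limiting cases exact — an
independent sample calibrates to `(c, f) ≈ (1, 4)` (Fisher) and
identical columns to exactly `(2, 2)`, under which the combination
returns the single p unchanged. A raw sample-covariance estimator
(`estimator="covariance"`) is available for sensitivity checks; the
correlation of inverse-normal z-scores is reported alongside as `rho`.
Calibration requires ≥ 10 non-degenerate pairs and should be done per
reference dataset — dependence structure varies with cohort composition —
then frozen to a JSON sidecar and reused, keeping scores comparable
across runs against that dataset.

The combined p is floored at the smallest positive normal float so the
score `−log10(p)` stays finite. Confidence tiers use inclusive lower
bounds: high ≥ 4.5, medium ∈ [2.5, 4.5), low < 2.5.

Benjamini–Hochberg adjusted p-values are computed across all matches of a
run, for completeness only: they depend on the run's match count and are
not portable across cohorts, unlike the score itself.

## Gene ranking and benchmarking

A gene's score is the mean of its two best match scores — repeated
support counts, but a pile of weak matches cannot outrank one strong one;
a single match contributes its score unchanged. Ranking sorts descending,
ties broken alphabetically for determinism.

Benchmarking labels a match TP when its gene is among the query's known
diagnostic genes. Threshold sweeps use inclusive comparison
(score ≥ t) on a 0.5-step grid from 1.0 to 6.0 by default; FDR of an
empty call set is defined as 0. Because matched cohorts are heavily
FP-dominated, the FDR–TPR sweep is the primary operating view; the ROC
curve and trapezoid auROC are also computed (tested against an O(n²)
Mann–Whitney oracle). The top-k summary counts a multigenic query as a
hit when any of its diagnostic genes ranks within k, over queries with at
least one ranked gene.

## Synthetic data generator

The generator emulates the structure the pipeline sees in practice, not
any particular cohort's content. Ontology: one root, `n_top_level = 23`
first-level category branches, each a complete tree with
`branching = 3`, `depth = 3`, plus ~5% extra parent links toward
shallower nodes in the same branch to make the DAG genuine.
Disease annotations (150 diseases, ~6 terms each) draw terms with
Zipf-skewed popularity, producing the right-skewed frequency profile of
real annotation corpora (few common terms, many rare ones).

Each of the 20 genes owns a term pool — the subtree under one
second-level node — so patients sharing a causal gene share a coherent
ontology region. A patient takes `ceil(signal_frac · terms_per_patient)`
pool terms and fills to `terms_per_patient = 12` with uniform noise;
`signal_frac` (default 0.7) interpolates between a pure null and fully
penetrant phenotypes. Each gene gets `refs_per_gene = 3` diagnosed
references; each of the 40 queries carries its causal gene plus 5
Zipf-popularity-weighted decoys, mimicking recurrently prioritized genes;
the gene corpus is the multiset of all candidate entries.

What the generator does **not** emulate: real HPO depth and topology,
inter-patient phenotyping-quality variation, multigenic diagnoses,
relatedness between patients, and candidate lists produced by actual
variant analysis. Passing recovery tests therefore demonstrates the
statistical machinery is sound under its own assumptions, not clinical
performance on real cohorts.

## Problem sizes and tolerances in the test suite

Stochastic tests run at reduced but honest sizes chosen once: 400–1,000
Monte-Carlo replicates per match in pipeline tests (the p-value floor
moves accordingly; orderings and calibrations do not), 500 same-gene
pairs for the null-uniformity check, and the spec-level recovery setting
(20 genes × 3 references, signal 0.7) for auROC. The null-uniformity
check uses 8-term patients so simulated null lists and real query lists
have identical lengths; with longer queries the 10-term cap itself
induces a systematic length mismatch that is a property of the method
(conservatism), not a calibration error. Analytic comparisons use 3
binomial standard errors; exact identities are asserted at 1e-12.

## Known limitations

- The phenotype null ignores ontology-induced term correlation.
- Gene identity is upper-cased string equality; no alias resolution.
- A gene absent from the diagnosed reference cohort can never be
  recovered — coverage of the reference set bounds diagnostic reach.
- Self-matching is prevented by patient id only; excluding phenotypically
  identical relatives is the cohort curator's responsibility.
- BH adjustment is run-scoped by design; compare scores, not adjusted
  p-values, across cohorts.
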