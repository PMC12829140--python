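# Methods

## The discovery model

`lbdkit` implements Swanson-style serial A-B-C literature-based discovery.
The unit of analysis is a document consisting of a title and abstract; a
corpus of *N* documents is the statistical population. A term query is a
disjunction of conjunctions of exact phrases (`|` outer, `&` inner, no
parentheses). Two terms *co-occur* when both queries match the same
document.

For each candidate pair, occurrence and co-occurrence counts form a 2×2
contingency table (n₁₁ both, n₁₂/n₂₁ one only, n₂₂ neither). The pair is
scored by the one-sided Fisher's exact test for enrichment:
P(X ≥ n₁₁) with X ~ Hypergeom(N, n₁₁+n₁₂, n₁₁+n₂₁). The one-sided
(greater) form is used because co-occurrence discovery asks whether two
terms appear together *more* often than independence predicts;
under-representation is not a discovery signal. The test is symmetric in
the two terms and equals 1 whenever n₁₁ = 0.

The serial search proceeds in two gated stages: A-B pairs with p ≤ α
survive stage 1; B-C pairs for surviving Bs with p ≤ α survive stage 2;
each (A, B, C) with both stages significant becomes a hit. A pair must
also co-occur in at least one document — with n₁₁ = 0 there is no evidence
to retrieve, and p = 1 would otherwise pass an α = 1 gate.

### Ranking

Hits are ranked by

    score = -log10(max(p_ab, p_bc)) × min(1, (n11_ab + n11_bc) / scale)

with `scale` = 10 by default. The weaker p-value dominates (a chain is only
as strong as its weaker link); the capped count factor damps hits supported
by very few co-occurring documents while not rewarding raw frequency beyond
the cap. The scoring strategy is pluggable (`SkimConfig.score_fn`) and the
strategy name is recorded in each run's manifest. Ties are broken by
p_ab + p_bc ascending, then lexicographically by the raw (a, b, c) query
strings, so rankings are fully reproducible.

### Matching semantics

Matching is exact-phrase, case-insensitive, at token boundaries: a phrase
matches iff it occurs as a contiguous substring of `title + " " + text`
whose flanking characters are non-alphanumeric or the string edge. Hyphens
are boundaries, so `AHR` matches "AHR-dependent" but not "SAHRA".
Case-folding is used because gene symbols and drug names vary in casing
across abstracts. No stemming or synonym expansion is applied beyond
explicit `|` alternatives — the relevance filter exists precisely to clean
up the ambiguity that exact matching admits. Time-slicing (`cutoff_year`)
excludes documents with year > cutoff; documents without a year are kept,
and the population N is reduced accordingly.

### Defaults that matter

| parameter | default | rationale |
|---|---|---|
| α (FET gate) | 1e-5 | B lists routinely hold thousands of genes; an uncorrected 0.05 would be meaningless. No multiple-testing correction is applied; the strict α plays that role. Configurable. |
| top_k | 100 | ranked hits returned |
| score scale | 10 | co-occurrence count cap in the ranking score |
| abstract cap | 25 | max abstracts per co-occurrence list / fed to the judge |
| n_runs | 10 | judge runs aggregated per hypothesis |

Retrieved abstracts are ordered by doc_id descending, a recency proxy for
PMID-like identifiers (citation counts are unavailable offline), and
truncated to the cap per list (A-B, B-C, A-C). All three lists are included
in the judge prompt bundle.

## Relevance filtering

The filter is a *contract*: any total, deterministic callable
`(abstract_text, hypothesis_text) → {0, 1}`, with 1 = relevant. Relevance
means the abstract can be used to evaluate the hypothesis, regardless of
whether it supports or contradicts it. Shipped implementations:

- **keyword baseline** — 1 iff at least 2 of the 3 instantiated entity
  queries match the abstract under the search matching rules. This is a
  deliberately simple offline stand-in; it inherits exact matching's
  blindness to context (an abstract mentioning the disease and gene but no
  treatment still passes), which is exactly the error mode a trained
  relevance model is meant to remove.
- **constant classifier** — for pipeline plumbing and ablations.
- **external-process adapter** — one `abstract \t hypothesis` line on
  stdin, one `0`/`1` line on stdout, so any trained model can be plugged in
  without adding dependencies.

Evaluation uses the standard 2×2 confusion matrix with relevant as the
positive class. Undefined precision/recall/F1 (zero denominator) are
reported as 0 with a warning rather than NaN so downstream arithmetic stays
finite. Note that an F1 computed from 2-decimal-rounded precision and
recall can differ in the second decimal from the F1 of the raw counts
(e.g. counts (tp=44, fn=4, tn=5, fp=19) give F1 = 0.793 raw but 0.80 from
the rounded 0.70/0.92); `metrics_report` therefore exposes both full-
precision and display-rounded values. When every abstract for a hit is
classified 0, the hit is flagged "no relevant abstracts" and reported as
`N/A` instead of being scored.

## Hypothesis scoring

Templates contain `{a-term}`, `{b-term}`, `{c-term}` placeholders, each at
most once; substitution is verbatim (no re-casing), and when a term is a
boolean query the first alternative's first phrase is the display surface
form. Prompts serialize deterministically as guidelines, hypothesis, then
numbered abstracts `[doc_id] title / text`; an empty abstract list is legal
only in explicit no-text mode (the leakage baseline).

The judge contract is `(prompt, run_index) → raw text`. Responses must end
with a `Score: n` marker, n ∈ {−2…2}; the marker is required by the
shipped guidelines because an explicit marker makes parsing testable, and
the marker string is configurable for judges with other formats. Bracketed
tokens are parsed as abstract citations and filtered to the prompt's ids.
A response that fails to parse is retried once, then recorded as missing
and excluded from the aggregate with a warning; a fully failed run set is
an error. The aggregate is the standard sample median (half-integers for
even counts), with min/max retained.

## Agreement statistics

Five statistics compare score sets on the −2…+2 scale:

- **RMSE** = sqrt(mean((x−y)²)).
- **QWK**: κ = 1 − Σw·O / Σw·E with w_ij = (i−j)²/(K−1)², O the observed
  joint proportion matrix over the K = 5 ordinal categories, E the outer
  product of its marginals. Inputs are rounded to the nearest category
  (halves away from zero, so a −0.5 median becomes −1). If both raters are
  constant, chance agreement is undefined: identical constants return 1,
  differing constants raise.
- **ICC(2,1)**: two-way random effects, absolute agreement, single
  measure, (MSR−MSE)/(MSR+(k−1)MSE+(k/n)(MSC−MSE)) from the two-way ANOVA
  decomposition. Zero total variance raises (undefined).
- **Directional concordance**: agreement in sign category (negative /
  exactly zero / positive) of paired medians. Zero is its own category —
  a "no evidence either way" median is treated as agreeing only with
  another neutral verdict.
- **Within-range agreement**: whether the system median lies in the closed
  interval [min, max] of the human scores for that hypothesis.

Half-integer system medians are used raw by RMSE, ICC and the range check
(they carry information) and rounded only for QWK, which needs categories.
In `agreement_report` the pairwise statistics compare the system column
against the per-hypothesis *human median* (configurable), and ICC(2,1) is
computed over the full hypotheses × raters table with the system as one
rater. Where a comparison could equally be made against each human
individually, the human-median convention was chosen as the single
documented default.

## Synthetic data: what it emulates, and what it does not

The corpus generator emulates the statistical skeleton of a PubMed slice:
background terms appear independently in each document at
`background_rate` (default 0.02) while each planted (A,B) and (B,C) pair
receives `n_link_docs_per_pair` (default 20) dedicated link documents in a
500-document corpus, in which the pair co-occurs with probability
`boost_rate` (default 1.0, so the planted co-occurrence count is a
construction guarantee). At these rates a planted pair's FET p-value is
astronomically small (≈10⁻²⁵) while a random background pair exceeds
p = 0.05 unless it collides in ≥ 2 documents (probability ≈ 2% under the
defaults). Documents are templated pseudo-abstract sentences with ordinary
token boundaries, so generated text is matched by the same rules as real
text. All generators are pure functions of configuration + seed.

Sentiment-controlled abstracts assert a positive, neutral ("no
relationship exists…"), or negative drug-disease relationship in natural
language *and* carry an explicit marker token (`POSFINDING`, `NEUFINDING`,
`NEGFINDING`). The mock judge scores by comparing abstract markers with the
hypothesis direction: full agreement → +2, full contradiction → −2, mixed
→ the rounded proportional integer, no abstracts → 0. Markerless (real-
corpus) abstracts count as supporting. The marker design makes the mock
judge correct by construction: the offline test surface exercises
plumbing, determinism and statistics, **not** language understanding.
Consequently passing tests say nothing about how a real LLM judge would
score real abstracts; in particular, a real LLM's no-text responses leak
parametric knowledge (scoring well-known drugs positively with no evidence
supplied), whereas the mock's no-text output is a neutral 0 by design. The
leakage harness reproduces the matched-sentiment grounding *pattern*
(median +2 in every matched condition) rather than any real model's
behavior; plugging in a live judge via the external-process adapter is how
the real experiment would be run.

The 20-drug leakage fixture list contains the seventeen distinct drugs of
the worked disease-gene-drug evaluation plus trastuzumab, tamoxifen and
letrozole.

## Numerical and degenerate-input choices

- FET p-values are computed via the hypergeometric survival function and
  clamped to (0, 1]; n₁₁ = 0 short-circuits to exactly 1.0.
- The ranking score raises on p ≤ 0 (unreachable from the test itself).
- Rounding onto the ordinal grid is half-away-from-zero (numpy's default
  half-even would map −0.5 to 0, losing the refuting signal).
- Empty corpora, empty term lists, zero-variance ICC tables, degenerate
  QWK marginals, and unresolved template placeholders all raise typed
  errors rather than returning sentinel values.
- Manifest files key input checksums by file name, not path, so relocated
  reruns of the same configuration remain byte-identical.

## Problem sizes

The shipped tests and the acceptance script use 300–500-document corpora,
50 seeded replicates for recovery rates, 20 drugs × 10 runs for the
leakage pattern, and 100 seeded random tables for the statistics oracles —
sizes at which every property being checked (exact test correctness,
ranking, determinism, rates) is already fully expressed.

## Known limitations

- Exact-phrase matching has no concept normalization (no MeSH/UMLS); it
  will conflate homonyms (the classic "AHR" ambiguity) and miss unlisted
  synonyms. That is by design — the relevance filter is the mitigation.
- The shipped relevance baseline is a keyword heuristic, not a trained
  model; its precision on ambiguous abstracts is poor by construction.
- The mock judge cannot assess real abstracts' semantics; live-judge
  adapters are provided but deliberately untested offline.
- No full-text retrieval; titles and abstracts only.
- Significance gating uses a fixed α with no FDR control; with very large
  B lists users should tighten α accordingly.
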