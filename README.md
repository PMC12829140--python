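# lbdkit

Literature-based discovery (LBD) with automated hypothesis evaluation.

Co-occurrence LBD systems surface Swanson-style *A-B-C* leads — A and B
co-occur in the literature, B and C co-occur, so A and C may be related
through B — but they find statistical associations, not biological
relationships, and their hit lists are expensive to curate by hand.
`lbdkit` implements the full triage workflow around that problem for
computational biologists and text-mining researchers:

1. **Serial A-B-C search** — exact-phrase matching of boolean term queries
   (`|` for synonyms, `&` for conjunction) over a title+abstract corpus,
   with each A-B and B-C pair scored by a one-sided Fisher's exact test on
   its 2×2 document co-occurrence table. With corpus size *N* and term
   margins *m_x*, *m_y*, the pair p-value is
   *P(X ≥ n₁₁)* for *X* ~ Hypergeom(*N*, *m_x*, *m_y*). Hits linking A and
   C through a significant B are ranked by
   `score = -log10(max(p_ab, p_bc)) · min(1, (n11_ab + n11_bc)/10)`.
2. **Relevance filtering** — retrieved abstracts are classified 0/1 for
   relevance to the user's instantiated hypothesis (e.g. "*{c-term} treats
   {a-term} through its effect on {b-term}*") by any classifier satisfying
   a simple contract; a 2-of-3 entity keyword baseline, a constant
   classifier, and an external-process adapter are shipped, plus
   confusion-matrix / accuracy / precision / recall / F1 evaluation.
3. **Hypothesis scoring** — a judge (deterministic mock, external process,
   or HTTP adapter) reads the rubric, hypothesis, and relevant abstracts
   and returns an integer score from −2 (strongly refutes) to +2 (strongly
   supports); 10 independent runs are aggregated into a median score
   distribution.
4. **Agreement statistics** — RMSE, quadratic-weighted Cohen's κ,
   ICC(2,1), directional concordance, and within-range agreement for
   comparing system scores with expert raters.
5. **Synthetic data** — corpus generation with planted A-B/B-C
   associations, sentiment-controlled fake abstracts, and a deterministic
   mock judge, so the whole pipeline (including a parametric-knowledge-
   leakage harness) runs and is testable fully offline.

## Worked example

Generate a 500-document synthetic corpus with one planted chain
(*breast cancer* — *EGFR* — *erlotinib*), search it, and evaluate the top
hit with the deterministic mock judge:

```bash
lbd simulate --seed 7 --out run/sim
lbd skim --corpus run/sim/corpus.jsonl \
    --a-terms run/sim/a_terms.txt --b-terms run/sim/b_terms.txt \
    --c-terms run/sim/c_terms.txt --out run/skim
lbd evaluate --skim-dir run/skim --corpus run/sim/corpus.jsonl \
    --seed 7 --out run/eval
```

`run/skim/hits.tsv` contains the single significant hit:

```
rank  a_term         b_term  c_term     p_ab         p_bc         n11_ab  n11_bc  n11_ac  prediction_score
1     breast cancer  EGFR    erlotinib  5.16821e-25  5.16821e-25  20      20      0       24.2867
```

The planted pair co-occurs in 20 of 500 documents, which under the
hypergeometric null has p ≈ 5·10⁻²⁵ for both stages; no background pair
passes the default gate (α = 10⁻⁵). `run/eval/summary.tsv` then shows the
scored hypothesis:

```
rank  a_term         b_term  c_term     hypothesis                                                  score_median  score_min  score_max  n_runs  n_relevant  label
1     breast cancer  EGFR    erlotinib  erlotinib treats breast cancer through its effect on EGFR   2             2          2          10      25          
```

All 25 retained abstracts support the hypothesis, so all 10 judge runs
score +2 (median +2). A hit whose abstracts are all filtered out is
reported as `N/A` rather than scored. The `label` column is left blank for
manual true-positive/true-negative annotation.

Agreement statistics for a hypotheses × raters score table:

```bash
lbd agree --table scores.tsv --out agreement.json
```

and the leakage experiment (20 fixture drugs × conditions):

```bash
lbd leakage --n-runs 10 --seed 0 --out run/leakage
```

Every command writes a `manifest.json` (config hash, seed, input
checksums); reruns with the same manifest are byte-identical.

## Layout

- `src/lbdkit/corpus.py` — corpus readers (JSONL, MEDLINE), query parsing,
  exact-phrase matching
- `src/lbdkit/search.py` — contingency tables, Fisher's exact test,
  ranking, serial search, abstract retrieval
- `src/lbdkit/relevance.py` — relevance-classifier contract, baselines,
  metrics
- `src/lbdkit/judge.py` — hypothesis templates, prompts, judge contract,
  score aggregation
- `src/lbdkit/agreement.py` — RMSE / QWK / ICC(2,1) / concordance / range
- `src/lbdkit/synth.py` — synthetic corpora, sentiment abstracts, mock
  judge, leakage harness
- `src/lbdkit/cli.py` — `lbd` command with `simulate`, `skim`, `evaluate`,
  `agree`, `leakage` subcommands

See `docs/methods.md` for the statistical model, default parameters, and
known limitations.
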