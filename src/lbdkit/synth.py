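"""Synthetic corpora, sentiment-controlled abstracts, and a mock judge.

Everything needed to exercise the discovery pipeline offline:

* :func:`generate_corpus` builds a PubMed-like corpus of templated
  pseudo-abstracts in which chosen A-B and B-C term pairs are planted as
  co-occurrence-enriched "link" documents against an independent background,
  so the planted pairs are Fisher-exact significant and background pairs
  are not.
* :func:`generate_sentiment_abstracts` writes fake abstracts asserting a
  positive, neutral, or negative relationship between a drug and a disease,
  each carrying a machine-detectable sentiment marker token. These drive
  the parametric-knowledge-leakage harness: a judge that grounds its answer
  in the supplied text must score matched sentiment/hypothesis pairs
  highly regardless of what is true of the real drug.
* :func:`mock_judge` is a deterministic judge-contract implementation that
  scores by comparing abstract sentiment markers with the hypothesis
  direction. It tests plumbing and statistics, not language understanding;
  in particular its no-text output is a documented neutral 0, unlike a real
  LLM whose parametric memory leaks into no-text scores.
* :func:`leakage_harness` runs drugs x conditions through a judge and
  emits per-cell score distributions plus a long-format table.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .corpus import AbstractRecord, Corpus, match_documents, parse_query
from .judge import JudgePrompt, ScoreDistribution, build_prompt, run_judge

__all__ = [
    "CorpusGenConfig",
    "SentimentSpec",
    "SynthError",
    "SENTIMENT_MARKERS",
    "BREAST_CANCER_DRUGS",
    "DEFAULT_VOCAB",
    "generate_corpus",
    "generate_sentiment_abstracts",
    "sentiment_hypothesis",
    "mock_judge",
    "leakage_harness",
]


class SynthError(ValueError):
    """Raised for invalid generator configurations."""


# Explicit marker tokens let the mock judge score by construction.
SENTIMENT_MARKERS = {
    "positive": "POSFINDING",
    "neutral": "NEUFINDING",
    "negative": "NEGFINDING",
}

# Fixture drug list for the leakage harness: the drugs of the worked
# disease-gene-drug evaluation plus three standard FDA-approved
# breast-cancer therapies, totalling twenty.
BREAST_CANCER_DRUGS = [
    "venetoclax", "olaparib", "abemaciclib", "fulvestrant", "palbociclib",
    "afatinib", "cetuximab", "crizotinib", "dacomitinib", "erlotinib",
    "gefitinib", "panitumumab", "pemetrexed", "alpelisib", "everolimus",
    "temsirolimus", "isosulfan blue", "trastuzumab", "tamoxifen", "letrozole",
]

DEFAULT_VOCAB = tuple(
    [f"GENE{i:03d}" for i in range(1, 41)]
    + [f"CMPD{i:03d}" for i in range(1, 31)]
    + [f"disorder type {i}" for i in range(1, 11)]
)


@dataclass
class CorpusGenConfig:
    """Synthetic-corpus generator configuration.

    Defaults are the standing study conditions for planted-link recovery:
    a 500-document corpus, background terms appearing independently in 2%
    of documents, and 20 dedicated link documents per planted pair in which
    the pair co-occurs with probability ``boost_rate`` (1.0, so the planted
    co-occurrence count is guaranteed by construction).
    """

    n_docs: int = 500
    vocab: Sequence[str] = DEFAULT_VOCAB
    planted_triples: Sequence[tuple[str, str, str]] = (
        ("breast cancer", "EGFR", "erlotinib"),
    )
    background_rate: float = 0.02
    boost_rate: float = 1.0
    n_link_docs_per_pair: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.background_rate <= 1 and 0 <= self.boost_rate <= 1):
            raise SynthError("rates must lie in [0, 1]")
        n_link_total = 2 * self.n_link_docs_per_pair * len(self.planted_triples)
        if self.n_docs < n_link_total:
            raise SynthError(
                f"n_docs={self.n_docs} cannot hold {n_link_total} link documents"
            )


_BACKGROUND_TEMPLATES = [
    "We examined the role of {t} in a retrospective cohort.",
    "Expression of {t} was quantified across tissue samples.",
    "Prior reports have implicated {t} in disease progression.",
    "Levels of {t} varied substantially between patients.",
]

_LINK_TEMPLATES = [
    "A significant association between {x} and {y} was observed.",
    "Our data link {x} with {y} in multiple patient subgroups.",
    "Co-regulation of {x} and {y} emerged as a consistent finding.",
]


def generate_corpus(config: Optional[CorpusGenConfig] = None) -> Corpus:
    """Generate a pseudo-abstract corpus with planted pair co-occurrences.

    Each document embeds its sampled terms in templated sentences with
    ordinary whitespace/punctuation token boundaries, so generated text is
    matched correctly by the exact-phrase search rules. Fully reproducible
    from ``config.seed``.
    """
    config = config or CorpusGenConfig()
    planted_terms = {t.lower() for triple in config.planted_triples for t in triple}
    for v in config.vocab:
        if v.lower() in planted_terms:
            raise SynthError(f"vocabulary term {v!r} collides with a planted term")

    rng = random.Random(config.seed)
    doc_terms: list[list[str]] = []
    doc_pairs: list[list[tuple[str, str]]] = []
    for _ in range(config.n_docs):
        doc_terms.append([t for t in config.vocab if rng.random() < config.background_rate])
        doc_pairs.append([])

    # Assign disjoint link-document blocks for each planted pair.
    order = list(range(config.n_docs))
    rng.shuffle(order)
    cursor = 0
    for a, b, c in config.planted_triples:
        for x, y in ((a, b), (b, c)):
            for _ in range(config.n_link_docs_per_pair):
                i = order[cursor]
                cursor += 1
                if rng.random() < config.boost_rate:
                    doc_pairs[i].append((x, y))
                else:
                    doc_terms[i].append(rng.choice((x, y)))

    records = []
    for i in range(config.n_docs):
        sentences = []
        for x, y in doc_pairs[i]:
            sentences.append(rng.choice(_LINK_TEMPLATES).format(x=x, y=y))
        for t in doc_terms[i]:
            sentences.append(rng.choice(_BACKGROUND_TEMPLATES).format(t=t))
        if not sentences:
            sentences.append("No notable molecular findings were reported.")
        first = doc_pairs[i][0][0] if doc_pairs[i] else (
            doc_terms[i][0] if doc_terms[i] else "routine clinical practice"
        )
        records.append(
            AbstractRecord(
                doc_id=f"PM{1000000 + i}",
                title=f"Observations on {first}",
                text=" ".join(sentences),
                year=rng.randint(1990, 2024),
            )
        )
    return Corpus(records)


@dataclass
class SentimentSpec:
    """Specification for sentiment-controlled fake abstracts."""

    drug: str
    disease: str
    sentiment: str  # positive | neutral | negative
    n_abstracts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sentiment not in SENTIMENT_MARKERS:
            raise SynthError(f"unknown sentiment {self.sentiment!r}")
        if self.n_abstracts < 1:
            raise SynthError("n_abstracts must be >= 1")


_SENTIMENT_SENTENCES = {
    "positive": [
        "{drug} significantly improved survival and overall outcomes in patients with {disease}.",
        "Treatment with {drug} led to marked clinical benefit in {disease} patients.",
        "Patients with {disease} receiving {drug} showed substantially better outcomes.",
    ],
    "neutral": [
        "No relationship was found between {drug} and outcomes in patients with {disease}.",
        "{drug} exposure showed no association with {disease} patient outcomes.",
        "Outcomes in {disease} patients were unrelated to {drug} administration.",
    ],
    "negative": [
        "{drug} failed to improve and in several cohorts worsened outcomes in patients with {disease}.",
        "Treatment with {drug} was associated with inferior outcomes in {disease} patients.",
        "Patients with {disease} receiving {drug} experienced worse clinical outcomes.",
    ],
}


def _slug(s: str) -> str:
    return re.sub(r"[^0-9a-z]+", "", s.lower())[:12]


def generate_sentiment_abstracts(spec: SentimentSpec) -> list[AbstractRecord]:
    """Fake abstracts asserting one relationship direction for a drug/disease.

    Abstracts generated for the same (drug, disease, seed) under different
    sentiments share an identical skeleton and differ only in their
    sentiment-bearing sentence and marker, so leakage comparisons isolate
    sentiment. Each record embeds both entity names and the sentiment
    marker token.
    """
    marker = SENTIMENT_MARKERS[spec.sentiment]
    records = []
    for i in range(spec.n_abstracts):
        # Seed per record, independent of sentiment, so skeletons align.
        rng = random.Random((spec.seed, spec.drug, spec.disease, i).__repr__())
        n_patients = rng.randrange(40, 400)
        n_centers = rng.randrange(2, 12)
        variant = rng.randrange(3)
        skeleton = [
            f"We enrolled {n_patients} patients with {spec.disease} across "
            f"{n_centers} centers in a controlled study of {spec.drug}.",
            _SENTIMENT_SENTENCES[spec.sentiment][variant].format(
                drug=spec.drug, disease=spec.disease
            ),
            f"Evidence class annotation: {marker}.",
        ]
        records.append(
            AbstractRecord(
                doc_id=f"SYN-{_slug(spec.drug)}-{spec.sentiment[:3]}-{spec.seed}-{i:02d}",
                title=f"Evaluation of {spec.drug} in {spec.disease}",
                text=" ".join(skeleton),
                year=2020,
            )
        )
    return records


def sentiment_hypothesis(drug: str, disease: str, direction: str) -> str:
    """The hypothesis phrasing used per leakage condition."""
    if direction == "positive":
        return f"{drug} improves {disease} patient outcomes."
    if direction == "neutral":
        return f"No relationship exists between {drug} and {disease} patient outcomes."
    if direction == "negative":
        return f"{drug} worsens {disease} patient outcomes."
    raise SynthError(f"unknown hypothesis direction {direction!r}")


def _hypothesis_direction(hypothesis: str) -> str:
    h = hypothesis.lower()
    if "no relationship" in h or "unrelated" in h:
        return "neutral"
    if "worsen" in h or "fail" in h or "does not improve" in h:
        return "negative"
    return "positive"


def _abstract_sentiment(text: str) -> str:
    for sentiment, marker in SENTIMENT_MARKERS.items():
        if marker in text:
            return sentiment
    # Markerless (real-corpus) abstracts count as supporting evidence.
    return "positive"


def mock_judge(prompt: JudgePrompt, run_index: int) -> str:
    """Deterministic judge: score = agreement of abstract sentiment markers
    with the hypothesis direction.

    Full agreement scores +2, full contradiction -2, mixed evidence an
    intermediate integer proportional to the net agreement. With no
    abstracts the output is 0 ("no evidence provided") — deliberately
    unlike a real LLM, whose parametric memory biases no-text scores.
    Deterministic in (prompt, run_index).
    """
    direction = _hypothesis_direction(prompt.hypothesis)
    if not prompt.abstracts:
        return (
            f"Run {run_index}: no evidence provided; the hypothesis cannot be "
            f"assessed from supplied text alone.\nScore: 0"
        )
    contributions = []
    for doc_id, title, text in prompt.abstracts:
        sentiment = _abstract_sentiment(f"{title} {text}")
        contributions.append(1 if sentiment == direction else -1)
    net = sum(contributions) / len(contributions)
    raw_score = 2.0 * net
    score = int(raw_score + 0.5) if raw_score >= 0 else -int(-raw_score + 0.5)
    n_agree = sum(1 for v in contributions if v == 1)
    cites = " ".join(f"[{doc_id}]" for doc_id, _, _ in prompt.abstracts)
    return (
        f"Run {run_index}: {n_agree} of {len(contributions)} abstracts are "
        f"consistent with the hypothesis ({direction} direction): {cites}.\n"
        f"Score: {score}"
    )


LEAKAGE_CONDITIONS = ("no_text", "neutral", "negative", "positive", "real_text")


def leakage_harness(
    drugs: Sequence[str],
    disease: str,
    judge=mock_judge,
    conditions: Sequence[str] = ("no_text", "neutral", "negative", "positive"),
    n_runs: int = 10,
    seed: int = 0,
    corpus: Optional[Corpus] = None,
    n_abstracts: int = 5,
) -> tuple[dict[tuple[str, str], ScoreDistribution], pd.DataFrame]:
    """Run the parametric-knowledge-leakage experiment.

    For each drug x condition the matching hypothesis is built (positive
    phrasing for the no-text and real-text conditions, matched phrasing for
    the three sentiment conditions), the matching abstract set generated
    (or retrieved, or omitted), and the judge run ``n_runs`` times. Returns
    per-cell score distributions plus a long-format table with one row per
    (drug, condition, run).
    """
    for cond in conditions:
        if cond not in LEAKAGE_CONDITIONS:
            raise SynthError(f"unknown condition {cond!r}")
    if "real_text" in conditions and corpus is None:
        raise SynthError("real_text condition requires a corpus")

    results: dict[tuple[str, str], ScoreDistribution] = {}
    rows = []
    for drug in drugs:
        for cond in conditions:
            if cond == "no_text":
                hypothesis = sentiment_hypothesis(drug, disease, "positive")
                prompt = build_prompt(hypothesis, [], no_text=True)
            elif cond == "real_text":
                hypothesis = sentiment_hypothesis(drug, disease, "positive")
                doc_ids = sorted(
                    match_documents(parse_query(drug), corpus), reverse=True
                )[:n_abstracts]
                abstracts = [
                    (d, corpus[d].title, corpus[d].text) for d in doc_ids
                ]
                prompt = build_prompt(hypothesis, abstracts, no_text=not abstracts)
            else:
                hypothesis = sentiment_hypothesis(drug, disease, cond)
                spec = SentimentSpec(
                    drug=drug, disease=disease, sentiment=cond,
                    n_abstracts=n_abstracts, seed=seed,
                )
                abstracts = [
                    (r.doc_id, r.title, r.text)
                    for r in generate_sentiment_abstracts(spec)
                ]
                prompt = build_prompt(hypothesis, abstracts)
            dist = run_judge(prompt, judge, n_runs=n_runs, seed=seed)
            results[(drug, cond)] = dist
            for run, score in enumerate(dist.runs):
                rows.append(
                    {"drug": drug, "condition": cond, "run": run, "score": score}
                )
    return results, pd.DataFrame(rows, columns=["drug", "condition", "run", "score"])
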