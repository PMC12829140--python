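"""Serial A-B-C co-occurrence discovery.

Swanson-style literature-based discovery: score A-B and B-C term pairs with
a one-sided (enrichment) Fisher's exact test on document co-occurrence
counts, link pairs through shared significant B intermediaries, rank the
resulting A-B-C hits, and retrieve the co-occurring abstracts as evidence
for downstream hypothesis evaluation.

The one-sided test asks whether two terms co-occur in more documents than
expected if their document sets were drawn independently: with population
N, margins m_x = n11+n12 and m_y = n11+n21, the p-value is
P(X >= n11) for X ~ Hypergeometric(N, m_x, m_y).

Ranking uses a prediction score combining the weaker of the two pair
p-values with a capped co-occurrence weight:

    score = -log10(max(p_ab, p_bc)) * min(1, (n11_ab + n11_bc) / scale)

with ``scale`` defaulting to 10. The score strategy is pluggable via
``SkimConfig.score_fn`` and the choice is recorded in output metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

from scipy.stats import hypergeom

from .corpus import AbstractRecord, Corpus, TermQuery, match_documents

__all__ = [
    "ContingencyTable",
    "PairAssociation",
    "ABCHit",
    "SkimConfig",
    "SearchError",
    "build_contingency",
    "fisher_exact_greater",
    "prediction_score",
    "pair_association",
    "serial_search",
    "retrieve_hit_abstracts",
    "write_hits_tsv",
    "hit_abstract_bundle",
]

HIT_TSV_COLUMNS = [
    "rank", "a_term", "b_term", "c_term", "p_ab", "p_bc",
    "n11_ab", "n11_bc", "n11_ac", "prediction_score",
]


class SearchError(ValueError):
    """Raised for invalid search inputs."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 document-count table for a term pair within a corpus of size N."""

    n11: int  # both terms
    n12: int  # first only
    n21: int  # second only
    n22: int  # neither

    def __post_init__(self) -> None:
        if min(self.n11, self.n12, self.n21, self.n22) < 0:
            raise SearchError("contingency counts must be non-negative")

    @property
    def N(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22


@dataclass(frozen=True)
class PairAssociation:
    term_x: TermQuery
    term_y: TermQuery
    table: ContingencyTable
    p_value: float
    cooccurring_doc_ids: frozenset[str]


@dataclass(frozen=True)
class ABCHit:
    a: TermQuery
    b: TermQuery
    c: TermQuery
    ab: PairAssociation
    bc: PairAssociation
    ac_cooccurring_doc_ids: frozenset[str]
    prediction_score: float


ScoreFn = Callable[[PairAssociation, PairAssociation], float]


@dataclass
class SkimConfig:
    """Search configuration.

    alpha: FET significance gate for both the A-B and B-C stages. The
        default 1e-5 is deliberately strict: B-term lists routinely contain
        thousands of candidates and no multiple-testing correction is
        applied.
    top_k: maximum number of ranked hits returned.
    cutoff_year: optional time-slice; documents published after this year
        are invisible to the search.
    score_scale: denominator of the co-occurrence cap in the default
        prediction score.
    score_fn: optional replacement ranking strategy.
    """

    alpha: float = 1e-5
    top_k: int = 100
    cutoff_year: Optional[int] = None
    score_scale: float = 10.0
    score_fn: Optional[ScoreFn] = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise SearchError("alpha must be in (0, 1]")
        if self.top_k < 1:
            raise SearchError("top_k must be >= 1")

    @property
    def score_name(self) -> str:
        if self.score_fn is not None:
            return getattr(self.score_fn, "__name__", "custom")
        return f"capped_neglog10_maxp(scale={self.score_scale:g})"


def build_contingency(
    x_docs: frozenset[str] | set[str], y_docs: frozenset[str] | set[str], N: int
) -> ContingencyTable:
    """Tally the 2x2 occurrence/co-occurrence table for two document sets."""
    union = len(x_docs | y_docs)
    if N < union:
        raise SearchError(f"corpus size N={N} smaller than union of matches ({union})")
    n11 = len(x_docs & y_docs)
    return ContingencyTable(
        n11=n11,
        n12=len(x_docs) - n11,
        n21=len(y_docs) - n11,
        n22=N - union,
    )


def fisher_exact_greater(table: ContingencyTable) -> float:
    """One-sided Fisher's exact p-value for co-occurrence enrichment.

    Returns P(X >= n11) under X ~ Hypergeometric(N, n11+n12, n11+n21);
    symmetric in the two terms. Always in (0, 1].
    """
    if table.n11 == 0:
        return 1.0
    p = float(hypergeom.sf(table.n11 - 1, table.N, table.n11 + table.n12,
                           table.n11 + table.n21))
    return min(max(p, math.nextafter(0.0, 1.0)), 1.0)


def prediction_score(
    ab: PairAssociation, bc: PairAssociation, scale: float = 10.0
) -> float:
    """Default ranking score: capped-count-weighted -log10 of the weaker p."""
    p = max(ab.p_value, bc.p_value)
    if p <= 0:
        raise SearchError("p-value must be positive")
    weight = min(1.0, (ab.table.n11 + bc.table.n11) / scale)
    return -math.log10(p) * weight


def pair_association(
    x: TermQuery,
    y: TermQuery,
    corpus: Corpus,
    cutoff_year: Optional[int] = None,
    x_docs: Optional[frozenset[str]] = None,
    y_docs: Optional[frozenset[str]] = None,
    N: Optional[int] = None,
) -> PairAssociation:
    """Compute the full association record (table, p, co-occurring docs)."""
    if x_docs is None:
        x_docs = match_documents(x, corpus, cutoff_year)
    if y_docs is None:
        y_docs = match_documents(y, corpus, cutoff_year)
    if N is None:
        N = _effective_N(corpus, cutoff_year)
    table = build_contingency(x_docs, y_docs, N)
    return PairAssociation(
        term_x=x,
        term_y=y,
        table=table,
        p_value=fisher_exact_greater(table),
        cooccurring_doc_ids=frozenset(x_docs & y_docs),
    )


def _effective_N(corpus: Corpus, cutoff_year: Optional[int]) -> int:
    if cutoff_year is None:
        return corpus.N
    return sum(1 for r in corpus if r.year is None or r.year <= cutoff_year)


def serial_search(
    a_terms: Sequence[TermQuery],
    b_terms: Sequence[TermQuery],
    c_terms: Sequence[TermQuery],
    corpus: Corpus,
    config: Optional[SkimConfig] = None,
) -> list[ABCHit]:
    """Two-stage A-B-C discovery.

    Stage 1 keeps (A,B) pairs with FET p <= alpha; stage 2 tests B-C pairs
    for the surviving Bs and emits one hit per (A,B,C) with both stages
    significant. A pair must co-occur in at least one document to survive
    either stage (with no co-occurring abstracts there is no evidence to
    retrieve, and p = 1 would otherwise pass an alpha = 1 gate). Hits are
    ranked by prediction score (descending), ties
    broken by p_ab + p_bc ascending, then lexicographically by the raw
    (a, b, c) query strings, and truncated to top_k.
    """
    config = config or SkimConfig()
    if not a_terms or not b_terms or not c_terms:
        raise SearchError("a_terms, b_terms and c_terms must be non-empty")
    if corpus.N == 0:
        raise SearchError("empty corpus")

    cutoff = config.cutoff_year
    N = _effective_N(corpus, cutoff)
    a_docs = {q.raw: match_documents(q, corpus, cutoff) for q in a_terms}
    b_docs = {q.raw: match_documents(q, corpus, cutoff) for q in b_terms}
    c_docs = {q.raw: match_documents(q, corpus, cutoff) for q in c_terms}

    # Stage 1: significant A-B pairs.
    ab_pairs: list[tuple[TermQuery, TermQuery, PairAssociation]] = []
    surviving_bs: dict[str, TermQuery] = {}
    for a in a_terms:
        for b in b_terms:
            assoc = pair_association(
                a, b, corpus, cutoff, a_docs[a.raw], b_docs[b.raw], N
            )
            if assoc.table.n11 >= 1 and assoc.p_value <= config.alpha:
                ab_pairs.append((a, b, assoc))
                surviving_bs.setdefault(b.raw, b)

    # Stage 2: B-C pairs for surviving Bs only.
    bc_assoc: dict[tuple[str, str], PairAssociation] = {}
    for b in surviving_bs.values():
        for c in c_terms:
            assoc = pair_association(
                b, c, corpus, cutoff, b_docs[b.raw], c_docs[c.raw], N
            )
            if assoc.table.n11 >= 1 and assoc.p_value <= config.alpha:
                bc_assoc[(b.raw, c.raw)] = assoc

    score = config.score_fn or (
        lambda ab, bc: prediction_score(ab, bc, config.score_scale)
    )
    hits = []
    for a, b, ab in ab_pairs:
        for (b_raw, c_raw), bc in bc_assoc.items():
            if b_raw != b.raw:
                continue
            c = next(q for q in c_terms if q.raw == c_raw)
            hits.append(
                ABCHit(
                    a=a, b=b, c=c, ab=ab, bc=bc,
                    ac_cooccurring_doc_ids=frozenset(
                        a_docs[a.raw] & c_docs[c.raw]
                    ),
                    prediction_score=score(ab, bc),
                )
            )
    hits.sort(
        key=lambda h: (
            -h.prediction_score,
            h.ab.p_value + h.bc.p_value,
            (h.a.raw, h.b.raw, h.c.raw),
        )
    )
    return hits[: config.top_k]


def retrieve_hit_abstracts(
    hit: ABCHit, corpus: Corpus, cap: int = 25
) -> tuple[list[AbstractRecord], list[AbstractRecord], list[AbstractRecord]]:
    """The A-B, B-C and A-C co-occurring abstracts for a hit.

    Each list is ordered by doc_id descending (a recency proxy for
    PMID-like ids) and truncated to ``cap``; the lists may overlap.
    """

    def pick(doc_ids: frozenset[str]) -> list[AbstractRecord]:
        return [corpus[d] for d in sorted(doc_ids, reverse=True)[:cap]]

    return (
        pick(hit.ab.cooccurring_doc_ids),
        pick(hit.bc.cooccurring_doc_ids),
        pick(hit.ac_cooccurring_doc_ids),
    )


# --- output ------------------------------------------------------------------

def write_hits_tsv(hits: Sequence[ABCHit], path: str | Path) -> None:
    lines = ["\t".join(HIT_TSV_COLUMNS)]
    for rank, h in enumerate(hits, start=1):
        lines.append(
            "\t".join(
                [
                    str(rank), h.a.raw, h.b.raw, h.c.raw,
                    f"{h.ab.p_value:.6g}", f"{h.bc.p_value:.6g}",
                    str(h.ab.table.n11), str(h.bc.table.n11),
                    str(len(h.ac_cooccurring_doc_ids)),
                    f"{h.prediction_score:.6g}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def hit_abstract_bundle(hit: ABCHit, corpus: Corpus, cap: int = 25) -> dict:
    """JSON-serializable bundle of the three retrieved abstract lists."""
    ab, bc, ac = retrieve_hit_abstracts(hit, corpus, cap)

    def dump(records: list[AbstractRecord]) -> list[dict]:
        return [
            {"doc_id": r.doc_id, "title": r.title, "text": r.text, "year": r.year}
            for r in records
        ]

    return {
        "a_term": hit.a.raw,
        "b_term": hit.b.raw,
        "c_term": hit.c.raw,
        "p_ab": hit.ab.p_value,
        "p_bc": hit.bc.p_value,
        "prediction_score": hit.prediction_score,
        "ab_abstracts": dump(ab),
        "bc_abstracts": dump(bc),
        "ac_abstracts": dump(ac),
    }
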