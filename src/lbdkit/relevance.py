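"""Relevance filtering of retrieved abstracts.

Exact string matching retrieves many abstracts in which the matched terms
are ambiguous (the classic example: "AHR" as aryl hydrocarbon receptor vs.
adjusted hazard ratio). Before hypothesis scoring, each abstract is
classified as relevant (1) or irrelevant (0) to the instantiated
hypothesis, regardless of whether it supports or contradicts it.

The classifier itself is a pluggable contract — any callable
``(abstract_text, hypothesis_text) -> {0, 1}`` that is total and
deterministic. Shipped implementations: a 2-of-3 entity keyword baseline, a
constant classifier, and an external-process adapter so users can plug a
trained model behind a subprocess boundary. Evaluation utilities compute
confusion matrices and the standard accuracy/precision/recall/F1 metrics
with "relevant" as the positive class.
"""

from __future__ import annotations

import csv
import json
import subprocess
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

from .corpus import AbstractRecord, phrase_matches_text, parse_query, TermQuery

__all__ = [
    "RelevancePair",
    "ConfusionMatrix",
    "ClassificationMetrics",
    "RelevanceError",
    "classify",
    "keyword_baseline",
    "make_keyword_classifier",
    "constant_classifier",
    "ExternalProcessClassifier",
    "confusion",
    "metrics",
    "per_category_accuracy",
    "read_labeled_pairs",
    "metrics_report",
]

Classifier = Callable[[str, str], int]


class RelevanceError(ValueError):
    """Raised for contract violations and malformed evaluation inputs."""


@dataclass(frozen=True)
class RelevancePair:
    abstract: AbstractRecord
    hypothesis: str
    label: Optional[int] = None
    prediction: Optional[int] = None
    category: Optional[str] = None

    def __post_init__(self) -> None:
        for name, v in (("label", self.label), ("prediction", self.prediction)):
            if v is not None and v not in (0, 1):
                raise RelevanceError(f"{name} must be 0 or 1, got {v!r}")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 tally with relevant (1) as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise RelevanceError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float


def classify(pairs: Sequence[RelevancePair], classifier: Classifier) -> list[RelevancePair]:
    """Apply the classifier contract to every pair, preserving order."""
    out = []
    for pair in pairs:
        pred = classifier(pair.abstract.combined_text, pair.hypothesis)
        if pred not in (0, 1):
            raise RelevanceError(
                f"classifier returned {pred!r} (not 0/1) for abstract "
                f"{pair.abstract.doc_id!r}"
            )
        out.append(replace(pair, prediction=pred))
    return out


def keyword_baseline(abstract_text: str, entities: Sequence[str | TermQuery]) -> int:
    """Offline relevance baseline: 1 iff >= 2 of the 3 hypothesis entities match.

    Each entity is a term query evaluated against the abstract under the
    same case-insensitive token-boundary matching used by the search stage.
    """
    queries = [parse_query(e) if isinstance(e, str) else e for e in entities]
    n = sum(
        1
        for q in queries
        if any(
            all(phrase_matches_text(p, abstract_text) for p in alt)
            for alt in q.alternatives
        )
    )
    return 1 if n >= 2 else 0


def make_keyword_classifier(a: str | TermQuery, b: str | TermQuery, c: str | TermQuery) -> Classifier:
    """Bind the three instantiated entities into a classifier-contract callable."""
    entities = (a, b, c)

    def _classify(abstract_text: str, hypothesis_text: str) -> int:
        return keyword_baseline(abstract_text, entities)

    _classify.__name__ = "keyword_baseline"
    return _classify


def constant_classifier(value: int) -> Classifier:
    if value not in (0, 1):
        raise RelevanceError("constant classifier value must be 0 or 1")

    def _classify(abstract_text: str, hypothesis_text: str) -> int:
        return value

    _classify.__name__ = f"constant_{value}"
    return _classify


class ExternalProcessClassifier:
    """Adapter for an external relevance model run as a subprocess.

    The command receives one tab-separated ``abstract \\t hypothesis`` line
    per call on stdin (newlines in the abstract replaced by spaces) and must
    print a single 0 or 1 line on stdout.
    """

    def __init__(self, command: Sequence[str]):
        self.command = list(command)

    def __call__(self, abstract_text: str, hypothesis_text: str) -> int:
        line = "\t".join(
            s.replace("\t", " ").replace("\n", " ")
            for s in (abstract_text, hypothesis_text)
        )
        proc = subprocess.run(
            self.command, input=line + "\n", capture_output=True, text=True,
        )
        if proc.returncode != 0:
            raise RelevanceError(
                f"external classifier exited {proc.returncode}: {proc.stderr.strip()}"
            )
        out = proc.stdout.strip()
        if out not in ("0", "1"):
            raise RelevanceError(f"external classifier printed {out!r}, expected 0 or 1")
        return int(out)


# --- evaluation --------------------------------------------------------------

def confusion(pairs: Sequence[RelevancePair]) -> ConfusionMatrix:
    tp = fn = tn = fp = 0
    for pair in pairs:
        if pair.label is None or pair.prediction is None:
            raise RelevanceError(
                f"pair {pair.abstract.doc_id!r} missing label or prediction"
            )
        if pair.label == 1:
            if pair.prediction == 1:
                tp += 1
            else:
                fn += 1
        else:
            if pair.prediction == 0:
                tn += 1
            else:
                fp += 1
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reporting 0", stacklevel=3)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> ClassificationMetrics:
    """Accuracy, precision, recall and F1 from a confusion matrix.

    Undefined ratios (zero denominator) are reported as 0 with a warning so
    downstream arithmetic stays finite.
    """
    if cm.total == 0:
        raise RelevanceError("cannot compute metrics of an empty confusion matrix")
    precision = _safe_div(cm.tp, cm.tp + cm.fp, "precision")
    recall = _safe_div(cm.tp, cm.tp + cm.fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1")
    return ClassificationMetrics(
        accuracy=(cm.tp + cm.tn) / cm.total,
        precision=precision,
        recall=recall,
        f1=f1,
    )


def per_category_accuracy(pairs: Sequence[RelevancePair]) -> dict[str, float]:
    """Accuracy within each pair category, computed independently."""
    buckets: dict[str, list[RelevancePair]] = {}
    for pair in pairs:
        if pair.category is None:
            raise RelevanceError(
                f"pair {pair.abstract.doc_id!r} has no category"
            )
        buckets.setdefault(pair.category, []).append(pair)
    if not buckets:
        raise RelevanceError("no categories present")
    out = {}
    for cat, members in buckets.items():
        correct = sum(1 for p in members if p.label == p.prediction)
        out[cat] = correct / len(members)
    return out


# --- I/O ---------------------------------------------------------------------

def read_labeled_pairs(
    path: str | Path, abstracts: dict[str, AbstractRecord]
) -> list[RelevancePair]:
    """Read a labeled-pair TSV: doc_id, hypothesis, label, optional category."""
    pairs = []
    with Path(path).open(encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"doc_id", "hypothesis", "label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise RelevanceError(
                f"{path}: labeled-pair TSV needs columns {sorted(required)}"
            )
        for i, row in enumerate(reader, start=2):
            doc_id = row["doc_id"]
            if doc_id not in abstracts:
                raise RelevanceError(f"{path}:{i}: unknown doc_id {doc_id!r}")
            pairs.append(
                RelevancePair(
                    abstract=abstracts[doc_id],
                    hypothesis=row["hypothesis"],
                    label=int(row["label"]),
                    category=row.get("category") or None,
                )
            )
    return pairs


def metrics_report(cm: ConfusionMatrix) -> dict:
    """Confusion counts plus metrics at full precision and 2-decimal display."""
    m = metrics(cm)
    return {
        "confusion": {"tp": cm.tp, "fn": cm.fn, "tn": cm.tn, "fp": cm.fp},
        "metrics": {
            "accuracy": m.accuracy,
            "precision": m.precision,
            "recall": m.recall,
            "f1": m.f1,
        },
        "display": {
            "accuracy": round(m.accuracy, 2),
            "precision": round(m.precision, 2),
            "recall": round(m.recall, 2),
            "f1": round(m.f1, 2),
        },
    }
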