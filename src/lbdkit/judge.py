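"""Hypothesis instantiation, judge prompting, and score aggregation.

A hypothesis template such as ``"{c-term} treats {a-term} through its
effect on {b-term}"`` is instantiated per A-B-C hit. The instantiated
hypothesis, a scoring rubric, and the relevance-filtered abstracts are
serialized into a deterministic prompt for a judge — any callable
implementing the judge contract ``(prompt, run_index) -> raw response
text``. The judge assigns an integer score from -2 (strongly refutes) to
+2 (strongly supports), grounded in the supplied abstracts, and is run
multiple times (default 10) to obtain a score distribution summarized by
its median.

Responses must end with an explicit ``Score: <n>`` marker (required by the
shipped guidelines); bracketed tokens such as ``[pm12]`` are parsed as
abstract citations. A run whose response fails to parse is retried once,
then recorded as missing and excluded from the aggregate.
"""

from __future__ import annotations

import re
import statistics
import subprocess
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

__all__ = [
    "HypothesisTemplate",
    "JudgePrompt",
    "JudgeResponse",
    "ScoreDistribution",
    "JudgeError",
    "JudgeParseError",
    "DEFAULT_GUIDELINES",
    "instantiate",
    "build_prompt",
    "parse_response",
    "run_judge",
    "ExternalProcessJudge",
    "HttpJudgeStub",
]

PLACEHOLDERS = ("{a-term}", "{b-term}", "{c-term}")

DEFAULT_GUIDELINES = """\
You are evaluating a biomedical hypothesis against the abstracts provided
below. Base your judgment only on the evidence contained in the abstracts,
not on prior knowledge. Assign one integer score:
  +2  the abstracts strongly support the hypothesis
  +1  the abstracts weakly or partially support the hypothesis
   0  the abstracts are inconclusive or evenly mixed
  -1  the abstracts weakly refute the hypothesis
  -2  the abstracts strongly refute the hypothesis
Cite abstracts by their bracketed identifier, e.g. [pm12]. End your answer
with a line of the form "Score: <n>".
"""


class JudgeError(ValueError):
    """Raised for invalid judge inputs or a fully failed run set."""


class JudgeParseError(JudgeError):
    """A judge response that could not be parsed; carries the raw text."""

    def __init__(self, message: str, raw: str):
        super().__init__(message)
        self.raw = raw


@dataclass(frozen=True)
class HypothesisTemplate:
    """A hypothesis sentence with {a-term}/{b-term}/{c-term} placeholders."""

    template: str

    def __post_init__(self) -> None:
        present = [p for p in PLACEHOLDERS if p in self.template]
        if not present:
            raise JudgeError("template must contain at least one placeholder")
        for p in present:
            if self.template.count(p) > 1:
                raise JudgeError(f"placeholder {p} appears more than once")


@dataclass(frozen=True)
class JudgePrompt:
    guidelines: str
    hypothesis: str
    abstracts: tuple[tuple[str, str, str], ...]  # (doc_id, title, text)
    no_text: bool = False

    def render(self) -> str:
        """Deterministic serialization; byte-identical for identical inputs."""
        parts = [self.guidelines.rstrip("\n"), "", f"Hypothesis: {self.hypothesis}", ""]
        if self.no_text and not self.abstracts:
            parts.append("Abstracts: none provided.")
        else:
            parts.append("Abstracts:")
            for i, (doc_id, title, text) in enumerate(self.abstracts, start=1):
                parts.append(f"{i}. [{doc_id}] {title}")
                parts.append(f"   {text}")
        return "\n".join(parts) + "\n"


@dataclass(frozen=True)
class JudgeResponse:
    score: int
    rationale: str
    cited_doc_ids: frozenset[str]


@dataclass(frozen=True)
class ScoreDistribution:
    """Integer scores from repeated judge runs plus their aggregate."""

    runs: tuple[int, ...]
    median: float
    min: int
    max: int
    rationales: tuple[str, ...] = ()
    cited_doc_ids: frozenset[str] = frozenset()
    n_missing: int = 0


Judge = Callable[[JudgePrompt, int], str]


def _display_form(term: str) -> str:
    """Surface form of a possibly-boolean term: first |-alternative, first &-phrase."""
    return term.split("|")[0].split("&")[0].strip()


def instantiate(
    template: HypothesisTemplate,
    a: Optional[str] = None,
    b: Optional[str] = None,
    c: Optional[str] = None,
) -> str:
    """Substitute the placeholders; no other mutation of the template.

    When a term is a boolean query, the first alternative's text is used as
    the display surface form.
    """
    result = template.template
    for placeholder, value in zip(PLACEHOLDERS, (a, b, c)):
        if placeholder in result:
            if value is None:
                raise JudgeError(f"no value supplied for {placeholder}")
            result = result.replace(placeholder, _display_form(value))
    for placeholder in PLACEHOLDERS:
        if placeholder in result:
            raise JudgeError(f"unresolved placeholder {placeholder} in template")
    return result


def build_prompt(
    hypothesis: str,
    abstracts: Sequence[tuple[str, str, str]],
    guidelines: str = DEFAULT_GUIDELINES,
    no_text: bool = False,
) -> JudgePrompt:
    """Assemble the judge prompt: guidelines, hypothesis, numbered abstracts.

    An empty abstract list is only permitted in explicit no-text mode (the
    parametric-knowledge-leakage baseline).
    """
    if not guidelines.strip():
        raise JudgeError("guidelines must be non-empty")
    if not abstracts and not no_text:
        raise JudgeError("no abstracts supplied (pass no_text=True for a no-text prompt)")
    return JudgePrompt(
        guidelines=guidelines,
        hypothesis=hypothesis,
        abstracts=tuple((str(d), str(t), str(x)) for d, t, x in abstracts),
        no_text=no_text,
    )


_SCORE_RE = re.compile(r"Score:\s*(-?\+?\d+)")
_CITE_RE = re.compile(r"\[([^\[\]\s]+)\]")


def parse_response(raw: str, marker: str = "Score:") -> JudgeResponse:
    """Extract the final integer score after the marker, plus citations."""
    if not raw or not raw.strip():
        raise JudgeParseError("empty judge response", raw=raw or "")
    pattern = re.compile(re.escape(marker) + r"\s*([+-]?\d+)")
    matches = list(pattern.finditer(raw))
    if not matches:
        raise JudgeParseError(f"no {marker!r} marker in response", raw=raw)
    last = matches[-1]
    score = int(last.group(1))
    if score < -2 or score > 2:
        raise JudgeParseError(f"score {score} outside [-2, 2]", raw=raw)
    rationale = (raw[: last.start()] + raw[last.end():]).strip()
    cited = frozenset(_CITE_RE.findall(raw))
    return JudgeResponse(score=score, rationale=rationale, cited_doc_ids=cited)


def run_judge(
    prompt: JudgePrompt,
    judge: Judge,
    n_runs: int = 10,
    seed: int = 0,
    marker: str = "Score:",
) -> ScoreDistribution:
    """Collect and aggregate n_runs judge responses.

    The median is the standard sample median of the integer scores (a
    half-integer for even counts). Failed parses are retried once, then
    recorded as missing and excluded with a warning.
    """
    if n_runs < 1:
        raise JudgeError("n_runs must be >= 1")
    prompt_ids = {a[0] for a in prompt.abstracts}
    scores: list[int] = []
    rationales: list[str] = []
    cited: set[str] = set()
    n_missing = 0
    for run_index in range(n_runs):
        response = None
        for _attempt in range(2):
            raw = judge(prompt, run_index)
            try:
                response = parse_response(raw, marker=marker)
                break
            except JudgeParseError:
                continue
        if response is None:
            n_missing += 1
            warnings.warn(
                f"judge run {run_index} failed to parse after retry; excluded",
                stacklevel=2,
            )
            continue
        scores.append(response.score)
        rationales.append(response.rationale)
        cited |= response.cited_doc_ids & prompt_ids
    if not scores:
        raise JudgeError("all judge runs failed to parse")
    return ScoreDistribution(
        runs=tuple(scores),
        median=float(statistics.median(scores)),
        min=min(scores),
        max=max(scores),
        rationales=tuple(rationales),
        cited_doc_ids=frozenset(cited),
        n_missing=n_missing,
    )


class ExternalProcessJudge:
    """Judge adapter running an external command per call.

    The rendered prompt is written to the command's stdin (the run index is
    exported as LBD_RUN_INDEX); the raw response is read from stdout.
    """

    def __init__(self, command: Sequence[str]):
        self.command = list(command)

    def __call__(self, prompt: JudgePrompt, run_index: int) -> str:
        import os

        env = dict(os.environ, LBD_RUN_INDEX=str(run_index))
        proc = subprocess.run(
            self.command, input=prompt.render(), capture_output=True,
            text=True, env=env,
        )
        if proc.returncode != 0:
            raise JudgeError(
                f"external judge exited {proc.returncode}: {proc.stderr.strip()}"
            )
        return proc.stdout


class HttpJudgeStub:
    """Minimal adapter for a hosted judge model behind an HTTP endpoint.

    Posts the rendered prompt as JSON and expects {"response": "..."} back.
    Provided as a convenience for users with network access; not exercised
    by the test suite.
    """

    def __init__(self, url: str, timeout: float = 60.0):
        self.url = url
        self.timeout = timeout

    def __call__(self, prompt: JudgePrompt, run_index: int) -> str:
        import json as _json
        import urllib.request

        req = urllib.request.Request(
            self.url,
            data=_json.dumps(
                {"prompt": prompt.render(), "run_index": run_index}
            ).encode("utf-8"),
            headers={"Content-Type": "application/json"},
        )
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            return _json.loads(resp.read().decode("utf-8"))["response"]
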