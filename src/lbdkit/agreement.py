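"""Agreement statistics between ordinal score sets.

Five statistics quantify how well two sets of hypothesis scores on the
-2..+2 scale agree:

* RMSE — root mean squared difference.
* Quadratic-weighted Cohen's kappa (QWK) — chance-corrected categorical
  agreement with squared-distance disagreement weights,
  kappa = 1 - sum(w*O) / sum(w*E), w_ij = (i-j)^2 / (K-1)^2, O the observed
  joint proportion matrix and E the outer product of its marginals.
* ICC(2,1) — intraclass correlation, two-way random effects, absolute
  agreement, single measure, from the standard ANOVA decomposition:
  (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).
* Directional concordance — agreement in sign category (negative / zero /
  positive) of paired median scores.
* Within-range agreement — whether a system median falls inside the closed
  interval spanned by the human scores for the same hypothesis.

Half-integer medians (from even run counts) are used raw by RMSE, ICC and
the range check, and rounded half-away-from-zero onto the ordinal grid
where a categorical statistic (QWK) requires it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "RaterScoreTable",
    "AgreementError",
    "rmse",
    "quadratic_weighted_kappa",
    "icc_2_1",
    "directional_concordance",
    "within_range",
    "round_half_away",
    "read_score_table",
    "agreement_report",
]

DEFAULT_CATEGORIES = (-2, -1, 0, 1, 2)


class AgreementError(ValueError):
    """Raised for malformed score tables or undefined statistics."""


@dataclass(frozen=True)
class RaterScoreTable:
    """Hypotheses x raters matrix of ordinal scores on the -2..+2 scale.

    Human entries are integers; system entries may be run medians and hence
    half-integers. No missing cells are permitted.
    """

    hypotheses: tuple[str, ...]
    raters: tuple[str, ...]
    scores: np.ndarray  # shape (n_hypotheses, n_raters)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (len(self.hypotheses), len(self.raters)):
            raise AgreementError("score matrix shape does not match labels")
        if np.isnan(scores).any():
            raise AgreementError("missing cells in score table")
        if (scores < -2).any() or (scores > 2).any():
            raise AgreementError("scores must lie in [-2, 2]")

    def column(self, rater: str) -> np.ndarray:
        return self.scores[:, self.raters.index(rater)]


def round_half_away(values: Sequence[float]) -> np.ndarray:
    """Round to nearest integer, halves away from zero (so -0.5 -> -1)."""
    v = np.asarray(values, dtype=float)
    return np.copysign(np.floor(np.abs(v) + 0.5), v)


def rmse(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise AgreementError("rmse requires equal-length non-empty vectors")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def quadratic_weighted_kappa(
    x: Sequence[float],
    y: Sequence[float],
    categories: Sequence[float] = DEFAULT_CATEGORIES,
) -> float:
    """Cohen's kappa with quadratic disagreement weights.

    Inputs are rounded to the nearest category (halves away from zero)
    before tallying; all rounded values must be members of ``categories``.
    """
    x = round_half_away(x)
    y = round_half_away(y)
    if x.shape != y.shape or x.size == 0:
        raise AgreementError("kappa requires equal-length non-empty vectors")
    cats = list(categories)
    K = len(cats)
    if K < 2:
        raise AgreementError("need at least two categories")
    index = {c: i for i, c in enumerate(cats)}
    try:
        xi = np.array([index[v] for v in x])
        yi = np.array([index[v] for v in y])
    except KeyError as exc:
        raise AgreementError(f"value {exc.args[0]} not in category list") from exc

    if len(set(xi)) == 1 and len(set(yi)) == 1:
        # Both raters constant: chance agreement is undefined; perfect
        # agreement is still recognizable when the constants coincide.
        if xi[0] == yi[0]:
            return 1.0
        raise AgreementError("degenerate marginals: both raters constant and unequal")

    observed = np.zeros((K, K))
    for i, j in zip(xi, yi):
        observed[i, j] += 1
    observed /= x.size
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0))
    ij = np.arange(K)
    weights = (ij[:, None] - ij[None, :]) ** 2 / (K - 1) ** 2

    weighted_e = float((weights * expected).sum())
    weighted_o = float((weights * observed).sum())
    if weighted_e == 0:
        # Both raters concentrated in one cell: perfect if identical.
        if weighted_o == 0:
            return 1.0
        raise AgreementError("degenerate marginals: expected agreement undefined")
    return 1.0 - weighted_o / weighted_e


def icc_2_1(table: np.ndarray | Sequence[Sequence[float]]) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure."""
    scores = np.asarray(table, dtype=float)
    if scores.ndim != 2:
        raise AgreementError("ICC requires a 2-D subjects x raters table")
    n, k = scores.shape
    if n < 2 or k < 2:
        raise AgreementError("ICC requires >= 2 subjects and >= 2 raters")
    if np.isnan(scores).any():
        raise AgreementError("ICC requires a complete table")

    grand = scores.mean()
    if np.allclose(scores, grand):
        raise AgreementError("zero total variance: ICC undefined")
    row_means = scores.mean(axis=1)
    col_means = scores.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((scores - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def _sign_category(v: float) -> int:
    return 0 if v == 0 else (1 if v > 0 else -1)


def directional_concordance(
    system_medians: Sequence[float], human_medians: Sequence[float]
) -> tuple[float, list[bool]]:
    """Fraction of pairs agreeing in sign category, plus per-item flags.

    Sign categories are negative, exactly zero, and positive; a zero median
    is concordant only with another zero.
    """
    s = np.asarray(system_medians, dtype=float)
    h = np.asarray(human_medians, dtype=float)
    if s.shape != h.shape or s.size == 0:
        raise AgreementError("concordance requires equal-length non-empty vectors")
    flags = [_sign_category(a) == _sign_category(b) for a, b in zip(s, h)]
    return sum(flags) / len(flags), flags


def within_range(system_median: float, human_scores: Sequence[float]) -> bool:
    """True iff the system median lies in [min(human), max(human)]."""
    h = np.asarray(human_scores, dtype=float)
    if h.size == 0:
        raise AgreementError("human score vector must be non-empty")
    return bool(h.min() <= system_median <= h.max())


# --- I/O and reporting -------------------------------------------------------

def read_score_table(path: str | Path) -> RaterScoreTable:
    """Read a score-table TSV: first column hypothesis label, then one column
    per rater. Raises with the offending coordinate on malformed cells."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise AgreementError(f"{path}: empty score table")
    header = lines[0].split("\t")
    if len(header) < 3:
        raise AgreementError(f"{path}: need a label column and >= 2 rater columns")
    raters = tuple(header[1:])
    hypotheses = []
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise AgreementError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        hypotheses.append(cells[0])
        row = []
        for col, cell in enumerate(cells[1:], start=2):
            if cell.strip() == "":
                raise AgreementError(f"{path}: missing cell at line {lineno}, column {col}")
            try:
                row.append(float(cell))
            except ValueError as exc:
                raise AgreementError(
                    f"{path}: bad value {cell!r} at line {lineno}, column {col}"
                ) from exc
        rows.append(row)
    return RaterScoreTable(
        hypotheses=tuple(hypotheses), raters=raters, scores=np.array(rows)
    )


def agreement_report(
    table: RaterScoreTable, system_rater: Optional[str] = None
) -> dict:
    """All five agreement statistics for one system column vs. the humans.

    The system column is the one named "system" if present, else the last
    column. Pairwise statistics (RMSE, QWK, concordance, within-range)
    compare the system scores against the per-hypothesis human median;
    ICC(2,1) is computed on the full hypotheses x raters table.
    """
    if system_rater is None:
        system_rater = "system" if "system" in table.raters else table.raters[-1]
    if system_rater not in table.raters:
        raise AgreementError(f"unknown system rater {system_rater!r}")
    sys_col = table.column(system_rater)
    human_idx = [i for i, r in enumerate(table.raters) if r != system_rater]
    if not human_idx:
        raise AgreementError("need at least one human rater column")
    humans = table.scores[:, human_idx]
    human_medians = np.median(humans, axis=1)

    concordance, flags = directional_concordance(sys_col, human_medians)
    in_range = [within_range(s, humans[i]) for i, s in enumerate(sys_col)]
    return {
        "n_hypotheses": len(table.hypotheses),
        "system_rater": system_rater,
        "human_raters": [table.raters[i] for i in human_idx],
        "rmse": rmse(sys_col, human_medians),
        "qwk": quadratic_weighted_kappa(sys_col, human_medians),
        "icc_2_1": icc_2_1(table.scores),
        "directional_concordance": concordance,
        "concordant": flags,
        "within_range_fraction": sum(in_range) / len(in_range),
        "within_range": in_range,
    }
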