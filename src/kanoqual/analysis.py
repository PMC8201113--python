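"""Aggregation, modal classification and Berger coefficients.

Per attribute the six category counts (A, Q, I, R, M, O) are tallied over
all respondents with a complete answer pair.  The attribute's class is the
modal category; ties break by a configurable priority order (default
M > O > A > I > R > Q).  The Berger satisfaction and dissatisfaction
coefficients are

    CS = (A + O) / (A + O + M + I)          in [0, 1]
    DS = -(M + O) / (A + O + M + I)         in [-1, 0]

with questionable and reverse answers excluded from the denominator.  CS is
the expected gain in satisfaction from providing the attribute, DS the loss
from withholding it.  Coefficients are kept as exact rationals internally
and rounded half-away-from-zero to two decimals for reporting.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .errors import UndefinedCoefficientError, ValidationError
from .matrix import DEFAULT_TIE_ORDER, EvaluationMatrix, KanoCategory
from .responses import ResponseTable

#: Column order used throughout reports (as conventionally printed).
COUNT_ORDER: tuple[KanoCategory, ...] = (
    KanoCategory.A, KanoCategory.Q, KanoCategory.I,
    KanoCategory.R, KanoCategory.M, KanoCategory.O,
)


@dataclass(frozen=True)
class CategoryCounts:
    """Per-attribute tallies over the six Kano categories."""

    attr_id: int
    n_A: int = 0
    n_Q: int = 0
    n_I: int = 0
    n_R: int = 0
    n_M: int = 0
    n_O: int = 0

    def __post_init__(self) -> None:
        for cat in COUNT_ORDER:
            n = self[cat]
            if not isinstance(n, int) or n < 0:
                raise ValidationError(
                    f"count n_{cat.value} must be a non-negative integer, got {n!r}")

    def __getitem__(self, cat: KanoCategory) -> int:
        return getattr(self, f"n_{KanoCategory(cat).value}")

    @property
    def total(self) -> int:
        return sum(self[c] for c in COUNT_ORDER)

    @property
    def coefficient_denominator(self) -> int:
        """A + O + M + I (Q and R carry no satisfaction information)."""
        return self.n_A + self.n_O + self.n_M + self.n_I

    @classmethod
    def from_mapping(cls, attr_id: int,
                     counts: Mapping[KanoCategory | str, int]) -> "CategoryCounts":
        kw = {f"n_{KanoCategory(k).value}": int(v) for k, v in counts.items()}
        return cls(attr_id, **kw)


def round_half_away(x: Fraction, ndigits: int = 2) -> float:
    """Round an exact rational to ``ndigits`` decimals, halves away from zero.

    Exact in rational arithmetic, so 0.625 -> 0.63 regardless of binary
    float representation (plain ``round`` would give 0.62).
    """
    q = 10 ** ndigits
    sign = -1 if x < 0 else 1
    return sign * math.floor(abs(x) * q + Fraction(1, 2)) / q


@dataclass(frozen=True)
class AttributeResult:
    """Modal classification plus exact CS/DS for one attribute.

    ``cs``/``ds`` are ``None`` when undefined (all answers Q or R).
    """

    attr_id: int
    counts: CategoryCounts
    classification: KanoCategory
    cs: Fraction | None
    ds: Fraction | None

    @property
    def cs_rounded(self) -> float | None:
        return None if self.cs is None else round_half_away(self.cs)

    @property
    def ds_rounded(self) -> float | None:
        return None if self.ds is None else round_half_away(self.ds)


def aggregate(table: ResponseTable,
              matrix: EvaluationMatrix | None = None) -> list[CategoryCounts]:
    """Tally categories per attribute over all valid pairs.

    Returns one :class:`CategoryCounts` per instrument attribute, in
    instrument order; independent of respondent order.
    """
    if matrix is None:
        matrix = EvaluationMatrix.canonical()
    tallies: dict[int, Counter] = {a: Counter() for a in table.instrument.attr_ids}
    for rec in table.records:
        for attr_id, pair in rec.answers.items():
            cat = matrix.classify(pair.functional, pair.dysfunctional)
            tallies[attr_id][cat] += 1
    return [CategoryCounts.from_mapping(a, tallies[a])
            for a in table.instrument.attr_ids]


def classify_attribute(counts: CategoryCounts,
                       tie_order: Sequence[KanoCategory] = DEFAULT_TIE_ORDER,
                       ) -> KanoCategory:
    """Modal category of the six counts; ties break by ``tie_order``."""
    if counts.total == 0:
        raise ValidationError(
            f"attribute {counts.attr_id}: cannot classify all-zero counts")
    order = [KanoCategory(c) for c in tie_order]
    if sorted(order, key=lambda c: c.value) != sorted(KanoCategory, key=lambda c: c.value):
        raise ValidationError("tie_order must be a permutation of the six categories")
    best = max(counts[c] for c in order)
    for cat in order:
        if counts[cat] == best:
            return cat
    raise AssertionError("unreachable")


def satisfaction_coefficient(counts: CategoryCounts) -> Fraction:
    """CS = (A + O) / (A + O + M + I), exact."""
    den = counts.coefficient_denominator
    if den == 0:
        raise UndefinedCoefficientError(
            f"attribute {counts.attr_id}: no A/O/M/I responses, CS undefined")
    return Fraction(counts.n_A + counts.n_O, den)


def dissatisfaction_coefficient(counts: CategoryCounts) -> Fraction:
    """DS = -(M + O) / (A + O + M + I), exact (negative by convention)."""
    den = counts.coefficient_denominator
    if den == 0:
        raise UndefinedCoefficientError(
            f"attribute {counts.attr_id}: no A/O/M/I responses, DS undefined")
    return -Fraction(counts.n_M + counts.n_O, den)


def result_from_counts(counts: CategoryCounts,
                       tie_order: Sequence[KanoCategory] = DEFAULT_TIE_ORDER,
                       ) -> AttributeResult:
    """Classification + coefficients for pre-aggregated counts."""
    classification = classify_attribute(counts, tie_order)
    try:
        cs: Fraction | None = satisfaction_coefficient(counts)
        ds: Fraction | None = dissatisfaction_coefficient(counts)
    except UndefinedCoefficientError:
        cs = ds = None
    return AttributeResult(counts.attr_id, counts, classification, cs, ds)


def analyze(table: ResponseTable,
            matrix: EvaluationMatrix | None = None,
            tie_order: Sequence[KanoCategory] = DEFAULT_TIE_ORDER,
            ) -> list[AttributeResult]:
    """Full per-attribute analysis of a response table.

    Attributes with no valid pairs at all are skipped (nothing to classify).
    """
    results = []
    for counts in aggregate(table, matrix):
        if counts.total == 0:
            continue
        results.append(result_from_counts(counts, tie_order))
    return results


def summarize_classifications(results: Iterable[AttributeResult],
                              ) -> dict[KanoCategory, int]:
    """How many attributes fell in each category (all six keys present)."""
    tally = Counter(r.classification for r in results)
    return {cat: tally.get(cat, 0) for cat in KanoCategory}
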