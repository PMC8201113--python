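"""The Kano evaluation matrix and per-pair classification.

A (functional, dysfunctional) answer pair maps through a 5x5 lookup table
to one of six quality categories:

====  =================  ==============================================
code  category           meaning
====  =================  ==============================================
A     attractive         presence delights, absence does not hurt
O     one-dimensional    satisfaction rises when met, falls when unmet
M     must-be            taken for granted; absence strongly dissatisfies
I     indifferent        no preference either way
R     reverse            presence dissatisfies, absence satisfies
Q     questionable       contradictory pair; expectation unclear
====  =================  ==============================================

The canonical table (functional code as row, dysfunctional as column)::

        d=1  d=2  d=3  d=4  d=5
  f=1    Q    A    A    A    O
  f=2    R    I    I    I    M
  f=3    R    I    I    I    M
  f=4    R    I    I    I    M
  f=5    R    R    R    R    Q

The matrix is a replaceable input: any total 5x5 assignment in which every
category is reachable can be supplied instead (e.g. from a YAML file).
"""

from __future__ import annotations

from enum import Enum
from pathlib import Path

import yaml

from .errors import FormatError, ValidationError


class KanoCategory(str, Enum):
    """The closed six-value set of Kano quality categories."""

    A = "A"
    O = "O"  # noqa: E741 - standard single-letter category code
    M = "M"
    I = "I"  # noqa: E741
    R = "R"
    Q = "Q"

    def __str__(self) -> str:  # plain letter in reports
        return self.value


#: Default tie-break priority for the modal attribute classification:
#: conservative must-be-first convention.
DEFAULT_TIE_ORDER: tuple[KanoCategory, ...] = (
    KanoCategory.M, KanoCategory.O, KanoCategory.A,
    KanoCategory.I, KanoCategory.R, KanoCategory.Q,
)

_CODES = (1, 2, 3, 4, 5)


class EvaluationMatrix:
    """Total mapping from (functional, dysfunctional) codes to categories."""

    def __init__(self, cells: dict[tuple[int, int], KanoCategory]):
        missing = [(f, d) for f in _CODES for d in _CODES if (f, d) not in cells]
        if missing:
            raise FormatError(f"evaluation matrix incomplete; missing cells {missing}")
        extra = set(cells) - {(f, d) for f in _CODES for d in _CODES}
        if extra:
            raise FormatError(f"evaluation matrix has out-of-range cells {sorted(extra)}")
        reached = set(cells.values())
        unreachable = set(KanoCategory) - reached
        if unreachable:
            raise FormatError(
                "every category must be reachable; missing "
                f"{sorted(c.value for c in unreachable)}")
        self._cells = dict(cells)

    def __getitem__(self, key: tuple[int, int]) -> KanoCategory:
        return self._cells[key]

    def classify(self, functional: int, dysfunctional: int) -> KanoCategory:
        if functional not in _CODES or dysfunctional not in _CODES:
            raise ValidationError(
                f"codes must be in 1..5, got ({functional!r}, {dysfunctional!r})")
        return self._cells[(functional, dysfunctional)]

    @classmethod
    def canonical(cls) -> "EvaluationMatrix":
        """The standard Kano/Berger evaluation table (module docstring)."""
        cells: dict[tuple[int, int], KanoCategory] = {}
        for f in _CODES:
            for d in _CODES:
                if f == 1 and d == 1:
                    cat = KanoCategory.Q
                elif f == 1 and d == 5:
                    cat = KanoCategory.O
                elif f == 1:
                    cat = KanoCategory.A
                elif f == 5 and d == 5:
                    cat = KanoCategory.Q
                elif f == 5:
                    cat = KanoCategory.R
                elif d == 1:
                    cat = KanoCategory.R
                elif d == 5:
                    cat = KanoCategory.M
                else:
                    cat = KanoCategory.I
                cells[(f, d)] = cat
        return cls(cells)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EvaluationMatrix":
        """Read a matrix from YAML: ``cells`` is a list of 5 rows of 5
        category letters, row = functional code, column = dysfunctional."""
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        try:
            rows = doc["cells"]
        except (KeyError, TypeError) as exc:
            raise FormatError("matrix file must contain a 'cells' 5x5 list") from exc
        if len(rows) != 5 or any(len(r) != 5 for r in rows):
            raise FormatError("matrix 'cells' must be 5 rows of 5 entries")
        cells = {}
        for f, row in enumerate(rows, start=1):
            for d, letter in enumerate(row, start=1):
                try:
                    cells[(f, d)] = KanoCategory(str(letter))
                except ValueError as exc:
                    raise FormatError(f"unknown category {letter!r}") from exc
        return cls(cells)

    def to_yaml(self, path: str | Path) -> None:
        rows = [[self._cells[(f, d)].value for d in _CODES] for f in _CODES]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"cells": rows}, fh, sort_keys=False)


def classify_pair(functional: int, dysfunctional: int,
                  matrix: EvaluationMatrix | None = None) -> KanoCategory:
    """Classify one answer pair; defaults to the canonical matrix."""
    if matrix is None:
        matrix = EvaluationMatrix.canonical()
    return matrix.classify(functional, dysfunctional)
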