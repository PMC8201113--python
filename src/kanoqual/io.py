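"""Delimited-text readers and writers.

Responses use a wide one-row-per-respondent CSV: ``respondent_id,
age_group, gender, hospital`` followed by ``a{k}_f`` and ``a{k}_d`` columns
for every attribute ``k``.  Blank cells are missing; a pair counts only if
both sides are present.  An optional ``frequency_of_use`` column is
accepted and ignored.  Results use one row per attribute with the six
counts, the classification, CS/DS rounded to two decimals, and the exact
rational coefficients (so write -> read is lossless).

All files are UTF-8, comma-delimited, with a mandatory header.
"""

from __future__ import annotations

import csv
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import pandas as pd

from .analysis import AttributeResult, CategoryCounts, result_from_counts
from .errors import FormatError, ValidationError
from .instrument import Instrument
from .matrix import KanoCategory
from .responses import RespondentRecord, ResponsePair, ResponseTable

_DEMOGRAPHICS = ["respondent_id", "age_group", "gender", "hospital"]
_OPTIONAL_COLUMNS = {"frequency_of_use"}


def _pair_columns(instrument: Instrument) -> list[str]:
    cols = []
    for a in instrument.attr_ids:
        cols += [f"a{a}_f", f"a{a}_d"]
    return cols


def _parse_code(raw: object, row: int, column: str) -> int | None:
    """A cell is either blank (missing) or an integer code 1..5."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    text = str(raw).strip()
    if text == "" or text.lower() == "nan":
        return None
    try:
        code = int(float(text)) if float(text).is_integer() else None
    except ValueError:
        code = None
    if code is None or not 1 <= code <= 5:
        raise ValidationError(
            f"row {row}, column {column!r}: code must be in 1..5, got {raw!r}")
    return code


def read_responses(path: str | Path, instrument: Instrument) -> ResponseTable:
    """Read a wide responses CSV against an instrument."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = _DEMOGRAPHICS + _pair_columns(instrument)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        answers: dict[int, ResponsePair] = {}
        for attr_id in instrument.attr_ids:
            f = _parse_code(row_d[f"a{attr_id}_f"], i, f"a{attr_id}_f")
            d = _parse_code(row_d[f"a{attr_id}_d"], i, f"a{attr_id}_d")
            if f is not None and d is not None:
                answers[attr_id] = ResponsePair(f, d)
        records.append(RespondentRecord(
            respondent_id=str(row_d["respondent_id"]).strip(),
            age_group=str(row_d["age_group"]).strip(),
            gender=str(row_d["gender"]).strip(),
            hospital=str(row_d["hospital"]).strip(),
            answers=answers,
        ))
    return ResponseTable(instrument, tuple(records))


def write_responses(table: ResponseTable, path: str | Path) -> None:
    """Write a response table to the wide CSV layout (inverse of read)."""
    cols = _DEMOGRAPHICS + _pair_columns(table.instrument)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for rec in table.records:
            row: list[str] = [rec.respondent_id, rec.age_group,
                              rec.gender, rec.hospital]
            for attr_id in table.instrument.attr_ids:
                pair = rec.answers.get(attr_id)
                row += (["", ""] if pair is None
                        else [str(pair.functional), str(pair.dysfunctional)])
            writer.writerow(row)


_RESULT_COLUMNS = ["attr_id", "n_A", "n_Q", "n_I", "n_R", "n_M", "n_O",
                   "classification", "cs", "ds", "cs_exact", "ds_exact"]


def write_results(results: Sequence[AttributeResult], path: str | Path) -> None:
    """Write per-attribute results: counts, class, 2-dp and exact CS/DS."""
    if not results:
        raise ValidationError("cannot write an empty results list")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_RESULT_COLUMNS)
        for r in results:
            c = r.counts
            writer.writerow([
                r.attr_id, c.n_A, c.n_Q, c.n_I, c.n_R, c.n_M, c.n_O,
                r.classification.value,
                "" if r.cs is None else f"{r.cs_rounded:.2f}",
                "" if r.ds is None else f"{r.ds_rounded:.2f}",
                "" if r.cs is None else str(r.cs),
                "" if r.ds is None else str(r.ds),
            ])


def read_results(path: str | Path) -> list[AttributeResult]:
    """Read a results CSV written by :func:`write_results`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    results = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        counts = CategoryCounts(
            int(d["attr_id"]),
            **{f"n_{c}": int(d[f"n_{c}"]) for c in "AQIRMO"})
        try:
            classification = KanoCategory(d["classification"])
        except ValueError as exc:
            raise FormatError(
                f"unknown classification {d['classification']!r}") from exc
        cs = Fraction(d["cs_exact"]) if d["cs_exact"] != "" else None
        ds = Fraction(d["ds_exact"]) if d["ds_exact"] != "" else None
        results.append(AttributeResult(counts.attr_id, counts,
                                       classification, cs, ds))
    return results


def read_counts(path: str | Path) -> list[CategoryCounts]:
    """Read pre-aggregated per-attribute counts (attr_id + six count columns)."""
    df = pd.read_csv(path)
    needed = ["attr_id", "n_A", "n_Q", "n_I", "n_R", "n_M", "n_O"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    return [CategoryCounts(int(row.attr_id), n_A=int(row.n_A), n_Q=int(row.n_Q),
                           n_I=int(row.n_I), n_R=int(row.n_R), n_M=int(row.n_M),
                           n_O=int(row.n_O))
            for row in df.itertuples(index=False)]
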