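"""Respondent-level records and the response table container.

Answers are stored per attribute as a (functional, dysfunctional) pair of
Likert codes.  A pair is *valid* only when both codes are present; a pair
with either side missing is excluded from that attribute's tally, so the
valid n may differ across attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .instrument import AGE_GROUPS, GENDERS, HOSPITALS, Instrument


@dataclass(frozen=True)
class ResponsePair:
    """One respondent's paired answers for one attribute."""

    functional: int
    dysfunctional: int

    def __post_init__(self) -> None:
        for side, code in (("functional", self.functional),
                           ("dysfunctional", self.dysfunctional)):
            if not isinstance(code, int) or not 1 <= code <= 5:
                raise ValidationError(
                    f"{side} code must be an integer in 1..5, got {code!r}")


@dataclass(frozen=True)
class RespondentRecord:
    """One survey respondent: demographics plus answers keyed by attr_id.

    Missing attributes are simply absent from ``answers``.
    """

    respondent_id: str
    age_group: str
    gender: str
    hospital: str
    answers: dict[int, ResponsePair] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(
                f"age_group must be one of {AGE_GROUPS}, got {self.age_group!r}")
        if self.gender not in GENDERS:
            raise ValidationError(
                f"gender must be one of {GENDERS}, got {self.gender!r}")
        if self.hospital not in HOSPITALS:
            raise ValidationError(
                f"hospital must be one of {HOSPITALS}, got {self.hospital!r}")


@dataclass(frozen=True)
class ResponseTable:
    """An instrument together with the records collected under it."""

    instrument: Instrument
    records: tuple[RespondentRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.respondent_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate respondent_id(s): {dup}")
        known = set(self.instrument.attr_ids)
        for rec in self.records:
            unknown = set(rec.answers) - known
            if unknown:
                raise ValidationError(
                    f"respondent {rec.respondent_id!r} answers unknown "
                    f"attribute(s) {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.records)

    def valid_n(self, attr_id: int) -> int:
        """Number of respondents with a complete pair for this attribute."""
        return sum(1 for r in self.records if attr_id in r.answers)
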