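"""Questionnaire data model.

A Kano-style instrument pairs every service attribute with two five-point
items: a *functional* question (how does the respondent feel when the
attribute is present?) and a *dysfunctional* one (how do they feel when it
is absent?).  The default instrument bundled with the package covers 31
attributes of hospital service quality grouped into four dimensions
(health personnel, non-health personnel, facilities/equipment/tangibles,
efficiency), plus three demographic items, for 65 questions in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

from .errors import FormatError, ValidationError

#: Answer labels of the five-point Kano response scale, keyed by code.
LIKERT_LABELS: dict[int, str] = {
    1: "I like it",
    2: "I hope it is so",
    3: "I am neutral",
    4: "I can accept it being that way",
    5: "I dislike it that way",
}

#: Closed vocabulary of instrument dimensions.
DIMENSIONS = (
    "health_personnel",
    "non_health_personnel",
    "facilities_equipment_tangibles",
    "efficiency",
)

#: Demographic vocabularies (closed; matches the survey strata).
AGE_GROUPS = ("18-34", "35-54", "55-74", "75+")
GENDERS = ("male", "female")
HOSPITALS = ("barton", "kaelin")
DEMOGRAPHIC_FIELDS = ("age_group", "gender", "hospital")


@dataclass(frozen=True)
class LikertAnswer:
    """A single five-point answer; the label is determined by the code."""

    code: int

    def __post_init__(self) -> None:
        if self.code not in LIKERT_LABELS:
            raise ValidationError(f"Likert code must be in 1..5, got {self.code}")

    @property
    def label(self) -> str:
        return LIKERT_LABELS[self.code]


@dataclass(frozen=True)
class Attribute:
    """One service attribute (implies one functional + one dysfunctional item)."""

    attr_id: int
    text: str
    dimension: str

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise FormatError(f"unknown dimension {self.dimension!r}")
        if self.attr_id < 1:
            raise FormatError(f"attr_id must be positive, got {self.attr_id}")


@dataclass(frozen=True)
class Instrument:
    """An ordered collection of attributes plus the demographic fields."""

    attributes: tuple[Attribute, ...]
    demographic_fields: tuple[str, ...] = DEMOGRAPHIC_FIELDS
    name: str = "instrument"

    def __post_init__(self) -> None:
        ids = [a.attr_id for a in self.attributes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate attr_id(s): {dup}")

    @property
    def attr_ids(self) -> tuple[int, ...]:
        return tuple(a.attr_id for a in self.attributes)

    @property
    def dimensions(self) -> tuple[str, ...]:
        """Dimensions in first-appearance order."""
        seen: list[str] = []
        for a in self.attributes:
            if a.dimension not in seen:
                seen.append(a.dimension)
        return tuple(seen)

    def __len__(self) -> int:
        return len(self.attributes)

    def __getitem__(self, attr_id: int) -> Attribute:
        for a in self.attributes:
            if a.attr_id == attr_id:
                return a
        raise KeyError(attr_id)

    def attributes_in(self, dimension: str) -> tuple[Attribute, ...]:
        return tuple(a for a in self.attributes if a.dimension == dimension)

    @property
    def n_questions(self) -> int:
        """Total questionnaire length: two items per attribute plus demographics."""
        return 2 * len(self.attributes) + len(self.demographic_fields)


def _instrument_from_mapping(doc: dict, name: str) -> Instrument:
    try:
        dims = doc["dimensions"]
    except (KeyError, TypeError) as exc:
        raise FormatError("instrument file must contain a 'dimensions' list") from exc
    attrs: list[Attribute] = []
    for dim in dims:
        try:
            dim_name = dim["name"]
            entries = dim["attributes"]
        except (KeyError, TypeError) as exc:
            raise FormatError("each dimension needs 'name' and 'attributes'") from exc
        for entry in entries:
            try:
                attrs.append(Attribute(int(entry["id"]), str(entry["text"]), dim_name))
            except (KeyError, TypeError) as exc:
                raise FormatError(f"malformed attribute entry {entry!r}") from exc
    return Instrument(tuple(attrs), name=str(doc.get("name", name)))


def read_instrument(path: str | Path) -> Instrument:
    """Read an instrument definition from a YAML file.

    Raises :class:`FormatError` on duplicate attribute ids or unknown
    dimension names.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _instrument_from_mapping(doc, Path(path).stem)


def write_instrument(instrument: Instrument, path: str | Path) -> None:
    """Write an instrument to YAML (inverse of :func:`read_instrument`)."""
    doc = {
        "name": instrument.name,
        "dimensions": [
            {
                "name": dim,
                "attributes": [
                    {"id": a.attr_id, "text": a.text}
                    for a in instrument.attributes_in(dim)
                ],
            }
            for dim in instrument.dimensions
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def default_instrument() -> Instrument:
    """The bundled 31-attribute, 4-dimension hospital-quality instrument."""
    ref = resources.files("kanoqual.data").joinpath("instrument.yaml")
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _instrument_from_mapping(doc, "hospital-service-quality")
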