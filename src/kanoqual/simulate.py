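"""Synthetic respondent generation and deterministic count expansion.

The generator emulates a cross-sectional outpatient satisfaction survey:
each respondent draws demographics from the study strata and, per
attribute, one of the 25 (functional, dysfunctional) answer cells from a
per-attribute distribution.  Attributes and respondents are independent —
real surveys correlate both, so the simulator tests the pipeline's
arithmetic, not respondent psychology.

A profile may specify each attribute either by a full 5x5 cell
distribution or by six category probabilities; the latter are realized
through one designated *representative cell* per category, chosen so that
each cell maps back to its category under the canonical evaluation matrix
(making count -> table -> count round trips exact):

    A -> (1,3)   O -> (1,5)   M -> (3,5)   I -> (3,3)   R -> (5,1)   Q -> (1,1)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .analysis import COUNT_ORDER, CategoryCounts
from .errors import FormatError, ValidationError
from .instrument import AGE_GROUPS, GENDERS, HOSPITALS, Instrument
from .matrix import KanoCategory
from .responses import RespondentRecord, ResponsePair, ResponseTable

#: Representative (functional, dysfunctional) cell per category.
REPRESENTATIVE_CELLS: dict[KanoCategory, tuple[int, int]] = {
    KanoCategory.A: (1, 3),
    KanoCategory.O: (1, 5),
    KanoCategory.M: (3, 5),
    KanoCategory.I: (3, 3),
    KanoCategory.R: (5, 1),
    KanoCategory.Q: (1, 1),
}

#: Survey strata proportions (counts out of 250: 67/101/60/22, 122/128, 128/122).
DEFAULT_AGE_PROBS = {"18-34": 67 / 250, "35-54": 101 / 250,
                     "55-74": 60 / 250, "75+": 22 / 250}
DEFAULT_GENDER_PROBS = {"male": 122 / 250, "female": 128 / 250}
DEFAULT_HOSPITAL_PROBS = {"barton": 128 / 250, "kaelin": 122 / 250}

_PROB_TOL = 1e-9


def _check_probs(probs: np.ndarray, what: str) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if (probs < 0).any():
        raise ValidationError(f"{what}: negative probability")
    if abs(probs.sum() - 1.0) > _PROB_TOL:
        raise ValidationError(f"{what}: probabilities sum to {probs.sum()!r}, not 1")
    return probs


def cell_probs_from_categories(category_probs: Mapping[KanoCategory | str, float],
                               ) -> np.ndarray:
    """Turn six category probabilities into a 5x5 cell distribution via the
    representative cells."""
    grid = np.zeros((5, 5))
    for cat, p in category_probs.items():
        f, d = REPRESENTATIVE_CELLS[KanoCategory(cat)]
        grid[f - 1, d - 1] += float(p)
    return _check_probs(grid, "category_probs").reshape(5, 5)


@dataclass(frozen=True)
class SyntheticProfile:
    """Specification of a simulated survey.

    ``cell_probs`` maps attr_id to a 5x5 array over (functional,
    dysfunctional) cells.  Demographics default to the study strata.
    """

    n_respondents: int
    cell_probs: dict[int, np.ndarray]
    age_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AGE_PROBS))
    gender_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENDER_PROBS))
    hospital_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HOSPITAL_PROBS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValidationError("n_respondents must be >= 1")
        for attr_id, grid in self.cell_probs.items():
            g = _check_probs(np.asarray(grid, dtype=float), f"attribute {attr_id}")
            if g.shape != (5, 5):
                raise ValidationError(
                    f"attribute {attr_id}: cell_probs must be 5x5, got {g.shape}")
            self.cell_probs[attr_id] = g
        for probs, keys, what in ((self.age_probs, AGE_GROUPS, "age"),
                                  (self.gender_probs, GENDERS, "gender"),
                                  (self.hospital_probs, HOSPITALS, "hospital")):
            unknown = set(probs) - set(keys)
            if unknown:
                raise ValidationError(f"{what}: unknown categories {sorted(unknown)}")
            _check_probs(np.array([probs.get(k, 0.0) for k in keys]), what)

    @classmethod
    def from_category_probs(cls,
                            category_probs: Mapping[KanoCategory | str, float],
                            instrument: Instrument,
                            n_respondents: int = 250,
                            seed: int = 0,
                            **kwargs) -> "SyntheticProfile":
        """One shared category distribution applied to every attribute."""
        grid = cell_probs_from_categories(category_probs)
        return cls(n_respondents,
                   {a: grid.copy() for a in instrument.attr_ids},
                   seed=seed, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path, instrument: Instrument,
                  seed: int | None = None) -> "SyntheticProfile":
        """Read a profile config.

        Layout: ``n_respondents``, optional ``seed``, ``attributes`` with a
        ``default`` entry and/or per-attr-id overrides, each holding either
        ``category_probs`` (mapping letter -> prob) or ``cell_probs`` (5x5
        row-major list, rows = functional code).
        """
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "attributes" not in doc:
            raise FormatError("profile must contain an 'attributes' mapping")

        def to_grid(entry: dict) -> np.ndarray:
            if "category_probs" in entry:
                return cell_probs_from_categories(entry["category_probs"])
            if "cell_probs" in entry:
                return np.asarray(entry["cell_probs"], dtype=float)
            raise FormatError(
                "attribute entry needs 'category_probs' or 'cell_probs'")

        entries = doc["attributes"]
        default = to_grid(entries["default"]) if "default" in entries else None
        cell_probs: dict[int, np.ndarray] = {}
        for a in instrument.attr_ids:
            if a in entries:
                cell_probs[a] = to_grid(entries[a])
            elif str(a) in entries:
                cell_probs[a] = to_grid(entries[str(a)])
            elif default is not None:
                cell_probs[a] = default.copy()
            else:
                raise FormatError(f"no profile entry for attribute {a} and no default")
        return cls(
            n_respondents=int(doc.get("n_respondents", 250)),
            cell_probs=cell_probs,
            seed=int(doc.get("seed", 0) if seed is None else seed),
        )


def generate(profile: SyntheticProfile, instrument: Instrument) -> ResponseTable:
    """Draw a synthetic response table; reproducible given the profile seed."""
    missing = set(instrument.attr_ids) - set(profile.cell_probs)
    if missing:
        raise ValidationError(f"profile lacks cell_probs for attributes {sorted(missing)}")
    rng = np.random.default_rng(profile.seed)
    n = profile.n_respondents
    ages = rng.choice(AGE_GROUPS, size=n,
                      p=[profile.age_probs.get(k, 0.0) for k in AGE_GROUPS])
    genders = rng.choice(GENDERS, size=n,
                         p=[profile.gender_probs.get(k, 0.0) for k in GENDERS])
    hospitals = rng.choice(HOSPITALS, size=n,
                           p=[profile.hospital_probs.get(k, 0.0) for k in HOSPITALS])
    draws: dict[int, np.ndarray] = {}
    for attr_id in instrument.attr_ids:
        flat = profile.cell_probs[attr_id].reshape(25)
        draws[attr_id] = rng.choice(25, size=n, p=flat / flat.sum())
    width = len(str(n))
    records = []
    for i in range(n):
        answers = {}
        for attr_id in instrument.attr_ids:
            cell = int(draws[attr_id][i])
            answers[attr_id] = ResponsePair(cell // 5 + 1, cell % 5 + 1)
        records.append(RespondentRecord(
            respondent_id=f"r{i + 1:0{width}d}",
            age_group=str(ages[i]), gender=str(genders[i]),
            hospital=str(hospitals[i]), answers=answers))
    return ResponseTable(instrument, tuple(records))


def _demographic_blocks(n: int) -> tuple[list[str], list[str], list[str]]:
    """Deterministic demographics whose margins scale the study strata.

    For n = 250 the margins are exactly 67/101/60/22, 122/128, 128/122.
    The joint structure (block assignment) is arbitrary: only marginal
    counts are specified by the strata.
    """
    def blocks(probs: Mapping[str, float], keys: Sequence[str]) -> list[str]:
        counts = [int(round(probs[k] * n)) for k in keys]
        counts[-1] = n - sum(counts[:-1])
        out: list[str] = []
        for k, c in zip(keys, counts):
            out += [k] * c
        return out

    return (blocks(DEFAULT_AGE_PROBS, AGE_GROUPS),
            blocks(DEFAULT_GENDER_PROBS, GENDERS),
            blocks(DEFAULT_HOSPITAL_PROBS, HOSPITALS))


def expand_counts(counts: CategoryCounts, instrument: Instrument) -> ResponseTable:
    """Deterministically expand one attribute's counts to respondent level.

    Each counted respondent gets the representative cell of its category
    (in printed column order A, Q, I, R, M, O), so re-aggregating returns
    the input counts exactly.  Other attributes are left missing.
    """
    return expand_table([counts], instrument)


def expand_table(counts_list: Sequence[CategoryCounts],
                 instrument: Instrument) -> ResponseTable:
    """Expand several attributes' counts into one aligned table.

    Respondent i receives, for each attribute, the representative cell of
    the i-th entry of that attribute's expansion (categories laid out in
    printed order).  The table length is the maximum per-attribute total;
    attributes with fewer counted respondents are missing for the tail.
    """
    known = set(instrument.attr_ids)
    for c in counts_list:
        if c.attr_id not in known:
            raise ValidationError(f"attribute {c.attr_id} not in instrument")
    n = max((c.total for c in counts_list), default=0)
    per_attr: dict[int, list[ResponsePair]] = {}
    for c in counts_list:
        pairs = []
        for cat in COUNT_ORDER:
            f, d = REPRESENTATIVE_CELLS[cat]
            pairs += [ResponsePair(f, d)] * c[cat]
        per_attr[c.attr_id] = pairs
    ages, genders, hospitals = _demographic_blocks(max(n, 1))
    width = len(str(max(n, 1)))
    records = []
    for i in range(n):
        answers = {a: pairs[i] for a, pairs in per_attr.items() if i < len(pairs)}
        records.append(RespondentRecord(
            respondent_id=f"r{i + 1:0{width}d}",
            age_group=ages[i], gender=genders[i], hospital=hospitals[i],
            answers=answers))
    return ResponseTable(instrument, tuple(records))
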