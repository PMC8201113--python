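"""Bundled reference data: the two-hospital outpatient survey.

The package ships the per-attribute Kano category counts reported by a
250-respondent outpatient satisfaction survey run in two Peruvian
hospitals (31 attributes in 4 dimensions; every attribute has a complete
tally over all 250 respondents).  ``hospital_survey_table`` expands these
counts deterministically to respondent level — each counted respondent is
assigned the representative answer cell of its category, and demographics
are laid out to match the published strata margins exactly (ages
67/101/60/22; 122 male / 128 female; 128 Barton / 122 Kaelin).  The
respondent-level joint structure is synthetic: only the per-attribute
tallies and demographic margins are observed quantities.
"""

from __future__ import annotations

import csv
from importlib import resources

from .analysis import CategoryCounts
from .instrument import Instrument, default_instrument
from .responses import ResponseTable
from .simulate import expand_table


def hospital_survey_counts() -> list[CategoryCounts]:
    """The 31 published per-attribute category count rows."""
    ref = resources.files("kanoqual.data").joinpath("survey_counts.csv")
    rows = list(csv.DictReader(ref.read_text(encoding="utf-8").splitlines()))
    return [CategoryCounts(int(r["attr_id"]),
                           **{f"n_{c}": int(r[f"n_{c}"]) for c in "AQIRMO"})
            for r in rows]


def hospital_survey_table(instrument: Instrument | None = None) -> ResponseTable:
    """Deterministic 250-respondent expansion of the published counts."""
    if instrument is None:
        instrument = default_instrument()
    return expand_table(hospital_survey_counts(), instrument)
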