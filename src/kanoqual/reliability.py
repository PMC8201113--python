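"""Internal-consistency reliability of the paired questionnaire.

Standardized Cronbach's alpha is computed from the mean pairwise Pearson
correlation r̄ of the k items:

    alpha = k * r̄ / (1 + (k - 1) * r̄)

The item matrix can be built from the functional items only, the
dysfunctional items only, or all paired items (default).  Respondents with
any missing selected pair are dropped listwise.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

from .errors import ValidationError, ZeroVarianceItemError
from .responses import ResponseTable

ItemSet = Literal["functional", "dysfunctional", "all_paired"]


def build_item_matrix(table: ResponseTable,
                      item_set: ItemSet = "all_paired") -> pd.DataFrame:
    """Respondents x items matrix of Likert codes, listwise-complete.

    Columns are named ``a{k}_f`` / ``a{k}_d``.  Rows (respondents) with any
    missing selected pair are dropped.
    """
    if item_set not in ("functional", "dysfunctional", "all_paired"):
        raise ValidationError(f"unknown item_set {item_set!r}")
    attr_ids = table.instrument.attr_ids
    rows, index = [], []
    for rec in table.records:
        if any(a not in rec.answers for a in attr_ids):
            continue  # listwise deletion
        row = []
        for a in attr_ids:
            pair = rec.answers[a]
            if item_set in ("functional", "all_paired"):
                row.append(pair.functional)
            if item_set in ("dysfunctional", "all_paired"):
                row.append(pair.dysfunctional)
        rows.append(row)
        index.append(rec.respondent_id)
    cols = []
    for a in attr_ids:
        if item_set in ("functional", "all_paired"):
            cols.append(f"a{a}_f")
        if item_set in ("dysfunctional", "all_paired"):
            cols.append(f"a{a}_d")
    return pd.DataFrame(rows, index=index, columns=cols, dtype=float)


def standardized_alpha(items: pd.DataFrame | np.ndarray) -> float:
    """Standardized Cronbach's alpha of a respondents x items matrix.

    Requires at least 2 items, at least 2 respondents, and nonzero variance
    in every item (the offending item is named otherwise).
    """
    df = pd.DataFrame(items)
    n, k = df.shape
    if k < 2:
        raise ValidationError(f"need at least 2 items, got {k}")
    if n < 2:
        raise ValidationError(f"need at least 2 respondents, got {n}")
    variances = df.var(axis=0, ddof=1)
    dead = variances[variances == 0]
    if len(dead):
        raise ZeroVarianceItemError(str(dead.index[0]))
    corr = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    off_diag = corr[~np.eye(k, dtype=bool)]
    r_bar = float(off_diag.mean())
    return k * r_bar / (1.0 + (k - 1) * r_bar)


def alpha_threshold_check(alpha: float, threshold: float = 0.7) -> bool:
    """Is the reliability acceptable?  Boundary value counts as acceptable."""
    return alpha >= threshold
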