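"""CS-|DS| quadrant charts.

Convention (labelled on every chart): x = |DS|, y = CS, quadrant split at
0.5 on both axes by default.  Low x / high y = attractive, high x / high
y = one-dimensional, high x / low y = must-be, low x / low y =
indifferent.  Points exactly on a split line count as the "low" side.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .analysis import AttributeResult
from .instrument import Instrument

logger = logging.getLogger(__name__)

_QUADRANT_LABELS = {
    (False, True): "attractive",
    (True, True): "one_dimensional",
    (True, False): "must_be",
    (False, False): "indifferent",
}


def quadrant_of(cs: float, ds: float, split: float = 0.5) -> str:
    """Quadrant name for a (CS, DS) pair under the |DS|/CS convention."""
    x, y = abs(ds), cs
    return _QUADRANT_LABELS[(x > split, y > split)]


def quadrant_chart(results: Sequence[AttributeResult],
                   path: str | Path,
                   split: float = 0.5,
                   title: str | None = None,
                   labels: dict[int, str] | None = None) -> Path:
    """Scatter attributes in the |DS| x CS unit square and save the figure.

    Attributes with undefined coefficients are skipped with a warning.
    """
    fig, ax = plt.subplots(figsize=(6, 6))
    for r in results:
        if r.cs is None or r.ds is None:
            logger.warning("attribute %d: coefficients undefined; "
                           "skipped in quadrant chart", r.attr_id)
            continue
        x, y = abs(float(r.ds)), float(r.cs)
        ax.scatter([x], [y], color="tab:blue", zorder=3)
        text = labels.get(r.attr_id, str(r.attr_id)) if labels else str(r.attr_id)
        ax.annotate(text, (x, y), textcoords="offset points",
                    xytext=(4, 4), fontsize=8)
    ax.axhline(split, color="grey", lw=1)
    ax.axvline(split, color="grey", lw=1)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("|DS| (degree of dissatisfaction, absolute)")
    ax.set_ylabel("CS (degree of satisfaction)")
    pad = 0.02
    ax.text(pad, 1 - pad, "attractive", ha="left", va="top", fontsize=9, color="grey")
    ax.text(1 - pad, 1 - pad, "one-dimensional", ha="right", va="top",
            fontsize=9, color="grey")
    ax.text(1 - pad, pad, "must-be", ha="right", va="bottom", fontsize=9, color="grey")
    ax.text(pad, pad, "indifferent", ha="left", va="bottom", fontsize=9, color="grey")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def charts_by_dimension(results: Iterable[AttributeResult],
                        instrument: Instrument,
                        out_dir: str | Path,
                        split: float = 0.5,
                        fmt: str = "png") -> list[Path]:
    """One quadrant chart per instrument dimension."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {r.attr_id: r for r in results}
    paths = []
    for dim in instrument.dimensions:
        dim_results = [by_id[a.attr_id] for a in instrument.attributes_in(dim)
                       if a.attr_id in by_id]
        if not dim_results:
            continue
        labels = {a.attr_id: f"{a.attr_id}" for a in instrument.attributes_in(dim)}
        paths.append(quadrant_chart(
            dim_results, out_dir / f"quadrant_{dim}.{fmt}", split=split,
            title=dim.replace("_", " "), labels=labels))
    return paths
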