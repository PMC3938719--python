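"""Cohort-level category tables for site locations and motif classes.

Percentages are integers obtained by round-half-up (49 of 105 -> 47%,
99 of 105 -> 94%), the convention used when such cohort compositions are
reported as pie-chart labels.  Raw fractions are always emitted alongside
the integer percents, so no information is lost to rounding, and the percent
column is allowed to sum to 99-101.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .annotate import CATEGORIES, SiteAnnotation
from .motifs import SiteMotifClass

MOTIF_CLASSES = ("canonical", "general_only", "none")


def percent_half_up(count: int, total: int) -> int:
    """Integer percentage of count/total with exact half-up rounding."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(
        (Decimal(100 * count) / Decimal(total)).quantize(Decimal(1), ROUND_HALF_UP)
    )


def _table(counts: dict[str, int], total: int) -> pd.DataFrame:
    rows = [
        (label, n, n / total, percent_half_up(n, total))
        for label, n in counts.items()
    ]
    return pd.DataFrame(rows, columns=["label", "count", "fraction", "percent"])


def location_table(annotations: Sequence[SiteAnnotation]) -> pd.DataFrame:
    """Four-way location table plus a combined-intron row and an ``other`` row.

    Percent denominators are the full cohort size (including flagged exonic
    sites, reported under ``other``).  ``intron_total`` combines intron1 and
    internal_intron, mirroring the "within introns" cohort summary.
    """
    if not annotations:
        raise ValueError("cannot summarize an empty cohort")
    total = len(annotations)
    counts = {c: 0 for c in CATEGORIES}
    counts["other"] = 0
    for a in annotations:
        counts[a.category] += 1
    counts["intron_total"] = counts["intron1"] + counts["internal_intron"]
    order = [
        "intergenic",
        "upstream_lt10kb",
        "intron1",
        "internal_intron",
        "intron_total",
        "other",
    ]
    return _table({k: counts[k] for k in order}, total)


def motif_table(site_classes: Sequence[SiteMotifClass]) -> pd.DataFrame:
    """Three-way motif-class table plus a derived ``any_motif`` row."""
    if not site_classes:
        raise ValueError("cannot summarize an empty cohort")
    total = len(site_classes)
    counts = {c: 0 for c in MOTIF_CLASSES}
    for c in site_classes:
        counts[c.site_class] += 1
    counts["any_motif"] = counts["canonical"] + counts["general_only"]
    return _table(counts, total)


def pie_chart(table: pd.DataFrame, path: str, title: str = "") -> None:
    """Optional pie-chart export of a category table (counts > 0 only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    base = table[~table["label"].isin(["intron_total", "any_motif"])]
    base = base[base["count"] > 0]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.pie(
        base["count"],
        labels=[
            f"{label} ({pct}%)"
            for label, pct in zip(base["label"], base["percent"])
        ],
    )
    ax.set_title(title)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
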