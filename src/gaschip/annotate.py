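"""Genomic-location classification of cloned sites and target-gene nomination.

Each ChIP-cloned fragment is assigned exactly one location category relative
to a set of annotated gene models:

* ``intron1`` / ``internal_intron`` — the fragment midpoint lies in an intron;
  the ordinal is strand-aware (intron 1 is nearest the TSS) and the host gene
  is nominated as the candidate target.
* ``upstream_lt10kb`` — the midpoint lies within 10 kb 5' of a TSS
  (strand-aware); the nearest such gene is the candidate target.
* ``intergenic`` — more than 10 kb from the 5' ends of the two closest genes;
  both flanking genes are nominated (one at a chromosome end).
* ``other`` — the midpoint falls in exonic/UTR gene territory; these are
  flagged and reported separately from the four-way summary.

Classification uses the fragment midpoint by default (fragments are short,
~0.2-1 kb, and a midpoint rule is deterministic at category boundaries); an
``any_overlap`` mode is available for sensitivity analysis.  Precedence is
intron > upstream > exonic > intergenic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .genomic import ClonedSite, GeneModel

logger = logging.getLogger(__name__)

CATEGORIES = ("intron1", "internal_intron", "upstream_lt10kb", "intergenic")
DEFAULT_UPSTREAM_WINDOW = 10_000


@dataclass(frozen=True)
class SiteAnnotation:
    site_id: str
    category: str
    genes: tuple[str, ...]
    dist_to_nearest_tss: int | None
    intron_ordinal: int | None = None


def interval_gap(a: tuple[str, int, int], b: tuple[str, int, int]) -> int:
    """Gap in bp between two half-open intervals on the same chromosome.

    Returns 0 for overlapping or book-ended intervals, otherwise the distance
    between the nearest ends (downstream start minus upstream end).
    """
    chrom_a, start_a, end_a = a
    chrom_b, start_b, end_b = b
    if chrom_a != chrom_b:
        raise ValueError(f"intervals on different chromosomes: {chrom_a} vs {chrom_b}")
    if start_a > start_b:
        start_a, end_a, start_b, end_b = start_b, end_b, start_a, end_a
    return max(0, start_b - end_a)


def _interval_candidates(site: ClonedSite, lo: int, hi: int, mode: str) -> bool:
    """Does the site hit [lo, hi) under the active classification mode?"""
    if mode == "midpoint":
        return lo <= site.midpoint < hi
    return site.start < hi and site.end > lo  # any_overlap


def locate_site(
    site: ClonedSite,
    genes_on_chrom: Sequence[GeneModel],
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
    mode: str = "midpoint",
) -> SiteAnnotation:
    """Classify one site against the genes of its chromosome.

    `genes_on_chrom` must all share the site's chromosome.  With no genes on
    the chromosome the site is intergenic with an empty gene list.
    """
    if mode not in ("midpoint", "any_overlap"):
        raise ValueError(f"unknown classification mode {mode!r}")
    genes = [g for g in genes_on_chrom if g.chrom == site.chrom]
    if len(genes) != len(genes_on_chrom):
        raise ValueError(f"site {site.site_id}: gene list mixes chromosomes")
    mid = site.midpoint
    if not genes:
        logger.warning(
            "site %s: no genes on chromosome %s; intergenic with no targets",
            site.site_id,
            site.chrom,
        )
        return SiteAnnotation(site.site_id, "intergenic", (), None)

    dist_tss = min(abs(mid - g.tss) for g in genes)

    # 1) intronic (ties between overlapping host genes broken by gene_id)
    intronic: list[tuple[str, int]] = []
    for g in genes:
        for s, e, ordinal in g.introns_with_ordinals():
            if _interval_candidates(site, s, e, mode):
                intronic.append((g.gene_id, ordinal))
    if intronic:
        gene_id, ordinal = min(intronic)
        category = "intron1" if ordinal == 1 else "internal_intron"
        return SiteAnnotation(site.site_id, category, (gene_id,), dist_tss, ordinal)

    # 2) within the upstream window 5' of a TSS, strand-aware
    upstream: list[tuple[int, str]] = []
    for g in genes:
        if mode == "midpoint":
            d = g.upstream_distance(mid)
            if d is not None and d <= upstream_window:
                upstream.append((d, g.gene_id))
        else:
            if g.strand == "+":
                window_lo, window_hi = g.tss - upstream_window, g.tss
            else:
                window_lo, window_hi = g.tss + 1, g.tss + 1 + upstream_window
            if site.start < window_hi and site.end > window_lo:
                d = g.upstream_distance(mid)
                upstream.append((d if d is not None else 1, g.gene_id))
    if upstream:
        d, gene_id = min(upstream)
        return SiteAnnotation(site.site_id, "upstream_lt10kb", (gene_id,), dist_tss)

    # 3) exonic/UTR gene territory -> flagged, outside the four-way scheme
    exonic = sorted(
        g.gene_id
        for g in genes
        if _interval_candidates(site, g.tx_start, g.tx_end, mode)
    )
    if exonic:
        return SiteAnnotation(site.site_id, "other", (exonic[0],), dist_tss)

    # 4) intergenic: nearest gene by TSS on each side of the midpoint
    left = [g for g in genes if g.tss < mid]
    right = [g for g in genes if g.tss > mid]
    flanking = []
    if left:
        flanking.append(max(left, key=lambda g: (g.tss, g.gene_id)).gene_id)
    if right:
        flanking.append(min(right, key=lambda g: (g.tss, g.gene_id)).gene_id)
    return SiteAnnotation(site.site_id, "intergenic", tuple(flanking), dist_tss)


def annotate_cohort(
    sites: Sequence[ClonedSite],
    genes: Sequence[GeneModel],
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
    mode: str = "midpoint",
) -> list[SiteAnnotation]:
    """Annotate every site; output ordered by (chrom, start, site_id)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    ordered = sorted(sites, key=lambda s: (s.chrom, s.start, s.site_id))
    return [
        locate_site(s, by_chrom.get(s.chrom, []), upstream_window, mode)
        for s in ordered
    ]


def annotations_table(annotations: Sequence[SiteAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                a.site_id,
                a.category,
                ",".join(a.genes),
                a.dist_to_nearest_tss,
                a.intron_ordinal,
            )
            for a in annotations
        ],
        columns=[
            "site_id",
            "category",
            "genes",
            "dist_to_nearest_tss",
            "intron_ordinal",
        ],
    )
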