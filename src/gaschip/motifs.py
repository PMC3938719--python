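"""GAS-motif scanning and exclusive per-site motif classification.

STAT5 dimers recognize the canonical GAS element TTCN3GAA; tetrameric STAT5
complexes can additionally bind the relaxed consensus TTN5AA.  Both patterns
are 9 bp and, as degenerate patterns, each is its own reverse complement, so
a single plus-strand scan finds every GAS element regardless of which strand
carries it (a minus-strand element is a plus-strand pattern match at the same
locus).  Pattern N positions match exactly one of {A,C,G,T} in the subject;
a subject N (assembly gap) never matches, so motifs are not called in gaps.

A site's motif class is exclusive with canonical precedence: any canonical
hit makes the site ``canonical``; otherwise any relaxed hit makes it
``general_only``; otherwise ``none``.  Every canonical 9-mer also satisfies
the relaxed pattern, so the three classes partition a cohort cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .genomic import ClonedSite, DNA_ALPHABET

PATTERN_LENGTH = 9


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate DNA pattern over {A,C,G,T,N}; N matches any single base."""

    name: str
    consensus: str

    def __post_init__(self):
        if set(self.consensus) - DNA_ALPHABET:
            raise ValueError(f"pattern {self.name}: invalid consensus")

    def __len__(self) -> int:
        return len(self.consensus)

    def matches(self, window: str) -> bool:
        """True if `window` (same length) matches; subject N never matches."""
        if len(window) != len(self.consensus):
            return False
        for p, c in zip(self.consensus, window):
            if p == "N":
                if c not in "ACGT":
                    return False
            elif c != p:
                return False
        return True


CANONICAL = MotifPattern("canonical", "TTCNNNGAA")
GENERAL = MotifPattern("general", "TTNNNNNAA")


@dataclass(frozen=True)
class MotifMatch:
    site_id: str
    offset: int
    matched: str
    match_class: str  # "canonical" or "general"


@dataclass(frozen=True)
class SiteMotifClass:
    """Exclusive motif category of one site, with the underlying hit counts.

    ``n_general_total`` counts all relaxed-pattern hits including canonical
    ones (canonical is a subset of the relaxed pattern).
    """

    site_id: str
    n_canonical: int
    n_general_total: int

    @property
    def site_class(self) -> str:
        if self.n_canonical >= 1:
            return "canonical"
        if self.n_general_total >= 1:
            return "general_only"
        return "none"


def scan_pattern(seq: str, pattern: MotifPattern, site_id: str = "") -> list[MotifMatch]:
    """All (overlapping) pattern matches in `seq`, sorted by offset."""
    seq = seq.upper()
    k = len(pattern)
    matches = []
    for offset in range(len(seq) - k + 1):
        window = seq[offset : offset + k]
        if pattern.matches(window):
            matches.append(
                MotifMatch(
                    site_id=site_id,
                    offset=offset,
                    matched=window,
                    match_class=pattern.name,
                )
            )
    return matches


def classify_site(seq: str, site_id: str = "") -> SiteMotifClass:
    """Count canonical and relaxed GAS hits and classify the site."""
    n_canonical = len(scan_pattern(seq, CANONICAL, site_id))
    n_general = len(scan_pattern(seq, GENERAL, site_id))
    return SiteMotifClass(
        site_id=site_id, n_canonical=n_canonical, n_general_total=n_general
    )


def classify_cohort(sites: Sequence[ClonedSite]) -> list[SiteMotifClass]:
    """Classify every site; sites without a sequence are an error."""
    out = []
    for s in sites:
        if s.sequence is None:
            raise ValueError(f"site {s.site_id}: no sequence available for scanning")
        out.append(classify_site(s.sequence, s.site_id))
    return out


def scan_cohort(sites: Sequence[ClonedSite]) -> list[MotifMatch]:
    """All canonical and relaxed matches across a cohort (canonical hits are
    reported once, under their canonical label)."""
    matches: list[MotifMatch] = []
    for s in sites:
        if s.sequence is None:
            raise ValueError(f"site {s.site_id}: no sequence available for scanning")
        canonical = scan_pattern(s.sequence, CANONICAL, s.site_id)
        canonical_offsets = {m.offset for m in canonical}
        matches.extend(canonical)
        matches.extend(
            m
            for m in scan_pattern(s.sequence, GENERAL, s.site_id)
            if m.offset not in canonical_offsets
        )
    return matches


def matches_table(matches: Iterable[MotifMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.site_id, m.offset, m.matched, m.match_class) for m in matches],
        columns=["site_id", "offset", "matched", "match_class"],
    )


def site_class_table(classes: Iterable[SiteMotifClass]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.site_id, c.n_canonical, c.n_general_total, c.site_class)
            for c in classes
        ],
        columns=["site_id", "n_canonical", "n_general_total", "site_class"],
    )
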