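"""Consensus motif scanning for HRE, HAS and E-box in promoter windows.

HRE is the 5-mer consensus 5'-RCGTG-3' (R = A|G) bound by HIF; HAS (the
hypoxia ancillary sequence) is 5'-CA(G|C)(A|G)(T|G|C)-3'. An RCGTG
occurrence immediately preceded by C forms the E-box context C.RCGTG
(canonically CACGTG), a bHLH site that HIF rarely binds; such hits are
reclassified EBOX and excluded from the HRE set. An HRE is considered a
candidate functional HIF binding site when a HAS lies downstream within a
constrained gap, 7-15 nt by default.

Only the gene-sense strand of each window is scanned; positions holding
non-ACGT letters never match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product

from .promoter_extract import PromoterWindow, axis_index

HRE_5MERS = frozenset(r + "CGTG" for r in "AG")
HAS_5MERS = frozenset(
    "CA" + a + b + c for (a, b, c) in product("GC", "AG", "TGC")
)

_PATTERNS = {
    "hre": re.compile(r"(?=([AG]CGTG))"),
    "has": re.compile(r"(?=(CA[GC][AG][TGC]))"),
}

MOTIF_LEN = 5


@dataclass
class MotifHit:
    """One located motif occurrence inside a promoter window.

    ``rel_start``/``rel_end`` are the relative positions of the 5' and 3'
    bases in gene sense; ``genomic_start <= genomic_end`` always (GFF3
    convention). ``region`` is the promoter-region label once assigned.
    """

    gene_id: str
    kind: str  # HRE | EBOX | HAS
    rel_start: int
    rel_end: int
    genomic_start: int
    genomic_end: int
    matched_seq: str
    chrom: str = ""
    strand: str = "+"
    context_6mer: str | None = None
    region: str | None = None


@dataclass(frozen=True)
class LinkSpec:
    """Gap constraint linking an HRE to a downstream HAS.

    The gap counts nucleotides strictly between the HRE 3' end and the
    HAS 5' start.
    """

    min_gap: int = 7
    max_gap: int = 15

    def __post_init__(self) -> None:
        if not 0 <= self.min_gap <= self.max_gap:
            raise ValueError(f"need 0 <= min_gap <= max_gap, got {self}")


@dataclass(frozen=True)
class HreHasPair:
    hre: MotifHit
    has: MotifHit
    gap: int


@dataclass(frozen=True)
class RegionScheme:
    """Promoter-region boundaries on the no-zero relative axis.

    Defaults partition the standard -4,900..+100 window into core
    (-900..+100], proximal (-2900..-900] and distal [-4900..-2900]:
    lower bounds are exclusive except the distal floor, so position -900
    is proximal and -2900 is distal. On the no-zero axis the realized
    sizes are 999 / 2,000 / 2,001 nt (nominally 1,000 / 2,000 / 2,000).
    """

    core_floor: int = -900      # exclusive
    proximal_floor: int = -2900  # exclusive
    distal_floor: int = -4900    # inclusive
    ceiling: int = 100           # inclusive

    def assign(self, r: int) -> str:
        if r == 0:
            raise ValueError("relative position 0 does not exist")
        if r > self.ceiling or r < self.distal_floor:
            raise ValueError(f"relative position {r} outside all promoter regions")
        if r > self.core_floor:
            return "CORE"
        if r > self.proximal_floor:
            return "PROXIMAL"
        return "DISTAL"

    def sizes(self, rel_start: int = -4900, rel_end: int = 100) -> dict[str, int]:
        """Realized region sizes over a window, by direct enumeration."""
        from .promoter_extract import rel_range

        counts = {"CORE": 0, "PROXIMAL": 0, "DISTAL": 0}
        for r in rel_range(rel_start, rel_end):
            counts[self.assign(r)] += 1
        return counts


def _hit_from_offset(window: PromoterWindow, offset: int, kind: str) -> MotifHit:
    rel_start = window.offset_to_rel(offset)
    rel_end = window.offset_to_rel(offset + MOTIF_LEN - 1)
    g5 = window.rel_to_genomic(rel_start)
    g3 = window.rel_to_genomic(rel_end)
    return MotifHit(
        gene_id=window.gene_id,
        kind=kind,
        rel_start=rel_start,
        rel_end=rel_end,
        genomic_start=min(g5, g3),
        genomic_end=max(g5, g3),
        matched_seq=window.sequence[offset : offset + MOTIF_LEN],
        chrom=window.chrom,
        strand=window.strand,
    )


def scan_motif(window: PromoterWindow, pattern: str) -> list[MotifHit]:
    """All (possibly overlapping) occurrences of ``pattern`` in a window.

    ``pattern`` is ``"hre"`` or ``"has"``. Hits are returned 5'->3'.
    """
    if pattern not in _PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; expected 'hre' or 'has'")
    kind = "HRE" if pattern == "hre" else "HAS"
    seq = window.sequence
    return [
        _hit_from_offset(window, m.start(), kind)
        for m in _PATTERNS[pattern].finditer(seq)
    ]


def classify_ebox(hits: list[MotifHit], window: PromoterWindow) -> tuple[list[MotifHit], list[MotifHit]]:
    """Partition RCGTG hits into true HRE and E-box (C-preceded) hits.

    A hit at the window's first position has no context base and stays
    HRE. Returns ``(hre_hits, ebox_hits)``; the sets are disjoint by
    construction and their union is the input.
    """
    hre: list[MotifHit] = []
    ebox: list[MotifHit] = []
    for hit in hits:
        off = window.rel_to_offset(hit.rel_start)
        if off > 0 and window.sequence[off - 1] == "C":
            hit.kind = "EBOX"
            hit.context_6mer = window.sequence[off - 1 : off + MOTIF_LEN]
            ebox.append(hit)
        else:
            hre.append(hit)
    return hre, ebox


def gap_between(hre: MotifHit, has: MotifHit) -> int:
    """Nucleotides strictly between an HRE 3' end and a HAS 5' start."""
    return axis_index(has.rel_start) - axis_index(hre.rel_end) - 1


def link_has(
    hre_hits: list[MotifHit], has_hits: list[MotifHit], spec: LinkSpec = LinkSpec()
) -> list[HreHasPair]:
    """Every HRE-HAS combination whose downstream gap satisfies ``spec``.

    One HRE may pair with several HAS and vice versa. Pairs are sorted by
    HRE position, then gap.
    """
    pairs = [
        HreHasPair(hre, has, gap)
        for hre in hre_hits
        for has in has_hits
        if spec.min_gap <= (gap := gap_between(hre, has)) <= spec.max_gap
    ]
    pairs.sort(key=lambda p: (axis_index(p.hre.rel_start), p.gap))
    return pairs


def assign_region(hit: MotifHit, scheme: RegionScheme = RegionScheme()) -> str:
    """Label a hit by the promoter region containing its 5' base."""
    hit.region = scheme.assign(hit.rel_start)
    return hit.region


def scan_window(
    window: PromoterWindow,
    link_spec: LinkSpec = LinkSpec(),
    scheme: RegionScheme = RegionScheme(),
) -> tuple[list[MotifHit], list[MotifHit], list[MotifHit], list[HreHasPair]]:
    """Full per-window scan: (hre, ebox, has, linked pairs), regions set.

    Linked pairs are built from the non-E-box HRE hits only; an RCGTG in
    E-box context is not counted as a candidate HIF site.
    """
    raw = scan_motif(window, "hre")
    hre, ebox = classify_ebox(raw, window)
    has = scan_motif(window, "has")
    for hit in hre + ebox + has:
        assign_region(hit, scheme)
    pairs = link_has(hre, has, link_spec)
    return hre, ebox, has, pairs
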