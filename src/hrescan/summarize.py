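"""Genome-wide accounting of motif hits.

Per-gene summaries, four-set Venn accounting (all genes / HRE / linked
HRE+HAS / E-box), positional bin profiles over the upstream window, and
construction of fixed-length fragments around each HRE for downstream
de novo motif analysis (MEME-ChIP-style input).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from itertools import combinations

from .motif_scan import MotifHit, HreHasPair, MOTIF_LEN
from .promoter_extract import PromoterWindow, WindowSpec, axis_index, rel_range

log = logging.getLogger(__name__)


@dataclass
class GeneMotifSummary:
    """Per-gene motif membership: the Venn accounting unit."""

    gene_id: str
    n_hre: int = 0
    n_ebox: int = 0
    n_has: int = 0
    n_linked_pairs: int = 0
    n_core: int = 0
    n_proximal: int = 0
    n_distal: int = 0

    def check(self) -> None:
        if self.n_hre != self.n_core + self.n_proximal + self.n_distal:
            raise AssertionError(
                f"gene {self.gene_id}: per-region HRE counts do not sum to n_hre"
            )


def summarize_gene(
    gene_id: str,
    hre: list[MotifHit],
    ebox: list[MotifHit],
    has: list[MotifHit],
    pairs: list[HreHasPair],
) -> GeneMotifSummary:
    s = GeneMotifSummary(
        gene_id=gene_id,
        n_hre=len(hre),
        n_ebox=len(ebox),
        n_has=len(has),
        n_linked_pairs=len(pairs),
        n_core=sum(1 for h in hre if h.region == "CORE"),
        n_proximal=sum(1 for h in hre if h.region == "PROXIMAL"),
        n_distal=sum(1 for h in hre if h.region == "DISTAL"),
    )
    s.check()
    return s


def venn_sets(summaries: list[GeneMotifSummary]) -> dict:
    """Four gene-ID sets plus all pairwise/triple intersection counts.

    Sets: ALL (every analyzed gene), HRE (>=1 non-E-box RCGTG),
    HAS_LINKED (>=1 linked HRE-HAS pair), EBOX (>=1 E-box). A gene
    counts as HRE-positive only via a non-C-preceded RCGTG; a linked
    pair requires such an HRE, so HAS_LINKED is a subset of HRE.
    """
    seen: set[str] = set()
    for s in summaries:
        if s.gene_id in seen:
            raise ValueError(f"duplicate gene_id {s.gene_id!r} across summaries")
        seen.add(s.gene_id)

    sets = {
        "ALL": {s.gene_id for s in summaries},
        "HRE": {s.gene_id for s in summaries if s.n_hre >= 1},
        "HAS_LINKED": {s.gene_id for s in summaries if s.n_linked_pairs >= 1},
        "EBOX": {s.gene_id for s in summaries if s.n_ebox >= 1},
    }
    counts = {name: len(ids) for name, ids in sets.items()}
    for a, b in combinations(sets, 2):
        counts[f"{a}&{b}"] = len(sets[a] & sets[b])
    for a, b, c in combinations(sets, 3):
        counts[f"{a}&{b}&{c}"] = len(sets[a] & sets[b] & sets[c])
    return {"sets": sets, "counts": counts}


def write_venn_files(venn: dict, outdir: str | os.PathLike) -> None:
    """One file per set, one gene ID per line (Venn-tool input layout)."""
    os.makedirs(outdir, exist_ok=True)
    for name, ids in venn["sets"].items():
        with open(os.path.join(outdir, f"venn_{name}.txt"), "w") as fh:
            for gid in sorted(ids):
                fh.write(gid + "\n")


@dataclass
class BinProfile:
    bin_width: int
    bins: list[tuple[int, int, int]] = field(default_factory=list)  # (rel_lo, rel_hi, count)

    @property
    def total(self) -> int:
        return sum(c for _, _, c in self.bins)


def bin_profile(
    hits: list[MotifHit],
    window: WindowSpec = WindowSpec(),
    bin_width: int = 500,
) -> BinProfile:
    """Tile the relative axis with consecutive bins and count hit 5' starts.

    Default: 500-nt bins over -4,900..+100; pass ``WindowSpec(-400, 100)``
    with ``bin_width=100`` for the TSS-zoom view. A final short bin is
    kept (and logged) when the width does not divide the window length.
    """
    positions = rel_range(window.rel_start, window.rel_end)
    edges = list(range(0, len(positions), bin_width))
    profile = BinProfile(bin_width=bin_width)
    counts = [0] * len(edges)
    base = axis_index(window.rel_start)
    for hit in hits:
        idx = axis_index(hit.rel_start) - base
        if 0 <= idx < len(positions):
            counts[idx // bin_width] += 1
    for k, lo in enumerate(edges):
        hi = min(lo + bin_width, len(positions)) - 1
        profile.bins.append((positions[lo], positions[hi], counts[k]))
    if len(positions) % bin_width:
        log.info("last bin truncated to %d nt", len(positions) % bin_width)
    return profile


def region_percentages(summaries: list[GeneMotifSummary]) -> tuple[float, float, float]:
    """(core %, proximal %, distal %) of all HRE hits; error on zero hits."""
    core = sum(s.n_core for s in summaries)
    prox = sum(s.n_proximal for s in summaries)
    dist = sum(s.n_distal for s in summaries)
    total = core + prox + dist
    if total == 0:
        raise ValueError("no HRE hits; region percentages undefined")
    return (100.0 * core / total, 100.0 * prox / total, 100.0 * dist / total)


def meme_windows(
    hits: list[MotifHit],
    windows: dict[str, PromoterWindow],
    half_spec: tuple[int, int] = (10, 30),
) -> tuple[list[tuple[str, str]], int]:
    """Fixed-length fragments around each HRE for de novo motif analysis.

    ``half_spec=(u, d)`` takes u positions up to and including the HRE 3'
    end and d positions after it (default 10+30 = 40 nt). Fragments that
    would run past the realized window are dropped and counted. Returns
    ``(records, n_dropped)`` with records as (name, sequence).
    """
    up, down = half_spec
    records: list[tuple[str, str]] = []
    n_dropped = 0
    for i, hit in enumerate(hits):
        win = windows[hit.gene_id]
        end_off = win.rel_to_offset(hit.rel_end)
        lo = end_off - (up - 1)
        hi = end_off + down  # inclusive
        if lo < 0 or hi >= len(win.sequence):
            n_dropped += 1
            continue
        name = f"{hit.gene_id}|{hit.rel_start}..{hit.rel_end}|{hit.matched_seq}"
        records.append((name, win.sequence[lo : hi + 1]))
    if n_dropped:
        log.info("dropped %d fragments running past realized windows", n_dropped)
    return records, n_dropped


def write_meme_fasta(records: list[tuple[str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
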