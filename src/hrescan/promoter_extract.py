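"""Strand-aware extraction of upstream promoter windows.

The relative coordinate axis has no position 0: position +1 is the
transcription start site (the annotated gene boundary, strand-aware) and
-1 is the base immediately 5' of it, so the default window -4,900..+100
holds exactly 5,000 nt. Windows are returned 5'->3' in gene sense, i.e.
reverse-complemented for minus-strand genes, and each window carries a
bijective map between relative and genomic coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

from .annotation_io import GeneRecord, GenomeStore

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)
_IUPAC = set("ACGTRYSWKMBDHVNacgtryswkmbdhvn")


def revcomp(seq: str) -> str:
    """Reverse complement with the full IUPAC complement table."""
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def axis_index(r: int) -> int:
    """Collapse the no-zero relative axis onto contiguous integers.

    -1 maps next to +1, so distances computed on axis indices are
    nucleotide counts.
    """
    if r == 0:
        raise ValueError("relative position 0 does not exist on the axis")
    return r if r < 0 else r - 1


def rel_range(rel_start: int, rel_end: int) -> list[int]:
    """All relative positions from rel_start to rel_end, skipping 0."""
    return [r for r in range(rel_start, rel_end + 1) if r != 0]


def span_length(rel_start: int, rel_end: int) -> int:
    """Number of nucleotides between two relative positions, inclusive."""
    return axis_index(rel_end) - axis_index(rel_start) + 1


@dataclass(frozen=True)
class WindowSpec:
    """Upstream window bounds on the no-zero relative axis."""

    rel_start: int = -4900
    rel_end: int = 100

    def __post_init__(self) -> None:
        if self.rel_start == 0 or self.rel_end == 0:
            raise ValueError("window bounds cannot be 0 (no-zero axis)")
        if axis_index(self.rel_start) > axis_index(self.rel_end):
            raise ValueError("rel_start must not lie 3' of rel_end")

    @property
    def length(self) -> int:
        return span_length(self.rel_start, self.rel_end)


def rel_to_genomic(gene: GeneRecord, r: int) -> int:
    """Genomic position of relative position ``r`` for a placed gene.

    TSS (+1) is gene.start on the plus strand and gene.end on the minus
    strand; negative positions run upstream in gene sense.
    """
    if r == 0:
        raise ValueError("relative position 0 does not exist on the axis")
    if gene.strand == "+":
        return gene.start + (r - 1 if r > 0 else r)
    return gene.end - (r - 1 if r > 0 else r)


def upstream_span(gene: GeneRecord, window: WindowSpec) -> tuple[int, int]:
    """Genomic (min, max) 1-based inclusive span of the unclipped window."""
    a = rel_to_genomic(gene, window.rel_start)
    b = rel_to_genomic(gene, window.rel_end)
    return (a, b) if a <= b else (b, a)


@dataclass
class PromoterWindow:
    """A strand-oriented upstream sequence with its coordinate map.

    ``sequence`` reads 5'->3' in transcription sense. ``rel_axis_bounds``
    are the realized (possibly clipped) relative bounds; ``genomic_span``
    is the 1-based inclusive genomic interval covered.
    """

    gene_id: str
    chrom: str
    strand: str
    sequence: str
    rel_axis_bounds: tuple[int, int]
    genomic_span: tuple[int, int]
    truncated_5p: bool = False
    truncated_3p: bool = False
    _rel_positions: list[int] = field(default_factory=list, repr=False)

    @property
    def rel_positions(self) -> list[int]:
        if not self._rel_positions:
            self._rel_positions = rel_range(*self.rel_axis_bounds)
        return self._rel_positions

    def offset_to_rel(self, i: int) -> int:
        """Relative position of 0-based string offset ``i``."""
        return self.rel_positions[i]

    def rel_to_offset(self, r: int) -> int:
        lo = axis_index(self.rel_axis_bounds[0])
        i = axis_index(r) - lo
        if not 0 <= i < len(self.sequence):
            raise ValueError(f"relative position {r} outside realized window")
        return i

    def rel_to_genomic(self, r: int) -> int:
        self.rel_to_offset(r)  # bounds check
        if self.strand == "+":
            return self.genomic_span[0] + (axis_index(r) - axis_index(self.rel_axis_bounds[0]))
        return self.genomic_span[1] - (axis_index(r) - axis_index(self.rel_axis_bounds[0]))

    def genomic_to_rel(self, g: int) -> int:
        lo_idx = axis_index(self.rel_axis_bounds[0])
        if self.strand == "+":
            idx = lo_idx + (g - self.genomic_span[0])
        else:
            idx = lo_idx + (self.genomic_span[1] - g)
        r = idx if idx < 0 else idx + 1
        self.rel_to_offset(r)  # bounds check
        return r

    def __len__(self) -> int:
        return len(self.sequence)


def extract_upstream(
    genome: GenomeStore, gene: GeneRecord, window: WindowSpec = WindowSpec()
) -> PromoterWindow:
    """Extract the strand-aware upstream window of one placed gene.

    Windows running past a chromosome edge are clipped and flagged
    (``truncated_5p``/``truncated_3p``), never padded.
    """
    if gene.unplaced:
        raise ValueError(f"gene {gene.gene_id} is unplaced; no window can be extracted")
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom!r} of gene {gene.gene_id} not in genome")

    n = genome.length(gene.chrom)
    g_lo = rel_to_genomic(gene, window.rel_start)
    g_hi = rel_to_genomic(gene, window.rel_end)
    gmin, gmax = min(g_lo, g_hi), max(g_lo, g_hi)

    # clip to [1, n]; the mapping is monotone so the realized relative
    # range stays contiguous
    cmin, cmax = max(gmin, 1), min(gmax, n)
    if cmin > cmax:
        raise ValueError(
            f"window of gene {gene.gene_id} lies entirely off chromosome {gene.chrom}"
        )
    if gene.strand == "+":
        lost_5p, lost_3p = cmin - gmin, gmax - cmax
    else:
        lost_5p, lost_3p = gmax - cmax, cmin - gmin

    lo_idx = axis_index(window.rel_start) + lost_5p
    hi_idx = axis_index(window.rel_end) - lost_3p
    rel_lo = lo_idx if lo_idx < 0 else lo_idx + 1
    rel_hi = hi_idx if hi_idx < 0 else hi_idx + 1

    raw = genome.fetch(gene.chrom, cmin, cmax)
    seq = raw if gene.strand == "+" else revcomp(raw)

    return PromoterWindow(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        sequence=seq,
        rel_axis_bounds=(rel_lo, rel_hi),
        genomic_span=(cmin, cmax),
        truncated_5p=lost_5p > 0,
        truncated_3p=lost_3p > 0,
    )


def fasta_header(win: PromoterWindow) -> str:
    lo, hi = win.rel_axis_bounds
    g0, g1 = win.genomic_span
    return f"{win.gene_id}|{win.chrom}|{win.strand}|{g0}..{g1}|{lo}..{hi}"


def write_promoter_fasta(windows: Iterable[PromoterWindow], path: str | os.PathLike) -> None:
    """One record per gene; header encodes placement and realized bounds."""
    with open(path, "w") as fh:
        for win in windows:
            fh.write(f">{fasta_header(win)}\n")
            for i in range(0, len(win.sequence), 80):
                fh.write(win.sequence[i : i + 80] + "\n")
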