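"""End-to-end orchestration: extract -> scan -> classify -> link -> label.

Also owns the tabular hit report format shared by the CLI subcommands.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from .annotation_io import GeneRecord, GenomeStore
from .motif_scan import HreHasPair, LinkSpec, MotifHit, RegionScheme, scan_window
from .promoter_extract import PromoterWindow, WindowSpec, extract_upstream
from .summarize import GeneMotifSummary, summarize_gene

log = logging.getLogger(__name__)

HITS_COLUMNS = [
    "gene_id", "kind", "matched_seq", "context_6mer", "rel_start", "rel_end",
    "genomic_start", "genomic_end", "chrom", "strand", "region",
    "linked_has_rel_start", "gap",
]


@dataclass
class ScanResult:
    windows: dict[str, PromoterWindow] = field(default_factory=dict)
    hre: list[MotifHit] = field(default_factory=list)
    ebox: list[MotifHit] = field(default_factory=list)
    has: list[MotifHit] = field(default_factory=list)
    pairs: list[HreHasPair] = field(default_factory=list)
    summaries: list[GeneMotifSummary] = field(default_factory=list)

    @property
    def all_hits(self) -> list[MotifHit]:
        return self.hre + self.ebox + self.has


def scan_genes(
    genome: GenomeStore,
    genes: list[GeneRecord],
    window: WindowSpec = WindowSpec(),
    link_spec: LinkSpec = LinkSpec(),
    scheme: RegionScheme = RegionScheme(),
) -> ScanResult:
    """Run the full promoter scan over a gene table."""
    result = ScanResult()
    for gene in genes:
        win = extract_upstream(genome, gene, window)
        hre, ebox, has, pairs = scan_window(win, link_spec, scheme)
        result.windows[gene.gene_id] = win
        result.hre.extend(hre)
        result.ebox.extend(ebox)
        result.has.extend(has)
        result.pairs.extend(pairs)
        result.summaries.append(summarize_gene(gene.gene_id, hre, ebox, has, pairs))
    log.info(
        "scanned %d genes: %d HRE, %d E-box, %d HAS, %d linked pairs",
        len(genes), len(result.hre), len(result.ebox), len(result.has), len(result.pairs),
    )
    return result


def hits_frame(result: ScanResult) -> pd.DataFrame:
    """Flat hit table; linked HAS columns are filled on HRE rows."""
    linked: dict[int, tuple[int, int]] = {}
    for pair in result.pairs:
        key = id(pair.hre)
        # keep the smallest-gap partner on the HRE row; all pairs stay
        # available through pairs_frame
        if key not in linked or pair.gap < linked[key][1]:
            linked[key] = (pair.has.rel_start, pair.gap)
    rows = []
    for hit in result.all_hits:
        has_rel, gap = linked.get(id(hit), (None, None))
        rows.append({
            "gene_id": hit.gene_id,
            "kind": hit.kind,
            "matched_seq": hit.matched_seq,
            "context_6mer": hit.context_6mer or "",
            "rel_start": hit.rel_start,
            "rel_end": hit.rel_end,
            "genomic_start": hit.genomic_start,
            "genomic_end": hit.genomic_end,
            "chrom": hit.chrom,
            "strand": hit.strand,
            "region": hit.region or "",
            "linked_has_rel_start": has_rel,
            "gap": gap,
        })
    df = pd.DataFrame(rows, columns=HITS_COLUMNS)
    # nullable ints: unlinked hits stay blank instead of becoming floats
    return df.astype({"linked_has_rel_start": "Int64", "gap": "Int64"})


def pairs_frame(result: ScanResult) -> pd.DataFrame:
    rows = [
        {
            "gene_id": p.hre.gene_id,
            "hre_rel_start": p.hre.rel_start,
            "hre_rel_end": p.hre.rel_end,
            "hre_seq": p.hre.matched_seq,
            "has_rel_start": p.has.rel_start,
            "has_rel_end": p.has.rel_end,
            "has_seq": p.has.matched_seq,
            "gap": p.gap,
            "hre_region": p.hre.region or "",
        }
        for p in result.pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "hre_rel_start", "hre_rel_end", "hre_seq",
            "has_rel_start", "has_rel_end", "has_seq", "gap", "hre_region",
        ],
    )


def summaries_frame(summaries: list[GeneMotifSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "n_hre": s.n_hre,
                "n_ebox": s.n_ebox,
                "n_has": s.n_has,
                "n_linked_pairs": s.n_linked_pairs,
                "n_core": s.n_core,
                "n_proximal": s.n_proximal,
                "n_distal": s.n_distal,
            }
            for s in summaries
        ]
    )


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
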