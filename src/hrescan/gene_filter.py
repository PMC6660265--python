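"""Gene filtration: unplaced, mitochondrial, and housekeeping genes.

Housekeeping genes (HKGs, constitutively expressed and hence
uninformative for inducible-promoter analysis) are removed in two
passes: an exact case-insensitive symbol match against a reference HKG
symbol list, then an mRNA homology screen against reference HKG mRNAs
for genes hiding behind LOC-style placeholder symbols. Rules run in a
fixed order (unplaced -> mitochondrial -> symbol -> homology) and each
gene is charged to the first rule that removes it, so per-rule counts
are disjoint and conserve the input total.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from Bio import SeqIO

from .align import align_local
from .annotation_io import GeneRecord

log = logging.getLogger(__name__)

DEFAULT_MITO_PATTERN = "MT"


@dataclass
class FilterReport:
    n_input: int = 0
    n_unplaced_removed: int = 0
    n_mito_removed: int = 0
    n_hkg_symbol_removed: int = 0
    n_hkg_homology_removed: int = 0
    n_kept: int = 0
    removed_ids: dict[str, list[str]] = field(
        default_factory=lambda: {"unplaced": [], "mito": [], "hkg_symbol": [], "hkg_homology": []}
    )

    def check(self) -> None:
        total_removed = (
            self.n_unplaced_removed
            + self.n_mito_removed
            + self.n_hkg_symbol_removed
            + self.n_hkg_homology_removed
        )
        if self.n_kept + total_removed != self.n_input:
            raise AssertionError("filter report does not conserve gene count")


@dataclass(frozen=True)
class HomologyParams:
    """Thresholds for calling two mRNAs homologous."""

    min_identity_pct: float = 80.0
    min_coverage_frac: float = 0.5
    backend: str = "builtin"  # builtin | table

    def __post_init__(self) -> None:
        if not 0 < self.min_identity_pct <= 100:
            raise ValueError("min_identity_pct must be in (0, 100]")
        if not 0 < self.min_coverage_frac <= 1:
            raise ValueError("min_coverage_frac must be in (0, 1]")
        if self.backend not in {"builtin", "table"}:
            raise ValueError(f"unknown homology backend {self.backend!r}")


def is_mitochondrial_accession(
    chrom: str,
    pattern: str = DEFAULT_MITO_PATTERN,
    extra_accessions: frozenset[str] | set[str] = frozenset(),
) -> bool:
    """Default rule: accession contains the MT token or is listed explicitly."""
    return bool(chrom) and (pattern in chrom or chrom in extra_accessions)


def filter_unplaced_mito(
    genes: list[GeneRecord],
    mito_pattern: str = DEFAULT_MITO_PATTERN,
    mito_accessions: frozenset[str] | set[str] = frozenset(),
) -> tuple[list[GeneRecord], FilterReport]:
    """Drop unplaced genes, then mitochondrial genes; order preserved."""
    report = FilterReport(n_input=len(genes))
    kept: list[GeneRecord] = []
    for gene in genes:
        if gene.unplaced:
            report.n_unplaced_removed += 1
            report.removed_ids["unplaced"].append(gene.gene_id)
        elif gene.is_mitochondrial or is_mitochondrial_accession(
            gene.chrom, mito_pattern, mito_accessions
        ):
            report.n_mito_removed += 1
            report.removed_ids["mito"].append(gene.gene_id)
        else:
            kept.append(gene)
    report.n_kept = len(kept)
    return kept, report


def read_hkg_symbols(path: str | os.PathLike) -> set[str]:
    """Plain-text symbol list, one per line, '#' comments allowed."""
    symbols: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.add(line)
    log.info("loaded %d housekeeping symbols from %s", len(symbols), path)
    return symbols


def filter_hkg_by_symbol(
    genes: list[GeneRecord], hkg_symbols: set[str]
) -> tuple[list[GeneRecord], list[str]]:
    """Remove genes whose symbol matches the HKG list (case-insensitive).

    Placeholder symbols (LOC12345 and friends) only match if literally
    present in the list, which is exactly what exact matching gives.
    """
    if not hkg_symbols:
        raise ValueError("housekeeping symbol set is empty")
    lowered = {s.lower() for s in hkg_symbols}
    kept, removed = [], []
    for gene in genes:
        if gene.symbol.lower() in lowered:
            removed.append(gene.gene_id)
        else:
            kept.append(gene)
    return kept, removed


def read_mrna_gene_map(path: str | os.PathLike) -> dict[str, str]:
    """Two-column TSV (mrna_id, gene_id) with header."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mrna_id", "gene_id"} <= set(df.columns):
        raise ValueError(f"{path}: need columns mrna_id, gene_id")
    return dict(zip(df["mrna_id"], df["gene_id"]))


def _load_fasta(path_or_records):
    if isinstance(path_or_records, (str, os.PathLike)):
        return list(SeqIO.parse(str(path_or_records), "fasta"))
    return list(path_or_records)


def homologous_gene_ids_builtin(
    query_records, hkg_records, mrna_to_gene: dict[str, str], params: HomologyParams
) -> set[str]:
    hits: set[str] = set()
    for q in query_records:
        if q.id not in mrna_to_gene:
            raise ValueError(f"mRNA record {q.id!r} has no gene mapping")
        gid = mrna_to_gene[q.id]
        if gid in hits:
            continue
        qs = str(q.seq)
        for s in hkg_records:
            res = align_local(qs, str(s.seq))
            if (
                res.identity_pct >= params.min_identity_pct
                and res.coverage_frac >= params.min_coverage_frac
            ):
                hits.add(gid)
                break
    return hits


def homologous_gene_ids_table(
    table_path: str | os.PathLike,
    mrna_to_gene: dict[str, str],
    mrna_lengths: dict[str, int],
    params: HomologyParams,
) -> set[str]:
    """Apply the same thresholds to a precomputed 12-column alignment table.

    Standard tabular layout (query, subject, pident, length, mismatch,
    gapopen, qstart, qend, sstart, send, evalue, bitscore); only pident
    and length are consumed; coverage uses the query length as the
    shorter-sequence proxy.
    """
    import pandas as pd

    cols = [
        "query", "subject", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(table_path, sep="\t", names=cols, dtype={"query": str, "subject": str})
    hits: set[str] = set()
    for row in df.itertuples(index=False):
        if row.query not in mrna_to_gene:
            raise ValueError(f"alignment row names unmapped mRNA {row.query!r}")
        qlen = mrna_lengths.get(row.query)
        coverage = row.length / qlen if qlen else 0.0
        if row.pident >= params.min_identity_pct and coverage >= params.min_coverage_frac:
            hits.add(mrna_to_gene[row.query])
    return hits


def filter_hkg_by_homology(
    genes: list[GeneRecord],
    query_mrna,
    hkg_mrna,
    mrna_to_gene: dict[str, str],
    params: HomologyParams = HomologyParams(),
    table_path: str | os.PathLike | None = None,
) -> tuple[list[GeneRecord], list[str]]:
    """Remove genes with an mRNA homologous to any reference HKG mRNA."""
    query_records = _load_fasta(query_mrna)
    if params.backend == "builtin":
        hkg_records = _load_fasta(hkg_mrna)
        if not hkg_records:
            raise ValueError("housekeeping mRNA set is empty")
        flagged = homologous_gene_ids_builtin(query_records, hkg_records, mrna_to_gene, params)
    else:
        if table_path is None:
            raise ValueError("backend='table' requires table_path")
        lengths = {r.id: len(r.seq) for r in query_records}
        flagged = homologous_gene_ids_table(table_path, mrna_to_gene, lengths, params)
    kept, removed = [], []
    for gene in genes:
        if gene.gene_id in flagged:
            removed.append(gene.gene_id)
        else:
            kept.append(gene)
    return kept, removed


def run_filter_chain(
    genes: list[GeneRecord],
    hkg_symbols: set[str] | None = None,
    query_mrna=None,
    hkg_mrna=None,
    mrna_to_gene: dict[str, str] | None = None,
    params: HomologyParams = HomologyParams(),
    mito_pattern: str = DEFAULT_MITO_PATTERN,
    mito_accessions: frozenset[str] | set[str] = frozenset(),
    table_path=None,
) -> tuple[list[GeneRecord], FilterReport]:
    """Full filtration in fixed order; optional stages skip cleanly."""
    kept, report = filter_unplaced_mito(genes, mito_pattern, mito_accessions)
    if hkg_symbols:
        kept, removed = filter_hkg_by_symbol(kept, hkg_symbols)
        report.n_hkg_symbol_removed = len(removed)
        report.removed_ids["hkg_symbol"] = removed
    if query_mrna is not None and (hkg_mrna is not None or table_path is not None):
        kept, removed = filter_hkg_by_homology(
            kept, query_mrna, hkg_mrna, mrna_to_gene or {}, params, table_path
        )
        report.n_hkg_homology_removed = len(removed)
        report.removed_ids["hkg_homology"] = removed
    report.n_kept = len(kept)
    report.check()
    return kept, report
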