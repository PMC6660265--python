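"""Reading genomes and gene annotations; writing GFF3 and tabular reports.

Canonical in-memory containers for the promoter-mining pipeline: a
:class:`GeneRecord` per annotated protein-coding gene and a
:class:`GenomeStore` holding chromosome sequences. All external
coordinates are 1-based inclusive (GFF3 / NCBI convention).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

GFF_SOURCE = "hre-scan"

#: feature types write_gff3 is allowed to emit
_GFF_TYPES = {"gene", "promoter", "HRE", "HAS", "E_box"}


@dataclass
class GeneRecord:
    """One annotated gene with genomic placement and strand.

    ``chrom`` is the chromosome/scaffold accession; an empty string means
    the gene is unplaced in the assembly. ``start``/``end`` are 1-based
    inclusive genomic coordinates with ``start <= end`` regardless of
    strand.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    is_mitochondrial: bool = False
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        # NCBI tables sometimes carry the typographic minus sign
        self.strand = {"−": "-"}.get(self.strand, self.strand)
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.chrom and self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )

    @property
    def unplaced(self) -> bool:
        return self.chrom == ""


class GenomeStore:
    """Mapping from chromosome accession to uppercase sequence.

    Lookups use 1-based inclusive coordinates; out-of-range access is an
    error rather than a silent clip.
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("genome has no sequences")
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "GenomeStore":
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate FASTA record ID {rec.id!r} in {path}")
            seqs[rec.id] = str(rec.seq)
        if not seqs:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self):
        return iter(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the 1-based inclusive slice ``chrom[start..end]``."""
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        n = len(self._seqs[chrom])
        if not (1 <= start <= end <= n):
            raise ValueError(
                f"range {start}..{end} outside [1, {n}] on {chrom}"
            )
        return self._seqs[chrom][start - 1 : end]


_TSV_REQUIRED = ["gene_id", "symbol", "chrom", "strand", "start", "end"]


def read_gene_table(path: str | os.PathLike, format: str = "tsv") -> list[GeneRecord]:
    """Read gene records from a GFF3 file or a tab-separated gene-info table.

    Only ``protein_coding`` genes are returned; skipped features are
    counted in the log. Records come back in file order. Duplicate
    ``gene_id`` values and malformed coordinates raise ``ValueError``.
    """
    if format == "gff3":
        records = _read_gff3_genes(path)
    elif format == "tsv":
        records = _read_tsv_genes(path)
    else:
        raise ValueError(f"unknown gene table format {format!r}")

    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r} in {path}")
        seen.add(rec.gene_id)
    return records


def _read_tsv_genes(path: str | os.PathLike) -> list[GeneRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TSV_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    records: list[GeneRecord] = []
    n_skipped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        biotype = getattr(row, "biotype", "protein_coding") or "protein_coding"
        if biotype != "protein_coding":
            n_skipped += 1
            continue
        try:
            start, end = int(row.start), int(row.end)
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: non-integer coordinate ({exc})") from None
        try:
            rec = GeneRecord(
                gene_id=row.gene_id,
                symbol=row.symbol,
                chrom=row.chrom,
                strand=row.strand,
                start=start,
                end=end,
                is_mitochondrial=_parse_bool(getattr(row, "is_mitochondrial", "")),
                biotype=biotype,
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: {exc}") from None
        records.append(rec)
    if n_skipped:
        log.info("skipped %d non-protein-coding rows in %s", n_skipped, path)
    return records


def _parse_bool(value: str) -> bool:
    return str(value).strip().lower() in {"1", "true", "yes"}


def _read_gff3_genes(path: str | os.PathLike) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[GeneRecord] = []
    n_skipped = 0
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        biotype = (feat.attributes.get("gene_biotype")
                   or feat.attributes.get("biotype")
                   or ["protein_coding"])[0]
        if biotype != "protein_coding":
            n_skipped += 1
            continue
        raw_id = (feat.attributes.get("ID") or [feat.id])[0]
        # tolerate "gene:g1"-style prefixed IDs
        gene_id = raw_id.split(":", 1)[1] if raw_id.startswith("gene:") else raw_id
        symbol = (feat.attributes.get("Name") or feat.attributes.get("gene_name") or [gene_id])[0]
        records.append(
            GeneRecord(
                gene_id=gene_id,
                symbol=symbol,
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
                biotype=biotype,
            )
        )
    if n_skipped:
        log.info("skipped %d non-protein-coding genes in %s", n_skipped, path)
    return records


read_genome = GenomeStore.from_fasta


def _escape_attr(value: str) -> str:
    return (
        str(value)
        .replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(",", "%2C")
    )


def write_gff3(records: Iterable, path: str | os.PathLike) -> None:
    """Write genes, promoter windows, or motif hits as GFF3.

    Every record must carry a genomic placement (chrom + 1-based inclusive
    start/end + strand); GFF3 lines always have start <= end regardless of
    strand. Attribute column carries gene_id, the relative coordinates and
    the promoter-region label where the record has them.
    """
    lines = ["##gff-version 3"]
    for rec in records:
        lines.append("\t".join(_gff_fields(rec)))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _gff_fields(rec) -> list[str]:
    # duck-typed over GeneRecord, PromoterWindow and MotifHit
    attrs: list[tuple[str, str]] = []
    if isinstance(rec, GeneRecord):
        if rec.unplaced:
            raise ValueError(f"gene {rec.gene_id} has no genomic placement")
        ftype, chrom, start, end, strand = "gene", rec.chrom, rec.start, rec.end, rec.strand
        attrs = [("ID", rec.gene_id), ("Name", rec.symbol)]
    elif hasattr(rec, "kind"):  # MotifHit
        if not getattr(rec, "chrom", ""):
            raise ValueError(f"hit for gene {rec.gene_id} has no genomic placement")
        ftype = {"HRE": "HRE", "HAS": "HAS", "EBOX": "E_box"}[rec.kind]
        chrom, start, end, strand = rec.chrom, rec.genomic_start, rec.genomic_end, rec.strand
        attrs = [
            ("gene_id", rec.gene_id),
            ("matched_seq", rec.matched_seq),
            ("rel_start", str(rec.rel_start)),
            ("rel_end", str(rec.rel_end)),
        ]
        if rec.region:
            attrs.append(("region", rec.region))
        if getattr(rec, "context_6mer", None):
            attrs.append(("context", rec.context_6mer))
    elif hasattr(rec, "rel_axis_bounds"):  # PromoterWindow
        chrom, strand = rec.chrom, rec.strand
        start, end = rec.genomic_span
        ftype = "promoter"
        lo, hi = rec.rel_axis_bounds
        attrs = [("gene_id", rec.gene_id), ("rel_start", str(lo)), ("rel_end", str(hi))]
    else:
        raise TypeError(f"cannot express {type(rec).__name__} as GFF3")
    if ftype not in _GFF_TYPES:
        raise ValueError(f"unsupported GFF3 feature type {ftype!r}")
    if start > end:
        raise ValueError(f"GFF3 feature with start {start} > end {end}")
    attr_col = ";".join(f"{k}={_escape_attr(v)}" for k, v in attrs) or "."
    return [chrom, GFF_SOURCE, ftype, str(start), str(end), ".", strand, ".", attr_col]


def gc_percent(seq: str) -> float:
    """GC content of ``seq`` as a percentage of its full length.

    Case-insensitive; IUPAC ambiguity codes count only as themselves, so
    an N contributes to the denominator but never to the GC count.
    """
    if not seq:
        raise ValueError("gc_percent of empty sequence")
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)
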