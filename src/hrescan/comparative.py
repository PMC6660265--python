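"""Cross-species promoter comparison.

Orthologs are mapped by best mRNA identity (placeholder gene symbols of
the LOC/zgc/si kind make symbol matching useless across species, so
symbol equality is deliberately not used). Reported hypoxia-gene tables
from a reference species are re-mined with the identical pipeline, and
conservation of HRE-containing fragments is scored by local alignment
of the hit plus flanking bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import align_local
from .annotation_io import GeneRecord, GenomeStore
from .gene_filter import HomologyParams
from .motif_scan import LinkSpec, MotifHit, RegionScheme
from .pipeline import ScanResult, scan_genes
from .promoter_extract import PromoterWindow, WindowSpec

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologPair:
    query_gene_id: str
    subject_gene_id: str
    identity_pct: float
    coverage_frac: float
    via: tuple[str, str]  # (query mRNA id, subject mRNA id)


@dataclass
class ConservationRecord:
    pair: OrthologPair
    query_hit: MotifHit
    subject_hit: MotifHit | None
    flank_identity_pct: float
    conserved: bool


def map_orthologs(
    query_mrna: list[tuple[str, str]],
    subject_mrna: list[tuple[str, str]],
    query_map: dict[str, str],
    subject_map: dict[str, str],
    params: HomologyParams = HomologyParams(),
    reciprocal: bool = False,
) -> tuple[list[OrthologPair], list[str]]:
    """Best-hit ortholog mapping by mRNA identity.

    For each query gene the best-identity subject gene meeting the
    identity/coverage thresholds wins; ties break by coverage, then
    lexicographic subject gene ID. ``reciprocal=True`` additionally
    requires the query to be the subject's best hit. Returns
    ``(pairs, unmapped_query_gene_ids)``.
    """
    if not query_mrna or not subject_mrna:
        raise ValueError("ortholog mapping needs non-empty mRNA sets on both sides")
    for mid, _ in query_mrna:
        if mid not in query_map:
            raise ValueError(f"query mRNA {mid!r} has no gene mapping")
    for mid, _ in subject_mrna:
        if mid not in subject_map:
            raise ValueError(f"subject mRNA {mid!r} has no gene mapping")

    def best_hits(records, others, rec_map, other_map):
        best: dict[str, OrthologPair] = {}
        for qid, qseq in records:
            qgene = rec_map[qid]
            for sid, sseq in others:
                res = align_local(qseq, sseq)
                if (res.identity_pct < params.min_identity_pct
                        or res.coverage_frac < params.min_coverage_frac):
                    continue
                cand = OrthologPair(
                    qgene, other_map[sid], res.identity_pct, res.coverage_frac, (qid, sid)
                )
                cur = best.get(qgene)
                if cur is None or _better(cand, cur):
                    best[qgene] = cand
        return best

    forward = best_hits(query_mrna, subject_mrna, query_map, subject_map)
    if reciprocal:
        backward = best_hits(subject_mrna, query_mrna, subject_map, query_map)
        forward = {
            g: p for g, p in forward.items()
            if backward.get(p.subject_gene_id, None)
            and backward[p.subject_gene_id].subject_gene_id == g
        }
    all_query_genes = sorted({query_map[mid] for mid, _ in query_mrna})
    unmapped = [g for g in all_query_genes if g not in forward]
    pairs = [forward[g] for g in sorted(forward)]
    return pairs, unmapped


def _better(a: OrthologPair, b: OrthologPair) -> bool:
    if a.identity_pct != b.identity_pct:
        return a.identity_pct > b.identity_pct
    if a.coverage_frac != b.coverage_frac:
        return a.coverage_frac > b.coverage_frac
    return a.subject_gene_id < b.subject_gene_id  # smaller ID wins a full tie


@dataclass
class RemineFlags:
    gene_id: str
    n_hre: int
    n_linked_pairs: int
    no_hre: bool
    hre_outside_core_only: bool
    core_linked_pair: bool


def remine_reported(
    genes: list[GeneRecord],
    genome: GenomeStore,
    window: WindowSpec = WindowSpec(),
    link_spec: LinkSpec = LinkSpec(),
    scheme: RegionScheme = RegionScheme(),
) -> tuple[ScanResult, list[RemineFlags]]:
    """Re-mine a prepared reference gene table with the standard pipeline.

    Flags per gene: no HRE at all (the class of reported hypoxia genes
    whose 5-kb upstream holds no RCGTG), HRE only outside the core
    promoter, and presence of a linked pair anchored in the core.
    """
    result = scan_genes(genome, genes, window, link_spec, scheme)
    flags = []
    for s in result.summaries:
        core_pair = any(
            p.hre.gene_id == s.gene_id and p.hre.region == "CORE" for p in result.pairs
        )
        flags.append(
            RemineFlags(
                gene_id=s.gene_id,
                n_hre=s.n_hre,
                n_linked_pairs=s.n_linked_pairs,
                no_hre=s.n_hre == 0 and s.n_ebox == 0,
                hre_outside_core_only=s.n_hre > 0 and s.n_core == 0,
                core_linked_pair=core_pair,
            )
        )
    return result, flags


def _flank_fragment(window: PromoterWindow, hit: MotifHit, flank_k: int) -> str:
    off5 = window.rel_to_offset(hit.rel_start)
    off3 = window.rel_to_offset(hit.rel_end)
    lo = max(0, off5 - flank_k)
    hi = min(len(window.sequence) - 1, off3 + flank_k)
    return window.sequence[lo : hi + 1]


def conservation_scan(
    pair: OrthologPair,
    query_hits: list[MotifHit],
    subject_hits: list[MotifHit],
    query_window: PromoterWindow,
    subject_window: PromoterWindow,
    flank_k: int = 10,
    threshold: float = 80.0,
) -> list[ConservationRecord]:
    """Score conservation of each query HRE against subject HRE fragments.

    Each query hit's +/-flank_k fragment is locally aligned against every
    subject hit's fragment; the best flank identity decides conservation
    at ``threshold``. Subjects without any HRE yield an unconserved
    record with no subject hit.
    """
    records: list[ConservationRecord] = []
    for qh in query_hits:
        qfrag = _flank_fragment(query_window, qh, flank_k)
        best_identity = 0.0
        best_hit: MotifHit | None = None
        for sh in subject_hits:
            sfrag = _flank_fragment(subject_window, sh, flank_k)
            res = align_local(qfrag, sfrag)
            if res.identity_pct > best_identity:
                best_identity, best_hit = res.identity_pct, sh
        conserved = best_hit is not None and best_identity >= threshold
        records.append(
            ConservationRecord(
                pair=pair,
                query_hit=qh,
                subject_hit=best_hit,
                flank_identity_pct=best_identity,
                conserved=conserved,
            )
        )
    return records
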