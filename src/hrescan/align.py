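"""Local pairwise alignment used for homology screens.

Thin wrapper around Biopython's PairwiseAligner with a fixed scheme
(match +1, mismatch -1, gap -2, local mode). Identity is matches over
alignment columns; coverage is aligned columns over the shorter
sequence. Decisions downstream are thresholded, so the exact scoring
scheme is not load-bearing.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align


@dataclass(frozen=True)
class AlignmentResult:
    identity_pct: float
    coverage_frac: float
    n_columns: int
    n_matches: int


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -2
    return al


def align_local(query: str, subject: str) -> AlignmentResult:
    """Best local alignment of two nucleotide sequences."""
    if not query or not subject:
        raise ValueError("cannot align an empty sequence")
    al = _aligner()
    aln = al.align(query.upper(), subject.upper())[0]
    counts = aln.counts()  # gaps, identities, mismatches
    n_cols = counts.gaps + counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / n_cols if n_cols else 0.0
    coverage = n_cols / min(len(query), len(subject))
    return AlignmentResult(
        identity_pct=identity,
        coverage_frac=coverage,
        n_columns=n_cols,
        n_matches=counts.identities,
    )
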