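import pytest

from hrescan.promoter_extract import PromoterWindow, axis_index


def make_window(seq: str, rel_start: int = -100, gene_id: str = "gX",
                strand: str = "+", chrom: str = "c1", g_start: int = 1000) -> PromoterWindow:
    """A free-standing promoter window around a literal sequence."""
    lo = axis_index(rel_start)
    hi = lo + len(seq) - 1
    rel_hi = hi if hi < 0 else hi + 1
    return PromoterWindow(
        gene_id=gene_id, chrom=chrom, strand=strand, sequence=seq,
        rel_axis_bounds=(rel_start, rel_hi),
        genomic_span=(g_start, g_start + len(seq) - 1),
    )


@pytest.fixture
def planted_dataset():
    """Small deterministic planted-motif genome shared across tests."""
    from hrescan.synth import default_fixture

    return default_fixture(seed=11, n_genes=30)
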