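import random

import pytest
from hypothesis import given, settings, strategies as st

from hrescan.align import align_local
from hrescan.annotation_io import GeneRecord
from hrescan.gene_filter import (
    HomologyParams,
    filter_hkg_by_homology,
    filter_hkg_by_symbol,
    filter_unplaced_mito,
    read_hkg_symbols,
    run_filter_chain,
)


def gene(gid, chrom="c1", symbol=None, strand="+"):
    return GeneRecord(gid, symbol or gid, chrom, strand, 10, 20)


class Rec:
    """Minimal stand-in for a FASTA record."""

    def __init__(self, rid, seq):
        self.id, self.seq = rid, seq


class TestUnplacedMito:
    def test_unplaced_removed_placed_kept(self):
        kept, rep = filter_unplaced_mito([gene("g1"), gene("g2", chrom="")])
        assert [g.gene_id for g in kept] == ["g1"]
        assert rep.n_unplaced_removed == 1 and rep.n_kept == 1

    def test_mt_accession_removed_by_default_pattern(self):
        kept, rep = filter_unplaced_mito([gene("g1", chrom="NC_MT01")])
        assert kept == [] and rep.n_mito_removed == 1

    def test_empty_input_all_zero(self):
        kept, rep = filter_unplaced_mito([])
        assert kept == [] and rep.n_input == 0 and rep.n_kept == 0

    def test_explicit_accession_set(self):
        kept, rep = filter_unplaced_mito(
            [gene("g1", chrom="NC_009144")], mito_accessions={"NC_009144"}
        )
        assert kept == []


class TestSymbolFilter:
    def test_case_insensitive_exact_match(self):
        genes = [gene("g1", symbol="actb1"), gene("g2", symbol="LOC123")]
        kept, removed = filter_hkg_by_symbol(genes, {"ACTB1"})
        assert removed == ["g1"]
        assert [g.gene_id for g in kept] == ["g2"]

    def test_disjoint_symbols_remove_nothing(self):
        genes = [gene("g1", symbol="vegfaa")]
        kept, removed = filter_hkg_by_symbol(genes, {"ACTB1", "GAPDH"})
        assert removed == [] and len(kept) == 1

    def test_loc_placeholder_matches_only_if_listed(self):
        genes = [gene("g1", symbol="LOC123")]
        _, removed = filter_hkg_by_symbol(genes, {"LOC123"})
        assert removed == ["g1"]

    def test_loader_reports_symbol_count(self, tmp_path):
        # emulation of a reference housekeeping list: loader must report
        # exactly the number of distinct symbols in the file
        lines = [f"HKG{i}" for i in range(120)] + ["# comment", "", "HKG0  # dup"]
        path = tmp_path / "hkg.txt"
        path.write_text("\n".join(lines))
        assert len(read_hkg_symbols(path)) == 120


class TestHomologyFilter:
    params = HomologyParams()

    def test_identical_mrna_removes_gene(self):
        seq = "ACGT" * 60
        genes = [gene("g1")]
        kept, removed = filter_hkg_by_homology(
            genes, [Rec("m1", seq)], [Rec("hk1", seq)], {"m1": "g1"}, self.params
        )
        assert removed == ["g1"] and kept == []

    def test_dissimilar_mrna_keeps_gene(self):
        rng = random.Random(0)
        a = "".join(rng.choice("ACGT") for _ in range(240))
        b = "".join(rng.choice("ACGT") for _ in range(240))
        kept, removed = filter_hkg_by_homology(
            [gene("g1")], [Rec("m1", a)], [Rec("hk1", b)], {"m1": "g1"}, self.params
        )
        assert removed == [] and len(kept) == 1

    def test_seventy_substitutions_in_300nt_stays(self):
        """230/300 identical positions = 76.7% identity: below the 80%
        threshold, so the gene survives, and the aligner's identity must
        equal the hand count when the substitutions avoid the ends."""
        rng = random.Random(1)
        subject = "".join(rng.choice("ACGT") for _ in range(300))
        positions = rng.sample(range(10, 290), 70)
        q = list(subject)
        for p in positions:
            q[p] = rng.choice([b for b in "ACGT" if b != q[p]])
        query = "".join(q)
        res = align_local(query, subject)
        assert res.identity_pct == pytest.approx(100 * 230 / 300, abs=1.0)
        kept, removed = filter_hkg_by_homology(
            [gene("g1")], [Rec("m1", query)], [Rec("hk1", subject)], {"m1": "g1"},
            self.params,
        )
        assert removed == []

    def test_unmapped_mrna_raises_naming_record(self):
        with pytest.raises(ValueError, match="m9"):
            filter_hkg_by_homology(
                [gene("g1")], [Rec("m9", "ACGT" * 30)], [Rec("hk1", "ACGT" * 30)],
                {}, self.params,
            )

    def test_table_backend_agrees_with_builtin(self, tmp_path):
        rng = random.Random(2)
        subject = "".join(rng.choice("ACGT") for _ in range(200))
        near = list(subject)
        for p in rng.sample(range(10, 190), 10):  # 95% identity -> removed
            near[p] = rng.choice([b for b in "ACGT" if b != near[p]])
        far = "".join(rng.choice("ACGT") for _ in range(200))  # unrelated -> kept
        queries = [Rec("m1", "".join(near)), Rec("m2", far)]
        mapping = {"m1": "g1", "m2": "g2"}
        genes_list = [gene("g1"), gene("g2")]

        kept_b, removed_b = filter_hkg_by_homology(
            genes_list, queries, [Rec("hk1", subject)], mapping, self.params
        )

        # build the tabular backend input from the builtin aligner's output
        rows = []
        for rec in queries:
            res = align_local(rec.seq, subject)
            rows.append(
                f"{rec.id}\thk1\t{res.identity_pct:.2f}\t{res.n_columns}"
                f"\t0\t0\t1\t200\t1\t200\t0.0\t100"
            )
        table = tmp_path / "aln.tsv"
        table.write_text("\n".join(rows) + "\n")
        kept_t, removed_t = filter_hkg_by_homology(
            genes_list, queries, None, mapping,
            HomologyParams(backend="table"), table_path=str(table),
        )
        assert removed_b == removed_t == ["g1"]
        assert [g.gene_id for g in kept_b] == [g.gene_id for g in kept_t]


class TestFilterChain:
    def make_input(self):
        return [
            gene("g1"), gene("g2", chrom=""), gene("g3", chrom="NC_MT01"),
            gene("g4", symbol="actb1"), gene("g5"),
        ]

    def test_conservation_and_rule_order(self):
        kept, rep = run_filter_chain(self.make_input(), hkg_symbols={"ACTB1"})
        rep.check()
        assert [g.gene_id for g in kept] == ["g1", "g5"]
        assert (rep.n_unplaced_removed, rep.n_mito_removed, rep.n_hkg_symbol_removed) == (1, 1, 1)

    def test_idempotent(self):
        kept1, _ = run_filter_chain(self.make_input(), hkg_symbols={"ACTB1"})
        kept2, rep2 = run_filter_chain(kept1, hkg_symbols={"ACTB1"})
        assert [g.gene_id for g in kept1] == [g.gene_id for g in kept2]
        assert rep2.n_kept == rep2.n_input

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["c1", "", "NC_MT01"]),
                st.sampled_from(["actb1", "gapdh", "vegfaa", "LOC9"]),
            ),
            max_size=30,
        )
    )
    @settings(max_examples=50, derandomize=True)
    def test_report_conserves_counts_on_random_tables(self, rows):
        genes_list = [
            gene(f"g{i}", chrom=chrom, symbol=sym) for i, (chrom, sym) in enumerate(rows)
        ]
        kept, rep = run_filter_chain(genes_list, hkg_symbols={"ACTB1", "GAPDH"})
        rep.check()
        removed_sets = [set(ids) for ids in rep.removed_ids.values()]
        for i, a in enumerate(removed_sets):
            for b in removed_sets[i + 1:]:
                assert a.isdisjoint(b)
        assert rep.n_kept == len(kept)
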