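"""Scanner correctness against enumeration oracles and the linkage rules."""

import random
from itertools import product

import pytest
from hypothesis import given, settings, strategies as st

from hrescan.motif_scan import (
    HAS_5MERS,
    HRE_5MERS,
    LinkSpec,
    MotifHit,
    RegionScheme,
    classify_ebox,
    gap_between,
    link_has,
    scan_motif,
    scan_window,
)

from conftest import make_window


def brute_force_offsets(seq: str, mers: frozenset[str]) -> list[int]:
    """Independent oracle: test every 5-window against the enumerated set."""
    return [i for i in range(len(seq) - 4) if seq[i : i + 5] in mers]


class TestConsensusEnumeration:
    def test_hre_matches_exactly_two_5mers(self):
        matched = {
            "".join(p) for p in product("ACGT", repeat=5)
            if "".join(p)[0] in "AG" and "".join(p)[1:] == "CGTG"
        }
        assert HRE_5MERS == matched and len(HRE_5MERS) == 2

    def test_has_matches_exactly_twelve_5mers(self):
        matched = {
            "".join(p) for p in product("ACGT", repeat=5)
            if p[0] == "C" and p[1] == "A" and p[2] in "GC" and p[3] in "AG" and p[4] in "TGC"
        }
        assert HAS_5MERS == matched and len(HAS_5MERS) == 12


class TestScanMotif:
    def test_single_hre_r_is_a(self):
        hits = scan_motif(make_window("ACGTG"), "hre")
        assert len(hits) == 1 and hits[0].matched_seq == "ACGTG"

    def test_two_hres_both_r_cases(self):
        hits = scan_motif(make_window("GCGTGTTACGTG"), "hre")
        assert [h.matched_seq for h in hits] == ["GCGTG", "ACGTG"]

    def test_has_pattern_definition(self):
        hits = scan_motif(make_window("CAGAT"), "has")
        assert len(hits) == 1 and hits[0].matched_seq == "CAGAT"

    def test_ambiguous_bases_never_match(self):
        assert scan_motif(make_window("ANGTGACGTN"), "hre") == []

    def test_random_sequences_equal_enumeration_oracle(self):
        rng = random.Random(42)
        win_rel = -150
        for _ in range(50):
            seq = "".join(rng.choice("ACGT") for _ in range(200))
            win = make_window(seq, rel_start=win_rel)
            for pattern, mers in (("hre", HRE_5MERS), ("has", HAS_5MERS)):
                got = [win.rel_to_offset(h.rel_start) for h in scan_motif(win, pattern)]
                assert got == brute_force_offsets(seq, mers)


class TestClassifyEbox:
    @pytest.mark.parametrize(
        "seq,n_hre,n_ebox,context",
        [
            ("CACGTG", 0, 1, "CACGTG"),
            ("TACGTG", 1, 0, None),
            ("CGCGTG", 0, 1, "CGCGTG"),
        ],
    )
    def test_context_rules(self, seq, n_hre, n_ebox, context):
        win = make_window(seq)
        hre, ebox = classify_ebox(scan_motif(win, "hre"), win)
        assert (len(hre), len(ebox)) == (n_hre, n_ebox)
        if ebox:
            assert ebox[0].context_6mer == context

    def test_hit_at_window_start_stays_hre(self):
        win = make_window("ACGTGAAAA")
        hre, ebox = classify_ebox(scan_motif(win, "hre"), win)
        assert len(hre) == 1 and not ebox

    def test_position_level_disjointness(self):
        rng = random.Random(3)
        for _ in range(30):
            seq = "".join(rng.choice("ACGT") for _ in range(300))
            win = make_window(seq)
            hre, ebox = classify_ebox(scan_motif(win, "hre"), win)
            assert {h.rel_start for h in hre}.isdisjoint({e.rel_start for e in ebox})
            assert len(hre) + len(ebox) == len(brute_force_offsets(seq, HRE_5MERS))


class TestLinkHas:
    def test_gap_nine_is_linked(self):
        hre = MotifHit("g", "HRE", -204, -200, 0, 0, "ACGTG")
        has = MotifHit("g", "HAS", -190, -186, 0, 0, "CAGAT")
        assert gap_between(hre, has) == 9
        assert len(link_has([hre], [has])) == 1

    def test_gap_five_not_linked(self):
        hre = MotifHit("g", "HRE", -204, -200, 0, 0, "ACGTG")
        has = MotifHit("g", "HAS", -194, -190, 0, 0, "CAGAT")
        assert gap_between(hre, has) == 5
        assert link_has([hre], [has]) == []

    def test_gap_sixteen_needs_wider_spec(self):
        hre = MotifHit("g", "HRE", -204, -200, 0, 0, "ACGTG")
        has = MotifHit("g", "HAS", -183, -179, 0, 0, "CAGAT")
        assert gap_between(hre, has) == 16
        assert link_has([hre], [has]) == []
        assert len(link_has([hre], [has], LinkSpec(7, 30))) == 1

    def test_has_upstream_of_hre_never_links(self):
        hre = MotifHit("g", "HRE", -100, -96, 0, 0, "ACGTG")
        has = MotifHit("g", "HAS", -120, -116, 0, 0, "CAGAT")
        assert link_has([hre], [has]) == []

    @given(
        hre_pos=st.integers(min_value=-400, max_value=-50),
        offsets=st.lists(st.integers(min_value=6, max_value=40), min_size=0, max_size=6),
        lo=st.integers(min_value=0, max_value=10),
        widen=st.integers(min_value=0, max_value=20),
    )
    @settings(max_examples=60, derandomize=True)
    def test_widening_gap_window_is_monotone(self, hre_pos, offsets, lo, widen):
        hre = MotifHit("g", "HRE", hre_pos, hre_pos + 4, 0, 0, "ACGTG")
        has_hits = [
            MotifHit("g", "HAS", hre_pos + 4 + d, hre_pos + 8 + d, 0, 0, "CAGAT")
            for d in offsets
        ]
        hi = lo + 10
        narrow = link_has([hre], has_hits, LinkSpec(lo, hi))
        wide = link_has([hre], has_hits, LinkSpec(max(0, lo - widen), hi + widen))
        narrow_keys = {(p.has.rel_start, p.gap) for p in narrow}
        wide_keys = {(p.has.rel_start, p.gap) for p in wide}
        assert narrow_keys <= wide_keys


class TestRegionScheme:
    @pytest.mark.parametrize(
        "rel,region",
        [
            (50, "CORE"), (100, "CORE"), (-899, "CORE"),
            (-900, "PROXIMAL"), (-2000, "PROXIMAL"), (-2899, "PROXIMAL"),
            (-2900, "DISTAL"), (-4000, "DISTAL"), (-4900, "DISTAL"),
        ],
    )
    def test_boundaries(self, rel, region):
        assert RegionScheme().assign(rel) == region

    def test_outside_window_is_error(self):
        with pytest.raises(ValueError):
            RegionScheme().assign(101)
        with pytest.raises(ValueError):
            RegionScheme().assign(-4901)

    def test_regions_partition_default_window(self):
        sizes = RegionScheme().sizes()
        assert sum(sizes.values()) == 5000
        assert sizes == {"CORE": 999, "PROXIMAL": 2000, "DISTAL": 2001}


def test_scan_window_region_counts_sum_to_totals():
    rng = random.Random(8)
    seq = "".join(rng.choice("ACGT") for _ in range(5000))
    win = make_window(seq, rel_start=-4900)
    hre, ebox, has, pairs = scan_window(win)
    for hits in (hre, ebox, has):
        regions = [h.region for h in hits]
        assert all(r in {"CORE", "PROXIMAL", "DISTAL"} for r in regions)
    assert len(hre) + len(ebox) == len(brute_force_offsets(seq, HRE_5MERS))
    assert len(has) == len(brute_force_offsets(seq, HAS_5MERS))
    # linked pairs come from non-E-box HREs only
    hre_keys = {h.rel_start for h in hre}
    assert all(p.hre.rel_start in hre_keys for p in pairs)
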