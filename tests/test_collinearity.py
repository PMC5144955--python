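"""Breakpoint delimitation from marker profiles and collinear-block chaining."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synbreak.core import BreakpointInterval
from synbreak.collinearity import (
    GeneAnnotation,
    LocationProfileTable,
    MarkerRecord,
    ancient_junction_overlap,
    chain_collinear_blocks,
    delimit_by_gene_pair,
    infer_candidate_arms,
    physical_size,
    profile_transition_scan,
)


def table_from_column(hit_sets, taxon="wheat", ref_arm="5DL", bands=None):
    rows = [
        MarkerRecord(
            f"m{i:02d}",
            i,
            {taxon: frozenset(h)},
            band_count=None if bands is None else bands[i],
        )
        for i, h in enumerate(hit_sets)
    ]
    return LocationProfileTable(ref_arm, rows)


class TestTransitionScan:
    def test_eleven_then_ten_marker_runs(self):
        """A 5L-reference column: 11 markers on the 5-group arms followed by
        10 markers whose group-5A copy moved to 4AL; the homoeologous
        background (5BL, 5DL) is constant and uninformative."""
        col = [{"5AL", "5BL", "5DL"}] * 11 + [{"4AL", "5BL", "5DL"}] * 10
        table = table_from_column(col)
        calls = profile_transition_scan(table, "wheat", min_run=2)
        assert len(calls) == 1
        iv = calls[0]
        assert iv.flank_pair() == ("m10", "m11")
        assert iv.ordinal_span == (10, 11)
        assert iv.proximal_consensus_arm == "5AL"
        assert iv.distal_consensus_arm == "4AL"

    def test_constant_column_no_calls(self):
        table = table_from_column([{"5AL"}] * 12)
        assert profile_transition_scan(table, "wheat") == []

    def test_single_discordant_marker_never_calls(self):
        col = [{"5AL"}] * 5 + [{"4AL"}] + [{"5AL"}] * 5
        assert profile_transition_scan(table_from_column(col), "wheat", min_run=2) == []

    def test_missing_markers_do_not_break_runs(self):
        col = [{"5AL"}] * 3 + [set()] * 2 + [{"5AL"}] * 2 + [{"4AL"}] * 3
        calls = profile_transition_scan(table_from_column(col), "wheat", min_run=2)
        assert len(calls) == 1
        assert calls[0].flank_pair() == ("m06", "m07")

    def test_ambiguous_multi_candidate_hits_are_skipped(self):
        col = [{"5AL"}] * 3 + [{"5AL", "4AL"}] + [{"4AL"}] * 3
        calls = profile_transition_scan(table_from_column(col), "wheat", min_run=2)
        assert len(calls) == 1
        assert calls[0].flank_pair() == ("m02", "m04")

    def test_explicit_candidate_arms_filter_off_target_hits(self):
        col = [{"5RL"}] * 2 + [{"3RS"}] + [{"5RL"}] * 2 + [{"7RS"}] * 2
        calls = profile_transition_scan(
            table_from_column(col, taxon="rye"), "rye", min_run=2,
            candidate_arms={"5RL", "7RS"},
        )
        assert len(calls) == 1
        assert calls[0].flank_pair() == ("m04", "m05")

    def test_absent_query_taxon_raises(self):
        with pytest.raises(KeyError):
            profile_transition_scan(table_from_column([{"5AL"}]), "rye")

    def test_min_run_validation(self):
        with pytest.raises(ValueError):
            profile_transition_scan(table_from_column([{"5AL"}]), "wheat", min_run=0)

    def test_size_kb_from_band_counts_in_gap(self):
        col = [{"5AL"}] * 3 + [{"4AL"}] * 3
        bands = [10, 10, 4, 6, 10, 10]
        calls = profile_transition_scan(table_from_column(col, bands=bands), "wheat")
        assert calls[0].size_kb == pytest.approx((4 + 6) * 1.5)

    def test_candidate_inference_drops_constant_background(self):
        col = [{"5AL", "5BL"}] * 3 + [{"4AL", "5BL"}] * 3
        table = table_from_column(col)
        assert infer_candidate_arms(table, "wheat") == {"5AL", "4AL"}


class TestDelimitByGenePair:
    def interval(self):
        return BreakpointInterval(
            "4DL", "wheat", "AT4D4118", "AT4D4119", (10, 20),
            {"4AL", "4BL", "4DL"}, {"5AL", "4BL", "4DL"},
        )

    def test_wd3l_hlh_refinement(self):
        anns = [
            GeneAnnotation("WD3L", 12.0, {"4AL", "4BL", "4DL"}),
            GeneAnnotation("HLH", 17.0, {"5AL", "4BL", "4DL"}),
        ]
        refined = delimit_by_gene_pair(self.interval(), anns)
        assert refined.flank_pair() == ("WD3L", "HLH")
        assert refined.ordinal_span == (12.0, 17.0)

    def test_all_concordant_unchanged(self):
        anns = [GeneAnnotation("WD3L", 12.0, {"4AL"})]
        refined = delimit_by_gene_pair(self.interval(), anns)
        assert refined.flank_pair() == ("AT4D4118", "AT4D4119")

    def test_innermost_pair_of_five_genes(self):
        anns = [
            GeneAnnotation(f"g{i}", 10 + i, {"4AL"} if i <= 3 else {"5AL"})
            for i in range(1, 6)
        ]
        refined = delimit_by_gene_pair(self.interval(), anns)
        assert refined.flank_pair() == ("g3", "g4")


class TestPhysicalSize:
    def test_examples(self):
        assert physical_size(0) == 0.0
        assert physical_size(10) == 15.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            physical_size(-1)

    @given(a=st.integers(0, 10_000), b=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=50)
    def test_linearity(self, a, b):
        assert physical_size(a + b) == physical_size(a) + physical_size(b)


def oracle_blocks(ref_order, out_order):
    """Independent chaining oracle: split the shared walk wherever the
    outgroup-index step is not a continuation of the current run."""
    out_index = {g: i for i, g in enumerate(out_order)}
    shared = [(g, out_index[g]) for g in ref_order if g in out_index]
    if not shared:
        return []
    pieces, cur, direction = [], [shared[0]], 0
    for prev, item in zip(shared, shared[1:]):
        step = item[1] - prev[1]
        if abs(step) == 1 and direction in (0, step):
            cur.append(item)
            direction = step
        else:
            pieces.append([g for g, _ in cur])
            cur, direction = [item], 0
    pieces.append([g for g, _ in cur])
    return pieces


class TestChaining:
    def test_swapped_blocks(self):
        blocks = chain_collinear_blocks(list("abcdef"), list("defabc"))
        assert [b.genes for b in blocks] == [["a", "b", "c"], ["d", "e", "f"]]
        assert all(b.strand == "same" for b in blocks)

    def test_identical_orders_single_block(self):
        (blk,) = chain_collinear_blocks(list("abcde"), list("abcde"))
        assert blk.genes == list("abcde")
        assert not blk.possible_transposition

    def test_reversed_segment(self):
        blocks = chain_collinear_blocks(list("abcdef"), list("abedcf"))
        strands = [(tuple(b.genes), b.strand) for b in blocks]
        assert (("c", "d", "e"), "reversed") in strands

    def test_no_shared_genes(self):
        assert chain_collinear_blocks(list("abc"), list("xyz")) == []

    def test_singleton_flagged(self):
        blocks = chain_collinear_blocks(list("abcd"), ["c", "a", "b", "d"])
        flagged = [b.genes[0] for b in blocks if b.possible_transposition]
        assert flagged  # relocation shows up as length-1 block(s)

    @given(perm=st.permutations(list("abcdefgh")))
    @settings(derandomize=True, max_examples=120)
    def test_matches_exhaustive_oracle_and_partitions(self, perm):
        ref = list("abcdefgh")
        blocks = chain_collinear_blocks(ref, perm)
        assert [b.genes for b in blocks] == oracle_blocks(ref, perm)
        # partition of the shared set
        flat = [g for b in blocks for g in b.genes]
        assert sorted(flat) == sorted(ref)
        # within-block outgroup indices are arithmetic with step +-1
        for b in blocks:
            steps = set(np.diff(b.out_indices)) if len(b) > 1 else set()
            assert steps <= {1} or steps <= {-1}


class TestAncientJunction:
    def breakpoint(self, span):
        return BreakpointInterval("4DL", "wheat", "p", "d", span, {"4AL"}, {"5AL"})

    def test_boundary_at_breakpoint_gap(self):
        blocks = chain_collinear_blocks(list("abcdef"), list("defabc"))
        assert ancient_junction_overlap(self.breakpoint((2, 3)), blocks) == "coincident"

    def test_single_block_not_coincident(self):
        blocks = chain_collinear_blocks(list("abcdef"), list("abcdef"))
        assert ancient_junction_overlap(self.breakpoint((2, 3)), blocks) == "not_coincident"

    def test_distant_breakpoint_not_coincident(self):
        blocks = chain_collinear_blocks(list("abcdef"), list("defabc"))
        assert ancient_junction_overlap(self.breakpoint((0, 1)), blocks) == "not_coincident"

    def test_wide_boundary_gap_from_transposed_flank(self):
        # the distal flank gene is absent from the outgroup (a lineage-
        # specific transposition): the block gap is wider than the
        # breakpoint gap but no marker separates them
        ref = ["KDM", "WD3L", "HLH", "PINX1", "DAGK", "STK"]
        out = ["PINX1", "DAGK", "STK", "KDM", "WD3L"]
        blocks = chain_collinear_blocks(ref, out)
        iv = self.breakpoint((1, 2))  # between WD3L and HLH
        assert ancient_junction_overlap(iv, blocks) == "coincident"
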