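"""Event algebra: rearrangements apply correctly and conserve gene content."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synbreak.core import (
    ChromosomeArm,
    EventType,
    Genome,
    OrientedGene,
    RearrangementEvent,
    apply_event,
    arm_location_of,
)


def make_genome(arm_specs: dict[str, list[str]], taxon: str = "t") -> Genome:
    arms = {
        arm_id: ChromosomeArm(
            arm_id, [OrientedGene(g, f"fam_{g}", "+") for g in genes]
        )
        for arm_id, genes in arm_specs.items()
    }
    return Genome(taxon, arms)


class TestApplyEvent:
    def test_translocation_swaps_distal_segments(self):
        g = make_genome({"A": ["a", "b", "c"], "B": ["x", "y", "z"]})
        ev = RearrangementEvent(EventType.RECIPROCAL_TRANSLOCATION, ("A", "B"), (1, 0))
        out = apply_event(g, ev)
        assert out.arms["A"].gene_ids() == ["a", "b", "y", "z"]
        assert out.arms["B"].gene_ids() == ["x", "c"]

    def test_translocation_twice_restores(self):
        g = make_genome({"A": ["a", "b", "c", "d"], "B": ["x", "y", "z"]})
        ev = RearrangementEvent(EventType.RECIPROCAL_TRANSLOCATION, ("A", "B"), (0, 1))
        back = apply_event(apply_event(g, ev), ev)
        assert back.arms["A"].gene_ids() == g.arms["A"].gene_ids()
        assert back.arms["B"].gene_ids() == g.arms["B"].gene_ids()

    def test_full_arm_inversion_is_involution(self):
        g = make_genome({"A": ["a", "b", "c", "d"]})
        inv = RearrangementEvent(EventType.INVERSION, ("A",), (-1, 3))
        once = apply_event(g, inv)
        assert once.arms["A"].gene_ids() == ["d", "c", "b", "a"]
        assert all(x.orientation == "-" for x in once.arms["A"].genes)
        twice = apply_event(once, inv)
        assert twice.arms["A"].genes == g.arms["A"].genes

    def test_inversion_reverses_relative_order_in_span(self):
        g = make_genome({"A": list("abcdef")})
        out = apply_event(g, RearrangementEvent(EventType.INVERSION, ("A",), (1, 4)))
        ids = out.arms["A"].gene_ids()
        assert ids == ["a", "b", "e", "d", "c", "f"]
        # inside the span the ordinal comparison flips
        assert ids.index("e") < ids.index("c")

    def test_transposition_moves_payload(self):
        g = make_genome({"A": list("abcd"), "B": list("xy")})
        ev = RearrangementEvent(
            EventType.TRANSPOSITION, ("B",), (0,), payload="b"
        )
        out = apply_event(g, ev)
        assert out.arms["A"].gene_ids() == ["a", "c", "d"]
        assert out.arms["B"].gene_ids() == ["x", "b", "y"]

    def test_deletion_and_duplication(self):
        g = make_genome({"A": list("abc")})
        gone = apply_event(
            g, RearrangementEvent(EventType.DELETION, ("A",), (), payload="b")
        )
        assert gone.arms["A"].gene_ids() == ["a", "c"]
        dup = apply_event(
            g, RearrangementEvent(EventType.DUPLICATION, ("A",), (), payload="b")
        )
        assert dup.arms["A"].gene_ids() == ["a", "b", "b_dup1", "c"]
        # the copy keeps the family of its template
        fams = {x.gene_id: x.family_id for x in dup.arms["A"].genes}
        assert fams["b_dup1"] == fams["b"]

    def test_te_insertion_adds_te_family_element(self):
        g = make_genome({"A": list("ab")})
        out = apply_event(g, RearrangementEvent(EventType.TE_INSERTION, ("A",), (-1,)))
        first = out.arms["A"].genes[0]
        assert first.family_id == "TE"
        assert out.arms["A"].gene_ids()[1:] == ["a", "b"]

    def test_input_genome_is_untouched(self):
        g = make_genome({"A": list("abc"), "B": list("xy")})
        apply_event(
            g, RearrangementEvent(EventType.RECIPROCAL_TRANSLOCATION, ("A", "B"), (0, 0))
        )
        assert g.arms["A"].gene_ids() == ["a", "b", "c"]

    @pytest.mark.parametrize(
        "event",
        [
            RearrangementEvent(EventType.RECIPROCAL_TRANSLOCATION, ("A", "Z"), (0, 0)),
            RearrangementEvent(EventType.RECIPROCAL_TRANSLOCATION, ("A", "B"), (5, 0)),
            RearrangementEvent(EventType.INVERSION, ("A",), (0, 99)),
            RearrangementEvent(EventType.UNCLASSIFIED, ("A",), (0,)),
        ],
    )
    def test_invalid_events_raise(self, event):
        g = make_genome({"A": list("abc"), "B": list("xyz")})
        with pytest.raises((KeyError, ValueError)):
            apply_event(g, event)


@given(
    cut1=st.integers(min_value=-1, max_value=4),
    cut2=st.integers(min_value=-1, max_value=3),
)
@settings(derandomize=True, max_examples=60)
def test_translocation_conserves_gene_multiset(cut1, cut2):
    g = make_genome({"A": list("abcde"), "B": list("vwxy")})
    ev = RearrangementEvent(EventType.RECIPROCAL_TRANSLOCATION, ("A", "B"), (cut1, cut2))
    out = apply_event(g, ev)
    assert Counter(out.gene_ids()) == Counter(g.gene_ids())


@given(
    b1=st.integers(min_value=-1, max_value=4),
    span=st.integers(min_value=1, max_value=5),
)
@settings(derandomize=True, max_examples=60)
def test_inversion_involution_and_conservation(b1, span):
    g = make_genome({"A": list("abcdef")})
    b2 = min(b1 + span, 5)
    inv = RearrangementEvent(EventType.INVERSION, ("A",), (b1, b2))
    once = apply_event(g, inv)
    assert Counter(once.gene_ids()) == Counter(g.gene_ids())
    assert apply_event(once, inv).arms["A"].genes == g.arms["A"].genes


class TestArmLocation:
    def test_fixture_gene_location(self, genomes):
        assert arm_location_of(genomes["wheat_A"], "WD3L") == "4AL"
        assert arm_location_of(genomes["tauschii_D"], "WD3L") == "4DL"

    def test_absent_gene_is_none_not_error(self, genomes):
        # PMEI family loss in barley: absence is an answer, not a failure
        assert arm_location_of(genomes["barley_H"], "PMEI") is None
        assert arm_location_of(Genome("empty", {}), "anything") is None

    def test_translocated_gene_maps_to_recipient_arm(self):
        g = make_genome({"A": list("abc"), "B": list("xyz")})
        ev = RearrangementEvent(EventType.RECIPROCAL_TRANSLOCATION, ("A", "B"), (0, 0))
        out = apply_event(g, ev)
        assert arm_location_of(out, "b") == "B"
        assert arm_location_of(out, "y") == "A"


class TestValidation:
    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValueError):
            ChromosomeArm("A", [OrientedGene("g", "f"), OrientedGene("g", "f")])
        with pytest.raises(ValueError):
            make_genome({"A": ["g"], "B": ["g"]})

    def test_orientation_values(self):
        OrientedGene("g", "f", "?")  # unknown orientation allowed for fixtures
        with pytest.raises(ValueError):
            OrientedGene("g", "f", "fwd")

    def test_breakpoint_interval_invariants(self):
        from synbreak.core import BreakpointInterval

        with pytest.raises(ValueError):
            BreakpointInterval("4DL", "q", "a", "b", (3, 2), {"4AL"}, {"5AL"})
        with pytest.raises(ValueError):
            BreakpointInterval("4DL", "q", "a", "b", (1, 2), {"4AL"}, {"4AL"})
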