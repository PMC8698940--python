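import pytest
from hypothesis import given, settings, strategies as st

from ductmorph.sequences import TargetTopology, enumerate_event_sequences


class TestEnumeration:
    def test_unbranched_duct_one_empty_sequence(self):
        count, seqs = enumerate_event_sequences(TargetTopology(1), max_events=2)
        assert count == 1 and seqs == [()]

    def test_single_terminal_bifurcation(self):
        count, seqs = enumerate_event_sequences(TargetTopology(2), max_events=2)
        assert count == 1 and seqs == [("terminal_bifed",)]

    def test_three_tip_cluster_has_three_histories(self):
        """The classic three-tip end state: trifed, bifed-bifed, or
        bifed-lateral — only sequential imaging separates them."""
        count, seqs = enumerate_event_sequences(TargetTopology(3), max_events=2)
        assert count == 3
        assert set(seqs) == {
            ("terminal_trifed",),
            ("terminal_bifed", "terminal_bifed"),
            ("terminal_bifed", "lateral"),
        }

    def test_interior_cluster_requires_lateral_first(self):
        count, seqs = enumerate_event_sequences(TargetTopology(1, (1,)), max_events=2)
        assert count == 1 and seqs == [("lateral",)]

    def test_unreachable_topology_counts_zero(self):
        count, seqs = enumerate_event_sequences(TargetTopology(5), max_events=1)
        assert count == 0 and seqs == []

    def test_tuple_form_accepted(self):
        assert enumerate_event_sequences((3, ()), max_events=2)[0] == 3

    def test_max_events_bounds(self):
        with pytest.raises(ValueError):
            enumerate_event_sequences(TargetTopology(2), max_events=7)
        with pytest.raises(ValueError):
            enumerate_event_sequences(TargetTopology(2), max_events=-1)


class TestEnumerationProperties:
    @given(tips=st.integers(1, 4), m=st.integers(0, 3))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_count_monotone_in_max_events(self, tips, m):
        c1, _ = enumerate_event_sequences(TargetTopology(tips), max_events=m)
        c2, _ = enumerate_event_sequences(TargetTopology(tips), max_events=m + 1)
        assert c2 >= c1

    @given(tips=st.integers(1, 4))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_sequences_have_valid_types_and_length(self, tips):
        count, seqs = enumerate_event_sequences(TargetTopology(tips), max_events=3)
        assert count == len(seqs)
        valid = {"terminal_bifed", "terminal_trifed", "lateral"}
        for s in seqs:
            assert len(s) <= 3 and set(s) <= valid
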