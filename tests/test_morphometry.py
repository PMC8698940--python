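import numpy as np
import pandas as pd
import pytest

import ductmorph as dm
from ductmorph.tracking import DetectedEvent


def _ev(i, t, etype, gen=0, ambiguous=False):
    return DetectedEvent(
        event_id=i, detect_t_a=t - 0.25, detect_t_b=t + 0.25, type=etype,
        parent_track=0, attachment_fraction=1.0 if etype != "lateral" else 0.5,
        child_tracks=(), generation=gen, ambiguous=ambiguous,
    )


class TestEventTables:
    def test_type_fractions(self):
        events = [
            _ev(0, 1, "terminal_bifed"), _ev(1, 2, "terminal_bifed"),
            _ev(2, 3, "terminal_trifed"), _ev(3, 4, "lateral"),
        ]
        tab = dm.event_type_counts(events, [5.0])
        row = tab.iloc[0]
        assert (row.frac_bifed, row.frac_trifed, row.frac_lateral) == (0.5, 0.25, 0.25)

    def test_empty_log_flagged_undefined(self):
        tab = dm.event_type_counts([], [5.0])
        assert bool(tab.iloc[0].undefined)
        assert np.isnan(tab.iloc[0].frac_bifed)

    def test_ambiguous_events_tallied_separately(self):
        events = [_ev(0, 1, "terminal_bifed"),
                  _ev(1, 2, "terminal_trifed", ambiguous=True)]
        tab = dm.event_type_counts(events, [5.0])
        assert tab.iloc[0].n_ambiguous == 1
        assert tab.iloc[0].n_trifed == 0  # ambiguous never counted as resolved
        byg = dm.branch_events_by_generation(events, [5.0])
        assert byg.iloc[0].cum_branch_events == 1
        assert byg.iloc[0].cum_ambiguous == 1

    def test_cumulative_counts_keyed_by_parent_generation(self):
        events = [_ev(0, 1, "terminal_bifed", gen=0),
                  _ev(1, 2, "terminal_bifed", gen=1),
                  _ev(2, 3, "lateral", gen=1)]
        tab = dm.branch_events_by_generation(events, [0.5, 2.5, 3.5])
        g1 = tab[tab.generation == 1].set_index("time_h")
        assert list(g1.cum_branch_events) == [0, 1, 2]


class TestImageDerived:
    def test_aggregate_length_trivial_pre_branching(self, branched_forest):
        forest, tree, log = branched_forest
        tab = dm.aggregate_length_by_generation(forest, [4.0])
        g0 = tab[tab.generation == 0].iloc[0]
        # one original duct: 30 um bud + 4 h at 20 um/h
        assert g0.aggregate_length_um == pytest.approx(110.0, rel=0.06)
        assert tab[tab.generation > 0].aggregate_length_um.sum() == 0

    def test_total_tips_series(self, branched_forest):
        forest, tree, log = branched_forest
        s = dm.total_tip_number(forest, [0.0, 10.0, 20.0])
        assert list(s) == [1, 2, 5]

    def test_max_generation(self, branched_forest):
        forest, tree, log = branched_forest
        assert dm.max_generation(forest) == 2

    def test_table_matches_ground_truth(self, branched_forest):
        forest, tree, log = branched_forest
        times = [10.0, 20.0]
        gt = dm.ground_truth_metrics(tree, log, times)
        mt = dm.morphometry_table(forest, times)
        m = gt.merge(mt, on=["time_h", "generation"], suffixes=("_gt", "_m"))
        for col in ("total_tips", "cum_branch_events", "cum_bifed",
                    "cum_trifed", "cum_lateral", "n_segments"):
            assert (m[col + "_gt"] == m[col + "_m"]).all(), col
        nz = m[m.aggregate_length_um_gt > 0]
        rel = (nz.aggregate_length_um_m - nz.aggregate_length_um_gt).abs() \
            / nz.aggregate_length_um_gt
        assert rel.max() < 0.05

    def test_cumulative_columns_monotone(self, branched_forest):
        forest, *_ = branched_forest
        tab = dm.morphometry_table(forest, [0.0, 5.0, 10.0, 15.0, 20.0])
        for g, sub in tab.groupby("generation"):
            sub = sub.sort_values("time_h")
            for col in ("aggregate_length_um", "cum_branch_events", "total_tips"):
                assert (np.diff(sub[col].to_numpy()) >= -1e-9).all()
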