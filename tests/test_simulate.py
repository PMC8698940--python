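import numpy as np
import pytest

import ductmorph as dm
from ductmorph.tree import TIP_DELTA


def conservation_holds(tree, log, t):
    c = log.counts_up_to(t)
    n0 = sum(1 for s in tree.segments.values() if s.parent_id is None)
    expected = n0 + sum(TIP_DELTA[k] * v for k, v in c.items())
    return tree.tips_at(t) == expected


class TestNoEventLimit:
    def test_hazard_zero_gives_pure_elongation(self):
        cfg = dm.lobe_preset("vp", seed=1).replace(
            tip_branch_hazard_per_h=0.0, n_original_ducts=4, initial_bud_length_um=0.0
        )
        tree, log = dm.sample_forest(cfg)
        assert len(log) == 0
        assert len(tree) == 4
        for s in tree.segments.values():
            assert s.generation == 0
            assert s.length == pytest.approx(90.0 * cfg.elongation_rate_um_h)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = dm.lobe_preset("vp", seed=7, duration_h=50.0)
        t1, l1 = dm.sample_forest(cfg)
        t2, l2 = dm.sample_forest(cfg)
        assert len(t1) == len(t2) and len(l1) == len(l2)
        for k in t1.segments:
            assert np.array_equal(t1.segments[k].points, t2.segments[k].points)
            assert np.array_equal(t1.segments[k].point_times, t2.segments[k].point_times)
        for a, b in zip(l1, l2):
            assert (a.time, a.type, a.parent_segment_id) == (b.time, b.type, b.parent_segment_id)

    def test_different_seed_differs(self):
        t1, _ = dm.sample_forest(dm.lobe_preset("vp", seed=1, duration_h=50.0))
        t2, _ = dm.sample_forest(dm.lobe_preset("vp", seed=2, duration_h=50.0))
        assert len(t1) != len(t2) or not np.array_equal(
            next(iter(t1.segments.values())).points,
            next(iter(t2.segments.values())).points,
        )


class TestStructure:
    @pytest.mark.parametrize("lobe", ["vp", "lp", "lp1", "lp2"])
    def test_generation_cap_never_exceeded(self, lobe):
        cfg = dm.lobe_preset(lobe, seed=5)
        tree, _ = dm.sample_forest(cfg)
        assert tree.max_generation <= cfg.max_generation

    def test_lp1_only_first_generation(self):
        for s in range(8):
            tree, _ = dm.sample_forest(dm.lobe_preset("lp1", seed=s))
            assert tree.max_generation <= 1

    def test_child_generation_and_birth_order(self):
        tree, _ = dm.sample_forest(dm.lobe_preset("vp", seed=3))
        for s in tree.segments.values():
            if s.parent_id is not None:
                p = tree.segments[s.parent_id]
                assert s.generation == p.generation + 1
                assert s.birth_time >= p.birth_time

    def test_lateral_attachment_interior_terminal_at_tip(self):
        tree, log = dm.sample_forest(dm.lobe_preset("vp", seed=3))
        for e in log:
            if e.type == "lateral":
                assert 0.0 < e.attachment_fraction < 1.0
                assert len(e.child_segment_ids) == 1
            else:
                assert e.attachment_fraction == 1.0
                assert len(e.child_segment_ids) == (
                    2 if e.type == "terminal_bifed" else 3
                )

    def test_tip_conservation_on_presets(self):
        for lobe in ("vp", "lp"):
            for s in range(5):
                tree, log = dm.sample_forest(dm.lobe_preset(lobe, seed=s))
                for t in (20.0, 55.0, 90.0):
                    assert conservation_holds(tree, log, t)

    def test_runaway_config_rejected(self):
        cfg = dm.GrowthConfig(
            tip_branch_hazard_per_h=1.0, duration_h=90.0, max_generation=50
        )
        with pytest.raises(dm.ConfigError, match="runaway"):
            dm.sample_forest(cfg)


class TestEventTypeLaw:
    def test_type_fractions_follow_multinomial(self):
        """Pooled type fractions over many runs fall inside the binomial
        99% CI around the generating probabilities."""
        probs = dict(zip(("terminal_bifed", "terminal_trifed", "lateral"),
                         (0.423, 0.197, 0.380)))
        counts = {k: 0 for k in probs}
        s = 0
        while sum(counts.values()) < 600:
            _, log = dm.sample_forest(dm.lobe_preset("vp", seed=400 + s))
            s += 1
            for e in log:
                counts[e.type] += 1
        n = sum(counts.values())
        for k, p in probs.items():
            half = 2.576 * np.sqrt(p * (1 - p) / n)
            assert abs(counts[k] / n - p) < half + 0.01

    def test_treatment_shifts_mean_tip_count(self):
        def mean_tips(tr):
            return np.mean([
                dm.sample_forest(
                    dm.lobe_preset("vp", treatment=tr, seed=s, duration_h=50.0)
                )[0].tips_at(50.0)
                for s in range(12)
            ])

        fgf10, ctrl, ml7 = mean_tips("fgf10"), mean_tips("control"), mean_tips("ml7")
        assert fgf10 > ctrl > ml7


class TestGroundTruthMetrics:
    def test_initial_state(self):
        cfg = dm.lobe_preset("vp", seed=1).replace(
            n_original_ducts=4, initial_bud_length_um=25.0, tip_branch_hazard_per_h=0.0
        )
        tree, log = dm.sample_forest(cfg)
        tab = dm.ground_truth_metrics(tree, log, [0.0])
        g0 = tab[tab.generation == 0].iloc[0]
        assert g0.aggregate_length_um == pytest.approx(100.0)
        assert g0.total_tips == 4
        assert g0.cum_branch_events == 0

    def test_tip_increments_by_event_type(self):
        st = dm.ScriptedTree(rate=15)
        r = st.add_original((60, 300), 0.0, 30)
        a, b = st.bifed(r, 5.0)
        st.trifed(a, 10.0)
        st.lateral(b, 15.0, 0.5)
        tree, log = st.build(20.0)
        tips = [tree.tips_at(t) for t in (4, 6, 11, 16)]
        assert tips == [1, 2, 4, 5]  # +1 bifed, +2 trifed, +1 lateral

    def test_lengths_monotone_in_time(self):
        tree, log = dm.sample_forest(dm.lobe_preset("lp2", seed=2))
        tab = dm.ground_truth_metrics(tree, log, [0, 30, 60, 90])
        for g, sub in tab.groupby("generation"):
            vals = sub.sort_values("time_h")["aggregate_length_um"].to_numpy()
            assert (np.diff(vals) >= -1e-9).all()

    def test_times_outside_duration_rejected(self):
        tree, log = dm.sample_forest(dm.lobe_preset("lp1", seed=0, duration_h=30.0))
        with pytest.raises(ValueError):
            dm.ground_truth_metrics(tree, log, [40.0])
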