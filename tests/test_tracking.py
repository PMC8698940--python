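import numpy as np
import pytest

import ductmorph as dm
from ductmorph.skeleton import binarize, build_graph, skeletonize
from ductmorph.tracking import TrackingParams, TrackLostError, track


def _graph_from_mask(mask, frame_index=0):
    return build_graph(skeletonize(mask), 2.0, anchor_x_px=10, frame_index=frame_index)


def _bar(h=64, w=160, stop=100):
    m = np.zeros((h, w), bool)
    m[30:35, 10:stop] = True
    return m


class TestTrackBasics:
    def test_identical_frames_no_new_tracks(self):
        g0, g1 = _graph_from_mask(_bar()), _graph_from_mask(_bar(), 1)
        forest = track([g0, g1], [0.0, 0.5])
        assert len(forest.tracks) == 1
        assert len(forest.events) == 0

    def test_new_lateral_stub_opens_one_track(self):
        m0 = _bar()
        m1 = _bar()
        m1[12:30, 50:55] = True  # side branch appearing at an interior point
        forest = track([_graph_from_mask(m0), _graph_from_mask(m1, 1)], [0.0, 0.5])
        assert len(forest.tracks) == 2
        assert len(forest.events) == 1
        assert forest.events[0].type == "lateral"
        assert 0.0 < forest.events[0].attachment_fraction < 1.0

    def test_static_stack_empty_log(self, ambiguity_stack):
        stack, *_ = ambiguity_stack
        frozen = dm.FrameStack(
            np.repeat(stack.frames[10:11], 5, axis=0),
            stack.timestamps[:5],
            stack.pixel_size,
            stack.anchor_x_um,
        )
        forest = dm.analyze_stack(frozen)
        assert len(forest.events) == 0

    def test_track_lost_error_on_shrinking_duct(self):
        g0 = _graph_from_mask(_bar(stop=120))
        g1 = _graph_from_mask(_bar(stop=60), 1)  # growth-only violated
        with pytest.raises(TrackLostError):
            track([g0, g1], [0.0, 0.5])


class TestEventDetection:
    def test_scripted_events_detected_with_correct_types(self, branched_forest):
        forest, tree, log = branched_forest
        detected = dm.detect_events(forest)
        assert [e.type for e in detected] == [
            "terminal_bifed", "lateral", "terminal_trifed",
        ]
        assert all(not e.ambiguous for e in detected)
        # detection lags truth by daughter protrusion, within ~2 h
        for d, t in zip(detected, log):
            assert -0.5 <= d.time - t.time <= 2.5

    def test_tip_count_matches_truth(self, branched_forest):
        forest, tree, log = branched_forest
        assert forest.n_tips(len(forest.graphs) - 1) == tree.tips_at(20.0)


class TestGenerations:
    def test_unbranched_duct_is_generation_zero(self):
        forest = track([_graph_from_mask(_bar()), _graph_from_mask(_bar(), 1)], [0, 0.5])
        assert [t.generation for t in forest.tracks.values()] == [0]

    def test_bifed_chain_generations(self):
        st = dm.ScriptedTree(rate=20.0)
        r = st.add_original((60, 400), 0.0, 30)
        a, b = st.bifed(r, 6.0, (-0.5, 0.5))
        st.bifed(a, 14.0, (-0.5, 0.5))
        tree, _ = st.build(22.0)
        cfg = dm.GrowthConfig(field_size_px=(512, 512), duration_h=22.0,
                              frame_interval_min=30.0)
        forest = dm.analyze_stack(dm.render_stack(tree, cfg))
        gens = sorted(t.generation for t in forest.tracks.values())
        assert gens == [0, 1, 1, 2, 2]

    def test_lateral_child_increments_generation(self, branched_forest):
        forest, tree, log = branched_forest
        lat = [e for e in forest.events if e.type == "lateral"][0]
        child = forest.tracks[lat.child_tracks[0]]
        parent = forest.tracks[lat.parent_track]
        assert child.generation == parent.generation + 1

    def test_assign_generations_recomputes_by_descent(self, branched_forest):
        forest, *_ = branched_forest
        original = {t.track_id: t.generation for t in forest.tracks.values()}
        for t in forest.tracks.values():
            t.generation = 99
        dm.assign_generations(forest)
        assert {t.track_id: t.generation for t in forest.tracks.values()} == original


class TestAmbiguity:
    def test_coarse_sampling_yields_single_ambiguous_event(self, ambiguity_stack):
        stack, *_ = ambiguity_stack
        forest = dm.analyze_stack(stack, times=[0, 10, 20, 30])
        assert len(forest.events) == 1
        e = forest.events[0]
        assert e.ambiguous
        assert set(e.candidates) == {
            "terminal_trifed", "terminal_bifed+terminal_bifed",
        }

    def test_fine_sampling_resolves_two_bifeds(self, ambiguity_stack):
        stack, *_ = ambiguity_stack
        forest = dm.analyze_stack(stack)
        assert [e.type for e in forest.events] == ["terminal_bifed", "terminal_bifed"]
        assert forest.n_ambiguous == 0
        gens = [e.generation for e in forest.events]
        assert gens == [0, 1]

    def test_refinement_monotone_on_fixture(self, ambiguity_stack):
        stack, *_ = ambiguity_stack
        coarse = dm.analyze_stack(stack, times=[0, 10, 20, 30]).n_ambiguous
        mid = dm.analyze_stack(stack, times=[0, 5, 10, 15, 20, 25, 30]).n_ambiguous
        fine = dm.analyze_stack(stack).n_ambiguous
        assert coarse >= mid >= fine

    def test_ambiguous_candidates_bracket_tip_count(self, ambiguity_stack):
        """Counting each candidate resolution, the conservation identity
        brackets the observed tip number."""
        stack, tree, log, _ = ambiguity_stack
        forest = dm.analyze_stack(stack, times=[0, 10, 20, 30])
        n0 = len([t for t in forest.tracks.values() if t.parent_track is None])
        delta = {"terminal_bifed": 1, "terminal_trifed": 2, "lateral": 1}
        lo = hi = n0
        for e in forest.events:
            if not e.ambiguous:
                lo += delta[e.type]
                hi += delta[e.type]
            else:
                deltas = []
                for cand in e.candidates:
                    deltas.append(sum(delta[c] for c in cand.split("+")))
                lo += min(deltas)
                hi += max(deltas)
        tips = forest.n_tips(len(forest.graphs) - 1)
        assert lo <= tips <= hi
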