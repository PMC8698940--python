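"""Oracle validation: compare the image pipeline against simulator truth.

The simulator knows the exact tree and event log behind every rendered
stack, which turns the whole imaging pipeline (rasterize, threshold, thin,
trace, track, classify) into a measurable instrument: segments are matched
to tracks by origin position, generation and lineage, detected events to
true events through that correspondence, and precision/recall are exact
counts, not estimates.

Validation runs use sparse growth in a *clean-separation regime* — the
conditions under which sequential imaging is informative: events at one
locus separated well beyond the frame interval, laterals observably
interior, no event so close to a morphometry mark that its daughters are
still invisible, and no stalled growth.  :func:`sample_clean_run` draws
simulator seeds until a run satisfies the regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GrowthConfig
from .render import render_stack
from .simulate import sample_forest
from .tracking import TrackedForest, TrackingParams, analyze_stack
from .tree import DuctalTree, EventLog

__all__ = [
    "validation_config",
    "clean_separation",
    "sample_clean_run",
    "match_segments_to_tracks",
    "match_events",
    "EventMatchResult",
]


def validation_config(seed: int = 0, duration_h: float = 48.0) -> GrowthConfig:
    """Sparse imaging-validation preset: few ducts, few well-spaced events,
    a field small enough to render quickly."""
    return GrowthConfig(
        lobe_preset="custom",
        n_original_ducts=3,
        initial_bud_length_um=40.0,
        elongation_rate_um_h=20.0,
        tip_branch_hazard_per_h=0.012,
        event_type_probs=(0.45, 0.2, 0.35),
        max_generation=3,
        duration_h=duration_h,
        frame_interval_min=30.0,
        seed=seed,
        field_size_px=(640, 640),
        duct_spacing_um=260.0,
        fan_half_angle_rad=0.35,
    )


def clean_separation(
    tree: DuctalTree,
    log: EventLog,
    marks=None,
    min_gap_h: float = 2.5,
    locus_radius_um: float = 80.0,
    mark_margin_h: float = 3.0,
    min_tip_margin_um: float = 35.0,
    end_margin_h: float = 3.0,
) -> bool:
    """True when a run is in the clean-separation regime.

    Conditions: no two events closer than ``locus_radius_um`` in space and
    ``min_gap_h`` in time; every lateral at least ``min_tip_margin_um``
    from its parent's tip at event time; no event within ``mark_margin_h``
    before a morphometry mark (daughters must be visible by the mark); no
    stalled segments; at least one event.
    """
    if len(log) == 0:
        return False
    if any(s.stalled for s in tree.segments.values()):
        return False
    ev = list(log)
    # an event right before the end of imaging has invisible daughters:
    # no instrument could detect it within the imaged span
    if any(e.time > tree.duration - end_margin_h for e in ev):
        return False
    pos = []
    for e in ev:
        parent = tree.segments[e.parent_segment_id]
        if e.type == "lateral":
            child = tree.segments[e.child_segment_ids[0]]
            p = child.points[0]
            tip_arc = parent.length_at(e.time)
            attach_arc = e.attachment_fraction * tip_arc
            if tip_arc - attach_arc < min_tip_margin_um:
                return False
        else:
            p = parent.points_at(e.time)[-1]
        pos.append(np.asarray(p))
    for i in range(len(ev)):
        for j in range(i + 1, len(ev)):
            if (
                abs(ev[i].time - ev[j].time) < min_gap_h
                and np.linalg.norm(pos[i] - pos[j]) < locus_radius_um
            ):
                return False
    if marks is not None:
        for e in ev:
            for m in marks:
                if 0 <= m - e.time < mark_margin_h:
                    return False
    return True


def sample_clean_run(
    base_seed: int,
    duration_h: float = 48.0,
    marks=None,
    max_tries: int = 200,
):
    """Draw seeds (base_seed, base_seed+10000, ...) until a clean run is
    found; returns (config, tree, log)."""
    for k in range(max_tries):
        cfg = validation_config(seed=base_seed + 10000 * k, duration_h=duration_h)
        tree, log = sample_forest(cfg)
        if clean_separation(tree, log, marks=marks):
            return cfg, tree, log
    raise RuntimeError("no clean-separation run found; loosen the regime")


# ----------------------------------------------------------------------
def match_segments_to_tracks(
    tree: DuctalTree, forest: TrackedForest, tol_um: float = 30.0
) -> dict[int, int]:
    """segment_id -> track_id by origin position, generation and lineage."""
    px = forest.params.pixel_size_um
    mapping: dict[int, int] = {}
    used: set[int] = set()
    # match by increasing generation so parents map before children
    for seg in sorted(tree.segments.values(), key=lambda s: (s.generation, s.birth_time)):
        seg_origin = seg.points[0]  # (x, y) um
        best, best_d = None, np.inf
        for tr in forest.tracks.values():
            if tr.track_id in used or tr.generation != seg.generation:
                continue
            if seg.parent_id is not None:
                want = mapping.get(seg.parent_id)
                if want is None or tr.parent_track != want:
                    continue
            tr_origin = np.array([tr.origin_px[1], tr.origin_px[0]]) * px
            d = float(np.linalg.norm(tr_origin - seg_origin))
            if d < best_d:
                best, best_d = tr.track_id, d
        if best is not None and best_d <= tol_um:
            mapping[seg.segment_id] = best
            used.add(best)
    return mapping


@dataclass
class EventMatchResult:
    n_true: int
    n_detected: int
    n_matched: int
    n_ambiguous: int

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else 1.0

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else 1.0


def match_events(
    log: EventLog,
    tree: DuctalTree,
    forest: TrackedForest,
    tol_h: float = 2.5,
) -> EventMatchResult:
    """Match detected events to true events on (parent, type, generation).

    A detected event matches a true event when the parent track maps to the
    true parent segment, types and parent generations agree, and the
    detection interval midpoint is within ``tol_h`` of the true time
    (detection lags truth by the daughters' protrusion time).
    """
    seg2track = match_segments_to_tracks(tree, forest)
    gen_of = {s.segment_id: s.generation for s in tree.segments.values()}
    detected = [e for e in forest.events]
    used: set[int] = set()
    n_matched = 0
    for te in log:
        want_track = seg2track.get(te.parent_segment_id)
        for de in detected:
            if de.event_id in used or de.ambiguous:
                continue
            if (
                de.parent_track == want_track
                and de.type == te.type
                and de.generation == gen_of[te.parent_segment_id]
                and -0.5 <= de.time - te.time <= tol_h
            ):
                used.add(de.event_id)
                n_matched += 1
                break
    return EventMatchResult(
        n_true=len(log),
        n_detected=len(detected),
        n_matched=n_matched,
        n_ambiguous=sum(e.ambiguous for e in detected),
    )


def validate_stack(base_seed: int, duration_h: float = 48.0, marks=None):
    """One full oracle round trip; returns (result, tree, log, forest)."""
    cfg, tree, log = sample_clean_run(base_seed, duration_h, marks=marks)
    stack = render_stack(tree, cfg)
    params = TrackingParams(
        duct_width_um=cfg.duct_width_um, pixel_size_um=cfg.pixel_size_um
    )
    forest = analyze_stack(stack, params=params)
    return match_events(log, tree, forest), tree, log, forest
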