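"""Ground-truth ductal trees, branching events, and oracle metrics.

A :class:`DuctalTree` is a rooted forest of elongating duct segments in
continuous um coordinates.  Every polyline vertex carries the time it was
laid down, so the full growth history — not just the end state — is
recoverable: ``segment.length_at(t)`` and ``tree.tips_at(t)`` reconstruct
any intermediate frame exactly.

:class:`BranchEvent` records one branching event of the three-type taxonomy
(terminal bifed, terminal trifed, lateral side branch).  Terminal events
consume the parent tip (attachment fraction 1, two or three children);
lateral events attach a single child strictly inside the parent and leave
the parent tip growing.

:class:`ScriptedTree` builds exact straight-line trees from a scripted
event list — the deterministic fixture generator used throughout the test
suite and for the classic three-tip ambiguity stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "DuctalTree",
    "BranchEvent",
    "EventLog",
    "ScriptedTree",
    "ground_truth_metrics",
    "EVENT_TYPES",
]

EVENT_TYPES = ("terminal_bifed", "terminal_trifed", "lateral")

#: tip-count increment per event type (bifed: 2 children replace 1 tip, etc.)
TIP_DELTA = {"terminal_bifed": 1, "terminal_trifed": 2, "lateral": 1}


@dataclass
class Segment:
    """One duct segment: a timed polyline from its birth point to its tip."""

    segment_id: int
    parent_id: int | None
    generation: int
    birth_time: float
    points: np.ndarray          # (n, 2) um
    point_times: np.ndarray     # (n,) h, non-decreasing
    active_tip: bool = True     # False after a terminal event consumed it
    stalled: bool = False       # growth blocked (collision); still a tip
    attachment_fraction: float | None = None  # 1.0 terminal, (0,1) lateral
    base_direction: float = 0.0  # radians, direction at birth

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.point_times = np.asarray(self.point_times, dtype=float)
        if len(self.points) != len(self.point_times):
            raise ValueError("points and point_times must have equal length")

    # cached cumulative arc length
    @property
    def _cumlen(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def length(self) -> float:
        return float(self._cumlen[-1]) if len(self.points) > 1 else 0.0

    def n_points_at(self, t: float) -> int:
        return int(np.searchsorted(self.point_times, t, side="right"))

    def length_at(self, t: float) -> float:
        n = self.n_points_at(t)
        if n < 2:
            return 0.0
        return float(self._cumlen[n - 1])

    def points_at(self, t: float) -> np.ndarray:
        return self.points[: self.n_points_at(t)]

    def point_at_arc(self, s: float) -> np.ndarray:
        """Interpolated point at arc-length ``s`` from the segment origin."""
        c = self._cumlen
        s = float(np.clip(s, 0.0, c[-1]))
        i = int(np.searchsorted(c, s, side="right")) - 1
        i = min(i, len(c) - 2) if len(c) > 1 else 0
        if len(self.points) == 1 or c[i + 1] == c[i]:
            return self.points[i].copy()
        f = (s - c[i]) / (c[i + 1] - c[i])
        return self.points[i] * (1 - f) + self.points[i + 1] * f


@dataclass
class BranchEvent:
    event_id: int
    time: float
    type: str  # one of EVENT_TYPES
    parent_segment_id: int
    attachment_fraction: float
    child_segment_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        n = len(self.child_segment_ids)
        if self.type == "terminal_bifed" and (n != 2 or self.attachment_fraction != 1.0):
            raise ValueError("terminal_bifed needs 2 children at fraction 1")
        if self.type == "terminal_trifed" and (n != 3 or self.attachment_fraction != 1.0):
            raise ValueError("terminal_trifed needs 3 children at fraction 1")
        if self.type == "lateral" and (
            n != 1 or not 0.0 < self.attachment_fraction < 1.0
        ):
            raise ValueError("lateral needs 1 child at interior fraction")


class EventLog:
    """Time-ordered list of ground-truth branching events."""

    def __init__(self, events: Iterable[BranchEvent] = ()) -> None:
        self.events: list[BranchEvent] = sorted(events, key=lambda e: e.time)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def up_to(self, t: float) -> list[BranchEvent]:
        return [e for e in self.events if e.time <= t]

    def counts_up_to(self, t: float) -> dict[str, int]:
        c = {k: 0 for k in EVENT_TYPES}
        for e in self.up_to(t):
            c[e.type] += 1
        return c

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                event_id=e.event_id,
                time_h=e.time,
                type=e.type,
                parent_segment=e.parent_segment_id,
                attachment_fraction=e.attachment_fraction,
                children=";".join(str(c) for c in e.child_segment_ids),
            )
            for e in self.events
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "event_id",
                "time_h",
                "type",
                "parent_segment",
                "attachment_fraction",
                "children",
            ],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventLog":
        df = pd.read_csv(path, dtype={"children": str})
        events = [
            BranchEvent(
                event_id=int(r.event_id),
                time=float(r.time_h),
                type=str(r.type),
                parent_segment_id=int(r.parent_segment),
                attachment_fraction=float(r.attachment_fraction),
                child_segment_ids=tuple(int(c) for c in str(r.children).split(";")),
            )
            for r in df.itertuples()
        ]
        return cls(events)


class DuctalTree:
    """Rooted forest of duct segments anchored on the UGS line."""

    def __init__(
        self,
        segments: Iterable[Segment],
        root_anchor: tuple[tuple[float, float], tuple[float, float]],
        duration: float,
    ) -> None:
        self.segments: dict[int, Segment] = {s.segment_id: s for s in segments}
        self.root_anchor = root_anchor  # ((x0,y0),(x1,y1)) in um
        self.duration = float(duration)
        self._validate()

    def _validate(self) -> None:
        for s in self.segments.values():
            if s.parent_id is None:
                if s.generation != 0:
                    raise ValueError("original ducts must be generation 0")
            else:
                p = self.segments[s.parent_id]
                if s.generation != p.generation + 1:
                    raise ValueError(
                        f"segment {s.segment_id}: generation must be parent+1"
                    )
                if s.birth_time < p.birth_time - 1e-9:
                    raise ValueError("child born before its parent")

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.segments)

    @property
    def max_generation(self) -> int:
        return max(s.generation for s in self.segments.values())

    def children_of(self, segment_id: int) -> list[Segment]:
        return [s for s in self.segments.values() if s.parent_id == segment_id]

    def segments_at(self, t: float) -> list[Segment]:
        return [s for s in self.segments.values() if s.birth_time <= t + 1e-9]

    def tips_at(self, t: float) -> int:
        """Free ductal endpoints at time t.

        A segment's distal end is a tip until a terminal event (a child
        with attachment fraction 1) consumes it; lateral children leave the
        parent tip intact.  Stalled tips are still free ends.
        """
        n = 0
        for s in self.segments_at(t):
            consumed = any(
                c.attachment_fraction == 1.0 and c.birth_time <= t + 1e-9
                for c in self.children_of(s.segment_id)
            )
            if not consumed:
                n += 1
        return n

    def total_length_at(self, t: float) -> float:
        return sum(s.length_at(t) for s in self.segments_at(t))

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        pts = np.vstack([s.points for s in self.segments.values()])
        return pts.min(axis=0), pts.max(axis=0)

    # ------------------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        d = dict(
            duration=self.duration,
            root_anchor=[list(self.root_anchor[0]), list(self.root_anchor[1])],
            segments=[
                dict(
                    segment_id=s.segment_id,
                    parent_id=s.parent_id,
                    generation=s.generation,
                    birth_time=s.birth_time,
                    active_tip=s.active_tip,
                    stalled=s.stalled,
                    attachment_fraction=s.attachment_fraction,
                    base_direction=s.base_direction,
                    points=np.round(s.points, 4).tolist(),
                    point_times=np.round(s.point_times, 6).tolist(),
                )
                for s in self.segments.values()
            ],
        )
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "DuctalTree":
        d = json.loads(Path(path).read_text())
        segs = [
            Segment(
                segment_id=s["segment_id"],
                parent_id=s["parent_id"],
                generation=s["generation"],
                birth_time=s["birth_time"],
                points=np.array(s["points"]),
                point_times=np.array(s["point_times"]),
                active_tip=s["active_tip"],
                stalled=s["stalled"],
                attachment_fraction=s["attachment_fraction"],
                base_direction=s["base_direction"],
            )
            for s in d["segments"]
        ]
        anchor = (tuple(d["root_anchor"][0]), tuple(d["root_anchor"][1]))
        return cls(segs, anchor, d["duration"])


# ----------------------------------------------------------------------
def ground_truth_metrics(
    tree: DuctalTree,
    log: EventLog,
    times: Sequence[float],
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Oracle morphometry computed directly from the ground truth.

    One row per (time, generation) present at any requested time, with the
    aggregate ductal length and segment count of that generation, the
    cumulative branch events keyed by the generation of the *parent*
    segment, per-type cumulative counts, and (repeated per time) the total
    tip number and maximum generation reached.
    """
    times = sorted(times)
    if times and (times[0] < -1e-9 or times[-1] > tree.duration + 1e-9):
        raise ValueError("requested times outside the simulated duration")
    gen_of = {s.segment_id: s.generation for s in tree.segments.values()}
    max_gen = tree.max_generation
    rows = []
    for t in times:
        tips = tree.tips_at(t)
        reached = max((s.generation for s in tree.segments_at(t)), default=0)
        events_t = log.up_to(t)
        for g in range(max_gen + 1):
            segs = [s for s in tree.segments_at(t) if s.generation == g]
            ev_g = [e for e in events_t if gen_of[e.parent_segment_id] == g]
            rows.append(
                dict(
                    sample_id=sample_id,
                    time_h=t,
                    generation=g,
                    aggregate_length_um=sum(s.length_at(t) for s in segs),
                    n_segments=len(segs),
                    cum_branch_events=len(ev_g),
                    cum_bifed=sum(e.type == "terminal_bifed" for e in ev_g),
                    cum_trifed=sum(e.type == "terminal_trifed" for e in ev_g),
                    cum_lateral=sum(e.type == "lateral" for e in ev_g),
                    total_tips=tips,
                    max_generation=reached,
                )
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
class ScriptedTree:
    """Deterministic straight-line tree builder for fixtures and tests.

    Segments elongate at a constant rate along fixed directions; events
    happen at scripted times.  Example::

        st = ScriptedTree(rate=15.0)
        root = st.add_original((60, 250), direction=0.0, initial_length=30)
        a, b = st.bifed(root, time=20.0)
        st.bifed(a, time=20.67)          # 40 min later -> ambiguity fixture
        tree, log = st.build(duration=30.0)
    """

    def __init__(self, rate: float = 15.0, step_um: float = 2.0) -> None:
        self.rate = float(rate)
        self.step = float(step_um)
        self._specs: list[dict] = []
        self._events: list[dict] = []

    def add_original(
        self,
        origin: tuple[float, float],
        direction: float = 0.0,
        initial_length: float = 30.0,
        t0: float = 0.0,
    ) -> int:
        sid = len(self._specs)
        self._specs.append(
            dict(
                parent=None,
                generation=0,
                birth=t0,
                origin=np.array(origin, float),
                direction=float(direction),
                initial_length=float(initial_length),
                end_time=None,
                attachment_fraction=None,
            )
        )
        return sid

    def _child(self, parent: int, time: float, direction: float, frac: float) -> int:
        p = self._specs[parent]
        sid = len(self._specs)
        if frac == 1.0:
            origin = self._tip_position(parent, time)
        else:
            origin = self._position_at_arc_fraction(parent, time, frac)
        self._specs.append(
            dict(
                parent=parent,
                generation=p["generation"] + 1,
                birth=float(time),
                origin=origin,
                direction=p["direction"] + float(direction),
                initial_length=0.0,
                end_time=None,
                attachment_fraction=frac,
            )
        )
        return sid

    def _length_at(self, sid: int, t: float) -> float:
        s = self._specs[sid]
        end = s["end_time"] if s["end_time"] is not None else t
        t_eff = min(t, end)
        return s["initial_length"] + self.rate * max(0.0, t_eff - s["birth"])

    def _tip_position(self, sid: int, t: float) -> np.ndarray:
        s = self._specs[sid]
        L = self._length_at(sid, t)
        d = np.array([np.cos(s["direction"]), np.sin(s["direction"])])
        return s["origin"] + L * d

    def _position_at_arc_fraction(self, sid: int, t: float, frac: float) -> np.ndarray:
        s = self._specs[sid]
        L = self._length_at(sid, t) * frac
        d = np.array([np.cos(s["direction"]), np.sin(s["direction"])])
        return s["origin"] + L * d

    def bifed(
        self, parent: int, time: float, angles: tuple[float, float] = (-0.5, 0.5)
    ) -> tuple[int, int]:
        if self._specs[parent]["end_time"] is not None:
            raise ValueError("parent tip already consumed by a terminal event")
        self._specs[parent]["end_time"] = float(time)
        kids = tuple(self._child(parent, time, a, 1.0) for a in angles)
        self._events.append(
            dict(time=time, type="terminal_bifed", parent=parent, frac=1.0, kids=kids)
        )
        return kids

    def trifed(
        self,
        parent: int,
        time: float,
        angles: tuple[float, float, float] = (-0.6, 0.0, 0.6),
    ) -> tuple[int, int, int]:
        if self._specs[parent]["end_time"] is not None:
            raise ValueError("parent tip already consumed by a terminal event")
        self._specs[parent]["end_time"] = float(time)
        kids = tuple(self._child(parent, time, a, 1.0) for a in angles)
        self._events.append(
            dict(time=time, type="terminal_trifed", parent=parent, frac=1.0, kids=kids)
        )
        return kids

    def lateral(self, parent: int, time: float, fraction: float, angle: float = 1.1) -> int:
        if not 0.0 < fraction < 1.0:
            raise ValueError("lateral attachment fraction must be in (0,1)")
        kid = self._child(parent, time, angle, fraction)
        self._events.append(
            dict(time=time, type="lateral", parent=parent, frac=fraction, kids=(kid,))
        )
        return kid

    def build(self, duration: float) -> tuple[DuctalTree, EventLog]:
        segments = []
        for sid, s in enumerate(self._specs):
            L = self._length_at(sid, duration)
            d = np.array([np.cos(s["direction"]), np.sin(s["direction"])])
            arcs = np.arange(0.0, L, self.step)
            arcs = np.append(arcs, L) if (len(arcs) == 0 or arcs[-1] < L) else arcs
            pts = s["origin"][None, :] + arcs[:, None] * d[None, :]
            L0 = s["initial_length"]
            times = np.where(
                arcs <= L0 + 1e-12, s["birth"], s["birth"] + (arcs - L0) / self.rate
            )
            consumed = s["end_time"] is not None
            segments.append(
                Segment(
                    segment_id=sid,
                    parent_id=s["parent"],
                    generation=s["generation"],
                    birth_time=s["birth"],
                    points=pts,
                    point_times=times,
                    active_tip=not consumed,
                    attachment_fraction=s["attachment_fraction"],
                    base_direction=s["direction"],
                )
            )
        # anchor: vertical line through the original origins
        origins = [s["origin"] for s in self._specs if s["parent"] is None]
        x0 = float(min(o[0] for o in origins))
        ys = [float(o[1]) for o in origins]
        anchor = ((x0, min(ys) - 50.0), (x0, max(ys) + 50.0))
        log = EventLog(
            BranchEvent(
                event_id=i,
                time=e["time"],
                type=e["type"],
                parent_segment_id=e["parent"],
                attachment_fraction=e["frac"],
                child_segment_ids=e["kids"],
            )
            for i, e in enumerate(sorted(self._events, key=lambda e: e["time"]))
        )
        return DuctalTree(segments, anchor, duration), log
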