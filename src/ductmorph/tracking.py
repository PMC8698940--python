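"""Temporal linking of skeleton graphs, generation labels, event detection.

The tracker walks the frame sequence once, maintaining one *track* per duct
segment.  Each frame it

1. prunes thinning spurs (tips accepted in the previous frame are
   protected),
2. roots the skeleton graph on the UGS anchor and orients every edge away
   from it,
3. matches branch nodes against the registry of known junctions; a branch
   node seen before is ignored, one adjacent to a very recent event extends
   that event (a trifurcation whose third daughter protrudes one frame
   later upgrades the recorded bifed to a trifed), and a genuinely new
   junction is classified as a *terminal* locus (at/near the distal end of
   the owning track's course) or a *lateral* locus (interior attachment,
   parent tip left intact),
4. analyses each new locus's distal structure and emits detected events,
   opening child tracks with generation = parent + 1 per descent (lateral
   children increment generation exactly like terminal children),
5. advances the tip of every surviving track along its distal path.

Temporal disambiguation: a locus whose structure could have arisen from
more than one event sequence within the bracketing frame interval (e.g.
three tips from a former tip: trifed, or bifed followed by bifed on a
daughter) is resolved using all frames available inside the interval;
sequential explanations are only entertained when the interval is longer
than the minimum event separation the analyst assumes (default 30 min, the
imaging cadence designed to resolve event order).  If several explanations
survive, a single event is emitted with ``ambiguous=True`` and the
candidate set — never silently resolved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .render import FrameStack
from .skeleton import SkeletonGraph, binarize, build_graph, prune_spurs, skeletonize

__all__ = [
    "TrackingParams",
    "Track",
    "DetectedEvent",
    "TrackedForest",
    "TrackingError",
    "UnrootedComponentError",
    "TrackLostError",
    "track",
    "analyze_stack",
    "assign_generations",
    "detect_events",
]


class TrackingError(RuntimeError):
    pass


class UnrootedComponentError(TrackingError):
    pass


class TrackLostError(TrackingError):
    pass


@dataclass
class TrackingParams:
    """Knobs of the tracker, in physical units where possible."""

    duct_width_um: float = 8.0
    pixel_size_um: float = 2.0
    #: minimal true event spacing assumed when weighing sequential
    #: explanations of one locus (the cadence designed to resolve order).
    min_event_separation_h: float = 0.5
    #: spur-pruning threshold; default 2 x duct width.
    prune_length_um: float | None = None
    #: junction merge / terminal-zone scale (1.5 x duct width).
    tip_zone_um: float | None = None
    #: two junctions closer than this may be one trifurcation split by
    #: thinning (2 x duct width): governs trifed candidacy at a locus.
    coincidence_um: float | None = None
    #: skeleton cycles up to this length are thinning artifacts at thick
    #: junction blobs and are collapsed (4.5 x duct width); larger cycles
    #: are genuine duct overlap and error out.
    small_cycle_um: float | None = None
    #: a branch appearing within this radius of a just-recorded event
    #: junction extends that event (late-protruding trifed daughter); a
    #: true trifed's split junction pixels lie within the tube radius,
    #: while a sequential event on a daughter lands farther out.
    upgrade_radius_um: float | None = None
    #: a new junction at most this far proximal of a track's course end is
    #: still a terminal locus (visibility-delay allowance).
    prox_thresh_um: float = 25.0
    upgrade_window_frames: int = 2
    #: +(w/2 - pixel) added per free (tip or root) end of a measured track
    #: length, compensating the end retraction of topological thinning
    #: (a thinned tube retracts about half a width minus one pixel).
    end_correction: bool = True

    def __post_init__(self) -> None:
        if self.prune_length_um is None:
            self.prune_length_um = 2.0 * self.duct_width_um
        if self.tip_zone_um is None:
            self.tip_zone_um = 1.5 * self.duct_width_um
        if self.coincidence_um is None:
            self.coincidence_um = 2.0 * self.duct_width_um
        if self.small_cycle_um is None:
            self.small_cycle_um = 4.5 * self.duct_width_um
        if self.upgrade_radius_um is None:
            self.upgrade_radius_um = (
                self.duct_width_um / 2.0 + 2.0 * self.pixel_size_um
            )

    @property
    def tip_zone_px(self) -> float:
        return self.tip_zone_um / self.pixel_size_um

    @property
    def lost_tol_px(self) -> float:
        return max(6.0, 2.0 * self.duct_width_um / self.pixel_size_um)


@dataclass
class Track:
    track_id: int
    parent_track: int | None
    generation: int
    origin_px: np.ndarray
    first_frame: int
    consumed_frame: int | None = None
    end_px: np.ndarray | None = None
    course_pts: list = field(default_factory=list)    # [(row, col)]
    course_frames: list = field(default_factory=list)
    tip_by_frame: dict = field(default_factory=dict)  # frame -> (row, col)

    @property
    def alive(self) -> bool:
        return self.consumed_frame is None

    @property
    def last_tip(self) -> np.ndarray:
        return np.asarray(self.course_pts[-1], dtype=float)


@dataclass
class DetectedEvent:
    event_id: int
    detect_t_a: float
    detect_t_b: float
    type: str | None                 # None only for unresolved complex loci
    parent_track: int
    attachment_fraction: float
    child_tracks: tuple
    generation: int                  # generation of the parent segment
    ambiguous: bool = False
    candidates: tuple = ()
    note: str = ""

    @property
    def time(self) -> float:
        return 0.5 * (self.detect_t_a + self.detect_t_b)


class TrackedForest:
    """Tracks + detected events + the per-frame graphs they came from."""

    def __init__(self, tracks, events, graphs, timestamps, params) -> None:
        self.tracks: dict[int, Track] = tracks
        self.events: list[DetectedEvent] = events
        self.graphs: list[SkeletonGraph] = graphs
        self.timestamps = np.asarray(timestamps, dtype=float)
        self.params: TrackingParams = params

    # ------------------------------------------------------------------
    def n_tips(self, frame: int) -> int:
        """Degree-1 non-root node count of the frame's (pruned) graph."""
        return len(self.graphs[frame].tips)

    def tracks_alive(self, frame: int) -> list[Track]:
        return [t for t in self.tracks.values() if t.first_frame <= frame]

    def measure_length(self, track: Track, frame: int) -> float:
        """Skeleton-measured length of a track at a frame (um).

        The geodesic in the frame graph between the nodes nearest the
        track's origin and its tip (or consuming junction); a parent
        bisected by a lateral spans the lateral junction, so its two graph
        edges are summed.  With ``end_correction`` each free end adds half
        a duct width, compensating thinning end-retraction.
        """
        sg = self.graphs[frame]
        g = sg.graph
        if track.first_frame > frame:
            return 0.0
        if track.consumed_frame is not None and frame >= track.consumed_frame:
            end = track.end_px
            free_ends = 0
        else:
            end = np.asarray(track.tip_by_frame[frame], dtype=float)
            free_ends = 1
        n0 = self._nearest_node(sg, track.origin_px)
        n1 = self._nearest_node(sg, end)
        if track.parent_track is None:
            free_ends += 1  # root end of an original duct
        if n0 == n1:
            length = 0.0
        else:
            try:
                nodes = nx.shortest_path(g, n0, n1, weight="length_um")
            except nx.NetworkXNoPath:
                return 0.0
            # concatenate the edge pixel paths and resample before summing:
            # raw chain-code length overestimates slanted lines by up to 8%,
            # resampling every few pixels removes the digitization bias
            pts = []
            for a, b in zip(nodes[:-1], nodes[1:]):
                d = min(g[a][b].values(), key=lambda e: e["length_um"])
                path = d["path"]
                if np.linalg.norm(path[0] - np.asarray(g.nodes[a]["pos"])) > \
                   np.linalg.norm(path[-1] - np.asarray(g.nodes[a]["pos"])):
                    path = path[::-1]
                pts.extend(path if not pts else path[1:])
            pts = np.asarray(pts, dtype=float)
            keep = np.r_[np.arange(0, len(pts) - 1, 4), len(pts) - 1]
            res = pts[keep]
            length = float(
                np.linalg.norm(np.diff(res, axis=0), axis=1).sum()
                * self.params.pixel_size_um
            )
        if self.params.end_correction:
            w2 = self.params.duct_width_um / 2.0
            length += free_ends * max(w2 - self.params.pixel_size_um, 0.0)
            if track.parent_track is not None:
                # a daughter's medial axis emerges only outside the parent
                # tube: about half a width is buried at the junction
                length += w2
        return length

    @staticmethod
    def _nearest_node(sg: SkeletonGraph, pos) -> int:
        pos = np.asarray(pos, dtype=float)
        best, best_d = None, np.inf
        for n, d in sg.graph.nodes(data=True):
            dist = float(np.linalg.norm(np.asarray(d["pos"]) - pos))
            if dist < best_d:
                best, best_d = n, dist
        return best

    # ------------------------------------------------------------------
    def lineage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    track_id=t.track_id,
                    parent_track=t.parent_track,
                    generation=t.generation,
                    first_frame=t.first_frame,
                    consumed_frame=t.consumed_frame,
                )
                for t in self.tracks.values()
            ]
        )

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    event_id=e.event_id,
                    detect_t_a=e.detect_t_a,
                    detect_t_b=e.detect_t_b,
                    type=e.type,
                    ambiguous=e.ambiguous,
                    candidates="|".join(e.candidates),
                    parent_track=e.parent_track,
                    attachment_fraction=e.attachment_fraction,
                    generation=e.generation,
                )
                for e in self.events
            ],
            columns=[
                "event_id",
                "detect_t_a",
                "detect_t_b",
                "type",
                "ambiguous",
                "candidates",
                "parent_track",
                "attachment_fraction",
                "generation",
            ],
        )

    def to_json(self, path: str | Path) -> None:
        d = dict(
            timestamps=self.timestamps.tolist(),
            tracks=[
                dict(
                    track_id=t.track_id,
                    parent_track=t.parent_track,
                    generation=t.generation,
                    first_frame=t.first_frame,
                    consumed_frame=t.consumed_frame,
                )
                for t in self.tracks.values()
            ],
            events=self.events_frame().to_dict(orient="records"),
        )
        Path(path).write_text(json.dumps(d))

    @property
    def n_ambiguous(self) -> int:
        return sum(e.ambiguous for e in self.events)


# ----------------------------------------------------------------------
# geometry helpers
# ----------------------------------------------------------------------
def _project_polyline(pts: np.ndarray, p: np.ndarray):
    """(min distance, arc length at projection, total arc) of p vs polyline."""
    pts = np.asarray(pts, dtype=float)
    p = np.asarray(p, dtype=float)
    if len(pts) == 1:
        return float(np.linalg.norm(pts[0] - p)), 0.0, 0.0
    seg = np.diff(pts, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    best_d, best_arc = np.inf, 0.0
    for i in range(len(seg)):
        if seglen[i] == 0:
            continue
        t = np.clip(np.dot(p - pts[i], seg[i]) / seglen[i] ** 2, 0.0, 1.0)
        q = pts[i] + t * seg[i]
        d = float(np.linalg.norm(q - p))
        if d < best_d:
            best_d = d
            best_arc = float(cum[i] + t * seglen[i])
    return best_d, best_arc, float(cum[-1])


class _Rooted:
    """Root-distance orientation of one frame graph (a forest)."""

    def __init__(self, sg: SkeletonGraph) -> None:
        self.sg = sg
        g = sg.graph
        roots = sg.roots
        comp_nodes = set(g.nodes)
        if comp_nodes and not roots:
            raise UnrootedComponentError(
                f"frame {sg.frame_index}: no root node on the anchor line"
            )
        self.dist = nx.multi_source_dijkstra_path_length(
            g, roots, weight="length_um"
        ) if roots else {}
        missing = comp_nodes - set(self.dist)
        if missing:
            raise UnrootedComponentError(
                f"frame {sg.frame_index}: component without anchor root "
                f"(e.g. node {next(iter(missing))})"
            )

    def distal_node(self, u, v) -> tuple:
        return (v, u) if self.dist[v] >= self.dist[u] else (u, v)

    def children_edges(self, node):
        """Edges leading distally from a node."""
        out = []
        for u, v, k, d in self.sg.graph.edges(node, keys=True, data=True):
            other = v if u == node else u
            if self.dist[other] > self.dist[node] or (
                self.dist[other] == self.dist[node] and other != node
            ):
                out.append((other, k, d))
        return out

    def parent_edge(self, node):
        for u, v, k, d in self.sg.graph.edges(node, keys=True, data=True):
            other = v if u == node else u
            if self.dist[other] < self.dist[node]:
                return (other, k, d)
        return None

    def subtree(self, node):
        """Nodes strictly distal of ``node`` (DFS over children edges)."""
        seen = {node}
        stack = [node]
        out = []
        while stack:
            n = stack.pop()
            for other, k, d in self.children_edges(n):
                if other not in seen:
                    seen.add(other)
                    out.append(other)
                    stack.append(other)
        return out


# ----------------------------------------------------------------------
# the tracker
# ----------------------------------------------------------------------
class _Tracker:
    def __init__(self, graphs, timestamps, params: TrackingParams) -> None:
        if len(graphs) < 1:
            raise TrackingError("need at least one frame")
        self.raw_graphs = graphs
        self.timestamps = list(timestamps)
        self.p = params
        self.tracks: dict[int, Track] = {}
        self.events: list[DetectedEvent] = []
        self.registry: list[dict] = []   # {pos, event_id|None, frame}
        self.pruned: list[SkeletonGraph] = []

    # -- public --------------------------------------------------------
    def run(self) -> TrackedForest:
        self._init_frame0()
        for f in range(1, len(self.raw_graphs)):
            self._step(f)
        return TrackedForest(
            self.tracks, self.events, self.pruned, self.timestamps, self.p
        )

    # -- helpers -------------------------------------------------------
    def _new_track(self, parent, gen, origin, frame, tip) -> Track:
        t = Track(
            track_id=len(self.tracks),
            parent_track=parent,
            generation=gen,
            origin_px=np.asarray(origin, dtype=float),
            first_frame=frame,
        )
        t.course_pts.append(np.asarray(origin, dtype=float))
        t.course_frames.append(frame)
        self._set_tip(t, frame, tip)
        self.tracks[t.track_id] = t
        return t

    def _set_tip(self, t: Track, frame: int, pos) -> None:
        pos = np.asarray(pos, dtype=float)
        t.tip_by_frame[frame] = pos
        if not np.array_equal(t.course_pts[-1], pos):
            t.course_pts.append(pos)
            t.course_frames.append(frame)

    def _consume(self, t: Track, frame: int, end_pos) -> None:
        t.consumed_frame = frame
        t.end_px = np.asarray(end_pos, dtype=float)
        # retract any course points mistakenly laid beyond the junction
        _, arc_j, total = _project_polyline(np.array(t.course_pts), t.end_px)
        while len(t.course_pts) > 2:
            _, arc_last, _ = _project_polyline(
                np.array(t.course_pts[:-1]), t.end_px
            )
            d_last = np.linalg.norm(t.course_pts[-1] - t.end_px)
            d_prev = np.linalg.norm(t.course_pts[-2] - t.end_px)
            if d_prev < d_last:
                t.course_pts.pop()
                t.course_frames.pop()
            else:
                break
        t.course_pts.append(t.end_px.copy())
        t.course_frames.append(frame)

    def _prune(self, f: int, protected) -> SkeletonGraph:
        sg = self.raw_graphs[f]
        return prune_spurs(
            sg,
            self.p.prune_length_um,
            protected_tips=protected,
            protect_radius_px=self.p.tip_zone_px,
        )

    # -- frame 0 -------------------------------------------------------
    def _init_frame0(self) -> None:
        sg = self._prune(0, None)
        self.pruned.append(sg)
        rooted = _Rooted(sg)
        g = sg.graph
        for root in sg.roots:
            self._init_descend(sg, rooted, root, None, 0, 0)

    def _init_descend(self, sg, rooted, node, parent_track, gen, frame) -> None:
        """Decompose the initial frame into tracks (junctions pre-exist)."""
        origin = sg.pos(node)
        cur = node
        while True:
            kids = rooted.children_edges(cur)
            if len(kids) == 0:
                self._new_track(parent_track, gen, origin, frame, sg.pos(cur))
                return
            if len(kids) == 1 and sg.graph.nodes[cur]["kind"] != "branch":
                cur = kids[0][0]
                continue
            # branch point present in the very first frame
            t = self._new_track(parent_track, gen, origin, frame, sg.pos(cur))
            self._consume(t, frame, sg.pos(cur))
            self.registry.append(dict(pos=sg.pos(cur), event_id=None, frame=frame))
            for other, k, d in kids:
                self._init_descend(sg, rooted, other, t.track_id, gen + 1, frame)
            return

    # -- one frame transition -----------------------------------------
    def _step(self, f: int) -> None:
        protected = [t.last_tip for t in self.tracks.values() if t.alive]
        sg = self._prune(f, protected)
        self.pruned.append(sg)
        rooted = _Rooted(sg)
        g = sg.graph
        t_a, t_b = self.timestamps[f - 1], self.timestamps[f]
        c_px = self.p.tip_zone_px
        px = self.p.pixel_size_um

        # -- classify branch nodes against the registry ----------------
        new_junctions = []
        for n in sg.branch_nodes:
            pos = sg.pos(n)
            matched = False
            for entry in self.registry:
                if np.linalg.norm(entry["pos"] - pos) <= 3.0:
                    entry["pos"] = pos  # follow small drift
                    matched = True
                    break
            if not matched:
                new_junctions.append(n)
        # upgrade pass: adjacent to a very recent event junction
        remaining = []
        for n in new_junctions:
            pos = sg.pos(n)
            upgraded = False
            for entry in self.registry:
                if (
                    entry["event_id"] is not None
                    and f - entry["frame"] <= self.p.upgrade_window_frames
                    and np.linalg.norm(entry["pos"] - pos)
                    <= self.p.upgrade_radius_um / px
                ):
                    self._upgrade_event(sg, rooted, entry["event_id"], n, f)
                    self.registry.append(dict(pos=pos, event_id=entry["event_id"], frame=entry["frame"]))
                    upgraded = True
                    break
            if not upgraded:
                remaining.append(n)
        new_junctions = remaining

        consumed_in_cluster: set = set()
        # -- terminal loci ---------------------------------------------
        # A new junction J is a terminal locus of track T when it lies in
        # T's distal growth: either J is a skeleton-descendant of T's last
        # tip position, or (visibility delay: the tip was mistakenly
        # advanced along one daughter before the junction protruded) J is
        # an ancestor of the tip within the proximal allowance.
        j_rootpath: dict[int, tuple[set, set]] = {}
        for n in new_junctions:
            nodes, edges = set(), set()
            cur = n
            while True:
                nodes.add(cur)
                pe = rooted.parent_edge(cur)
                if pe is None:
                    break
                other, k, d = pe
                edges.add((frozenset((cur, other)), k))
                cur = other
            j_rootpath[n] = (nodes, edges)
        for t in sorted(self.tracks.values(), key=lambda t: t.track_id):
            if not t.alive:
                continue
            dist, (u, v, k, i) = sg.nearest_point(t.last_tip)
            if dist > self.p.lost_tol_px:
                raise TrackLostError(
                    f"frame {f}: track {t.track_id} lost "
                    f"(nearest skeleton {dist:.1f} px from its tip)"
                )
            q_edge = (frozenset((u, v)), k)
            if u == v:
                q_rd = rooted.dist.get(u, 0.0)
                q_nodes: set = {u}
            else:
                d_edge = min(
                    sg.graph[u][v].values(), key=lambda e: e["length_um"]
                )
                path = d_edge["path"]
                arc = (
                    float(
                        np.linalg.norm(
                            np.diff(path[: i + 1], axis=0), axis=1
                        ).sum()
                    )
                    * px
                    if i > 0
                    else 0.0
                )
                prox, dst = (
                    (u, v) if rooted.dist[u] <= rooted.dist[v] else (v, u)
                )
                # path is stored starting at one endpoint; arc measured
                # from path[0]
                start_is_prox = np.linalg.norm(
                    path[0] - np.asarray(sg.graph.nodes[prox]["pos"])
                ) <= np.linalg.norm(
                    path[0] - np.asarray(sg.graph.nodes[dst]["pos"])
                )
                total = d_edge["length_um"]
                q_rd = rooted.dist[prox] + (arc if start_is_prox else total - arc)
                cur, q_nodes = prox, {prox}
                while True:
                    pe = rooted.parent_edge(cur)
                    if pe is None:
                        break
                    cur = pe[0]
                    q_nodes.add(cur)
            matches = []
            for n in new_junctions:
                if n in consumed_in_cluster:
                    continue
                nodes_j, edges_j = j_rootpath[n]
                if q_edge in edges_j or (
                    n in (u, v) and rooted.dist[n] >= q_rd - 1e-9
                ):
                    matches.append(n)  # J distal of the track tip
                elif (
                    n in q_nodes
                    and q_rd - rooted.dist[n] <= self.p.prox_thresh_um
                ):
                    matches.append(n)  # just proximal: delayed visibility
            if not matches:
                continue
            # root the cluster at the most proximal matching junction
            trigger = min(matches, key=lambda n: rooted.dist[n])
            cluster = [trigger] + [
                n
                for n in rooted.subtree(trigger)
                if n in new_junctions and n != trigger
            ]
            for n in cluster:
                consumed_in_cluster.add(n)
            self._terminal_locus(sg, rooted, t, cluster, f, t_a, t_b)
        new_junctions = [n for n in new_junctions if n not in consumed_in_cluster]

        # -- lateral loci ----------------------------------------------
        for n in sorted(new_junctions, key=lambda n: tuple(sg.pos(n))):
            if n in consumed_in_cluster:
                continue
            self._lateral_locus(sg, rooted, n, new_junctions, consumed_in_cluster, f, t_a, t_b)

        # -- advance surviving tips ------------------------------------
        taken = {
            tuple(np.round(t.tip_by_frame[f]))
            for t in self.tracks.values()
            if f in t.tip_by_frame
        }
        for t in sorted(self.tracks.values(), key=lambda t: t.track_id):
            if not t.alive or f in t.tip_by_frame:
                continue
            self._advance_tip(sg, rooted, t, f, taken)

        # -- unclaimed leaves: a daughter protruding late at a recorded
        #    event junction (e.g. the third arm of a trifed) -------------
        claimed = {
            tuple(np.round(t.tip_by_frame[f]))
            for t in self.tracks.values()
            if f in t.tip_by_frame
        }
        for n in sg.tips:
            if tuple(np.round(sg.pos(n))) in claimed:
                continue
            node = n
            while sg.graph.degree(node) < 3:
                pe = rooted.parent_edge(node)
                if pe is None:
                    break
                node = pe[0]
            pos_j = sg.pos(node)
            handled = False
            for entry in self.registry:
                if (
                    entry["event_id"] is not None
                    and f - entry["frame"] <= self.p.upgrade_window_frames
                    and np.linalg.norm(entry["pos"] - pos_j)
                    <= self.p.upgrade_radius_um / px
                ):
                    ev = self.events[entry["event_id"]]
                    child = self._new_track(
                        ev.parent_track, ev.generation + 1, pos_j, f, sg.pos(n)
                    )
                    ev.child_tracks = ev.child_tracks + (child.track_id,)
                    if ev.type == "terminal_bifed" and len(ev.child_tracks) == 3:
                        ev.type = "terminal_trifed"
                        ev.note = (ev.note + " upgraded to trifed").strip()
                    elif len(ev.child_tracks) > 3:
                        ev.ambiguous = True
                        ev.note = (ev.note + " >3 children at one locus").strip()
                    handled = True
                    break
            if not handled:
                raise TrackingError(
                    f"frame {f}: new tip at {tuple(np.round(sg.pos(n), 1))} "
                    "has no identifiable parent"
                )

    # ------------------------------------------------------------------
    def _upgrade_event(self, sg, rooted, event_id, junction, f) -> None:
        """A branch appearing at a just-recorded event locus: extra child."""
        ev = self.events[event_id]
        parent = self.tracks[ev.parent_track]
        known_tips = [
            self.tracks[c].last_tip for c in ev.child_tracks
        ]
        for other, k, d in rooted.children_edges(junction):
            leaves = self._leaves_under(sg, rooted, junction, other)
            for leaf in leaves:
                pos = sg.pos(leaf)
                if any(np.linalg.norm(pos - kt) <= self.p.lost_tol_px for kt in known_tips):
                    continue
                child = self._new_track(
                    ev.parent_track, ev.generation + 1, sg.pos(junction), f, pos
                )
                ev.child_tracks = ev.child_tracks + (child.track_id,)
                if ev.type == "terminal_bifed" and len(ev.child_tracks) == 3:
                    ev.type = "terminal_trifed"
                    ev.note = (ev.note + " upgraded to trifed").strip()
                elif len(ev.child_tracks) > 3:
                    ev.ambiguous = True
                    ev.note = (ev.note + " >3 children at one locus").strip()

    def _branch_contains_tip(self, sg, rooted, node, child_node, tips) -> bool:
        """Does the distal branch entered via child_node pass within the
        matching tolerance of any recorded track tip?"""
        if len(tips) == 0:
            return False
        tol = self.p.lost_tol_px

        def edge_hit(d) -> bool:
            path = d["path"]
            dmin = np.min(
                np.linalg.norm(path[:, None, :] - tips[None, :, :], axis=2)
            )
            return dmin <= tol

        for d in sg.graph[node][child_node].values():
            if edge_hit(d):
                return True
        seen = {node, child_node}
        stack = [child_node]
        while stack:
            a = stack.pop()
            for other, k, d in rooted.children_edges(a):
                if other in seen:
                    continue
                if edge_hit(d):
                    return True
                seen.add(other)
                stack.append(other)
        return False

    def _leaves_under(self, sg, rooted, node, child_node):
        """Leaf nodes in the subtree entered via child_node."""
        leaves = []
        if sg.graph.degree(child_node) == 1:
            return [child_node]
        seen = {node, child_node}
        stack = [child_node]
        while stack:
            n = stack.pop()
            kids = [e for e in rooted.children_edges(n) if e[0] not in seen]
            if not kids and sg.graph.degree(n) == 1:
                leaves.append(n)
            for other, k, d in kids:
                seen.add(other)
                stack.append(other)
        return leaves

    # ------------------------------------------------------------------
    def _terminal_locus(self, sg, rooted, t: Track, cluster, f, t_a, t_b) -> None:
        g = sg.graph
        px = self.p.pixel_size_um
        c_um = self.p.coincidence_um
        # the proximal-most junction of the cluster
        j1 = min(cluster, key=lambda n: rooted.dist[n])
        leaves = []
        for other, k, d in rooted.children_edges(j1):
            leaves.extend(self._leaves_under(sg, rooted, j1, other))
        leaves = sorted(set(leaves), key=lambda n: tuple(sg.pos(n)))
        interval = t_b - t_a
        feasible_two = interval > self.p.min_event_separation_h + 1e-9

        def geod(a, b):
            return nx.shortest_path_length(g, a, b, weight="length_um")

        self._consume(t, f, sg.pos(j1))
        self.registry.append(dict(pos=sg.pos(j1), event_id=len(self.events), frame=f))
        gen = t.generation

        if len(cluster) == 1 and len(leaves) == 2:
            ev = self._emit(
                "terminal_bifed", t, 1.0, f, t_a, t_b, gen,
            )
            for leaf in leaves:
                c = self._new_track(t.track_id, gen + 1, sg.pos(j1), f, sg.pos(leaf))
                ev.child_tracks = ev.child_tracks + (c.track_id,)
            return
        if len(cluster) == 1 and len(leaves) == 3:
            # one merged junction node carrying three daughters
            ev = self._emit("terminal_trifed", t, 1.0, f, t_a, t_b, gen)
            for leaf in leaves:
                c = self._new_track(t.track_id, gen + 1, sg.pos(j1), f, sg.pos(leaf))
                ev.child_tracks = ev.child_tracks + (c.track_id,)
            return
        if len(cluster) == 2 and len(leaves) == 3:
            j2 = max(cluster, key=lambda n: rooted.dist[n])
            self.registry.append(
                dict(pos=sg.pos(j2), event_id=len(self.events), frame=f)
            )
            d_um = geod(j1, j2)
            # leaf off j1 vs the two beyond j2
            outer = [lf for lf in leaves if not self._through(g, j1, lf, j2)]
            inner = [lf for lf in leaves if lf not in outer]
            if len(outer) != 1 or len(inner) != 2:
                self._complex_locus(sg, t, j1, leaves, f, t_a, t_b)
                return
            lb, lc = (geod(j2, lf) for lf in inner)
            eq_tol = max(8.0, 0.25 * max(lb, lc))
            equal = abs(lb - lc) <= eq_tol
            candidates = []
            if d_um <= c_um:
                candidates.append("terminal_trifed")
            if feasible_two and d_um > 2 * px:
                if equal:
                    candidates.append("terminal_bifed+terminal_bifed")
                else:
                    candidates.append("terminal_bifed+lateral")
            if len(candidates) == 1 and candidates[0] == "terminal_trifed":
                ev = self._emit("terminal_trifed", t, 1.0, f, t_a, t_b, gen)
                for leaf in leaves:
                    c = self._new_track(
                        t.track_id, gen + 1, sg.pos(j1), f, sg.pos(leaf)
                    )
                    ev.child_tracks = ev.child_tracks + (c.track_id,)
                return
            if len(candidates) == 1 and candidates[0] == "terminal_bifed+terminal_bifed":
                ev1 = self._emit("terminal_bifed", t, 1.0, f, t_a, t_b, gen)
                ca = self._new_track(t.track_id, gen + 1, sg.pos(j1), f, sg.pos(outer[0]))
                cm = self._new_track(t.track_id, gen + 1, sg.pos(j1), f, sg.pos(j2))
                self._consume(cm, f, sg.pos(j2))
                ev1.child_tracks = (ca.track_id, cm.track_id)
                ev2 = self._emit(
                    "terminal_bifed", cm, 1.0, f, t_a, t_b, gen + 1,
                    note="resolved sequential bifed-bifed",
                )
                for leaf in inner:
                    cg = self._new_track(
                        cm.track_id, gen + 2, sg.pos(j2), f, sg.pos(leaf)
                    )
                    ev2.child_tracks = ev2.child_tracks + (cg.track_id,)
                return
            if len(candidates) == 1 and candidates[0] == "terminal_bifed+lateral":
                longer, shorter = (
                    (inner[0], inner[1]) if geod(j2, inner[0]) >= geod(j2, inner[1])
                    else (inner[1], inner[0])
                )
                ev1 = self._emit("terminal_bifed", t, 1.0, f, t_a, t_b, gen)
                ca = self._new_track(t.track_id, gen + 1, sg.pos(j1), f, sg.pos(outer[0]))
                cm = self._new_track(t.track_id, gen + 1, sg.pos(j1), f, sg.pos(longer))
                ev1.child_tracks = (ca.track_id, cm.track_id)
                frac = d_um / max(d_um + geod(j2, longer), 1e-9)
                ev2 = self._emit(
                    "lateral", cm, frac, f, t_a, t_b, gen + 1,
                    note="resolved sequential bifed-lateral",
                )
                cl = self._new_track(cm.track_id, gen + 2, sg.pos(j2), f, sg.pos(shorter))
                ev2.child_tracks = (cl.track_id,)
                return
            # several (or zero) surviving explanations -> ambiguous
            primary = "terminal_trifed" if "terminal_trifed" in candidates else None
            ev = self._emit(
                primary, t, 1.0, f, t_a, t_b, gen,
                ambiguous=True, candidates=tuple(candidates),
                note="static interval cannot separate candidate sequences",
            )
            for leaf in leaves:
                c = self._new_track(t.track_id, gen + 1, sg.pos(j1), f, sg.pos(leaf))
                ev.child_tracks = ev.child_tracks + (c.track_id,)
            return
        self._complex_locus(sg, t, j1, leaves, f, t_a, t_b)

    @staticmethod
    def _through(g, a, b, via) -> bool:
        path = nx.shortest_path(g, a, b)
        return via in path

    def _complex_locus(self, sg, t, j1, leaves, f, t_a, t_b) -> None:
        ev = self._emit(
            None, t, 1.0, f, t_a, t_b, t.generation,
            ambiguous=True, candidates=(),
            note=f"complex locus with {len(leaves)} new tips; not separable",
        )
        for leaf in leaves:
            c = self._new_track(t.track_id, t.generation + 1, sg.pos(j1), f, sg.pos(leaf))
            ev.child_tracks = ev.child_tracks + (c.track_id,)

    # ------------------------------------------------------------------
    def _lateral_locus(self, sg, rooted, n, new_junctions, consumed, f, t_a, t_b) -> None:
        pos = sg.pos(n)
        px = self.p.pixel_size_um
        owner, best_d, best_arc, best_total = None, np.inf, 0.0, 0.0
        for t in self.tracks.values():
            course = np.array(t.course_pts)
            dist, arc, total = _project_polyline(course, pos)
            if dist < best_d:
                owner, best_d, best_arc, best_total = t, dist, arc, total
        if owner is None or best_d > self.p.lost_tol_px:
            raise TrackingError(
                f"frame {f}: new junction at {tuple(np.round(pos, 1))} "
                "has no identifiable parent track"
            )
        consumed.add(n)
        self.registry.append(dict(pos=pos, event_id=len(self.events), frame=f))
        # the new daughter branch: a distal branch already carrying another
        # track runs through that track's last recorded tip position, no
        # matter how far the tip has advanced since; branches free of any
        # recorded tip are new growth
        tracked_tips = np.array([
            t.tip_by_frame[max(t.tip_by_frame)]
            for t in self.tracks.values()
            if t.tip_by_frame
        ])
        new_leaves = []
        for other, k, d in rooted.children_edges(n):
            if self._branch_contains_tip(sg, rooted, n, other, tracked_tips):
                continue
            new_leaves.extend(self._leaves_under(sg, rooted, n, other))
        frac = best_arc / max(best_total, 1e-9)
        frac = min(max(frac, 1e-3), 1 - 1e-3)
        gen = owner.generation
        if len(new_leaves) == 1:
            ev = self._emit("lateral", owner, frac, f, t_a, t_b, gen)
            c = self._new_track(owner.track_id, gen + 1, pos, f, sg.pos(new_leaves[0]))
            ev.child_tracks = (c.track_id,)
            return
        # nested structure on a lateral daughter within one interval
        ev = self._emit(
            "lateral", owner, frac, f, t_a, t_b, gen,
            ambiguous=True, candidates=("lateral+terminal_bifed", "lateral+lateral"),
            note="nested growth at an interior locus within one interval",
        )
        for leaf in new_leaves:
            c = self._new_track(owner.track_id, gen + 1, pos, f, sg.pos(leaf))
            ev.child_tracks = ev.child_tracks + (c.track_id,)

    # ------------------------------------------------------------------
    def _advance_tip(self, sg, rooted, t: Track, f, taken) -> None:
        dist, (u, v, k, i) = sg.nearest_point(t.last_tip)
        if dist > self.p.lost_tol_px:
            raise TrackLostError(
                f"frame {f}: track {t.track_id} lost "
                f"(nearest skeleton {dist:.1f} px from its tip)"
            )
        if u == v and sg.graph.degree(u) == 0:
            self._set_tip(t, f, sg.pos(u))
            return
        node, _ = rooted.distal_node(u, v)
        leaf = self._follow_to_leaf(sg, rooted, t, node, taken)
        if leaf is None:
            raise TrackLostError(
                f"frame {f}: track {t.track_id} has no free distal tip"
            )
        self._set_tip(t, f, sg.pos(leaf))
        taken.add(tuple(np.round(sg.pos(leaf))))

    def _follow_to_leaf(self, sg, rooted, t: Track, node, taken):
        if sg.graph.degree(node) == 1:
            return node
        free = []
        for other, k, d in rooted.children_edges(node):
            for lf in self._leaves_under(sg, rooted, node, other):
                if tuple(np.round(sg.pos(lf))) not in taken:
                    free.append(lf)
        if not free:
            return None
        # a tip advances by at most one interval of growth, so the closest
        # free leaf to the previous tip is the track's continuation
        return min(free, key=lambda lf: np.linalg.norm(sg.pos(lf) - t.last_tip))

    # ------------------------------------------------------------------
    def _emit(
        self, etype, parent_track: Track, frac, f, t_a, t_b, gen,
        ambiguous=False, candidates=(), note="",
    ) -> DetectedEvent:
        ev = DetectedEvent(
            event_id=len(self.events),
            detect_t_a=t_a,
            detect_t_b=t_b,
            type=etype,
            parent_track=parent_track.track_id,
            attachment_fraction=float(frac),
            child_tracks=(),
            generation=gen,
            ambiguous=ambiguous,
            candidates=tuple(candidates),
            note=note,
        )
        self.events.append(ev)
        return ev


# ----------------------------------------------------------------------
# public API
# ----------------------------------------------------------------------
def track(
    graphs: list[SkeletonGraph],
    timestamps,
    params: TrackingParams | None = None,
) -> TrackedForest:
    """Link a sequence of skeleton graphs into a tracked forest.

    ``graphs`` are un-pruned measured graphs sharing one pixel grid;
    pruning runs internally so that previously accepted tips are protected.
    Detected events are available on the returned forest and via
    :func:`detect_events`.
    """
    if params is None:
        params = TrackingParams(pixel_size_um=graphs[0].pixel_size)
    return _Tracker(graphs, timestamps, params).run()


def analyze_stack(
    stack: FrameStack,
    times=None,
    params: TrackingParams | None = None,
    threshold: float | None = None,
    anchor_tol_px: float = 6.0,
) -> TrackedForest:
    """Full image pipeline: binarize, skeletonize, trace, track, detect.

    ``times`` selects the analysis cadence (must be a subset of the stack's
    timestamps); by default every frame is used.
    """
    ts = stack.timestamps
    if times is None:
        idx = list(range(len(ts)))
    else:
        idx = [int(np.argmin(np.abs(ts - t))) for t in times]
        for i, t in zip(idx, times):
            if abs(ts[i] - t) > 1e-6:
                raise ValueError(f"requested time {t} h is not a stack frame")
    anchor_x_px = stack.anchor_x_um / stack.pixel_size
    if params is None:
        params = TrackingParams(pixel_size_um=stack.pixel_size)
    graphs = []
    for j, i in enumerate(idx):
        mask = binarize(stack.frames[i], threshold)
        skel = skeletonize(mask)
        graphs.append(
            build_graph(
                skel, stack.pixel_size, anchor_x_px,
                anchor_tol_px=anchor_tol_px, frame_index=j,
                small_cycle_um=params.small_cycle_um,
            )
        )
    return track(graphs, [float(ts[i]) for i in idx], params)


def assign_generations(forest: TrackedForest) -> TrackedForest:
    """Validate and (re)assign generations by descent from the anchor.

    Original ducts rooted on the anchor are generation 0; every child track
    is its parent's generation + 1, whether it arose from a terminal or a
    lateral event.
    """
    for t in forest.tracks.values():
        if t.parent_track is None:
            t.generation = 0
    changed = True
    while changed:
        changed = False
        for t in forest.tracks.values():
            if t.parent_track is not None:
                g = forest.tracks[t.parent_track].generation + 1
                if t.generation != g:
                    t.generation = g
                    changed = True
    for e in forest.events:
        e.generation = forest.tracks[e.parent_track].generation
    return forest


def detect_events(forest: TrackedForest) -> list[DetectedEvent]:
    """The detected event log of a tracked forest (time-ordered)."""
    return sorted(forest.events, key=lambda e: (e.detect_t_b, e.event_id))
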