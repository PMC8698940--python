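"""Continuous-time stochastic simulator of lobe-specific ductal tree growth.

The model is a Gillespie-style marked point process layered on top of a
deterministic elongation geometry:

* Every active tip whose segment generation is below the preset's cap
  carries a constant branching hazard; when a tip event fires, its type is
  drawn from the (bifed, trifed, lateral) probability triple.  A drawn
  "lateral" is re-sited onto a uniform interior position of the tip's own
  segment, so laterals emerge from duct interiors as in tissue.
* An optional second channel generates laterals at a hazard per 100 um of
  eligible duct; because duct length grows linearly between events the
  integrated hazard is quadratic in time and the next event time is solved
  exactly by inverse transform.
* Between events tips elongate at the (generation-dependent) rate along a
  direction performing a bounded random walk; a coarse occupancy grid
  rejects steps that would bring a duct within the clearance distance of a
  foreign duct (with exemptions around shared junctions), so rendered tubes
  never merge.  A tip whose every deflection is blocked stalls: it stops
  growing and branching but remains a free end.

Terminal events consume the parent tip (the two or three children take
over); lateral events leave the parent growing.  A lateral child gets
generation parent+1 exactly like terminal children — generations count
descent, not event type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError, GrowthConfig
from .tree import BranchEvent, DuctalTree, EventLog, Segment, ground_truth_metrics

__all__ = ["sample_forest", "ground_truth_metrics", "SimulationError"]


class SimulationError(RuntimeError):
    """Raised when a run exceeds the configured safety caps."""


_DEFLECTIONS = (0.3, -0.3, 0.6, -0.6, 0.9, -0.9, 1.2, -1.2)


@dataclass
class _Seg:
    """Mutable per-segment growth state."""

    sid: int
    parent: int | None
    generation: int
    birth: float
    origin: np.ndarray
    base_dir: float
    theta: float
    xs: list = field(default_factory=list)
    ys: list = field(default_factory=list)
    times: list = field(default_factory=list)
    laid: float = 0.0      # arc length laid so far (um)
    carry: float = 0.0     # sub-step growth not yet laid
    active: bool = True    # tip not consumed by a terminal event
    stalled: bool = False
    attachment_fraction: float | None = None
    children: list = field(default_factory=list)

    @property
    def tip(self) -> np.ndarray:
        return np.array([self.xs[-1], self.ys[-1]])


class _Grid:
    """Coarse single-writer occupancy grid for clearance checks."""

    def __init__(self, size_um: tuple[float, float], cell: float = 6.0) -> None:
        self.cell = cell
        self.nx = int(size_um[1] / cell) + 3
        self.ny = int(size_um[0] / cell) + 3
        self.sid = np.full((self.ny, self.nx), -1, dtype=np.int32)
        self.px = np.zeros((self.ny, self.nx))
        self.py = np.zeros((self.ny, self.nx))
        self.arc = np.zeros((self.ny, self.nx))
        r = 3  # neighbourhood radius in cells (3*6um=18um >= clearance)
        off = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)]
        self.off = np.array(off)

    def write(self, xs, ys, arcs, sid: int) -> None:
        ix = (np.asarray(xs) / self.cell).astype(int) + 1
        iy = (np.asarray(ys) / self.cell).astype(int) + 1
        self.sid[iy, ix] = sid
        self.px[iy, ix] = xs
        self.py[iy, ix] = ys
        self.arc[iy, ix] = arcs

    def neighbours(self, pts: np.ndarray):
        """For each point: stored (sid, x, y, arc) over the neighbourhood."""
        ix = (pts[:, 0] / self.cell).astype(int) + 1
        iy = (pts[:, 1] / self.cell).astype(int) + 1
        gy = np.clip(iy[:, None] + self.off[None, :, 0], 0, self.ny - 1)
        gx = np.clip(ix[:, None] + self.off[None, :, 1], 0, self.nx - 1)
        return self.sid[gy, gx], self.px[gy, gx], self.py[gy, gx], self.arc[gy, gx]


class _Sim:
    def __init__(self, config: GrowthConfig) -> None:
        config.validate()
        if config.expected_event_bound() > config.max_events:
            raise ConfigError(
                "runaway growth: expected event count "
                f"~{config.expected_event_bound():.0f} exceeds the safety cap "
                f"{config.max_events}; reduce hazards or duration"
            )
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        h_px, w_px = config.field_size_px
        self.size_um = (h_px * config.pixel_size_um, w_px * config.pixel_size_um)
        self.grid = _Grid(self.size_um)
        self.margin = config.duct_width_um
        self.segs: list[_Seg] = []
        self.events: list[BranchEvent] = []
        self.t = 0.0

    # ------------------------------------------------------------------
    def run(self) -> tuple[DuctalTree, EventLog]:
        cfg = self.cfg
        self._init_originals()
        while True:
            lam_tip, lam_lat0, slope = self._rates()
            exp_draw = self.rng.exponential()
            tau = self._solve_tau(lam_tip + lam_lat0, slope, exp_draw)
            t_next = min(self.t + tau, cfg.duration_h)
            self._advance_all(t_next - self.t)
            self.t = t_next
            if self.t >= cfg.duration_h - 1e-12:
                break
            if len(self.events) >= cfg.max_events:
                raise SimulationError(
                    f"event count exceeded safety cap {cfg.max_events}"
                )
            lam_lat = lam_lat0 + slope * tau
            total = lam_tip + lam_lat
            if total <= 0:
                continue
            if self.rng.random() < lam_tip / total:
                self._tip_event()
            else:
                self._length_lateral_event()
        self._flush_carry()
        return self._finalize()

    # ------------------------------------------------------------------
    def _init_originals(self) -> None:
        cfg = self.cfg
        n = cfg.n_original_ducts
        if isinstance(n, (tuple, list)):
            n = int(self.rng.integers(n[0], n[1] + 1))
        x0 = cfg.anchor_margin_um
        cy = self.size_um[0] / 2.0
        ys = cy + (np.arange(n) - (n - 1) / 2.0) * cfg.duct_spacing_um
        half = cfg.fan_half_angle_rad
        for i in range(n):
            frac = 0.0 if n == 1 else (i - (n - 1) / 2.0) / ((n - 1) / 2.0)
            base = frac * half + self.rng.uniform(-0.05, 0.05)
            seg = _Seg(
                sid=len(self.segs),
                parent=None,
                generation=0,
                birth=0.0,
                origin=np.array([x0, ys[i]]),
                base_dir=base,
                theta=base,
            )
            self.segs.append(seg)
            self._lay_bud(seg, cfg.initial_bud_length_um)

    def _lay_bud(self, seg: _Seg, length: float) -> None:
        step = self.cfg.step_um
        arcs = list(np.arange(0.0, length, step))
        if not arcs or arcs[-1] < length:
            arcs.append(length)
        d = np.array([math.cos(seg.base_dir), math.sin(seg.base_dir)])
        for a in arcs:
            p = seg.origin + a * d
            seg.xs.append(p[0])
            seg.ys.append(p[1])
            seg.times.append(seg.birth)
        seg.laid = arcs[-1]
        self.grid.write(seg.xs, seg.ys, arcs, seg.sid)

    # ------------------------------------------------------------------
    def _eligible_tips(self) -> list[_Seg]:
        mg = self.cfg.max_generation
        return [
            s
            for s in self.segs
            if s.active and not s.stalled and s.generation < mg
        ]

    def _rates(self) -> tuple[float, float, float]:
        cfg = self.cfg
        tips = self._eligible_tips()
        lam_tip = cfg.tip_branch_hazard_per_h * len(tips)
        h_lat = cfg.lateral_hazard_per_h_per_100um / 100.0
        lam_lat0 = 0.0
        slope = 0.0
        if h_lat > 0:
            length = sum(
                s.laid for s in self.segs if s.generation < cfg.max_generation
            )
            lam_lat0 = h_lat * length
            slope = h_lat * sum(
                cfg.rate_for_generation(s.generation)
                for s in self.segs
                if s.active and not s.stalled and s.generation < cfg.max_generation
            )
        return lam_tip, lam_lat0, slope

    @staticmethod
    def _solve_tau(lam0: float, slope: float, e: float) -> float:
        if lam0 <= 0 and slope <= 0:
            return math.inf
        if slope <= 1e-15:
            return e / lam0
        # lam0*tau + slope*tau^2/2 = e
        return (-lam0 + math.sqrt(lam0 * lam0 + 2.0 * slope * e)) / slope

    # ------------------------------------------------------------------
    def _advance_all(self, dt: float) -> None:
        if dt <= 0:
            return
        for seg in self.segs:
            if seg.active and not seg.stalled:
                self._advance(seg, dt)

    def _advance(self, seg: _Seg, dt: float) -> None:
        cfg = self.cfg
        rate = cfg.rate_for_generation(seg.generation)
        if rate <= 0:
            return
        step = cfg.step_um
        growth = rate * dt + seg.carry
        n = int(growth / step)
        carry0 = seg.carry
        seg.carry = growth - n * step
        if n == 0:
            return
        t0 = self.t
        jit = self.rng.normal(0.0, cfg.waviness_rad, n)
        lo = seg.base_dir - cfg.max_deviation_rad
        hi = seg.base_dir + cfg.max_deviation_rad
        # propose the whole chunk with sequential clipping
        thetas = np.empty(n)
        th = seg.theta
        for k in range(n):
            th = min(max(th + jit[k], lo), hi)
            thetas[k] = th
        # continuous growth origin: arc a is reached at t0 + (a - g0) / rate
        g0 = seg.laid + carry0
        tip = seg.tip
        deltas = np.column_stack([np.cos(thetas), np.sin(thetas)]) * step
        pts = tip[None, :] + np.cumsum(deltas, axis=0)
        arcs = seg.laid + step * np.arange(1, n + 1)
        bad = self._conflicts(pts, arcs, seg)
        if not bad.any():
            self._accept(seg, pts, arcs, thetas[-1], t0, g0, rate)
            return
        # accept the clean prefix, then go step by step with deflection
        first = int(np.argmax(bad))
        if first > 0:
            self._accept(seg, pts[:first], arcs[:first], thetas[first - 1], t0, g0, rate)
        for _ in range(first, n):
            if not self._try_step(seg, t0, g0, rate):
                seg.stalled = True
                seg.carry = 0.0
                return

    def _try_step(self, seg: _Seg, t0: float, g0: float, rate: float) -> bool:
        cfg = self.cfg
        step = cfg.step_um
        lo = seg.base_dir - cfg.max_deviation_rad
        hi = seg.base_dir + cfg.max_deviation_rad
        tried = set()
        for off in (0.0,) + _DEFLECTIONS:
            th = min(max(seg.theta + off, lo), hi)
            key = round(th, 9)
            if key in tried:
                continue
            tried.add(key)
            p = seg.tip + step * np.array([math.cos(th), math.sin(th)])
            arc = seg.laid + step
            if not self._conflicts(p[None, :], np.array([arc]), seg)[0]:
                self._accept(seg, p[None, :], np.array([arc]), th, t0, g0, rate)
                return True
        return False

    def _accept(self, seg, pts, arcs, theta, t0, g0, rate) -> None:
        for i in range(len(pts)):
            seg.xs.append(pts[i, 0])
            seg.ys.append(pts[i, 1])
            seg.times.append(t0 + (arcs[i] - g0) / rate)
        seg.laid = float(arcs[-1])
        seg.theta = float(theta)
        self.grid.write(pts[:, 0], pts[:, 1], arcs, seg.sid)

    # ------------------------------------------------------------------
    def _conflicts(self, pts: np.ndarray, arcs: np.ndarray, seg: _Seg) -> np.ndarray:
        cfg = self.cfg
        m = self.margin
        bad = (
            (pts[:, 0] < m)
            | (pts[:, 0] > self.size_um[1] - m)
            | (pts[:, 1] < m)
            | (pts[:, 1] > self.size_um[0] - m)
        )
        sid_n, px_n, py_n, arc_n = self.grid.neighbours(pts)
        d2 = (px_n - pts[:, 0:1]) ** 2 + (py_n - pts[:, 1:2]) ** 2
        close = (sid_n >= 0) & (d2 < cfg.clearance_um**2)
        if not close.any():
            return bad
        ex = cfg.junction_exempt_um
        # own trailing path is always exempt within the junction window
        own = sid_n == seg.sid
        exempt = own & (arcs[:, None] - arc_n < ex)
        # related segments are exempt near the shared junction
        for rid, junction in self._related(seg):
            rel = sid_n == rid
            if not rel.any():
                continue
            dq = (px_n - junction[0]) ** 2 + (py_n - junction[1]) ** 2
            dp = (pts[:, 0:1] - junction[0]) ** 2 + (pts[:, 1:2] - junction[1]) ** 2
            exempt |= rel & ((dq < ex**2) | (dp < ex**2))
        conflict = close & ~exempt
        return bad | conflict.any(axis=1)

    def _related(self, seg: _Seg):
        out = []
        if seg.parent is not None:
            out.append((seg.parent, seg.origin))
            for sib in self.segs[seg.parent].children:
                if sib != seg.sid:
                    out.append((sib, self.segs[sib].origin))
        for c in seg.children:
            out.append((c, self.segs[c].origin))
        return out

    # ------------------------------------------------------------------
    def _tip_event(self) -> None:
        cfg = self.cfg
        tips = self._eligible_tips()
        if not tips:
            return
        seg = tips[int(self.rng.integers(len(tips)))]
        u = self.rng.random()
        p_bifed, p_trifed, _ = cfg.event_type_probs
        if u < p_bifed:
            self._terminal(seg, 2)
        elif u < p_bifed + p_trifed:
            self._terminal(seg, 3)
        else:
            self._lateral(seg)

    def _terminal(self, seg: _Seg, n_children: int) -> None:
        rng = self.rng
        if n_children == 2:
            a1 = rng.uniform(0.35, 0.7)
            a2 = rng.uniform(0.35, 0.7)
            rel = (-a1, a2)
            etype = "terminal_bifed"
        else:
            a = rng.uniform(0.7, 0.85)
            mid = rng.uniform(-0.05, 0.05)
            rel = (-a, mid, a)
            etype = "terminal_trifed"
        kids = []
        tip = seg.tip
        n_before = len(self.segs)
        children_before = list(seg.children)
        for r in rel:
            kid = _Seg(
                sid=len(self.segs),
                parent=seg.sid,
                generation=seg.generation + 1,
                birth=self.t,
                origin=tip.copy(),
                base_dir=seg.theta + r,
                theta=seg.theta + r,
                attachment_fraction=1.0,
            )
            kid.xs.append(tip[0])
            kid.ys.append(tip[1])
            kid.times.append(self.t)
            self.segs.append(kid)
            seg.children.append(kid.sid)
            kids.append(kid.sid)
        # contact inhibition: cancel the event if any daughter's first step
        # is blocked (crowding or field edge) — no invisible children
        step = self.cfg.step_um
        for sid in kids:
            kid = self.segs[sid]
            p = kid.tip + step * np.array(
                [math.cos(kid.base_dir), math.sin(kid.base_dir)]
            )
            if self._conflicts(p[None, :], np.array([step]), kid)[0]:
                del self.segs[n_before:]
                seg.children = children_before
                return
        seg.active = False
        seg.carry = 0.0
        self.events.append(
            BranchEvent(
                event_id=len(self.events),
                time=self.t,
                type=etype,
                parent_segment_id=seg.sid,
                attachment_fraction=1.0,
                child_segment_ids=tuple(kids),
            )
        )

    def _lateral(self, seg: _Seg) -> None:
        """Site a lateral on ``seg``'s interior; discard if no legal site."""
        cfg = self.cfg
        rng = self.rng
        L = seg.laid
        if L < 4.0 * cfg.step_um:
            return  # no usable interior on a newborn stub
        # exclusion around existing nodes (origin, tip, prior laterals)
        # avoids degenerate coincident branch points; scaled down on short
        # segments so they are not lateral-free
        excl = min(1.5 * cfg.duct_width_um, L / 4.0)
        lat_origins = [
            self.segs[c].origin
            for c in seg.children
            if self.segs[c].attachment_fraction not in (None, 1.0)
        ]
        for _ in range(20):
            frac = rng.uniform(0.1, 0.9)
            arc = frac * L
            if L - arc < excl or arc < excl:
                continue
            idx = min(int(arc / cfg.step_um), len(seg.xs) - 2)
            pos = np.array([seg.xs[idx], seg.ys[idx]])
            if any(np.linalg.norm(pos - o) < excl for o in lat_origins):
                continue
            if len(seg.xs) < 3:
                local = seg.theta
            else:
                j = min(max(idx, 1), len(seg.xs) - 2)
                local = math.atan2(
                    seg.ys[j + 1] - seg.ys[j - 1], seg.xs[j + 1] - seg.xs[j - 1]
                )
            side = 1.0 if rng.random() < 0.5 else -1.0
            ang = rng.uniform(0.9, 1.3)
            kid = None
            for s_try in (side, -side):  # try the other side if blocked
                cand = _Seg(
                    sid=len(self.segs),
                    parent=seg.sid,
                    generation=seg.generation + 1,
                    birth=self.t,
                    origin=pos,
                    base_dir=local + s_try * ang,
                    theta=local + s_try * ang,
                    attachment_fraction=float(arc / L),
                )
                cand.xs.append(pos[0])
                cand.ys.append(pos[1])
                cand.times.append(self.t)
                self.segs.append(cand)
                seg.children.append(cand.sid)
                step = self.cfg.step_um
                p = cand.tip + step * np.array(
                    [math.cos(cand.base_dir), math.sin(cand.base_dir)]
                )
                if self._conflicts(p[None, :], np.array([step]), cand)[0]:
                    self.segs.pop()
                    seg.children.pop()
                    continue
                kid = cand
                break
            if kid is None:
                continue
            self.events.append(
                BranchEvent(
                    event_id=len(self.events),
                    time=self.t,
                    type="lateral",
                    parent_segment_id=seg.sid,
                    attachment_fraction=float(arc / L),
                    child_segment_ids=(kid.sid,),
                )
            )
            return
        # no legal interior site (segment too short / crowded): event discarded

    def _length_lateral_event(self) -> None:
        cfg = self.cfg
        elig = [s for s in self.segs if s.generation < cfg.max_generation]
        weights = np.array([s.laid for s in elig])
        if weights.sum() <= 0:
            return
        i = int(self.rng.choice(len(elig), p=weights / weights.sum()))
        self._lateral(elig[i])

    # ------------------------------------------------------------------
    def _flush_carry(self) -> None:
        step = self.cfg.step_um
        for seg in self.segs:
            if seg.active and not seg.stalled and seg.carry > 1e-9:
                th = seg.theta
                p = seg.tip + seg.carry * np.array([math.cos(th), math.sin(th)])
                seg.xs.append(p[0])
                seg.ys.append(p[1])
                seg.times.append(self.cfg.duration_h)
                seg.laid += seg.carry
                seg.carry = 0.0

    def _finalize(self) -> tuple[DuctalTree, EventLog]:
        cfg = self.cfg
        segments = [
            Segment(
                segment_id=s.sid,
                parent_id=s.parent,
                generation=s.generation,
                birth_time=s.birth,
                points=np.column_stack([s.xs, s.ys]),
                point_times=np.array(s.times),
                active_tip=s.active,
                stalled=s.stalled,
                attachment_fraction=s.attachment_fraction,
                base_direction=s.base_dir,
            )
            for s in self.segs
        ]
        origins = [s.origin for s in self.segs if s.parent is None]
        x0 = float(min(o[0] for o in origins))
        ys = [float(o[1]) for o in origins]
        anchor = ((x0, min(ys) - 60.0), (x0, max(ys) + 60.0))
        return DuctalTree(segments, anchor, cfg.duration_h), EventLog(self.events)


def sample_forest(config: GrowthConfig) -> tuple[DuctalTree, EventLog]:
    """Simulate one organ-culture run; identical config (incl. seed) gives
    bit-identical output."""
    return _Sim(config).run()
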