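"""From image frames to measured skeleton graphs.

The automated counterpart of the hand-drawn skeletal maps of organ-culture
morphometry: each frame is thresholded, thinned to a one-pixel-wide
skeleton (topology-preserving, 8-connected foreground), and traced into a
graph whose nodes are tips (degree 1), branch points (degree >= 3) and
roots (endpoints on the declared UGS anchor line), and whose edges carry
the ordered pixel path and a measured length (axial step = pixel size,
diagonal step = sqrt(2) x pixel size — the transparent chain-length
convention, bit-reproducible).

Adjacent branch pixels are merged into a single node: thinning splits a
rasterized trifurcation into two neighbouring degree-3 pixels, and merging
restores the atomic branch point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize as _sk_skeletonize

__all__ = [
    "SkeletonGraph",
    "NoTissueError",
    "CycleError",
    "binarize",
    "skeletonize",
    "build_graph",
    "prune_spurs",
]


class NoTissueError(ValueError):
    """The frame contains no foreground."""


class CycleError(ValueError):
    """A skeleton component contains a cycle (ducts must form trees)."""


def binarize(frame: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Threshold a grayscale frame to a boolean duct mask.

    With ``threshold=None`` the midpoint of the frame's intensity range is
    used; for noiseless synthetic frames any threshold strictly between the
    background and foreground levels recovers the exact rasterized mask.
    """
    frame = np.asarray(frame)
    if threshold is None:
        lo, hi = float(frame.min()), float(frame.max())
        if lo == hi:
            raise NoTissueError("frame has no contrast (no tissue)")
        threshold = (lo + hi) / 2.0
    else:
        if not frame.min() <= threshold <= frame.max():
            raise ValueError("threshold outside the frame intensity range")
    mask = frame > threshold
    if not mask.any():
        raise NoTissueError("empty foreground (no tissue)")
    return mask


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to 1-px-wide curves.

    Uses Lee's method: its duct-end positions are stable within about one
    pixel as a tube elongates, where classic two-pass thinning oscillates
    by many pixels on diagonal tube ends.
    """
    return _sk_skeletonize(np.asarray(mask, dtype=bool), method="lee") > 0


_NEIGH = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SkeletonGraph:
    """Measured graph of one frame's skeleton.

    ``graph`` is a :class:`networkx.MultiGraph`; node attributes are
    ``pos`` (row, col, float) and ``kind`` in {tip, branch, root,
    isolated}; edge attributes are ``path`` (ordered (n,2) pixel array)
    and ``length_um``.
    """

    graph: nx.MultiGraph
    pixel_size: float
    frame_index: int = 0
    _kdtree: object = field(default=None, repr=False, compare=False)
    _kd_index: object = field(default=None, repr=False, compare=False)

    def nodes_of_kind(self, kind: str) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == kind]

    @property
    def tips(self) -> list:
        return self.nodes_of_kind("tip")

    @property
    def branch_nodes(self) -> list:
        return self.nodes_of_kind("branch")

    @property
    def roots(self) -> list:
        return self.nodes_of_kind("root")

    def pos(self, node) -> np.ndarray:
        return np.asarray(self.graph.nodes[node]["pos"], dtype=float)

    @property
    def total_length_um(self) -> float:
        return sum(d["length_um"] for *_, d in self.graph.edges(data=True))

    # -- nearest skeleton point lookup (used by tracking) --------------
    def _ensure_kdtree(self) -> None:
        if self._kdtree is not None:
            return
        pts, idx = [], []
        for u, v, k, d in self.graph.edges(keys=True, data=True):
            for i, p in enumerate(d["path"]):
                pts.append(p)
                idx.append((u, v, k, i))
        if not pts:
            for n, d in self.graph.nodes(data=True):
                pts.append(d["pos"])
                idx.append((n, n, 0, 0))
        self._kdtree = cKDTree(np.asarray(pts, dtype=float))
        self._kd_index = idx

    def nearest_point(self, pos_px) -> tuple[float, tuple]:
        """Distance (px) and (u, v, key, path index) of the closest
        skeleton pixel to ``pos_px`` = (row, col)."""
        self._ensure_kdtree()
        dist, i = self._kdtree.query(np.asarray(pos_px, dtype=float))
        return float(dist), self._kd_index[int(i)]

    # -- serialisation --------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        d = dict(
            pixel_size=self.pixel_size,
            frame_index=self.frame_index,
            nodes=[
                dict(id=int(n), pos=list(map(float, a["pos"])), kind=a["kind"])
                for n, a in self.graph.nodes(data=True)
            ],
            edges=[
                dict(
                    u=int(u),
                    v=int(v),
                    key=int(k),
                    length_um=float(a["length_um"]),
                    path=np.asarray(a["path"]).tolist(),
                )
                for u, v, k, a in self.graph.edges(keys=True, data=True)
            ],
        )
        Path(path).write_text(json.dumps(d))

    def edges_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                dict(
                    frame=self.frame_index,
                    edge_id=k,
                    node_a=int(u),
                    node_b=int(v),
                    length_um=float(a["length_um"]),
                )
                for u, v, k, a in self.graph.edges(keys=True, data=True)
            ]
        )


def _path_length_um(path: np.ndarray, pixel_size: float) -> float:
    if len(path) < 2:
        return 0.0
    steps = np.linalg.norm(np.diff(np.asarray(path, dtype=float), axis=0), axis=1)
    return float(steps.sum() * pixel_size)


def build_graph(
    skeleton: np.ndarray,
    pixel_size: float,
    anchor_x_px: float,
    anchor_tol_px: float = 6.0,
    frame_index: int = 0,
    small_cycle_um: float = 30.0,
) -> SkeletonGraph:
    """Trace the skeleton into a measured node/edge graph.

    Endpoints within ``anchor_tol_px`` (in x) of the anchor line are typed
    ``root``.  Thinning a thick junction blob can leave a tiny loop;
    cycles of total length at most ``small_cycle_um`` are collapsed by
    dropping their longest edge.  Any larger cycle (genuinely overlapping
    ducts) raises :class:`CycleError`.
    """
    skel = np.asarray(skeleton, dtype=bool)
    deg = ndimage.convolve(skel.astype(np.uint8), _NEIGH, mode="constant")
    deg = np.where(skel, deg, 0)
    node_mask = skel & (deg != 2)
    # a connected component with no degree!=2 pixel is a closed curve
    comp_labels, n_sk_comp = ndimage.label(skel, structure=np.ones((3, 3)))
    for cid in range(1, n_sk_comp + 1):
        comp = comp_labels == cid
        if not (node_mask & comp).any():
            if comp.sum() * pixel_size > small_cycle_um:
                r, c = np.argwhere(comp)[0]
                raise CycleError(
                    f"closed skeleton loop near pixel ({r}, {c}); "
                    "overlapping ducts cannot be resolved"
                )
            skel = skel & ~comp  # drop a tiny artifact ring
    labels, n_comp = ndimage.label(node_mask, structure=np.ones((3, 3)))

    g = nx.MultiGraph()
    comp_pixels: dict[int, list] = {i: [] for i in range(1, n_comp + 1)}
    for r, c in zip(*np.nonzero(node_mask)):
        comp_pixels[labels[r, c]].append((int(r), int(c)))
    for cid, pix in comp_pixels.items():
        arr = np.array(pix, dtype=float)
        pos = arr.mean(axis=0)
        degs = [deg[r, c] for r, c in pix]
        if max(degs) >= 3:
            kind = "branch"
        elif max(degs) == 0:
            kind = "isolated"
        else:
            kind = "tip"
        if kind in ("tip", "isolated") and abs(pos[1] - anchor_x_px) <= anchor_tol_px:
            kind = "root"
        g.add_node(cid, pos=tuple(pos), kind=kind)

    label_at = labels  # 0 where not a node pixel
    visited_dirs: set[tuple] = set()
    for cid, pix in comp_pixels.items():
        for r, c in pix:
            for dr, dc in _OFFSETS:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < skel.shape[0] and 0 <= cc < skel.shape[1]):
                    continue
                if not skel[rr, cc]:
                    continue
                if label_at[rr, cc] == cid:
                    continue  # internal to the same node component
                if ((r, c), (rr, cc)) in visited_dirs:
                    continue
                path = [(r, c), (rr, cc)]
                prev, cur = (r, c), (rr, cc)
                while label_at[cur] == 0:
                    nxt = None
                    for dr2, dc2 in _OFFSETS:
                        r2, c2 = cur[0] + dr2, cur[1] + dc2
                        if (r2, c2) == prev:
                            continue
                        if (
                            0 <= r2 < skel.shape[0]
                            and 0 <= c2 < skel.shape[1]
                            and skel[r2, c2]
                        ):
                            nxt = (r2, c2)
                            break
                    if nxt is None:  # dead end without a node pixel (rare)
                        break
                    path.append(nxt)
                    prev, cur = cur, nxt
                end_cid = label_at[cur]
                if end_cid == 0:
                    continue
                visited_dirs.add((path[0], path[1]))
                visited_dirs.add((path[-1], path[-2]))
                arr = np.array(path, dtype=float)
                g.add_edge(
                    cid,
                    int(end_cid),
                    path=arr,
                    length_um=_path_length_um(arr, pixel_size),
                )

    sg = SkeletonGraph(graph=g, pixel_size=pixel_size, frame_index=frame_index)
    _collapse_small_cycles(sg, small_cycle_um)
    _check_forest(sg)
    return sg


def _collapse_small_cycles(sg: SkeletonGraph, small_cycle_um: float) -> None:
    g = sg.graph
    changed = True
    while changed:
        changed = False
        # parallel edges between one node pair form a 2-edge cycle; an
        # artifact pair has at least one side within the junction-blob
        # scale (genuinely overlapping ducts give two long paths)
        for u, v in {(u, v) for u, v in g.edges() if u != v}:
            keys = list(g[u][v])
            if len(keys) > 1:
                lengths = {k: g[u][v][k]["length_um"] for k in keys}
                if min(lengths.values()) <= small_cycle_um:
                    g.remove_edge(u, v, max(lengths, key=lengths.get))
                    changed = True
        for u, v, k in list(g.edges(keys=True)):
            if u == v and g[u][v][k]["length_um"] <= small_cycle_um:
                g.remove_edge(u, v, k)
                changed = True
        if changed:
            continue
        simple = nx.Graph(g)
        for cyc in nx.cycle_basis(simple):
            edges = [
                (a, b, min(g[a][b], key=lambda k: g[a][b][k]["length_um"]))
                for a, b in zip(cyc, cyc[1:] + cyc[:1])
                if g.has_edge(a, b)
            ]
            total = sum(g[a][b][k]["length_um"] for a, b, k in edges)
            if total <= small_cycle_um and edges:
                a, b, k = max(edges, key=lambda e: g[e[0]][e[1]][e[2]]["length_um"])
                g.remove_edge(a, b, k)
                changed = True
                break


def _check_forest(sg: SkeletonGraph) -> None:
    g = sg.graph
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_edges() >= sub.number_of_nodes() and sub.number_of_nodes() > 0:
            node = next(iter(comp))
            pos = g.nodes[node]["pos"]
            raise CycleError(
                f"skeleton component near pixel {tuple(round(x) for x in pos)} "
                "contains a cycle; overlapping ducts cannot be resolved"
            )


def prune_spurs(
    sg: SkeletonGraph,
    min_length_um: float,
    protected_tips: list | None = None,
    protect_radius_px: float = 4.0,
) -> SkeletonGraph:
    """Iteratively remove tip-terminated edges shorter than ``min_length_um``.

    Tips within ``protect_radius_px`` of a position in ``protected_tips``
    (tips accepted in the previous frame — the tracking hook) are kept.
    Degree-2 nodes left behind are spliced so the result is in canonical
    form; the operation is idempotent at its fixed point.
    """
    if min_length_um < 0:
        raise ValueError("min_length_um must be >= 0")
    g = sg.graph.copy()
    protected = (
        np.asarray(protected_tips, dtype=float).reshape(-1, 2)
        if protected_tips is not None and len(protected_tips)
        else None
    )

    def is_protected(pos) -> bool:
        if protected is None:
            return False
        d = np.linalg.norm(protected - np.asarray(pos, dtype=float), axis=1)
        return bool((d <= protect_radius_px).any())

    changed = True
    while changed:
        changed = False
        if min_length_um > 0:
            for n in list(g.nodes):
                if g.degree(n) != 1 or g.nodes[n]["kind"] not in ("tip",):
                    continue
                (u, v, k, d) = next(iter(g.edges(n, keys=True, data=True)))
                if d["length_um"] < min_length_um and not is_protected(
                    g.nodes[n]["pos"]
                ):
                    g.remove_node(n)
                    changed = True
        # splice degree-2 non-root nodes
        for n in list(g.nodes):
            if g.degree(n) != 2 or g.nodes[n]["kind"] == "root":
                continue
            edges = list(g.edges(n, keys=True, data=True))
            if len(edges) != 2:
                continue  # self-loop safety
            (u1, v1, k1, d1), (u2, v2, k2, d2) = edges
            o1 = v1 if u1 == n else u1
            o2 = v2 if u2 == n else u2
            p1 = d1["path"]
            p2 = d2["path"]
            # orient p1 to end at n, p2 to start at n
            if not np.array_equal(p1[-1], _closest_end(p1, g.nodes[n]["pos"])):
                p1 = p1[::-1]
            if not np.array_equal(p2[0], _closest_end(p2, g.nodes[n]["pos"])):
                p2 = p2[::-1]
            newpath = np.vstack([p1, p2[1:]])
            g.remove_node(n)
            g.add_edge(
                o1,
                o2,
                path=newpath,
                length_um=_path_length_um(newpath, sg.pixel_size),
            )
            changed = True
        # refresh node kinds after removals
        for n in list(g.nodes):
            d = g.degree(n)
            kind = g.nodes[n]["kind"]
            if kind == "root":
                continue
            if d == 0:
                g.nodes[n]["kind"] = "isolated"
            elif d == 1:
                g.nodes[n]["kind"] = "tip"
            elif d >= 3:
                g.nodes[n]["kind"] = "branch"
    return SkeletonGraph(graph=g, pixel_size=sg.pixel_size, frame_index=sg.frame_index)


def _closest_end(path: np.ndarray, pos) -> np.ndarray:
    pos = np.asarray(pos, dtype=float)
    d0 = np.linalg.norm(path[0] - pos)
    d1 = np.linalg.norm(path[-1] - pos)
    return path[0] if d0 <= d1 else path[-1]
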