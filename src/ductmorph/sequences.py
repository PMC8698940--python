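"""Exhaustive enumeration of branching-event sequences behind an end state.

A static image of a branched duct cannot reveal the order of events that
produced it: three tips clustered at the end of a duct may have arisen from
a single terminal trifed, from a bifed followed by a bifed on one daughter,
or from a bifed followed by a lateral on one daughter — only sequential
imaging separates them.  This module makes that statement computable: it
brute-forces every ordered event sequence (types from the taxonomy
{terminal bifed, terminal trifed, lateral}, applied at any legal locus) up
to a length bound, starting from a single unbranched duct, and counts the
distinct sequences whose end state is observationally equal to a target
topology.

Observational equality models what a drawn end-state skeleton retains:
segments born *during* the sequence are short on the scale of a static
image, so all structure in the new growth at the parent's former tip
collapses into one distal tip cluster, while a lateral placed on the
pre-existing duct is an observably distinct interior locus.  Two
constraints follow from the event semantics: a terminal event needs a free
tip, and a lateral needs existing interior — so the first event at a
fresh tip locus is necessarily terminal.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TargetTopology", "enumerate_event_sequences"]


@dataclass(frozen=True)
class TargetTopology:
    """Observable end state of a single original duct.

    ``distal_tips`` — number of tips in the cluster at the duct's distal
    end (1 for an unbranched duct).  ``interior_clusters`` — sorted tip
    counts of side-branch clusters attached to the duct's interior.
    """

    distal_tips: int = 1
    interior_clusters: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.distal_tips < 1:
            raise ValueError("a duct always has at least one distal tip")
        object.__setattr__(
            self, "interior_clusters", tuple(sorted(self.interior_clusters))
        )


class _Seg:
    __slots__ = ("is_old", "terminal", "lateral")

    def __init__(self, is_old: bool) -> None:
        self.is_old = is_old
        self.terminal: list[_Seg] = []
        self.lateral: list[_Seg] = []

    def clone(self) -> "_Seg":
        c = _Seg(self.is_old)
        c.terminal = [s.clone() for s in self.terminal]
        c.lateral = [s.clone() for s in self.lateral]
        return c

    def all_segments(self):
        yield self
        for s in self.terminal + self.lateral:
            yield from s.all_segments()

    def cluster_tips(self) -> int:
        """Tips of the new-growth cluster rooted at this (new) segment."""
        own = 1 if not self.terminal else sum(s.cluster_tips() for s in self.terminal)
        return own + sum(s.cluster_tips() for s in self.lateral)


def _observable(root: _Seg) -> tuple[int, tuple[int, ...]]:
    if root.terminal:
        distal = sum(s.cluster_tips() for s in root.terminal)
    else:
        distal = 1
    interior = tuple(sorted(s.cluster_tips() for s in root.lateral))
    return distal, interior


def _locus_descriptor(root: _Seg, seg: _Seg, etype: str) -> tuple:
    """Canonical description of applying ``etype`` at ``seg``.

    Sequences are counted up to isomorphism of their construction: two
    moves with the same descriptor from the same state yield isomorphic
    outcomes (e.g. a second bifed on either daughter of a first bifed is
    one sequence, not two).
    """
    if seg is root:
        where = ("old",)
    else:
        # which cluster of the old duct does this new segment sit in?
        for s in root.terminal:
            if seg in s.all_segments():
                where = ("new-distal", s.cluster_tips())
                break
        else:
            for s in root.lateral:
                if seg in s.all_segments():
                    where = ("new-interior", s.cluster_tips())
                    break
            else:  # pragma: no cover - unreachable
                where = ("unknown",)
    return (etype, where, bool(seg.terminal))


def enumerate_event_sequences(
    final_topology: TargetTopology | tuple,
    max_events: int = 4,
) -> tuple[int, list[tuple[str, ...]]]:
    """Count ordered event sequences reaching ``final_topology``.

    Returns ``(count, sequences)`` where each sequence is a tuple of event
    type names in order of occurrence.  An unreachable topology yields
    ``(0, [])``.
    """
    if isinstance(final_topology, tuple):
        final_topology = TargetTopology(final_topology[0], tuple(final_topology[1]))
    if max_events < 0:
        raise ValueError("max_events must be >= 0")
    if max_events > 6:
        raise ValueError("enumeration is exponential; max_events must be <= 6")
    target = (final_topology.distal_tips, final_topology.interior_clusters)

    hits: list[tuple[str, ...]] = []

    def recurse(root: _Seg, seq: tuple[str, ...]) -> None:
        if _observable(root) == target:
            hits.append(seq)
        if len(seq) >= max_events:
            return
        seen_moves = set()
        segs = list(root.all_segments())
        for i, seg in enumerate(segs):
            moves = []
            if not seg.terminal:  # free tip: terminal events possible
                moves += ["terminal_bifed", "terminal_trifed"]
            moves.append("lateral")  # interior attachment, any segment
            for etype in moves:
                desc = _locus_descriptor(root, seg, etype)
                if desc in seen_moves:
                    continue
                seen_moves.add(desc)
                new_root = root.clone()
                new_seg = list(new_root.all_segments())[i]
                n_children = {"terminal_bifed": 2, "terminal_trifed": 3, "lateral": 1}
                kids = [_Seg(is_old=False) for _ in range(n_children[etype])]
                if etype == "lateral":
                    new_seg.lateral.extend(kids)
                else:
                    new_seg.terminal.extend(kids)
                recurse(new_root, seq + (etype,))

    recurse(_Seg(is_old=True), ())
    return len(hits), hits
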