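"""Kinetics read-outs of a tracked forest: the four classic curves.

Per sample and time point: aggregate ductal length per branch generation,
cumulative branch-point events per generation, total tip number, and
cumulative counts of the three branching types.  Lengths are measured from
the tracked skeleton edges at the sampled frame (not interpolated);
counts come from the detected event log, with ambiguous events tallied
separately and never silently resolved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tracking import DetectedEvent, TrackedForest

__all__ = [
    "aggregate_length_by_generation",
    "branch_events_by_generation",
    "total_tip_number",
    "event_type_counts",
    "max_generation",
    "morphometry_table",
]


def _frame_indices(forest: TrackedForest, times) -> list[int]:
    idx = []
    for t in times:
        i = int(np.argmin(np.abs(forest.timestamps - t)))
        if abs(forest.timestamps[i] - t) > 1e-6:
            raise ValueError(f"time {t} h is not an analyzed frame")
        idx.append(i)
    return idx


def max_generation(forest: TrackedForest) -> int:
    """Deepest branch generation reached by any track."""
    return max(t.generation for t in forest.tracks.values())


def total_tip_number(forest: TrackedForest, times) -> pd.Series:
    """Degree-1 non-root skeleton nodes at each sampled time."""
    idx = _frame_indices(forest, times)
    return pd.Series(
        [forest.n_tips(i) for i in idx], index=pd.Index(times, name="time_h"),
        name="total_tips",
    )


def aggregate_length_by_generation(
    forest: TrackedForest, times, sample_id: str = "sample"
) -> pd.DataFrame:
    """Sum of tracked segment lengths per (time, generation)."""
    idx = _frame_indices(forest, times)
    gmax = max_generation(forest)
    rows = []
    for t, i in zip(times, idx):
        for g in range(gmax + 1):
            tracks = [
                tr
                for tr in forest.tracks_alive(i)
                if tr.generation == g
            ]
            rows.append(
                dict(
                    sample_id=sample_id,
                    time_h=t,
                    generation=g,
                    aggregate_length_um=sum(
                        forest.measure_length(tr, i) for tr in tracks
                    ),
                    n_segments=len(tracks),
                )
            )
    return pd.DataFrame(rows)


def branch_events_by_generation(
    events: list[DetectedEvent], times, max_gen: int | None = None,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Cumulative branch events keyed by the parent segment's generation.

    Ambiguous events are counted in ``cum_ambiguous`` only; the per-type
    columns contain resolved events.
    """
    if max_gen is None:
        max_gen = max((e.generation for e in events), default=0)
    rows = []
    for t in times:
        done = [e for e in events if e.time <= t + 1e-9]
        for g in range(max_gen + 1):
            ev_g = [e for e in done if e.generation == g]
            res = [e for e in ev_g if not e.ambiguous]
            rows.append(
                dict(
                    sample_id=sample_id,
                    time_h=t,
                    generation=g,
                    cum_branch_events=len(res),
                    cum_bifed=sum(e.type == "terminal_bifed" for e in res),
                    cum_trifed=sum(e.type == "terminal_trifed" for e in res),
                    cum_lateral=sum(e.type == "lateral" for e in res),
                    cum_ambiguous=sum(e.ambiguous for e in ev_g),
                )
            )
    return pd.DataFrame(rows)


def event_type_counts(
    events: list[DetectedEvent], times, sample_id: str = "sample"
) -> pd.DataFrame:
    """Cumulative per-type counts and fractions over resolved events.

    With no resolved events the fractions are NaN and ``undefined`` is set
    — an empty log has no meaningful type mix.
    """
    rows = []
    for t in times:
        done = [e for e in events if e.time <= t + 1e-9 and not e.ambiguous]
        amb = [e for e in events if e.time <= t + 1e-9 and e.ambiguous]
        n = len(done)
        counts = {
            "terminal_bifed": sum(e.type == "terminal_bifed" for e in done),
            "terminal_trifed": sum(e.type == "terminal_trifed" for e in done),
            "lateral": sum(e.type == "lateral" for e in done),
        }
        rows.append(
            dict(
                sample_id=sample_id,
                time_h=t,
                n_bifed=counts["terminal_bifed"],
                n_trifed=counts["terminal_trifed"],
                n_lateral=counts["lateral"],
                n_ambiguous=len(amb),
                frac_bifed=counts["terminal_bifed"] / n if n else np.nan,
                frac_trifed=counts["terminal_trifed"] / n if n else np.nan,
                frac_lateral=counts["lateral"] / n if n else np.nan,
                undefined=n == 0,
            )
        )
    return pd.DataFrame(rows)


def morphometry_table(
    forest: TrackedForest, times, sample_id: str = "sample"
) -> pd.DataFrame:
    """The combined per-(time, generation) morphometry table.

    Schema matches the ground-truth oracle table, plus ``cum_ambiguous``;
    ``total_tips`` and ``max_generation`` are repeated across the
    generation rows of one time point.
    """
    from .tracking import detect_events

    events = detect_events(forest)
    gmax = max_generation(forest)
    lengths = aggregate_length_by_generation(forest, times, sample_id)
    counts = branch_events_by_generation(events, times, gmax, sample_id)
    tips = total_tip_number(forest, times)
    df = lengths.merge(counts, on=["sample_id", "time_h", "generation"])
    df["total_tips"] = df["time_h"].map(dict(zip(times, tips.values)))
    idx = _frame_indices(forest, times)
    reached = {
        t: max(
            (tr.generation for tr in forest.tracks_alive(i)), default=0
        )
        for t, i in zip(times, idx)
    }
    df["max_generation"] = df["time_h"].map(reached)
    return df
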