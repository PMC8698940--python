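"""Shared fixtures: scripted trees, rendered stacks, small configs.

Everything is generated programmatically and deterministically; rendered
stacks that several tests share are module/session scoped to keep the run
fast.
"""

from __future__ import annotations

import numpy as np
import pytest

import ductmorph as dm


@pytest.fixture(scope="session")
def small_cfg() -> dm.GrowthConfig:
    """Small field / short duration config for rendering scripted trees."""
    return dm.GrowthConfig(
        field_size_px=(512, 512), duration_h=30.0, frame_interval_min=30.0, seed=0
    )


def build_branched_tree():
    """Original duct with one bifed, one lateral, one trifed (straight
    geometry, known lengths)."""
    st = dm.ScriptedTree(rate=20.0, step_um=2.0)
    r = st.add_original((60, 400), direction=0.0, initial_length=30)
    a, b = st.bifed(r, time=6.0, angles=(-0.5, 0.5))
    st.lateral(r, time=12.0, fraction=0.5, angle=1.1)
    st.trifed(a, time=14.0, angles=(-0.75, 0.0, 0.75))
    return st.build(20.0)


def build_ambiguity_tree():
    """Bifed at 20 h, then bifed on one daughter 40 min later: the classic
    three-tip end state that a static image cannot classify."""
    st = dm.ScriptedTree(rate=20.0, step_um=2.0)
    r = st.add_original((60, 400), direction=0.0, initial_length=30)
    a, b = st.bifed(r, time=20.0, angles=(-0.5, 0.5))
    st.bifed(a, time=20.0 + 40.0 / 60.0, angles=(-0.5, 0.5))
    return st.build(30.0)


@pytest.fixture(scope="session")
def branched_stack(small_cfg):
    tree, log = build_branched_tree()
    cfg = small_cfg.replace(duration_h=20.0)
    return dm.render_stack(tree, cfg), tree, log, cfg


@pytest.fixture(scope="session")
def ambiguity_stack(small_cfg):
    tree, log = build_ambiguity_tree()
    return dm.render_stack(tree, small_cfg), tree, log, small_cfg


@pytest.fixture(scope="session")
def branched_forest(branched_stack):
    stack, tree, log, cfg = branched_stack
    return dm.analyze_stack(stack), tree, log
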