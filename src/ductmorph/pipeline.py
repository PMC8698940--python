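"""End-to-end experiment orchestration.

An experiment YAML names groups of samples (lobe preset x treatment x n),
a metric and a time grid; :func:`run_experiment` simulates every sample,
optionally pushes each rendered stack through the full image pipeline
(otherwise morphometry comes from the ground-truth tree), assembles the
per-sample morphometry tables, summarizes groups as mean +/- SEM and runs
the configured comparison — writing every stage product plus a checksummed
manifest, so a rerun with the same seeds is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import GrowthConfig, lobe_preset
from .morphometry import morphometry_table
from .render import render_stack
from .simulate import ground_truth_metrics, sample_forest
from .stats import GroupDesign, compare_multi, compare_two, summarize
from .tracking import TrackingParams, analyze_stack
from .tree import ScriptedTree

log = logging.getLogger("ductmorph")

__all__ = ["RunManifest", "run_experiment", "make_fixtures"]


@dataclass
class RunManifest:
    experiment: str
    seed: int
    outputs: dict = field(default_factory=dict)  # name -> {path, sha256}

    def add(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[name] = dict(path=str(path), sha256=digest)

    def write(self, path: Path) -> None:
        Path(path).write_text(
            json.dumps(
                dict(experiment=self.experiment, seed=self.seed, outputs=self.outputs),
                indent=2,
            )
        )

    def verify(self) -> bool:
        for name, rec in self.outputs.items():
            p = Path(rec["path"])
            if not p.exists():
                return False
            if hashlib.sha256(p.read_bytes()).hexdigest() != rec["sha256"]:
                return False
        return True


def _load_experiment(spec) -> dict:
    if isinstance(spec, (str, Path)):
        with open(spec) as fh:
            d = yaml.safe_load(fh)
        d.setdefault("name", Path(spec).stem)
    else:
        d = dict(spec)
        d.setdefault("name", "experiment")
    if "groups" not in d or not d["groups"]:
        raise ValueError("experiment needs a non-empty 'groups' mapping")
    for gname, g in d["groups"].items():
        if int(g.get("n", 0)) < 1:
            raise ValueError(f"group {gname!r}: n must be >= 1")
    d.setdefault("seed", 0)
    d.setdefault("metric", "total_tips")
    d.setdefault("times", [0, 10, 20, 30, 40, 50, 60, 70, 80, 90])
    d.setdefault("imaging", False)
    return d


def _sample_config(group: dict, seed: int, overrides: dict) -> GrowthConfig:
    cfg = lobe_preset(
        group["preset"],
        treatment=group.get("treatment", "control"),
        seed=seed,
        **overrides,
    )
    return cfg


def run_experiment(experiment, outdir) -> RunManifest:
    """Execute all stages of an experiment; deterministic given its seed."""
    exp = _load_experiment(experiment)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(experiment=exp["name"], seed=int(exp["seed"]))
    times = [float(t) for t in exp["times"]]
    overrides = dict(exp.get("overrides", {}))
    if "duration_h" in exp:
        overrides["duration_h"] = float(exp["duration_h"])

    tables, event_rows = [], []
    groups: dict[str, list] = {}
    for gi, (gname, g) in enumerate(sorted(exp["groups"].items())):
        groups[gname] = []
        for i in range(int(g["n"])):
            sid = f"{gname}_{i}"
            seed = int(exp["seed"]) + 1000 * gi + i
            cfg = _sample_config(g, seed, overrides)
            log.info("simulate %s (preset=%s seed=%d)", sid, g["preset"], seed)
            tree, gt_log = sample_forest(cfg)
            if exp["imaging"]:
                stack = render_stack(tree, cfg)
                params = TrackingParams(
                    duct_width_um=cfg.duct_width_um,
                    pixel_size_um=cfg.pixel_size_um,
                )
                forest = analyze_stack(stack, params=params)
                tab = morphometry_table(forest, times, sample_id=sid)
            else:
                tab = ground_truth_metrics(tree, gt_log, times, sample_id=sid)
            tables.append(tab)
            groups[gname].append(sid)
            for e in gt_log:
                event_rows.append(
                    dict(sample_id=sid, event_id=e.event_id, time_h=e.time,
                         type=e.type, parent_segment=e.parent_segment_id)
                )

    morpho = pd.concat(tables, ignore_index=True)
    morpho_path = outdir / "morphometry.csv"
    morpho.to_csv(morpho_path, index=False)
    manifest.add("morphometry", morpho_path)
    events_path = outdir / "events.csv"
    pd.DataFrame(event_rows).to_csv(events_path, index=False)
    manifest.add("events", events_path)

    pairing = None
    if exp.get("pairing") and len(groups) == 2:
        a, b = (groups[n] for n in sorted(groups))
        pairing = dict(zip(a, b))
    design = GroupDesign(
        groups=groups, metric=exp["metric"], times=tuple(times), pairing=pairing
    )
    summary = summarize(morpho, design)
    summary_path = outdir / "summary.csv"
    summary.to_csv(summary_path, index=False)
    manifest.add("summary", summary_path)

    if len(groups) == 2:
        comparison = compare_two(morpho, design)
    else:
        comparison = compare_multi(morpho, design)
    cmp_path = outdir / "comparison.csv"
    comparison.to_csv(cmp_path, index=False)
    manifest.add("comparison", cmp_path)

    manifest.write(outdir / "manifest.json")
    log.info("experiment %s complete: %d outputs", exp["name"], len(manifest.outputs))
    return manifest


# ----------------------------------------------------------------------
def make_fixtures(outdir, seed: int = 0) -> dict:
    """Small deterministic stacks + ground-truth logs for tests and demos.

    Includes the classic three-tip ambiguity stack (bifed then bifed on a
    daughter 40 min later) and an LP1 generation-cap stack.
    """
    from .validation import sample_clean_run

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    # 1. ambiguity stack
    st = ScriptedTree(rate=20.0, step_um=2.0)
    r = st.add_original((60, 400), direction=0.0, initial_length=30)
    a, b = st.bifed(r, time=20.0, angles=(-0.5, 0.5))
    st.bifed(a, time=20.0 + 40.0 / 60.0, angles=(-0.5, 0.5))
    tree, gt_log = st.build(30.0)
    cfg = GrowthConfig(field_size_px=(512, 512), duration_h=30.0,
                       frame_interval_min=30.0, seed=seed)
    stack = render_stack(tree, cfg)
    stack.save(outdir / "ambiguity_stack.tif")
    tree.to_json(outdir / "ambiguity_tree.json")
    gt_log.to_csv(outdir / "ambiguity_events.csv")
    written["ambiguity"] = str(outdir / "ambiguity_stack.tif")

    # 2. LP1 generation-cap stack (short culture, small field)
    cfg1 = lobe_preset(
        "lp1", seed=seed,
        duration_h=36.0, field_size_px=(768, 640), duct_spacing_um=150.0,
    )
    t1, l1 = sample_forest(cfg1)
    s1 = render_stack(t1, cfg1)
    s1.save(outdir / "lp1_stack.tif")
    t1.to_json(outdir / "lp1_tree.json")
    l1.to_csv(outdir / "lp1_events.csv")
    written["lp1"] = str(outdir / "lp1_stack.tif")

    # 3. clean validation stack with its ground truth
    cfgv, tv, lv = sample_clean_run(seed, duration_h=40.0)
    sv = render_stack(tv, cfgv)
    sv.save(outdir / "validation_stack.tif")
    tv.to_json(outdir / "validation_tree.json")
    lv.to_csv(outdir / "validation_events.csv")
    written["validation"] = str(outdir / "validation_stack.tif")

    checks = {
        name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
        for name, p in written.items()
    }
    (outdir / "checksums.json").write_text(json.dumps(checks, indent=2))
    return written
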