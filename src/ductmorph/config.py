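"""Growth-model configuration, lobe presets, and treatment modifiers.

A :class:`GrowthConfig` carries every parameter of the stochastic ductal
growth model: the number and anchoring of original ducts budding from the
urogenital sinus (UGS), elongation kinetics, branching hazards and the
terminal-bifed / terminal-trifed / lateral event-type mix, the generation
cap that distinguishes the prostate lobes, imaging cadence and rasterization
geometry, and a treatment label whose documented rate multipliers emulate
growth-factor stimulation (FGF10) or pathway inhibition (U0126, C3
transferase, Y-27632, ML-7).

Lobe presets are calibrated to the *ordinal* phenotypes of neonatal rat
prostate organ culture — the ventral prostate (VP) branches to the fourth
generation and out-grows the lateral prostate (LP), which stops at the
second; the LP1 sub-lobe has long original ducts and only first-generation
branches while LP2 is a compact bush reaching the third generation — not to
any absolute tissue measurement.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "GrowthConfig",
    "ConfigError",
    "LOBE_PRESETS",
    "TREATMENTS",
    "lobe_preset",
    "apply_treatment",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """Raised for an invalid or unsafe growth configuration."""


#: treatment -> (elongation multiplier, branching-hazard multiplier).
#: FGF10 stimulates both elongation and branching; the inhibitors scale
#: rates down with ML-7 the strongest and C3 transferase the weakest
#: (ML-7 < Y-27632 ~ U0126 < C3 on the branching hazard).
TREATMENTS: dict[str, tuple[float, float]] = {
    "control": (1.0, 1.0),
    "fgf10": (1.30, 1.80),
    "u0126": (0.70, 0.45),
    "y27632": (0.70, 0.40),
    "c3": (0.80, 0.60),
    "ml7": (0.50, 0.20),
}


@dataclass(frozen=True)
class GrowthConfig:
    """All parameters of one simulated organ-culture run.

    Attributes
    ----------
    lobe_preset:
        One of ``vp``, ``lp``, ``lp1``, ``lp2`` or ``custom``.
    n_original_ducts:
        Either a fixed integer or an inclusive ``(lo, hi)`` range from which
        the count of generation-0 ducts is drawn per seed.
    initial_bud_length_um:
        Length of each original bud at time 0.
    elongation_rate_um_h:
        Tip advance speed in um/h, optionally modulated per generation by
        ``generation_rate_multipliers`` (index = generation; the last entry
        applies to all deeper generations).
    tip_branch_hazard_per_h:
        Branching hazard per active tip whose segment generation is below
        ``max_generation``; the event type is drawn from
        ``event_type_probs`` (a drawn "lateral" is re-sited onto the
        interior of the tip's own segment).
    lateral_hazard_per_h_per_100um:
        Independent lateral-branch hazard per 100 um of eligible duct.
        Zero in all presets (the presets route laterals through the
        event-type mix so the realized mix equals ``event_type_probs``).
    event_type_probs:
        ``(p_bifed, p_trifed, p_lateral)``; must sum to 1.
    max_generation:
        Hard cap: no segment generation ever exceeds it.
    duration_h, frame_interval_min:
        Culture duration and imaging cadence; the interval must divide the
        duration evenly.
    treatment:
        Label from :data:`TREATMENTS`; rates are already scaled (see
        :func:`apply_treatment`).
    pixel_size_um, duct_width_um, field_size_px:
        Rasterization geometry (field is ``(height, width)`` pixels).
    noise_sigma:
        Optional additive Gaussian noise (intensity units) for rendering.
    """

    lobe_preset: str = "custom"
    n_original_ducts: int | tuple[int, int] = 4
    initial_bud_length_um: float = 30.0
    elongation_rate_um_h: float = 20.0
    generation_rate_multipliers: tuple[float, ...] = (1.0,)
    tip_branch_hazard_per_h: float = 0.02
    lateral_hazard_per_h_per_100um: float = 0.0
    event_type_probs: tuple[float, float, float] = (0.5, 0.1, 0.4)
    max_generation: int = 4
    duration_h: float = 90.0
    frame_interval_min: float = 30.0
    treatment: str = "control"
    seed: int = 0
    pixel_size_um: float = 2.0
    duct_width_um: float = 8.0
    field_size_px: tuple[int, int] = (1024, 1024)
    noise_sigma: float = 0.0
    # --- geometry of the growth process (rarely changed) ---
    step_um: float = 2.0                 # elongation discretization
    waviness_rad: float = 0.04           # per-step direction jitter (sd)
    max_deviation_rad: float = 0.5       # clamp vs segment base direction
    clearance_um: float = 20.0           # min distance between foreign ducts
    junction_exempt_um: float = 30.0     # no clearance check near junctions
    anchor_margin_um: float = 60.0       # UGS anchor line x-position
    fan_half_angle_rad: float = 0.45     # spread of original duct directions
    duct_spacing_um: float = 120.0       # anchor spacing of original ducts
    max_events: int = 5000               # safety cap on simulated events

    # ------------------------------------------------------------------
    def validate(self) -> None:
        p = self.event_type_probs
        if len(p) != 3 or any(x < 0 for x in p):
            raise ConfigError("event_type_probs must be 3 non-negative values")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ConfigError(f"event_type_probs must sum to 1, got {sum(p)!r}")
        for name in (
            "elongation_rate_um_h",
            "tip_branch_hazard_per_h",
            "lateral_hazard_per_h_per_100um",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.duration_h <= 0:
            raise ConfigError("duration_h must be > 0")
        if self.frame_interval_min <= 0:
            raise ConfigError("frame_interval_min must be > 0")
        n_frames = self.duration_h * 60.0 / self.frame_interval_min
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ConfigError("frame_interval_min must divide duration_h evenly")
        if self.max_generation < 0:
            raise ConfigError("max_generation must be >= 0")
        n = self.n_original_ducts
        if isinstance(n, (tuple, list)):
            if len(n) != 2 or n[0] > n[1] or n[0] < 1:
                raise ConfigError("n_original_ducts range must be (lo, hi), lo>=1")
        elif n < 1:
            raise ConfigError("n_original_ducts must be >= 1")
        if self.treatment not in TREATMENTS:
            raise ConfigError(f"unknown treatment {self.treatment!r}")
        if self.pixel_size_um <= 0 or self.duct_width_um <= 0:
            raise ConfigError("pixel_size_um and duct_width_um must be > 0")

    # ------------------------------------------------------------------
    @property
    def frame_times_h(self) -> list[float]:
        """Imaging time points 0 .. duration at the frame interval."""
        dt = self.frame_interval_min / 60.0
        n = round(self.duration_h / dt)
        return [i * dt for i in range(n + 1)]

    def rate_for_generation(self, generation: int) -> float:
        m = self.generation_rate_multipliers
        mult = m[generation] if generation < len(m) else m[-1]
        return self.elongation_rate_um_h * mult

    def expected_event_bound(self) -> float:
        """Crude upper bound on the expected number of branching events.

        Supremum branching-process estimate ignoring the generation cap:
        tips multiply at rate ``h_tip * (1 + p_trifed)`` plus a lateral
        contribution proportional to mean accumulated length.
        """
        h = self.tip_branch_hazard_per_h * (1.0 + self.event_type_probs[1])
        h += (
            self.lateral_hazard_per_h_per_100um
            / 100.0
            * self.elongation_rate_um_h
            * max(m for m in self.generation_rate_multipliers)
            * self.duration_h
            / 2.0
        )
        n0 = self.n_original_ducts
        if isinstance(n0, (tuple, list)):
            n0 = n0[1]
        return n0 * math.expm1(h * self.duration_h)

    def replace(self, **kw) -> "GrowthConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # YAML-friendly plain types
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthConfig":
        kw = dict(d)
        unknown = set(kw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for k in (
            "generation_rate_multipliers",
            "event_type_probs",
            "field_size_px",
        ):
            if k in kw and isinstance(kw[k], list):
                kw[k] = tuple(kw[k])
        if "n_original_ducts" in kw and isinstance(kw["n_original_ducts"], list):
            kw["n_original_ducts"] = tuple(kw["n_original_ducts"])
        cfg = cls(**kw)
        cfg.validate()
        return cfg


# ----------------------------------------------------------------------
# Lobe presets (control conditions).  Hazards/rates are model parameters
# chosen to reproduce the ordinal lobe phenotypes, not tissue measurements.
# ----------------------------------------------------------------------
LOBE_PRESETS: dict[str, dict] = {
    # 3-5 long main ducts, branches to the 4th generation ("elm tree").
    "vp": dict(
        n_original_ducts=(3, 5),
        initial_bud_length_um=40.0,
        elongation_rate_um_h=20.0,
        tip_branch_hazard_per_h=0.030,
        event_type_probs=(0.423, 0.197, 0.380),
        max_generation=4,
    ),
    # 5-6 shorter main ducts, stops branching at the 2nd generation
    # ("bushy tree"); bifeds dominate, trifeds infrequent.
    "lp": dict(
        n_original_ducts=(5, 6),
        initial_bud_length_um=25.0,
        elongation_rate_um_h=13.0,
        tip_branch_hazard_per_h=0.007,
        event_type_probs=(0.55, 0.08, 0.37),
        max_generation=2,
    ),
    # long original ducts, first-generation branches only ("palm tree").
    "lp1": dict(
        n_original_ducts=(5, 6),
        initial_bud_length_um=35.0,
        elongation_rate_um_h=16.0,
        generation_rate_multipliers=(1.3, 0.8),
        tip_branch_hazard_per_h=0.010,
        event_type_probs=(0.55, 0.08, 0.37),
        max_generation=1,
    ),
    # short original ducts, branches to the 3rd generation ("bush").
    "lp2": dict(
        n_original_ducts=(5, 6),
        initial_bud_length_um=22.0,
        elongation_rate_um_h=13.0,
        tip_branch_hazard_per_h=0.016,
        event_type_probs=(0.55, 0.08, 0.37),
        max_generation=3,
    ),
}


def lobe_preset(name: str, treatment: str = "control", seed: int = 0, **overrides) -> GrowthConfig:
    """Build a validated config for a named lobe, optionally treated."""
    key = name.lower()
    if key not in LOBE_PRESETS:
        raise ConfigError(f"unknown lobe preset {name!r}; choose from {sorted(LOBE_PRESETS)}")
    kw = dict(LOBE_PRESETS[key], lobe_preset=key, seed=seed)
    kw.update(overrides)
    cfg = GrowthConfig(**kw)
    cfg.validate()
    if treatment != "control":
        cfg = apply_treatment(cfg, treatment)
    return cfg


def apply_treatment(config: GrowthConfig, treatment: str) -> GrowthConfig:
    """Return a copy of ``config`` with treatment rate multipliers applied.

    ``control`` is the identity.  Re-treating an already treated config is
    rejected so multipliers never stack.
    """
    if treatment not in TREATMENTS:
        raise ConfigError(f"unknown treatment {treatment!r}")
    if treatment == "control":
        return config.replace()
    if config.treatment != "control":
        raise ConfigError(
            f"config already carries treatment {config.treatment!r}; "
            "apply treatments to a control config"
        )
    e_mult, b_mult = TREATMENTS[treatment]
    return config.replace(
        treatment=treatment,
        elongation_rate_um_h=config.elongation_rate_um_h * e_mult,
        tip_branch_hazard_per_h=config.tip_branch_hazard_per_h * b_mult,
        lateral_hazard_per_h_per_100um=config.lateral_hazard_per_h_per_100um * b_mult,
    )


def load_config(path: str | Path) -> GrowthConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: expected a mapping")
    return GrowthConfig.from_dict(d)


def save_config(config: GrowthConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
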