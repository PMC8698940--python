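"""Rasterize ground-truth trees into time-lapse image stacks.

Frames emulate the organ-culture imaging cadence: one grayscale frame per
frame interval, ducts drawn as tubes of the configured width.  Growth is
monotone, so rendering is incremental — each frame adds only the polyline
points laid down since the previous frame — and the foreground pixel count
is non-decreasing over frames by construction.

Frames are noiseless by default (foreground 200, background 10 on uint8);
optional additive Gaussian noise emulates camera noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .config import GrowthConfig
from .tree import DuctalTree

__all__ = ["FrameStack", "render_stack", "RenderError", "BACKGROUND", "FOREGROUND"]

BACKGROUND = 10
FOREGROUND = 200


class RenderError(ValueError):
    pass


@dataclass
class FrameStack:
    """Ordered image frames with uniform timestamps and pixel size."""

    frames: np.ndarray       # (T, H, W) uint8
    timestamps: np.ndarray   # hours, strictly increasing, uniform
    pixel_size: float        # um / px
    anchor_x_um: float = 0.0  # x-position of the UGS anchor line

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.frames) != len(self.timestamps):
            raise ValueError("one timestamp per frame required")
        dt = np.diff(self.timestamps)
        if len(dt) and (dt.min() <= 0 or not np.allclose(dt, dt[0])):
            raise ValueError("timestamps must be strictly increasing and uniform")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_interval_h(self) -> float:
        return float(self.timestamps[1] - self.timestamps[0]) if len(self) > 1 else 0.0

    def save(self, tiff_path: str | Path) -> None:
        """Write a multi-page TIFF plus a JSON sidecar with the metadata."""
        tiff_path = Path(tiff_path)
        tifffile.imwrite(tiff_path, self.frames)
        sidecar = tiff_path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                dict(
                    pixel_size_um=self.pixel_size,
                    timestamps_h=self.timestamps.tolist(),
                    anchor_x_um=self.anchor_x_um,
                )
            )
        )

    @classmethod
    def load(cls, tiff_path: str | Path) -> "FrameStack":
        tiff_path = Path(tiff_path)
        frames = tifffile.imread(tiff_path)
        if frames.ndim == 2:
            frames = frames[None]
        meta = json.loads(tiff_path.with_suffix(".json").read_text())
        return cls(
            frames=frames,
            timestamps=np.array(meta["timestamps_h"]),
            pixel_size=float(meta["pixel_size_um"]),
            anchor_x_um=float(meta.get("anchor_x_um", 0.0)),
        )


def _disk_offsets(radius_px: int) -> tuple[np.ndarray, np.ndarray]:
    r = radius_px
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy * dy + dx * dx <= r * r
    return dy[keep], dx[keep]


def render_stack(tree: DuctalTree, config: GrowthConfig) -> FrameStack:
    """Rasterize the tree's state at each frame time as tubes of duct width.

    Raises :class:`RenderError` if any polyline point falls too close to the
    field boundary for its tube to fit (advise a larger field).
    """
    h, w = config.field_size_px
    px = config.pixel_size_um
    r = max(1, int(round(config.duct_width_um / 2.0 / px)))
    times = np.array(config.frame_times_h)
    if tree.duration < times[-1] - 1e-9:
        raise RenderError("tree duration shorter than the configured imaging span")

    pts = np.vstack([s.points for s in tree.segments.values()])
    cols = np.round(pts[:, 0] / px).astype(int)
    rows = np.round(pts[:, 1] / px).astype(int)
    if (
        cols.min() < r
        or rows.min() < r
        or cols.max() >= w - r
        or rows.max() >= h - r
    ):
        raise RenderError(
            "tree extends beyond the rendering field; use a larger field_size_px"
        )

    pt_times = np.concatenate([s.point_times for s in tree.segments.values()])
    order = np.argsort(pt_times, kind="stable")
    cols, rows, pt_times = cols[order], rows[order], pt_times[order]

    dy, dx = _disk_offsets(r)
    canvas = np.full((h, w), BACKGROUND, dtype=np.uint8)
    frames = np.empty((len(times), h, w), dtype=np.uint8)
    rng = np.random.default_rng(config.seed + 777) if config.noise_sigma > 0 else None
    start = 0
    for i, t in enumerate(times):
        stop = int(np.searchsorted(pt_times, t, side="right"))
        if stop > start:
            yy = (rows[start:stop, None] + dy[None, :]).ravel()
            xx = (cols[start:stop, None] + dx[None, :]).ravel()
            canvas[yy, xx] = FOREGROUND
            start = stop
        if rng is None:
            frames[i] = canvas
        else:
            noisy = canvas.astype(float) + rng.normal(0, config.noise_sigma, (h, w))
            frames[i] = np.clip(noisy, 0, 255).astype(np.uint8)

    return FrameStack(
        frames=frames,
        timestamps=times,
        pixel_size=px,
        anchor_x_um=float(tree.root_anchor[0][0]),
    )
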