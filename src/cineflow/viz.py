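"""Vector-overlay rendering of velocity fields on cine frames.

Arrows are drawn at blood-pool pixels (subsampled on a regular stride) whose
speed exceeds a display threshold — 4 cm/s by default, which suppresses
velocity noise without hiding the inflow/outflow jets. Arrow length and
color are monotone in speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .types import BloodPoolMask, CineSequence, FlowField, ValidationError

DISPLAY_THRESHOLD_CM_S = 4.0


@dataclass(frozen=True)
class OverlayConfig:
    threshold: float = DISPLAY_THRESHOLD_CM_S  # cm/s; arrows only above this
    vector_scale: float = 0.2  # px of arrow per cm/s
    colormap: str = "viridis"
    stride: int = 2  # subsampling of arrow origins

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValidationError("threshold must be >= 0")
        if self.stride < 1:
            raise ValidationError("stride must be >= 1")


def overlay_arrows(
    flow: FlowField, mask: BloodPoolMask, cfg: OverlayConfig, phase: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arrow origins (row, col), vector components (du_col, dv_row) in display
    pixels, and speeds for one phase. Pure geometry, used by the renderer and
    directly testable."""
    pool = mask.binary()[phase]
    speed = flow.speed()[phase]
    show = pool & (speed > cfg.threshold)
    sub = np.zeros_like(show)
    sub[:: cfg.stride, :: cfg.stride] = True
    show = show & sub
    rr, cc = np.nonzero(show)
    origins = np.stack([rr, cc], axis=1)
    du = flow.vx[phase][show] * cfg.vector_scale
    dv = flow.vy[phase][show] * cfg.vector_scale
    return origins, np.stack([du, dv], axis=1), speed[show]


def render_overlay(
    cine: CineSequence,
    flow: FlowField,
    mask: BloodPoolMask,
    cfg: OverlayConfig,
    out_dir: str | Path,
    phases: Optional[List[int]] = None,
) -> List[Path]:
    """Write one PNG per phase with the velocity vectors overlaid; returns the
    file paths (frame_000.png, ...)."""
    if flow.shape != cine.shape or mask.shape != cine.shape:
        raise ValidationError("cine/flow/mask shapes inconsistent")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    T = cine.shape[0]
    phases = list(range(T)) if phases is None else phases
    vmax = max(flow.speed().max(), cfg.threshold + 1e-6)
    paths = []
    for t in phases:
        origins, vectors, speeds = overlay_arrows(flow, mask, cfg, t)
        fig, ax = plt.subplots(figsize=(4, 4), dpi=100)
        ax.imshow(cine.frames[t], cmap="gray", interpolation="nearest")
        if len(origins):
            ax.quiver(
                origins[:, 1],
                origins[:, 0],
                vectors[:, 0],
                -vectors[:, 1],  # matplotlib y-axis points up in quiver coords
                speeds,
                cmap=cfg.colormap,
                clim=(cfg.threshold, vmax),
                angles="xy",
                scale_units="xy",
                scale=1.0,
                width=0.004,
            )
        ax.set_axis_off()
        path = out_dir / f"frame_{t:03d}.png"
        fig.savefig(path, bbox_inches="tight", pad_inches=0)
        plt.close(fig)
        paths.append(path)
    return paths
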