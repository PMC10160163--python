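"""Core domain containers shared by every pipeline stage.

Conventions used throughout the package:

* arrays are ``[T, H, W]`` (phase, row, column), 0-based indexing;
* ``x`` is the image-column direction, ``y`` the image-row direction;
* pixel centers sit at integer coordinates;
* velocities are cm/s, pixel spacing is mm, displacements are pixels per
  inter-frame interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract."""


class FormatError(ValidationError):
    """Raised when an on-disk case container is malformed."""


class DegenerateInputError(ValidationError):
    """Raised when an operation is undefined for the given data (e.g. empty mask)."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition geometry and timing of a cine series.

    Parameters
    ----------
    pixel_spacing:
        ``(ps_x, ps_y)`` in mm/pixel, column then row direction.
    frame_interval:
        Time between consecutive reconstructed phases, seconds.
    heart_rate:
        Beats per minute at acquisition.
    n_phases:
        Number of reconstructed cardiac phases.
    """

    pixel_spacing: Tuple[float, float]
    frame_interval: float
    heart_rate: float
    n_phases: int

    def __post_init__(self) -> None:
        ps_x, ps_y = self.pixel_spacing
        if not (ps_x > 0 and ps_y > 0):
            raise ValidationError(f"pixel spacing must be positive, got {self.pixel_spacing}")
        if not self.frame_interval > 0:
            raise ValidationError(f"frame interval must be positive, got {self.frame_interval}")
        if self.n_phases < 3:
            raise ValidationError(f"need at least 3 phases, got {self.n_phases}")

    def to_dict(self) -> Dict:
        return {
            "ps_x": self.pixel_spacing[0],
            "ps_y": self.pixel_spacing[1],
            "frame_interval": self.frame_interval,
            "heart_rate": self.heart_rate,
            "n_phases": self.n_phases,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "AcquisitionMeta":
        return cls(
            pixel_spacing=(float(d["ps_x"]), float(d["ps_y"])),
            frame_interval=float(d["frame_interval"]),
            heart_rate=float(d["heart_rate"]),
            n_phases=int(d["n_phases"]),
        )


def _check_stack(name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise ValidationError(f"{name} must be [T,H,W], got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class CineSequence:
    """A T-phase intensity stack with its acquisition metadata."""

    frames: np.ndarray  # [T, H, W]
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.frames = _check_stack("frames", self.frames).astype(np.float64, copy=False)
        if self.frames.shape[0] != self.meta.n_phases:
            raise ValidationError(
                f"frames has {self.frames.shape[0]} phases but meta.n_phases={self.meta.n_phases}"
            )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.frames.shape


@dataclass
class FlowField:
    """Per-pixel in-plane velocity, cm/s. ``vx`` is along columns, ``vy`` along rows."""

    vx: np.ndarray  # [T, H, W]
    vy: np.ndarray  # [T, H, W]

    def __post_init__(self) -> None:
        self.vx = _check_stack("vx", self.vx).astype(np.float64, copy=False)
        self.vy = _check_stack("vy", self.vy).astype(np.float64, copy=False)
        if self.vx.shape != self.vy.shape:
            raise ValidationError(f"vx/vy shape mismatch: {self.vx.shape} vs {self.vy.shape}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.vx.shape

    def speed(self) -> np.ndarray:
        """Per-pixel speed magnitude, cm/s."""
        return np.hypot(self.vx, self.vy)


@dataclass
class DisplacementField:
    """Per-pixel displacement from frame t to t+1, in pixel units."""

    dx: np.ndarray  # [T, H, W]
    dy: np.ndarray  # [T, H, W]

    def __post_init__(self) -> None:
        self.dx = _check_stack("dx", self.dx).astype(np.float64, copy=False)
        self.dy = _check_stack("dy", self.dy).astype(np.float64, copy=False)
        if self.dx.shape != self.dy.shape:
            raise ValidationError(f"dx/dy shape mismatch: {self.dx.shape} vs {self.dy.shape}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.dx.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dx, self.dy)


# Chamber labels used in BloodPoolMask.labels.
CHAMBER_LABELS = {"LV": 1, "LA": 2, "RV": 3, "RA": 4}
LABEL_NAMES = {v: k for k, v in CHAMBER_LABELS.items()}


@dataclass
class BloodPoolMask:
    """Per-phase labelled chamber mask: 0 background, 1..4 = LV, LA, RV, RA."""

    labels: np.ndarray  # [T, H, W] integer

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValidationError(f"labels must be [T,H,W], got {labels.shape}")
        if labels.min() < 0 or labels.max() > 4:
            raise ValidationError("labels must be in 0..4")
        self.labels = labels.astype(np.int16, copy=False)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    def binary(self) -> np.ndarray:
        """Boolean blood-pool mask (any chamber)."""
        return self.labels > 0

    def chamber(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class ContourSet:
    """Closed chamber contours per phase.

    ``polylines[phase][chamber]`` is an ``(n, 2)`` float array of ``(row, col)``
    vertices. Contours are implicitly closed (last vertex connects to first).
    For the LV the first and last vertices are the valve hinge points.
    """

    polylines: Dict[int, Dict[int, np.ndarray]] = field(default_factory=dict)

    def add(self, phase: int, chamber: int, vertices: np.ndarray) -> None:
        vertices = np.asarray(vertices, dtype=np.float64)
        if vertices.ndim != 2 or vertices.shape[1] != 2 or vertices.shape[0] < 3:
            raise ValidationError(
                f"contour needs >=3 (row,col) vertices, got shape {vertices.shape}"
            )
        self.polylines.setdefault(phase, {})[chamber] = vertices

    def get(self, phase: int, chamber: int) -> np.ndarray:
        return self.polylines[phase][chamber]

    def phases(self) -> List[int]:
        return sorted(self.polylines)

    def is_empty(self) -> bool:
        return not any(self.polylines.values())
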