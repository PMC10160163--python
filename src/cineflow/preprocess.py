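"""Intensity normalization, velocity/displacement unit conversion, heart-rate
screening and projection of volumetric velocities onto a long-axis plane.

Velocities are cm/s, pixel spacing mm, frame interval seconds; displacement
``D = (dt * v_x / ps_x, dt * v_y / ps_y)`` is in pixels per inter-frame
interval, with velocity converted to mm/s before the division.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .types import (
    AcquisitionMeta,
    BloodPoolMask,
    CineSequence,
    DegenerateInputError,
    DisplacementField,
    FlowField,
    ValidationError,
)

MM_PER_CM = 10.0

# Cine series are excluded when heart rate deviates from the flow acquisition
# by more than this many beats per minute (strict inequality).
HEART_RATE_TOLERANCE_BPM = 6.0


@dataclass(frozen=True)
class NormalizationStats:
    """5th/95th percentile of pooled blood-pool intensities over all phases."""

    p5: float
    p95: float

    def __post_init__(self) -> None:
        if not self.p95 > self.p5:
            raise DegenerateInputError(
                f"degenerate intensity range: p95={self.p95} <= p5={self.p5}"
            )


def normalize_intensities(
    seq: CineSequence, mask: BloodPoolMask
) -> Tuple[CineSequence, NormalizationStats]:
    """Map intensities to ``(I - P5) / (P95 - P5)``.

    Percentiles are taken over the pooled blood-pool pixels of *all* phases
    (linear interpolation between order statistics). Every pixel, masked or
    not, is mapped; values outside [0, 1] are deliberately not clipped so
    flow-induced signal loss remains visible to the network.
    """
    pool = mask.binary()
    if pool.shape != seq.frames.shape:
        raise ValidationError(f"mask shape {pool.shape} != frames shape {seq.frames.shape}")
    values = seq.frames[pool]
    if values.size == 0:
        raise DegenerateInputError("empty blood-pool mask")
    p5, p95 = np.percentile(values, [5.0, 95.0], method="linear")
    stats = NormalizationStats(p5=float(p5), p95=float(p95))
    normed = (seq.frames - stats.p5) / (stats.p95 - stats.p5)
    return CineSequence(frames=normed, meta=seq.meta), stats


def velocity_to_displacement(v: FlowField, meta: AcquisitionMeta) -> DisplacementField:
    """Convert an in-plane velocity field (cm/s) to pixel displacements per frame."""
    ps_x, ps_y = meta.pixel_spacing
    dt = meta.frame_interval
    dx = dt * (v.vx * MM_PER_CM) / ps_x
    dy = dt * (v.vy * MM_PER_CM) / ps_y
    return DisplacementField(dx=dx, dy=dy)


def displacement_to_velocity(d: DisplacementField, meta: AcquisitionMeta) -> FlowField:
    """Exact inverse of :func:`velocity_to_displacement` (pixels/frame -> cm/s)."""
    ps_x, ps_y = meta.pixel_spacing
    dt = meta.frame_interval
    vx = d.dx * ps_x / dt / MM_PER_CM
    vy = d.dy * ps_y / dt / MM_PER_CM
    return FlowField(vx=vx, vy=vy)


def check_heart_rate(hr_cine: float, hr_flow: float) -> str:
    """Temporal-consistency screen between cine and flow acquisitions.

    Returns ``"exclude"`` iff the rates differ by strictly more than
    6 bpm, else ``"keep"``.
    """
    if hr_cine <= 0 or hr_flow <= 0:
        raise ValidationError("heart rates must be positive")
    return "exclude" if abs(hr_cine - hr_flow) > HEART_RATE_TOLERANCE_BPM else "keep"


@dataclass(frozen=True)
class PlaneGeometry:
    """World-space placement of an imaging plane inside a velocity volume.

    ``origin`` is the world coordinate (mm) of pixel (0, 0); ``e_x``/``e_y``
    are in-plane orthonormal axes along columns/rows; ``pixel_spacing`` is
    (ps_x, ps_y) mm; ``extent`` is (H, W).
    """

    origin: Tuple[float, float, float]
    e_x: Tuple[float, float, float]
    e_y: Tuple[float, float, float]
    pixel_spacing: Tuple[float, float]
    extent: Tuple[int, int]

    def __post_init__(self) -> None:
        ex = np.asarray(self.e_x, dtype=float)
        ey = np.asarray(self.e_y, dtype=float)
        if abs(np.dot(ex, ey)) > 1e-8:
            raise ValidationError("plane axes must be orthogonal")
        if abs(np.linalg.norm(ex) - 1) > 1e-8 or abs(np.linalg.norm(ey) - 1) > 1e-8:
            raise ValidationError("plane axes must be unit length")

    def pixel_world_coords(self) -> np.ndarray:
        """World coordinates (mm) of all pixel centers, shape [H, W, 3]."""
        H, W = self.extent
        ps_x, ps_y = self.pixel_spacing
        origin = np.asarray(self.origin, dtype=float)
        ex = np.asarray(self.e_x, dtype=float)
        ey = np.asarray(self.e_y, dtype=float)
        cols = np.arange(W)[None, :, None] * ps_x * ex[None, None, :]
        rows = np.arange(H)[:, None, None] * ps_y * ey[None, None, :]
        return origin[None, None, :] + rows + cols


def project_volume_velocity(
    volume: np.ndarray,
    grid_spacing: Tuple[float, float, float],
    plane: PlaneGeometry,
    grid_origin: Tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Sample a volumetric 3-component velocity on a plane and keep the
    in-plane components.

    ``volume`` is ``[X, Y, Z, 3]`` on a regular grid with node spacing
    ``grid_spacing`` mm starting at ``grid_origin``. Each pixel's 3-vector is
    sampled by trilinear interpolation at its world coordinate and projected:
    ``v_x = v . e_x``, ``v_y = v . e_y`` (out-of-plane component discarded).
    Pixels falling outside the volume are zeroed and counted.

    Returns ``(vx, vy, n_out_of_bounds)`` for a single phase.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 4 or volume.shape[3] != 3:
        raise ValidationError(f"volume must be [X,Y,Z,3], got {volume.shape}")
    axes = [
        grid_origin[i] + np.arange(volume.shape[i]) * grid_spacing[i] for i in range(3)
    ]
    interp = RegularGridInterpolator(
        axes, volume, method="linear", bounds_error=False, fill_value=np.nan
    )
    coords = plane.pixel_world_coords()  # [H, W, 3]
    sampled = interp(coords.reshape(-1, 3)).reshape(*plane.extent, 3)
    oob = np.isnan(sampled).any(axis=2)
    sampled = np.where(oob[..., None], 0.0, sampled)
    ex = np.asarray(plane.e_x, dtype=float)
    ey = np.asarray(plane.e_y, dtype=float)
    vx = sampled @ ex
    vy = sampled @ ey
    return vx, vy, int(oob.sum())
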