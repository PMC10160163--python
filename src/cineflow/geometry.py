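"""Contour rasterization, temporal windowing and in-plane translation."""

from __future__ import annotations

from typing import Tuple, Union

import numpy as np

from .types import (
    BloodPoolMask,
    CineSequence,
    ContourSet,
    FlowField,
    ValidationError,
)

_EDGE_TOL = 1e-9


def points_in_polygon(points: np.ndarray, polygon: np.ndarray, tol: float = _EDGE_TOL) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test, vectorized.

    Points lying exactly on a polygon edge (within ``tol``) count as inside,
    so a polygon traced through pixel centers labels those centers.

    Parameters
    ----------
    points:
        ``(n, 2)`` array of ``(row, col)`` query points.
    polygon:
        ``(m, 2)`` array of ``(row, col)`` vertices of an implicitly closed
        polygon.
    """
    pts = np.asarray(points, dtype=np.float64)
    poly = np.asarray(polygon, dtype=np.float64)
    py, px = pts[:, 0][:, None], pts[:, 1][:, None]  # rows, cols
    ay, ax = poly[:, 0][None, :], poly[:, 1][None, :]
    by, bx = np.roll(poly[:, 0], -1)[None, :], np.roll(poly[:, 1], -1)[None, :]

    # Crossing number: edge straddles the horizontal ray through the point.
    straddle = (ay > py) != (by > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_cross = ax + (py - ay) * (bx - ax) / (by - ay)
    crossings = straddle & (px < x_cross)
    inside = crossings.sum(axis=1) % 2 == 1

    # On-edge test: distance from point to segment below tol.
    ex, ey = bx - ax, by - ay
    seg_len2 = ex * ex + ey * ey
    t = np.where(seg_len2 > 0, ((px - ax) * ex + (py - ay) * ey) / np.where(seg_len2 > 0, seg_len2, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    d2 = (ax + t * ex - px) ** 2 + (ay + t * ey - py) ** 2
    on_edge = (d2 <= tol * tol).any(axis=1)
    return inside | on_edge


def rasterize_polygon(polygon: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixel centers inside (or on) a closed polygon."""
    H, W = shape
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)
    return points_in_polygon(pts, polygon).reshape(H, W)


def rasterize_contours(contours: ContourSet, shape: Tuple[int, int], n_phases: int | None = None) -> BloodPoolMask:
    """Rasterize per-phase chamber contours into a labelled mask.

    A pixel is labelled ``c`` iff its center lies inside the chamber-``c``
    polygon (even-odd rule, boundary inclusive); where chambers overlap the
    lowest chamber index wins.
    """
    phases = contours.phases()
    if n_phases is None:
        n_phases = (max(phases) + 1) if phases else 1
    H, W = shape
    labels = np.zeros((n_phases, H, W), dtype=np.int16)
    for phase in phases:
        for chamber in sorted(contours.polylines[phase]):
            poly = contours.polylines[phase][chamber]
            if poly.shape[0] < 3:
                raise ValidationError(f"degenerate contour (<3 vertices) phase {phase} chamber {chamber}")
            if poly.min() < 0 or poly[:, 0].max() > H - 1 or poly[:, 1].max() > W - 1:
                raise ValidationError(f"contour out of bounds: phase {phase} chamber {chamber}")
            region = rasterize_polygon(poly, shape)
            sub = labels[phase]
            sub[region & (sub == 0)] = chamber
    return BloodPoolMask(labels=labels)


def temporal_window(seq: CineSequence, t: int, k: int) -> np.ndarray:
    """Extract the ``2k+1``-frame window centered on phase ``t``.

    The cardiac cycle is periodic, so the window wraps cyclically; the
    central frame sits at index ``k`` of the result.
    """
    T = seq.frames.shape[0]
    if k < 0 or 2 * k + 1 > T:
        raise ValidationError(f"invalid half-width k={k} for T={T}")
    if not (0 <= t < T):
        raise ValidationError(f"phase index {t} out of range [0,{T})")
    idx = np.arange(t - k, t + k + 1) % T
    return seq.frames[idx]


def window_indices(T: int, t: int, k: int) -> np.ndarray:
    """Cyclic phase indices of the window centered at ``t`` (helper for samplers)."""
    if k < 0 or 2 * k + 1 > T:
        raise ValidationError(f"invalid half-width k={k} for T={T}")
    return np.arange(t - k, t + k + 1) % T


def _shift2d(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(arr)
    H, W = arr.shape[-2:]
    src_r = slice(max(0, -dr), min(H, H - dr))
    dst_r = slice(max(0, dr), min(H, H + dr))
    src_c = slice(max(0, -dc), min(W, W - dc))
    dst_c = slice(max(0, dc), min(W, W + dc))
    out[..., dst_r, dst_c] = arr[..., src_r, src_c]
    return out


def translate_inplane(
    field: Union[CineSequence, FlowField], offset: Tuple[int, int]
) -> Union[CineSequence, FlowField]:
    """Shift every phase by an integer ``(d_row, d_col)`` offset, zero-filling.

    Stands in for the manual in-plane alignment step between a cine series
    and the velocity reference; the same offset is applied to all phases.
    """
    dr, dc = offset
    if int(dr) != dr or int(dc) != dc:
        raise ValidationError(f"offset must be integer, got {offset}")
    dr, dc = int(dr), int(dc)
    if isinstance(field, CineSequence):
        H, W = field.frames.shape[1:]
        if abs(dr) >= H or abs(dc) >= W:
            raise ValidationError(f"offset {offset} exceeds image extent ({H},{W})")
        return CineSequence(frames=_shift2d(field.frames, dr, dc), meta=field.meta)
    if isinstance(field, FlowField):
        H, W = field.vx.shape[1:]
        if abs(dr) >= H or abs(dc) >= W:
            raise ValidationError(f"offset {offset} exceeds image extent ({H},{W})")
        return FlowField(vx=_shift2d(field.vx, dr, dc), vy=_shift2d(field.vy, dr, dc))
    raise ValidationError(f"unsupported field type {type(field)!r}")
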