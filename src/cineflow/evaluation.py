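"""Quantitative comparison of predicted and reference velocity fields.

Metrics follow optical-flow practice adapted to intra-cardiac flow:

* **EPE (cm/s)** — Euclidean distance between velocity vectors averaged over
  blood-pool pixels whose *reference* speed exceeds a threshold (default
  5 cm/s), pooled over all phases.
* **Angle error (degrees)** — mean arccos of the normalized dot product,
  in [0, 180], over the same qualifying pixels.
* **Relative error (%)** — signed difference of mean speeds over all masked
  pixels, ``100 * (mean|Vp| - mean|Vg|) / mean|Vg|`` (negative means the
  prediction underestimates).
* **PCC** — Pearson correlation of the two length-T spatially averaged speed
  series over the cardiac cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .types import (
    BloodPoolMask,
    DegenerateInputError,
    FlowField,
    ValidationError,
)

DEFAULT_SPEED_GATE = 5.0  # cm/s; reference-speed gate for EPE / angle error

REGIONS = {"4CH": None, "LV": 1, "LA": 2, "RV": 3, "RA": 4}


def _region_mask(mask: BloodPoolMask, label: Optional[int]) -> np.ndarray:
    return mask.binary() if label is None else mask.chamber(label)


def _check_shapes(pred: FlowField, ref: FlowField, region: np.ndarray) -> None:
    if pred.shape != ref.shape or region.shape != pred.shape:
        raise ValidationError(
            f"shape mismatch: pred {pred.shape}, ref {ref.shape}, mask {region.shape}"
        )


def velocity_epe(
    pred: FlowField,
    ref: FlowField,
    mask: BloodPoolMask,
    vmin: float = DEFAULT_SPEED_GATE,
    region: Optional[int] = None,
) -> float:
    """End-point error on velocity vectors (cm/s), reference speed > ``vmin``."""
    m = _region_mask(mask, region)
    _check_shapes(pred, ref, m)
    qual = m & (ref.speed() > vmin)
    if not qual.any():
        raise DegenerateInputError(f"no qualifying pixels above {vmin} cm/s")
    err = np.hypot(pred.vx - ref.vx, pred.vy - ref.vy)
    return float(err[qual].mean())


def angle_error(
    pred: FlowField,
    ref: FlowField,
    mask: BloodPoolMask,
    vmin: float = DEFAULT_SPEED_GATE,
    region: Optional[int] = None,
) -> Tuple[float, int]:
    """Mean angular deviation in degrees over qualifying pixels.

    Pixels where either vector has zero magnitude are excluded; the count of
    such exclusions is returned alongside the metric.
    """
    m = _region_mask(mask, region)
    _check_shapes(pred, ref, m)
    qual = m & (ref.speed() > vmin)
    if not qual.any():
        raise DegenerateInputError(f"no qualifying pixels above {vmin} cm/s")
    pvx, pvy = pred.vx[qual], pred.vy[qual]
    rvx, rvy = ref.vx[qual], ref.vy[qual]
    pn = np.hypot(pvx, pvy)
    rn = np.hypot(rvx, rvy)
    ok = (pn > 0) & (rn > 0)
    excluded = int((~ok).sum())
    if not ok.any():
        raise DegenerateInputError("all qualifying pixels have a zero-magnitude vector")
    cosang = (pvx[ok] * rvx[ok] + pvy[ok] * rvy[ok]) / (pn[ok] * rn[ok])
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(ang.mean()), excluded


def relative_error(
    pred: FlowField, ref: FlowField, mask: BloodPoolMask, region: Optional[int] = None
) -> float:
    """Signed relative difference (%) of mean speeds over all masked pixels."""
    m = _region_mask(mask, region)
    _check_shapes(pred, ref, m)
    if not m.any():
        raise DegenerateInputError("empty mask")
    mean_ref = float(ref.speed()[m].mean())
    if mean_ref == 0:
        raise DegenerateInputError("reference speed identically zero in mask")
    mean_pred = float(pred.speed()[m].mean())
    return 100.0 * (mean_pred - mean_ref) / mean_ref


def velocity_pcc(
    pred: FlowField, ref: FlowField, mask: BloodPoolMask, region: Optional[int] = None
) -> Optional[float]:
    """Pearson r between the per-phase spatially averaged speed series.

    Returns ``None`` when either series has zero variance (r undefined).
    """
    m = _region_mask(mask, region)
    _check_shapes(pred, ref, m)
    T = pred.shape[0]
    if T < 3:
        raise ValidationError("need at least 3 phases for a cycle correlation")
    ps, rs = [], []
    for t in range(T):
        mt = m[t]
        if not mt.any():
            raise DegenerateInputError(f"empty mask at phase {t}")
        ps.append(pred.speed()[t][mt].mean())
        rs.append(ref.speed()[t][mt].mean())
    ps, rs = np.asarray(ps), np.asarray(rs)
    if ps.std() == 0 or rs.std() == 0:
        return None
    return float(stats.pearsonr(ps, rs).statistic)


@dataclass(frozen=True)
class VelocityHistogram:
    """Normalized speed distribution over masked pixels of all phases."""

    bin_edges: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.probability < 0) or not np.isclose(self.probability.sum(), 1.0):
            raise ValidationError("histogram mass must be non-negative and sum to 1")


def velocity_histogram(
    field: FlowField,
    mask: BloodPoolMask,
    edges: Sequence[float],
    region: Optional[int] = None,
) -> VelocityHistogram:
    """Probability mass of speeds per bin; out-of-range mass folds into the end bins."""
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("edges must be a monotone 1-D sequence of >= 2 values")
    m = _region_mask(mask, region)
    if m.shape != field.shape:
        raise ValidationError("mask/field shape mismatch")
    speeds = field.speed()[m]
    if speeds.size == 0:
        raise DegenerateInputError("empty mask")
    clipped = np.clip(speeds, edges[0], edges[-1])
    counts, _ = np.histogram(clipped, bins=edges)
    return VelocityHistogram(bin_edges=edges, probability=counts / counts.sum())


def threshold_sweep(
    pred: FlowField,
    ref: FlowField,
    mask: BloodPoolMask,
    vmins: Sequence[float],
    region: Optional[int] = None,
) -> List[Dict]:
    """EPE and angle error at each reference-speed threshold.

    Rows where no pixel qualifies carry ``None`` metrics and a zero count.
    """
    if len(vmins) == 0:
        raise ValidationError("empty threshold list")
    m = _region_mask(mask, region)
    rows = []
    for vmin in vmins:
        qual = int((m & (ref.speed() > vmin)).sum())
        if qual == 0:
            rows.append({"vmin": float(vmin), "n_pixels": 0, "epe": None, "angle_error": None})
            continue
        ang, _ = angle_error(pred, ref, mask, vmin=vmin, region=region)
        rows.append(
            {
                "vmin": float(vmin),
                "n_pixels": qual,
                "epe": velocity_epe(pred, ref, mask, vmin=vmin, region=region),
                "angle_error": ang,
            }
        )
    return rows


def threshold_accuracy(
    pred: FlowField,
    ref: FlowField,
    mask: BloodPoolMask,
    percentile: float = 30.0,
    vmin: float = DEFAULT_SPEED_GATE,
    region: Optional[int] = None,
) -> float:
    """Fraction of qualifying pixels whose velocity EPE falls below the given
    percentile of the reference speed distribution.

    One plausible reading of a percentile-thresholded accuracy; reported only
    when explicitly requested, never part of the default metric set.
    """
    m = _region_mask(mask, region)
    _check_shapes(pred, ref, m)
    qual = m & (ref.speed() > vmin)
    if not qual.any():
        raise DegenerateInputError(f"no qualifying pixels above {vmin} cm/s")
    cutoff = np.percentile(ref.speed()[m], percentile)
    err = np.hypot(pred.vx - ref.vx, pred.vy - ref.vy)[qual]
    return float((err < cutoff).mean())


@dataclass
class MetricsReport:
    """Cohort metrics per region: case-level mean +/- sd, Table-style."""

    rows: Dict[str, Dict[str, Optional[float]]]
    vmin: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows).T


def cohort_metrics(
    preds: Dict[str, FlowField],
    refs: Dict[str, FlowField],
    masks: Dict[str, BloodPoolMask],
    vmin: float = DEFAULT_SPEED_GATE,
) -> MetricsReport:
    """Case-level metrics aggregated to cohort mean +/- sd for each region.

    Regions with no labelled pixels (or no qualifying pixels) in a case are
    skipped for that case.
    """
    rows: Dict[str, Dict[str, Optional[float]]] = {}
    for name, label in REGIONS.items():
        epes, angs, res, pccs = [], [], [], []
        for cid in preds:
            pred, ref, mask = preds[cid], refs[cid], masks[cid]
            region_pixels = _region_mask(mask, label)
            if not region_pixels.any():
                continue
            try:
                epes.append(velocity_epe(pred, ref, mask, vmin=vmin, region=label))
                angs.append(angle_error(pred, ref, mask, vmin=vmin, region=label)[0])
            except DegenerateInputError:
                pass
            try:
                res.append(relative_error(pred, ref, mask, region=label))
            except DegenerateInputError:
                pass
            r = velocity_pcc(pred, ref, mask, region=label)
            if r is not None:
                pccs.append(r)
        rows[name] = {
            "epe_mean": float(np.mean(epes)) if epes else None,
            "epe_sd": float(np.std(epes, ddof=1)) if len(epes) > 1 else None,
            "angle_mean": float(np.mean(angs)) if angs else None,
            "angle_sd": float(np.std(angs, ddof=1)) if len(angs) > 1 else None,
            "re_mean": float(np.mean(res)) if res else None,
            "re_sd": float(np.std(res, ddof=1)) if len(res) > 1 else None,
            "pcc_mean": float(np.mean(pccs)) if pccs else None,
            "n_cases": len(epes),
        }
    return MetricsReport(rows=rows, vmin=vmin)
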