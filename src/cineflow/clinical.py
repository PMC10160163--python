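"""Automated E/A-ratio extraction and diastolic-function classification.

The transmitral sampling region is built from three anatomical landmarks:
the two valve hinge points (first and last vertices of the LV endocardial
contour) and the LV cavity center. A clamped quadratic b-spline through the
three points bounds, together with the hinge-to-hinge chord, a region just
below the mitral valve plane. The E (early) and A (atrial) velocities are
the two prominent diastolic peaks of the per-phase maximum in-plane speed
within that region; 0.75 < E/A < 1.5 counts as normal diastolic function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline
from scipy.signal import find_peaks
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .geometry import rasterize_polygon
from .types import DegenerateInputError, FlowField, ValidationError

# Echocardiographic normal band for the E/A ratio (strict inequalities).
EA_NORMAL_LOW = 0.75
EA_NORMAL_HIGH = 1.5


class EADetectionError(RuntimeError):
    """E/A extraction failed (fewer than two prominent diastolic peaks)."""


@dataclass(frozen=True)
class EAResult:
    e_velocity: float  # cm/s
    a_velocity: float  # cm/s
    ratio: float
    diastolic_class: int  # 0 normal, 1 abnormal
    e_phase: float  # sub-phase (parabolic-refined) index
    a_phase: float

    def __post_init__(self) -> None:
        if self.e_velocity <= 0 or self.a_velocity <= 0:
            raise ValidationError("E and A velocities must be positive")


@dataclass(frozen=True)
class AgreementStats:
    bias: float
    loa_half_width: float  # 1.96 * SD of differences
    pcc: Optional[float]
    t_statistic: float
    p_value: float
    n: int


@dataclass
class ConfusionMetrics:
    matrix: np.ndarray  # rows = reference, cols = predicted
    accuracy: float
    per_class: Dict[int, Dict[str, float]]  # precision / recall / f1 per label


# ---------------------------------------------------------------------------
# mitral ROI
# ---------------------------------------------------------------------------

def mitral_roi(
    hinge1: Sequence[float],
    hinge2: Sequence[float],
    cavity_center: Sequence[float],
    shape: Tuple[int, int],
    lv_mask: Optional[np.ndarray] = None,
    n_samples: int = 64,
) -> Tuple[np.ndarray, bool]:
    """Region between the valve-plane chord and the b-spline bulging toward
    the cavity center.

    Returns ``(roi, degenerate)``; ``degenerate`` is True when the three
    points are (near-)collinear and the region collapses onto the chord.
    """
    h1 = np.asarray(hinge1, dtype=float)
    h2 = np.asarray(hinge2, dtype=float)
    c = np.asarray(cavity_center, dtype=float)
    # clamped quadratic b-spline through the three control points
    spline = BSpline(np.array([0, 0, 0, 1, 1, 1], dtype=float), np.stack([h1, c, h2]), 2)
    curve = spline(np.linspace(0.0, 1.0, n_samples))
    polygon = curve  # implicit closing edge h2 -> h1 is the valve-plane chord
    area = 0.5 * abs(
        np.sum(
            polygon[:, 0] * np.roll(polygon[:, 1], -1)
            - polygon[:, 1] * np.roll(polygon[:, 0], -1)
        )
    )
    degenerate = area < 0.5  # less than half a pixel of enclosed area
    roi = rasterize_polygon(polygon, shape)
    if lv_mask is not None:
        roi = roi & np.asarray(lv_mask, dtype=bool)
    return roi, degenerate


def mitral_roi_from_contour(
    lv_contour: np.ndarray,
    shape: Tuple[int, int],
    lv_mask: Optional[np.ndarray] = None,
    cavity_center: Optional[Sequence[float]] = None,
) -> Tuple[np.ndarray, bool]:
    """Convenience wrapper: hinge points are the contour's first/last vertices;
    the cavity center defaults to the contour centroid."""
    lv_contour = np.asarray(lv_contour, dtype=float)
    if cavity_center is None:
        cavity_center = lv_contour.mean(axis=0)
    return mitral_roi(lv_contour[0], lv_contour[-1], cavity_center, shape, lv_mask)


# ---------------------------------------------------------------------------
# velocity curve and peak detection
# ---------------------------------------------------------------------------

def max_velocity_curve(flow: FlowField, rois: np.ndarray) -> np.ndarray:
    """Per-phase maximum in-plane speed within the ROI, cm/s.

    ``rois`` is ``[T, H, W]`` boolean (a fixed ROI may be broadcast by the
    caller). Phases with an empty ROI yield NaN (value absent).
    """
    T = flow.shape[0]
    rois = np.asarray(rois, dtype=bool)
    if rois.shape != flow.shape:
        raise ValidationError(f"rois shape {rois.shape} != flow shape {flow.shape}")
    speed = flow.speed()
    curve = np.full(T, np.nan)
    for t in range(T):
        if rois[t].any():
            curve[t] = speed[t][rois[t]].max()
    return curve


def _parabolic_refine(seg: np.ndarray, i: int) -> Tuple[float, float]:
    """Refine a discrete peak by fitting a parabola through its 3-point
    neighbourhood; falls back to the sample itself at segment boundaries."""
    if 0 < i < len(seg) - 1:
        y0, y1, y2 = seg[i - 1], seg[i], seg[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            value = y1 - (y0 - y2) ** 2 / (8 * denom)
            return i + delta, float(value)
    return float(i), float(seg[i])


def default_diastole_onset(curve: np.ndarray) -> int:
    """Heuristic diastole onset: the minimum of the velocity curve in the
    mid-cycle window (after the systolic peak, before early filling)."""
    T = len(curve)
    lo, hi = int(0.3 * T), max(int(0.3 * T) + 1, int(0.6 * T))
    window = curve[lo:hi]
    if np.all(np.isnan(window)):
        raise EADetectionError("velocity curve undefined in mid-cycle window")
    return lo + int(np.nanargmin(window))


def detect_e_a(
    curve: np.ndarray,
    systole_end_phase: Optional[int] = None,
    prominence_fraction: float = 0.1,
) -> Tuple[float, float, float, float]:
    """Locate the E and A peaks on the diastolic part of the velocity curve.

    E is the first prominent local maximum after ``systole_end_phase``, A the
    last one before cycle end; prominence must exceed
    ``prominence_fraction`` of the diastolic range. Sub-phase peak positions
    and values are refined parabolically. Raises :class:`EADetectionError`
    when fewer than two prominent peaks exist (an explicit failure, never a
    NaN ratio).

    Returns ``(e_velocity, a_velocity, e_phase, a_phase)``.
    """
    curve = np.asarray(curve, dtype=float)
    if systole_end_phase is None:
        systole_end_phase = default_diastole_onset(curve)
    if not (0 <= systole_end_phase < len(curve) - 1):
        raise ValidationError(f"systole_end_phase {systole_end_phase} out of range")
    seg = curve[systole_end_phase:]
    if np.any(np.isnan(seg)):
        raise EADetectionError("velocity curve has undefined diastolic phases")
    rng_ = seg.max() - seg.min()
    if rng_ <= 0:
        raise EADetectionError("flat diastolic velocity curve")
    padded = np.r_[-np.inf, seg, -np.inf]
    peaks, _ = find_peaks(padded, prominence=prominence_fraction * rng_)
    peaks = peaks - 1
    if len(peaks) < 2:
        raise EADetectionError(
            f"found {len(peaks)} prominent diastolic peak(s); need E and A"
        )
    e_i, a_i = int(peaks[0]), int(peaks[-1])
    e_phase, e_vel = _parabolic_refine(seg, e_i)
    a_phase, a_vel = _parabolic_refine(seg, a_i)
    return e_vel, a_vel, e_phase + systole_end_phase, a_phase + systole_end_phase


def classify_diastolic(ratio: float) -> int:
    """0 (normal) iff ``0.75 < E/A < 1.5`` strictly, else 1 (abnormal)."""
    if not ratio > 0:
        raise ValidationError(f"E/A ratio must be positive, got {ratio}")
    return 0 if EA_NORMAL_LOW < ratio < EA_NORMAL_HIGH else 1


def ea_from_flow(
    flow: FlowField,
    rois: np.ndarray,
    systole_end_phase: Optional[int] = None,
) -> EAResult:
    """Full E/A pipeline: ROI speed curve -> peaks -> ratio -> class."""
    curve = max_velocity_curve(flow, rois)
    e_vel, a_vel, e_phase, a_phase = detect_e_a(curve, systole_end_phase)
    ratio = e_vel / a_vel
    return EAResult(
        e_velocity=e_vel,
        a_velocity=a_vel,
        ratio=ratio,
        diastolic_class=classify_diastolic(ratio),
        e_phase=e_phase,
        a_phase=a_phase,
    )


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def bland_altman(pairs: Sequence[Tuple[float, float]]) -> AgreementStats:
    """Bias, limits of agreement (1.96 x SD, sample SD), PCC and paired t-test
    for (predicted, reference) measurement pairs."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValidationError("need >= 2 (pred, ref) pairs")
    pred, ref = pairs[:, 0], pairs[:, 1]
    diffs = pred - ref
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if pred.std() == 0 or ref.std() == 0:
        pcc = None
    else:
        pcc = float(stats.pearsonr(pred, ref).statistic)
    if sd == 0:
        t_stat, p_val = 0.0, 1.0
    else:
        t = stats.ttest_rel(pred, ref)
        t_stat, p_val = float(t.statistic), float(t.pvalue)
    return AgreementStats(
        bias=bias,
        loa_half_width=1.96 * sd,
        pcc=pcc,
        t_statistic=t_stat,
        p_value=p_val,
        n=len(pairs),
    )


def confusion_metrics(
    ref_labels: Sequence[int], pred_labels: Sequence[int]
) -> ConfusionMetrics:
    """2x2 confusion counts (rows = reference) with accuracy and per-class
    precision/recall/F1. Metrics of a class absent from both label lists are
    omitted."""
    ref = np.asarray(ref_labels, dtype=int)
    pred = np.asarray(pred_labels, dtype=int)
    if ref.shape != pred.shape or ref.ndim != 1:
        raise ValidationError("label lists must be equal-length 1-D sequences")
    if not set(np.unique(np.r_[ref, pred])).issubset({0, 1}):
        raise ValidationError("labels must be binary (0/1)")
    matrix = confusion_matrix(ref, pred, labels=[0, 1])
    accuracy = float(np.trace(matrix)) / len(ref)
    precision, recall, f1, support = precision_recall_fscore_support(
        ref, pred, labels=[0, 1], zero_division=0.0
    )
    per_class: Dict[int, Dict[str, float]] = {}
    for label in (0, 1):
        present = (ref == label).any() or (pred == label).any()
        if not present:
            continue
        per_class[label] = {
            "precision": float(precision[label]),
            "recall": float(recall[label]),
            "f1": float(f1[label]),
        }
    return ConfusionMetrics(matrix=matrix, accuracy=accuracy, per_class=per_class)
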