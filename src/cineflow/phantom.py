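"""Cine phantom generator with exactly known in-plane velocity fields.

The phantom emulates a two-chamber long-axis view: an elliptical ventricle
("LV") joined at a valve gap to a smaller atrium ("LA"). The analytic flow is

* a solid-rotation vortex inside the LV, scaled by a systolic temporal
  envelope, and
* a biphasic diastolic inflow jet through the valve gap whose speed over the
  cycle is ``g(t) = E*exp(-(t-t_E)^2/2s^2) + A*exp(-(t-t_A)^2/2s^2)`` with
  configurable early (E) and atrial (A) peak speeds.

Image frames carry a band-limited speckle texture advected by the true
displacement field (backward warping, bilinear sampling), so the intensity
fluctuations that a tracking network exploits in vivo are present with a
known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .preprocess import velocity_to_displacement
from .types import (
    AcquisitionMeta,
    BloodPoolMask,
    CineSequence,
    ContourSet,
    FlowField,
    ValidationError,
)

_BACKGROUND_INTENSITY = 0.2


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom geometry, flow amplitudes and rendering parameters.

    Temporal quantities are phase-cycle fractions in (0, 1); speeds are cm/s.
    Geometry fields left at ``None`` are resolved from the grid size (the
    defaults trace a plausible two-chamber long-axis layout).
    """

    grid: Tuple[int, int] = (64, 64)
    n_phases: int = 30
    pixel_spacing: Tuple[float, float] = (1.5, 1.5)  # mm
    heart_rate: float = 60.0  # bpm
    frame_interval: Optional[float] = None  # s; derived from heart rate if None
    lv_center: Optional[Tuple[float, float]] = None  # (row, col)
    lv_semi_axes: Optional[Tuple[float, float]] = None  # (a_row, a_col) px
    vortex_peak_speed: float = 10.0  # cm/s, max speed of the systolic vortex
    vortex_baseline: float = 0.3  # persistent fraction of the vortex outside systole
    la_vortex_fraction: float = 0.5  # atrial swirl strength relative to the LV vortex
    systole_peak_fraction: float = 0.25
    systole_width: float = 0.08
    e_peak_speed: float = 56.0  # cm/s
    a_peak_speed: float = 40.0  # cm/s
    e_peak_fraction: float = 0.65
    a_peak_fraction: float = 0.90
    jet_sigma: float = 0.05  # temporal Gaussian width, cycle fractions
    gap_half_width: Optional[float] = None  # px, valve opening half-width
    texture_length: float = 1.5  # px, speckle correlation length
    noise_sd: float = 0.0  # fraction of intensity range
    attenuation: float = 0.0  # speed-proportional dimming exp(-attenuation*|v|)
    seed: int = 0

    def __post_init__(self) -> None:
        # tolerate list-valued fields (e.g. from YAML configs)
        for name in ("grid", "pixel_spacing", "lv_center", "lv_semi_axes"):
            v = getattr(self, name)
            if isinstance(v, list):
                object.__setattr__(self, name, tuple(v))
        H, W = self.grid
        if H < 8 or W < 8:
            raise ValidationError(f"grid too small: {self.grid}")
        if self.n_phases < 3:
            raise ValidationError("need at least 3 phases")
        for name in ("e_peak_fraction", "a_peak_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must be in (0,1), got {v}")
        if not self.e_peak_fraction < self.a_peak_fraction:
            raise ValidationError("E peak must precede A peak")
        if min(self.e_peak_speed, self.a_peak_speed, self.vortex_peak_speed) < 0:
            raise ValidationError("speeds must be non-negative")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be non-negative")

    # -- resolved geometry -------------------------------------------------
    @property
    def dt(self) -> float:
        if self.frame_interval is not None:
            return self.frame_interval
        return 60.0 / self.heart_rate / self.n_phases

    @property
    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(
            pixel_spacing=self.pixel_spacing,
            frame_interval=self.dt,
            heart_rate=self.heart_rate,
            n_phases=self.n_phases,
        )

    def geometry(self) -> dict:
        """Resolve chamber geometry in pixel coordinates."""
        H, W = self.grid
        lv_c = self.lv_center if self.lv_center is not None else (0.625 * H, 0.5 * W)
        lv_s = self.lv_semi_axes if self.lv_semi_axes is not None else (0.266 * H, 0.203 * W)
        la_s = (0.125 * H, 0.156 * W)
        la_c = (lv_c[0] - lv_s[0] - la_s[0], lv_c[1])
        gap = self.gap_half_width if self.gap_half_width is not None else 0.094 * W
        if gap >= lv_s[1]:
            raise ValidationError(
                f"jet gap half-width {gap} exceeds LV semi-axis {lv_s[1]}"
            )
        # Valve hinge points: intersections of the gap strip with the LV ellipse.
        u = gap / lv_s[1]
        hinge_row = lv_c[0] - lv_s[0] * np.sqrt(1.0 - u * u)
        return {
            "lv_center": lv_c,
            "lv_semi": lv_s,
            "la_center": la_c,
            "la_semi": la_s,
            "gap_half_width": gap,
            "hinge_row": hinge_row,
            "hinges": ((hinge_row, lv_c[1] - gap), (hinge_row, lv_c[1] + gap)),
        }


@dataclass
class Phantom:
    """A rendered phantom: cine frames, exact flow, masks, contours, config echo."""

    cine: CineSequence
    truth: FlowField
    mask: BloodPoolMask
    contours: ContourSet
    config: PhantomConfig


def _ellipse_interior(H: int, W: int, center, semi) -> np.ndarray:
    rr, cc = np.mgrid[0:H, 0:W]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def jet_speed_profile(cfg: PhantomConfig, fractions: np.ndarray) -> np.ndarray:
    """Biphasic inflow speed g(t) at the valve gap, cm/s."""
    f = np.asarray(fractions, dtype=float)
    s = cfg.jet_sigma
    return cfg.e_peak_speed * np.exp(-((f - cfg.e_peak_fraction) ** 2) / (2 * s * s)) + (
        cfg.a_peak_speed * np.exp(-((f - cfg.a_peak_fraction) ** 2) / (2 * s * s))
    )


def systolic_envelope(cfg: PhantomConfig, phase_fraction) -> np.ndarray:
    """Temporal modulation of the circulation: a persistent baseline plus a
    Gaussian systolic surge (intra-cardiac swirl never fully stops)."""
    f = np.asarray(phase_fraction, dtype=float)
    surge = np.exp(-((f - cfg.systole_peak_fraction) ** 2) / (2 * cfg.systole_width**2))
    return cfg.vortex_baseline + (1.0 - cfg.vortex_baseline) * surge


def vortex_component(cfg: PhantomConfig, phase_fraction: float) -> Tuple[np.ndarray, np.ndarray]:
    """Solid-rotation vortex velocity (cm/s) inside the LV at one phase.

    The rotation rate is scaled so the peak boundary speed equals
    ``vortex_peak_speed`` at the systolic envelope maximum. Being a rigid
    rotation, the field is divergence-free.
    """
    H, W = cfg.grid
    g = cfg.geometry()
    cy, cx = g["lv_center"]
    a_major = max(g["lv_semi"])
    omega = cfg.vortex_peak_speed / a_major * float(systolic_envelope(cfg, phase_fraction))
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    vx = -omega * (rr - cy)
    vy = omega * (cc - cx)
    inside = _ellipse_interior(H, W, g["lv_center"], g["lv_semi"])
    return vx * inside, vy * inside


def _la_vortex(cfg: PhantomConfig, phase_fraction: float, la_region: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Gentler counter-swirl inside the atrium, same temporal envelope."""
    H, W = cfg.grid
    g = cfg.geometry()
    cy, cx = g["la_center"]
    a_major = max(g["la_semi"])
    peak = cfg.la_vortex_fraction * cfg.vortex_peak_speed
    omega = -peak / a_major * float(systolic_envelope(cfg, phase_fraction))
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    return -omega * (rr - cy) * la_region, omega * (cc - cx) * la_region


def _jet_weight(cfg: PhantomConfig) -> np.ndarray:
    """Spatial weight of the inflow jet: 1 on an axial plateau through the
    valve region, Gaussian decay across and beyond it."""
    H, W = cfg.grid
    g = cfg.geometry()
    cy, cx = g["lv_center"]
    hinge_row = g["hinge_row"]
    sig_x = g["gap_half_width"] / 2.0
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    across = np.exp(-((cc - cx) ** 2) / (2 * sig_x * sig_x))
    top = hinge_row - 0.75 * g["la_semi"][0]
    bottom = hinge_row + 0.5 * (cy - hinge_row)
    sig_y = 0.1 * H
    axial = np.ones((H, W))
    axial = np.where(rr < top, np.exp(-((rr - top) ** 2) / (2 * sig_y * sig_y)), axial)
    axial = np.where(rr > bottom, np.exp(-((rr - bottom) ** 2) / (2 * sig_y * sig_y)), axial)
    return across * axial


def make_flow_field(cfg: PhantomConfig) -> Tuple[FlowField, BloodPoolMask, ContourSet]:
    """Analytic truth flow, labelled chamber mask and contours for a config."""
    H, W = cfg.grid
    T = cfg.n_phases
    g = cfg.geometry()

    lv = _ellipse_interior(H, W, g["lv_center"], g["lv_semi"])
    la = _ellipse_interior(H, W, g["la_center"], g["la_semi"]) & ~lv
    labels2d = np.zeros((H, W), dtype=np.int16)
    labels2d[lv] = 1
    labels2d[la] = 2
    pool = labels2d > 0

    jet_w = _jet_weight(cfg)
    fractions = np.arange(T) / T
    vx = np.zeros((T, H, W))
    vy = np.zeros((T, H, W))
    for t, f in enumerate(fractions):
        wx, wy = vortex_component(cfg, f)
        ax_, ay_ = _la_vortex(cfg, f, la)
        jet = jet_speed_profile(cfg, f) * jet_w  # directed row-wards (LA -> LV)
        vx[t] = (wx + ax_) * pool
        vy[t] = (wy + ay_ + jet) * pool

    labels = np.broadcast_to(labels2d, (T, H, W)).copy()
    contours = _make_contours(cfg, T)
    return FlowField(vx=vx, vy=vy), BloodPoolMask(labels=labels), contours


def _make_contours(cfg: PhantomConfig, n_phases: int, n_points: int = 120) -> ContourSet:
    g = cfg.geometry()
    cy, cx = g["lv_center"]
    ay, ax = g["lv_semi"]
    gap = g["gap_half_width"]
    u = gap / ax
    v = -np.sqrt(1.0 - u * u)
    # Traverse the LV ellipse from the right hinge the long way round to the
    # left hinge, leaving the valve gap open; first/last vertices = hinges.
    th_right = np.arctan2(v, u)
    th_left = np.arctan2(v, -u) + 2 * np.pi
    theta = np.linspace(th_right, th_left, n_points)
    lv_poly = np.stack([cy + ay * np.sin(theta), cx + ax * np.cos(theta)], axis=1)

    lay, lax = g["la_semi"]
    lcy, lcx = g["la_center"]
    phi = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    la_poly = np.stack([lcy + lay * np.sin(phi), lcx + lax * np.cos(phi)], axis=1)

    cs = ContourSet()
    for t in range(n_phases):
        cs.add(t, 1, lv_poly)
        cs.add(t, 2, la_poly)
    return cs


def render_cine(truth: FlowField, mask: BloodPoolMask, cfg: PhantomConfig) -> CineSequence:
    """Render the speckle cine by advecting a seeded texture with the truth flow.

    Frame 0 is band-limited Gaussian noise on a bright pool; frame ``t+1`` is
    frame ``t`` pulled backward along the true displacement (bilinear
    sampling, constant padding). Optional speed-proportional attenuation and
    additive Gaussian noise are applied on top of the clean advected chain,
    so the chain itself stays deterministic in the flow.
    """
    T, H, W = truth.shape
    if (H, W) != cfg.grid or T != cfg.n_phases:
        raise ValidationError("truth shape inconsistent with config")
    disp = velocity_to_displacement(truth, cfg.meta)
    max_disp = disp.magnitude().max()
    if max_disp > H / 4:
        raise ValidationError(
            f"peak displacement {max_disp:.1f} px exceeds H/4 = {H / 4:.1f} px; phantom unrealistic"
        )

    rng = np.random.default_rng(cfg.seed)
    noise0 = rng.standard_normal((H, W))
    tex = gaussian_filter(noise0, cfg.texture_length)
    tex = (tex - tex.mean()) / (tex.std() + 1e-12)
    pool0 = mask.labels[0] > 0
    frame0 = np.where(pool0, 1.0 + 0.25 * tex, _BACKGROUND_INTENSITY)

    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    frames = np.empty((T, H, W))
    frames[0] = frame0
    for t in range(T - 1):
        src_r = rr - disp.dy[t]
        src_c = cc - disp.dx[t]
        warped = map_coordinates(
            frames[t], [src_r, src_c], order=1, mode="constant", cval=_BACKGROUND_INTENSITY
        )
        pool_next = mask.labels[t + 1] > 0
        nxt = np.where(pool_next, warped, _BACKGROUND_INTENSITY)
        if cfg.attenuation > 0:
            speed = np.hypot(truth.vx[t + 1], truth.vy[t + 1])
            nxt = np.where(pool_next, nxt * np.exp(-cfg.attenuation * speed), nxt)
        frames[t + 1] = nxt

    if cfg.noise_sd > 0:
        span = frames.max() - frames.min()
        frames = frames + rng.normal(0.0, cfg.noise_sd * span, size=frames.shape)

    return CineSequence(frames=frames, meta=cfg.meta)


def make_phantom(cfg: PhantomConfig) -> Phantom:
    """Generate a complete phantom: truth flow, masks, contours and cine."""
    truth, mask, contours = make_flow_field(cfg)
    cine = render_cine(truth, mask, cfg)
    return Phantom(cine=cine, truth=truth, mask=mask, contours=contours, config=cfg)


def make_training_config(seed: int = 0, **overrides) -> PhantomConfig:
    """A gentle-flow variant used for tracking experiments.

    Speeds are scaled so the per-frame displacement stays below about 2 px,
    the regime where speckle tracking from 30-phase cine is well posed.
    """
    base = dict(
        vortex_peak_speed=7.0,
        vortex_baseline=0.6,
        e_peak_speed=6.0,
        a_peak_speed=4.2,
        texture_length=1.5,
        noise_sd=0.0,
        seed=seed,
    )
    base.update(overrides)
    return PhantomConfig(**base)


def phantom_cohort(n_cases: int, base_seed: int = 0, **overrides) -> list:
    """Generate ``n_cases`` phantoms differing in texture seed and flow amplitude."""
    cohort = []
    for i in range(n_cases):
        amp = 0.7 + 0.55 * (i % 4) / 3.0  # vary flow strength across cases
        cfg = make_training_config(seed=base_seed + i, **overrides)
        cfg = replace(
            cfg,
            vortex_peak_speed=cfg.vortex_peak_speed * amp,
            e_peak_speed=cfg.e_peak_speed * amp,
            a_peak_speed=cfg.a_peak_speed * amp,
        )
        cohort.append(make_phantom(cfg))
    return cohort
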